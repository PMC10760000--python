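"""Train and apply the random-forest reliability filter.

Events whose partner replicate crossed 1.5 IQR (shared + almost-shared)
are the positive class; unshared events the negative.  A direction-specific
forest learns reliability from probe statistics, the calling replicate's
deltaIQR, cell-type proportions and probe annotation, then flags
low-probability calls as not retained.
"""

import pandas as pd

import semscan as ss

cfg = ss.SimulationConfig(n_probes=4000, n_reference=120, n_subjects=20, seed=17)
reference, _ = ss.simulate_reference(cfg)
stats = ss.attach_methylation_class(ss.compute_reference_stats(reference), seed=17)
sim = ss.simulate_replicate_pairs(cfg, stats)
annotation = ss.simulate_annotation(reference.index, seed=17)

calls_a = ss.detect_sems(sim.betas_a, stats)
calls_b = ss.detect_sems(sim.betas_b, stats)
pairs = ss.replicate_pairs(sim.sample_sheet)
records = ss.classify_records(
    ss.match_replicate_events(calls_a, calls_b, sim.betas_a, sim.betas_b, stats, pairs)
)
labels = ss.label_ground_truth(records)
a_map = dict(zip(pairs["sample_a"], pairs["subject_id"]))

grid = {"max_features": ["sqrt", 0.5], "max_samples": [0.8], "n_estimators": [250]}
filtered_a, filtered_b = [], []
for direction in ("hypo", "hyper"):
    key = records.assign(reliable=labels).query(
        "direction == @direction").set_index(["subject_id", "probe_id"])["reliable"]
    ca = calls_a[calls_a["direction"] == direction].copy()
    ca["subject_id"] = ca["sample_id"].map(a_map)
    y = key.reindex(pd.MultiIndex.from_frame(ca[["subject_id", "probe_id"]]))
    feats = ss.assemble_features(ca.drop(columns="subject_id"), stats,
                                 annotation, sim.sample_sheet)
    model = ss.train_filter(feats, y.astype(int).reset_index(drop=True),
                            direction=direction, seed=17, tuning_grid=grid)
    print(f"{direction}: held-out AUC {model.holdout_auc:.3f}")
    print(f"  selected features: {model.feature_names}")
    print(f"  top importances: "
          f"{model.importances.head(3).round(3).to_dict()}")
    filtered_a.append(ss.apply_filter(model, ca.drop(columns="subject_id"),
                                      feats, prob_threshold=0.5))
    cb = calls_b[calls_b["direction"] == direction].reset_index(drop=True)
    feats_b = ss.assemble_features(cb, stats, annotation, sim.sample_sheet)
    filtered_b.append(ss.apply_filter(model, cb, feats_b, prob_threshold=0.5))

effect = ss.evaluate_filter(pd.concat(filtered_a, ignore_index=True),
                            pd.concat(filtered_b, ignore_index=True), pairs)
print("\nfilter effect (shared proportion before/after, removal by subtype):")
print(effect.round(3).to_string(index=False))

# The filter raises the mean shared proportion in both directions and
# removes calls preferentially from the least reliable subtypes (hypoSEMs
# on unmethylated probes, hyperSEMs on methylated probes) — calls are
# flagged via `retained`, never deleted.
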