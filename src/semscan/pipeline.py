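"""End-to-end orchestration: stats -> detect -> reliability -> filter -> loads.

A run consumes file inputs named in a :class:`RunConfig`, executes the
stages in order (probe exclusion, methylation-status clustering, SEM
detection, optional replicate-reliability analysis and random-forest
filtering, load export) and writes every artifact plus a resolved-config
snapshot into the output directory.  Outputs are a pure function of the
inputs, the config and the seed; worker count never changes them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .detect import DIRECTIONS, compute_loads, detect_sems
from .errors import SemScanError, ValidationError
from .probe_stats import attach_methylation_class, compute_reference_stats
from .reliability import (
    category_summary,
    classify_records,
    counterpart_deltas,
    fit_delta_gmm,
    load_icc,
    match_replicate_events,
    shared_proportion,
)
from .rf_filter import (
    apply_filter,
    assemble_features,
    evaluate_filter,
    label_ground_truth,
    train_filter,
)

log = logging.getLogger("semscan")


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run (defaults match the method)."""

    reference: str
    query_a: str
    out_dir: str
    query_b: str | None = None
    annotation: str | None = None
    sample_sheet: str | None = None
    threshold: float = 3.0
    almost_shared_cutoff: float = 1.5
    exclude_snp_probes: bool = False
    cluster_k: int = 3
    rf_filter: bool = True
    rf_prob_threshold: float = 0.5
    rf_min_assoc: float = 0.1
    rf_tuning_grid: dict | None = None
    zero_log10: str = "na"
    seed: int = 0
    n_workers: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def snapshot(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full SEM pipeline described by ``config``.

    Returns the output directory.  Any stage failure aborts with the stage
    name prefixed to the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    config.snapshot(out / "config_resolved.yaml")

    def stage(name):
        log.info("stage: %s", name)
        return name

    current = stage("read inputs")
    try:
        reference = sio.read_beta_matrix(config.reference)
        query_a = sio.read_beta_matrix(config.query_a)
        query_b = sio.read_beta_matrix(config.query_b) if config.query_b else None
        annotation = sio.read_annotation(config.annotation) if config.annotation else None
        sheet = (
            sio.read_sample_sheet(config.sample_sheet) if config.sample_sheet else None
        )

        current = stage("reference statistics and probe clustering")
        stats = compute_reference_stats(reference)
        n_zero_iqr = int((stats["iqr"] <= 0).sum())
        log.info("probes: %d total, %d with IQR = 0 excluded from calling",
                 len(stats), n_zero_iqr)
        stats = attach_methylation_class(stats, k=config.cluster_k, seed=config.seed)
        stats.to_csv(out / "reference_stats.tsv", sep="\t")

        current = stage("SEM detection")
        calls_a = detect_sems(
            query_a, stats, threshold=config.threshold,
            exclude_snp_probes=config.exclude_snp_probes,
            annotation=annotation, n_workers=config.n_workers,
        )
        log.info("replicate A: %d calls across %d samples",
                 len(calls_a), query_a.shape[1])
        calls_b = None
        if query_b is not None:
            calls_b = detect_sems(
                query_b, stats, threshold=config.threshold,
                exclude_snp_probes=config.exclude_snp_probes,
                annotation=annotation, n_workers=config.n_workers,
            )
            log.info("replicate B: %d calls", len(calls_b))

        pairs = None
        records = None
        reliability: dict = {}
        if query_b is not None and sheet is not None and "replicate_index" in sheet.columns:
            current = stage("replicate reliability")
            pairs = sio.replicate_pairs(sheet)
            records = match_replicate_events(
                calls_a, calls_b, query_a, query_b, stats, pairs
            )
            records = classify_records(
                records, lower=config.almost_shared_cutoff, upper=config.threshold
            )
            records.to_csv(out / "reliability_records.tsv", sep="\t", index=False)
            summary = category_summary(records)
            summary.to_csv(out / "category_summary.tsv", sep="\t", index=False)
            props = shared_proportion(calls_a, calls_b, pairs)
            props.to_csv(out / "shared_proportions.tsv", sep="\t", index=False)
            loads_a = compute_loads(calls_a, query_a.columns, zero_log10=config.zero_log10)
            loads_b = compute_loads(calls_b, query_b.columns, zero_log10=config.zero_log10)
            for d in DIRECTIONS:
                reliability[f"icc_{d}"] = load_icc(
                    loads_a, loads_b, pairs, direction=d
                ).as_dict()
                reliability[f"mean_shared_{d}"] = float(
                    props.loc[props["direction"] == d, "prop_mean"].mean()
                )
                try:
                    gmm = fit_delta_gmm(
                        counterpart_deltas(
                            records[records["direction"] == d],
                            threshold=config.threshold,
                        ),
                        direction=d, seed=config.seed,
                    )
                    reliability[f"gmm_cutoff_{d}"] = gmm.cutoff
                except SemScanError as exc:
                    log.warning("GMM cutoff (%s) unavailable: %s", d, exc)

        if config.rf_filter:
            if records is None or annotation is None or sheet is None:
                raise ValidationError(
                    "RF filtering needs paired queries, annotation and sample sheet"
                )
            current = stage("random-forest reliability filter")
            labelled = label_ground_truth(records)
            rec_lab = records.assign(reliable=labelled)
            a_map = dict(zip(pairs["sample_a"], pairs["subject_id"]))
            b_map = dict(zip(pairs["sample_b"], pairs["subject_id"]))
            new_a, new_b = [], []
            for direction in DIRECTIONS:
                sub = rec_lab[rec_lab["direction"] == direction]
                key = sub.set_index(["subject_id", "probe_id"])["reliable"]
                # training features come from replicate A's view of each event
                ca = calls_a[calls_a["direction"] == direction].copy()
                ca["subject_id"] = ca["sample_id"].map(a_map)
                ca["reliable"] = key.reindex(
                    pd.MultiIndex.from_frame(ca[["subject_id", "probe_id"]])
                ).to_numpy()
                feats = assemble_features(ca, stats, annotation, sheet)
                model = train_filter(
                    feats, ca["reliable"].astype(int), direction=direction,
                    seed=config.seed, tuning_grid=config.rf_tuning_grid,
                    min_assoc=config.rf_min_assoc,
                )
                model.save(out / f"rf_model_{direction}.joblib")
                log.info("%s model: holdout AUC %.3f, features %s",
                         direction, model.holdout_auc, model.feature_names)
                reliability[f"rf_auc_{direction}"] = model.holdout_auc
                new_a.append(apply_filter(model, ca.drop(columns=["subject_id", "reliable"]),
                                          feats, config.rf_prob_threshold))
                cb = calls_b[calls_b["direction"] == direction].copy()
                featsb = assemble_features(cb, stats, annotation, sheet)
                new_b.append(apply_filter(model, cb, featsb, config.rf_prob_threshold))
            calls_a = pd.concat(new_a, ignore_index=True).sort_values(
                ["sample_id", "probe_id", "direction"], kind="mergesort"
            ).reset_index(drop=True)
            calls_b = pd.concat(new_b, ignore_index=True).sort_values(
                ["sample_id", "probe_id", "direction"], kind="mergesort"
            ).reset_index(drop=True)
            log.info("filter removed %d of %d calls (A+B)",
                     int((~calls_a["retained"]).sum() + (~calls_b["retained"]).sum()),
                     len(calls_a) + len(calls_b))
            effect = evaluate_filter(calls_a, calls_b, pairs)
            effect.to_csv(out / "filter_effect.tsv", sep="\t", index=False)
            loads_a_f = compute_loads(calls_a, query_a.columns,
                                      zero_log10=config.zero_log10, retained_only=True)
            loads_b_f = compute_loads(calls_b, query_b.columns,
                                      zero_log10=config.zero_log10, retained_only=True)
            for d in DIRECTIONS:
                reliability[f"icc_{d}_filtered"] = load_icc(
                    loads_a_f, loads_b_f, pairs, direction=d
                ).as_dict()
            sio.write_loads(loads_a_f, out / "loads_a_filtered.tsv")
            sio.write_loads(loads_b_f, out / "loads_b_filtered.tsv")

        current = stage("write calls and loads")
        sio.write_calls(calls_a, out / "calls_a.tsv")
        sio.write_loads(
            compute_loads(calls_a, query_a.columns, zero_log10=config.zero_log10),
            out / "loads_a.tsv",
        )
        if calls_b is not None:
            sio.write_calls(calls_b, out / "calls_b.tsv")
            sio.write_loads(
                compute_loads(calls_b, query_b.columns, zero_log10=config.zero_log10),
                out / "loads_b.tsv",
            )
        if reliability:
            with open(out / "reliability.json", "w") as fh:
                json.dump(reliability, fh, indent=2, sort_keys=True)
    except SemScanError as exc:
        raise type(exc)(f"[stage: {current}] {exc}") from exc
    log.info("run complete: %s", out)
    return out
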