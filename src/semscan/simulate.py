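"""Synthetic methylation cohorts with known outlier ground truth.

No public methylation dataset ships with labelled outlier provenance, so
this generator builds one: a reference cohort whose probes fall into three
methylation classes (mean beta around 0.08 / 0.50 / 0.84), and technical
replicate pairs in which *biological* outliers perturb the subject's latent
methylation state (visible in both replicates) while *artifacts* perturb a
single measurement.  Every event is recorded in a truth table, so detection
recall, replicate-sharing behaviour and filter performance can all be
scored exactly.

Design notes
------------
* Per-probe beta values are drawn from a Beta distribution moment-matched
  to the probe's class-dependent mean and a low-variance-enriched spread,
  which reproduces the boundary-compressed heteroscedastic noise of real
  beta values without clipping artifacts.
* Artifacts are placed preferentially on low-IQR probes with a
  heavier-tailed magnitude distribution, mirroring the empirical finding
  that non-replicating outliers concentrate on low-variance probes.
* Biological outlier counts are Poisson with an optional exponential age
  link, so older synthetic subjects carry more genuine outliers.

The generator is an invention of this package: it emulates the statistical
structure the analyses assume, not array chemistry (probe type I/II
differences, batch effects, genotype-driven trimodality are all absent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CELL_TYPES

#: typical whole-blood leukocyte composition used for the Dirichlet draw
_BLOOD_PROFILE = {"CD8T": 0.08, "CD4T": 0.15, "NK": 0.04, "B": 0.05, "Mono": 0.08, "Gran": 0.60}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Rates are expected event counts: ``bio_outlier_rate`` per subject per
    direction, ``artifact_rate`` per replicate per direction.  Magnitudes
    are in deltaIQR units (distance beyond the reference quartile divided
    by the IQR).
    """

    n_probes: int = 20_000
    n_reference: int = 200
    n_subjects: int = 40
    class_weights: tuple[float, float, float] = (0.35, 0.25, 0.40)
    class_centers: tuple[float, float, float] = (0.08, 0.50, 0.84)
    #: log10-normal spread of per-probe sd (low-variance enriched)
    probe_sd_log10_mean: float = -1.75
    probe_sd_log10_sd: float = 0.35
    #: technical noise sd as a log10-normal fraction of the probe sd; on
    #: low-variance array probes technical noise rivals biological spread
    tech_noise_log10_mean: float = -0.6
    tech_noise_log10_sd: float = 0.4
    bio_outlier_rate: float = 40.0
    age_linked: bool = True
    age_slope: float = 0.03  # per year, exponential link
    age_range: tuple[float, float] = (35.0, 75.0)
    artifact_rate: float = 6.0
    #: biological magnitude: base + Exp(scale); the base sits at the
    #: detection fence so near-threshold events occur naturally
    bio_magnitude_base: float = 3.0
    bio_magnitude_scale: float = 2.0
    #: artifact magnitude: base + Pareto tail (heavier-tailed than Exp)
    artifact_magnitude_base: float = 3.3
    artifact_pareto_shape: float = 2.5
    artifact_pareto_scale: float = 1.5
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_reference < 10:
            raise ValidationError("n_reference must be >= 10")
        if self.n_probes < 100:
            raise ValidationError("n_probes must be >= 100")
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        w = np.asarray(self.class_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValidationError("class_weights must be non-negative and sum to 1")
        c = np.asarray(self.class_centers, dtype=float)
        if not (np.diff(c) > 0).all() or (c <= 0).any() or (c >= 1).any():
            raise ValidationError("class_centers must be strictly increasing in (0, 1)")
        if self.bio_outlier_rate < 0 or self.artifact_rate < 0:
            raise ValidationError("event rates must be non-negative")
        if self.bio_outlier_rate + self.artifact_rate > self.n_probes / 4:
            raise ValidationError("event rates imply too many events per subject")
        return self


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _probe_model(config: SimulationConfig):
    """Deterministic per-probe generative parameters (class, mean, sd, ...)."""
    rng = _rng(config, 0)
    n = config.n_probes
    classes = rng.choice(3, size=n, p=np.asarray(config.class_weights) / np.sum(config.class_weights))
    centers = np.asarray(config.class_centers)[classes]
    means = np.clip(centers + rng.normal(0.0, 0.03, size=n), 0.02, 0.98)
    sds = 10.0 ** rng.normal(config.probe_sd_log10_mean, config.probe_sd_log10_sd, size=n)
    # a Beta distribution cannot exceed sd^2 = m(1-m); stay well inside
    sds = np.minimum(sds, 0.6 * np.sqrt(means * (1 - means)))
    v = means * (1 - means) / sds**2 - 1.0
    alpha = means * v
    beta = (1 - means) * v
    tech_sd = sds * 10.0 ** rng.normal(
        config.tech_noise_log10_mean, config.tech_noise_log10_sd, size=n
    )
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)], dtype=object)
    return probe_ids, classes, means, sds, alpha, beta, tech_sd


def simulate_reference(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the reference beta matrix and the true probe classes.

    Reference samples are measured the same way the replicates are: a
    latent biological beta per (probe, sample) plus the probe's technical
    measurement noise, clipped to [0, 1].  Returns (probes x samples
    DataFrame, Series of true class labels).
    """
    config.validate()
    probe_ids, classes, _means, _sds, alpha, beta, tech_sd = _probe_model(config)
    rng = _rng(config, 1)
    shape = (config.n_probes, config.n_reference)
    latent = rng.beta(alpha[:, None], beta[:, None], size=shape)
    values = np.clip(latent + rng.normal(0.0, tech_sd[:, None], size=shape), 0.0, 1.0)
    samples = [f"ref{j:04d}" for j in range(config.n_reference)]
    ref = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    ref.columns.name = "sample_id"
    names = np.array(["unmethylated", "intermediate", "methylated"], dtype=object)
    true_class = pd.Series(names[classes], index=ref.index, name="true_class")
    return ref, true_class


def simulate_annotation(probe_ids, seed: int = 0) -> pd.DataFrame:
    """A manifest-like annotation stub with plausible marginal frequencies.

    Synthetic: flags and categories are drawn independently of the outlier
    process, so annotation carries no reliability signal by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    n = len(probe_ids)
    df = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
    for col, freq in (("snp_at_sbe", 0.04), ("snp_at_cpg", 0.06), ("snp_in_probe", 0.12),
                      ("dmr_overlap", 0.10), ("dhs", 0.15), ("enhancer", 0.20)):
        df[col] = pd.array(rng.random(n) < freq, dtype="boolean")
    df["color_channel"] = pd.Categorical(
        rng.choice(["red", "green", "both"], size=n, p=[0.4, 0.3, 0.3]),
        categories=["red", "green", "both"],
    )
    df["genomic_location"] = pd.Categorical(
        rng.choice(["island", "shore", "shelf", "open_sea"], size=n, p=[0.3, 0.25, 0.1, 0.35]),
        categories=["island", "shore", "shelf", "open_sea", "unknown"],
    )
    df["regulatory_feature"] = pd.Categorical(
        rng.choice(["promoter", "gene_body", "intergenic", "unclassified"],
                   size=n, p=[0.3, 0.3, 0.25, 0.15]),
        categories=["promoter", "gene_body", "intergenic", "unclassified", "unknown"],
    )
    df["n_cpgs_in_probe"] = rng.poisson(1.2, size=n) + 1
    return df


@dataclass
class SimulatedPairs:
    """Replicate-pair simulation output."""

    betas_a: pd.DataFrame
    betas_b: pd.DataFrame
    truth: pd.DataFrame
    sample_sheet: pd.DataFrame
    clip_fraction: float


def simulate_replicate_pairs(
    config: SimulationConfig, reference_stats: pd.DataFrame
) -> SimulatedPairs:
    """Simulate paired technical replicates with injected ground truth.

    Each subject holds a latent beta per probe (drawn from the probe's
    generative distribution); replicate measurements add independent
    technical noise.  Biological outliers move the latent value to
    ``magnitude`` deltaIQR beyond the reference quartile (both replicates
    see it); artifacts overwrite a single replicate's measurement.
    Magnitudes and fences use the supplied reference statistics, so the
    intended deltaIQR is exact up to technical noise.
    """
    config.validate()
    probe_ids, _cls, _means, _sds, alpha, beta, tech_sd = _probe_model(config)
    stats = reference_stats.reindex(probe_ids)
    if stats["q1"].isna().any():
        raise ValidationError("reference stats do not cover the simulated probes")
    q1 = stats["q1"].to_numpy(float)
    q3 = stats["q3"].to_numpy(float)
    iqr = stats["iqr"].to_numpy(float)
    mean_ref = stats["mean"].to_numpy(float)

    n_p, n_s = config.n_probes, config.n_subjects
    rng = _rng(config, 2)
    ages = rng.uniform(*config.age_range, size=n_s)
    sexes = rng.choice(["F", "M"], size=n_s)
    profile = np.array([_BLOOD_PROFILE[c] for c in CELL_TYPES])
    cells = rng.dirichlet(profile * 80.0, size=n_s)

    latent = rng.beta(alpha[:, None], beta[:, None], size=(n_p, n_s))

    usable = iqr > 0
    # feasible fence targets must stay inside (0, 1) with headroom
    hypo_ok = usable & (q1 - config.artifact_magnitude_base * iqr > 0.01)
    hyper_ok = usable & (q3 + config.artifact_magnitude_base * iqr < 0.99)
    if hypo_ok.sum() < 50 or hyper_ok.sum() < 50:
        raise ValidationError("too few probes admit outliers beyond the fence")

    def _weights(mask, kind, direction):
        w = np.zeros(n_p)
        if kind == "bio":
            # genuine outliers favour methylated probes for hypo events and
            # unmethylated probes for hyper events
            base = mean_ref if direction == "hypo" else (1.0 - mean_ref)
            w[mask] = base[mask] ** 2
        else:
            # artifacts concentrate on low-variance probes
            w[mask] = (1.0 / (iqr[mask] + 1e-3)) ** 1.5
        total = w.sum()
        if total <= 0:
            raise ValidationError("no candidate probes for event placement")
        return w / total

    w_bio = {d: _weights(m, "bio", d) for d, m in (("hypo", hypo_ok), ("hyper", hyper_ok))}
    w_art = {d: _weights(m, "art", d) for d, m in (("hypo", hypo_ok), ("hyper", hyper_ok))}

    def _target(p_idx, magnitude, direction):
        if direction == "hypo":
            return np.clip(q1[p_idx] - magnitude * iqr[p_idx], 0.0005, 0.9995)
        return np.clip(q3[p_idx] + magnitude * iqr[p_idx], 0.0005, 0.9995)

    subjects = [f"S{i:03d}" for i in range(n_s)]
    truth_rows: list[tuple] = []
    # --- biological outliers: shift the latent value ---------------------
    for si, subject in enumerate(subjects):
        lam = config.bio_outlier_rate
        if config.age_linked:
            mid = 0.5 * (config.age_range[0] + config.age_range[1])
            lam = lam * np.exp(config.age_slope * (ages[si] - mid))
        for direction in ("hypo", "hyper"):
            n_ev = rng.poisson(lam)
            if n_ev == 0:
                continue
            p_idx = rng.choice(n_p, size=n_ev, replace=False, p=w_bio[direction])
            mags = config.bio_magnitude_base + rng.exponential(
                config.bio_magnitude_scale, size=n_ev
            )
            latent[p_idx, si] = _target(p_idx, mags, direction)
            for p, m in zip(p_idx, mags):
                truth_rows.append(
                    (subject, probe_ids[p], direction, "biological", float(m), "both")
                )

    noise_a = rng.normal(0.0, tech_sd[:, None], size=(n_p, n_s))
    noise_b = rng.normal(0.0, tech_sd[:, None], size=(n_p, n_s))
    raw_a = latent + noise_a
    raw_b = latent + noise_b
    clip_fraction = float(
        np.mean((raw_a < 0) | (raw_a > 1)) / 2 + np.mean((raw_b < 0) | (raw_b > 1)) / 2
    )
    a = np.clip(raw_a, 0.0, 1.0)
    b = np.clip(raw_b, 0.0, 1.0)

    # --- artifacts: overwrite one replicate's measurement ----------------
    for si, subject in enumerate(subjects):
        for rep, mat in (("a_only", a), ("b_only", b)):
            for direction in ("hypo", "hyper"):
                n_ev = rng.poisson(config.artifact_rate)
                if n_ev == 0:
                    continue
                p_idx = rng.choice(n_p, size=n_ev, replace=False, p=w_art[direction])
                mags = config.artifact_magnitude_base + config.artifact_pareto_scale * rng.pareto(
                    config.artifact_pareto_shape, size=n_ev
                )
                mat[p_idx, si] = _target(p_idx, mags, direction)
                for p, m in zip(p_idx, mags):
                    truth_rows.append(
                        (subject, probe_ids[p], direction, "artifact", float(m), rep)
                    )

    index = pd.Index(probe_ids, name="probe_id")
    samples_a = [f"{s}_r1" for s in subjects]
    samples_b = [f"{s}_r2" for s in subjects]
    betas_a = pd.DataFrame(a, index=index, columns=samples_a)
    betas_b = pd.DataFrame(b, index=index, columns=samples_b)
    betas_a.columns.name = betas_b.columns.name = "sample_id"

    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "probe_id", "direction", "kind", "magnitude", "affected_replicates"],
    ).sort_values(["subject_id", "probe_id", "direction"], kind="mergesort").reset_index(drop=True)

    rows = []
    for si, subject in enumerate(subjects):
        for rep_i, sample in ((1, samples_a[si]), (2, samples_b[si])):
            row = {
                "sample_id": sample,
                "subject_id": subject,
                "replicate_index": rep_i,
                "age": round(float(ages[si]), 1),
                "sex": sexes[si],
            }
            row.update({c: float(cells[si, j]) for j, c in enumerate(CELL_TYPES)})
            rows.append(row)
    sheet = pd.DataFrame(rows)
    return SimulatedPairs(
        betas_a=betas_a,
        betas_b=betas_b,
        truth=truth,
        sample_sheet=sheet,
        clip_fraction=clip_fraction,
    )


def truth_confusion(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    truth: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Score detected calls against the injected ground truth.

    An injected event counts as detected when a call exists in at least one
    of its affected replicates; calls matching no injected event are
    spurious (typically natural tail draws of the latent distribution).
    Returns per-kind rows of detected / missed / recall plus a spurious
    tally.
    """
    a_map = dict(zip(pairs["sample_a"], pairs["subject_id"]))
    b_map = dict(zip(pairs["sample_b"], pairs["subject_id"]))

    def _events(calls, mapping):
        ev = calls[["sample_id", "probe_id", "direction"]].copy()
        ev["subject_id"] = ev["sample_id"].map(mapping)
        return set(zip(ev["subject_id"], ev["probe_id"], ev["direction"]))

    in_a = _events(calls_a, a_map)
    in_b = _events(calls_b, b_map)

    rows = []
    matched: set[tuple] = set()
    for kind, grp in truth.groupby("kind"):
        detected = 0
        for _, r in grp.iterrows():
            key = (r["subject_id"], r["probe_id"], r["direction"])
            hit = False
            if r["affected_replicates"] in ("both", "a_only") and key in in_a:
                hit = True
            if r["affected_replicates"] in ("both", "b_only") and key in in_b:
                hit = True
            if hit:
                detected += 1
                matched.add(key)
        n = len(grp)
        rows.append((kind, n, detected, n - detected, detected / n if n else np.nan))
    spurious = len((in_a | in_b) - set(
        zip(truth["subject_id"], truth["probe_id"], truth["direction"])
    ))
    out = pd.DataFrame(rows, columns=["kind", "injected", "detected", "missed", "recall"])
    out.attrs["spurious_events"] = spurious
    return out
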