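"""Technical-replicate reliability of SEM calls.

When the same DNA sample is assayed twice, a genuine biological outlier
should appear in both measurements while a technical artifact appears in
one.  This module quantifies that along three axes:

* event level — every SEM seen in at least one replicate is matched with
  the deltaIQR of its counterpart and classified as *shared* (both beyond
  the 3-IQR fence), *almost-shared* (counterpart between 1.5 and 3 IQR) or
  *unshared* (counterpart at or below 1.5 IQR).  The 1.5 boundary sits at
  the antimode of the empirically bimodal counterpart-deltaIQR
  distribution; a two-component Gaussian mixture fit recovers it as the
  density-intersection point between the component means.
* sample level — the proportion of each replicate's calls that are shared
  with its partner.
* load level — the intraclass correlation ICC(2,1) (single-rater,
  absolute-agreement, two-way random-effects) of per-subject SEM loads
  between replicates, optionally after residualizing out a covariate such
  as age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.mixture import GaussianMixture

from .detect import DIRECTIONS, compute_loads, detect_sems
from .errors import ConvergenceError, DegenerateModelError, PairingError, ValidationError
from .probe_stats import attach_methylation_class, compute_reference_stats

CATEGORIES = ["shared", "almost_shared", "unshared"]


# ---------------------------------------------------------------------------
# event matching and classification
# ---------------------------------------------------------------------------


def match_replicate_events(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    betas_a: pd.DataFrame,
    betas_b: pd.DataFrame,
    stats: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Match SEM events across replicate pairs.

    For every unique (subject, probe, direction) called in *either*
    replicate, record the deltaIQR of both replicates — including the one
    that did not reach the detection fence (its deltaIQR may be negative,
    i.e. inside the box).

    ``pairs`` comes from :func:`semscan.io.replicate_pairs`.
    """
    a_map = dict(zip(pairs["sample_a"], pairs["subject_id"]))
    b_map = dict(zip(pairs["sample_b"], pairs["subject_id"]))
    for name, calls, mapping in (("a", calls_a, a_map), ("b", calls_b, b_map)):
        unpaired = set(calls["sample_id"]) - set(mapping)
        if unpaired:
            raise PairingError(
                f"calls_{name} contain unpaired sample(s) {sorted(unpaired)[:5]}"
            )

    ev_a = calls_a[["sample_id", "probe_id", "direction"]].copy()
    ev_a["subject_id"] = ev_a["sample_id"].map(a_map)
    ev_b = calls_b[["sample_id", "probe_id", "direction"]].copy()
    ev_b["subject_id"] = ev_b["sample_id"].map(b_map)
    events = (
        pd.concat([ev_a, ev_b])[["subject_id", "probe_id", "direction"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    if len(events) == 0:
        return pd.DataFrame(
            columns=["subject_id", "probe_id", "direction", "delta_iqr_a", "delta_iqr_b"]
        )

    pair_idx = pairs.set_index("subject_id")
    q1 = stats["q1"]
    q3 = stats["q3"]
    iqr = stats["iqr"]

    def _delta(betas: pd.DataFrame, sample_col: str) -> np.ndarray:
        samples = pair_idx.loc[events["subject_id"], sample_col].to_numpy()
        b = betas.to_numpy(dtype=float)[
            betas.index.get_indexer(events["probe_id"]),
            betas.columns.get_indexer(samples),
        ]
        p = events["probe_id"]
        v1, v3, vi = (s.loc[p].to_numpy(dtype=float) for s in (q1, q3, iqr))
        hypo = events["direction"].to_numpy() == "hypo"
        return np.where(hypo, (v1 - b) / vi, (b - v3) / vi)

    missing = set(events["probe_id"]) - set(stats.index)
    if missing:
        raise ValidationError(f"called probes missing from stats: {sorted(missing)[:5]}")
    for betas, col in ((betas_a, "sample_a"), (betas_b, "sample_b")):
        if not set(events["probe_id"]) <= set(betas.index):
            raise ValidationError("replicate beta matrix does not cover all called probes")

    records = events.copy()
    records["delta_iqr_a"] = _delta(betas_a, "sample_a")
    records["delta_iqr_b"] = _delta(betas_b, "sample_b")
    return records.sort_values(
        ["subject_id", "probe_id", "direction"], kind="mergesort"
    ).reset_index(drop=True)


def classify_records(
    records: pd.DataFrame, lower: float = 1.5, upper: float = 3.0
) -> pd.DataFrame:
    """Attach the shared / almost_shared / unshared category to each record.

    shared: both replicates beyond ``upper``; almost_shared: the weaker one
    in (lower, upper]; unshared: the weaker one at or below ``lower``.
    """
    if not lower < upper:
        raise ValidationError(f"need lower < upper, got {lower} >= {upper}")
    out = records.copy()
    weaker = np.minimum(out["delta_iqr_a"], out["delta_iqr_b"])
    out["category"] = np.select(
        [weaker > upper, weaker > lower], ["shared", "almost_shared"], "unshared"
    )
    return out


def category_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Pooled category counts and percentages per direction."""
    rows = []
    for direction, grp in records.groupby("direction"):
        n = len(grp)
        for cat in CATEGORIES:
            c = int((grp["category"] == cat).sum())
            rows.append((direction, cat, c, 100.0 * c / n if n else np.nan))
    return pd.DataFrame(rows, columns=["direction", "category", "count", "percent"])


def counterpart_deltas(records: pd.DataFrame, threshold: float = 3.0) -> pd.Series:
    """The deltaIQR of the *other* replicate for each matched event.

    For an event that reached the detection fence in replicate A, this is
    the deltaIQR of replicate B (and vice versa); when both replicates
    reached it, replicate B is reported as the counterpart.  This is the
    distribution whose bimodality motivates the almost-shared boundary.
    """
    return pd.Series(
        np.where(
            records["delta_iqr_a"] > threshold,
            records["delta_iqr_b"],
            records["delta_iqr_a"],
        ),
        index=records.index,
        name="counterpart_delta_iqr",
    )


# ---------------------------------------------------------------------------
# Gaussian-mixture cutoff
# ---------------------------------------------------------------------------


@dataclass
class GmmCutoff:
    """Two-component mixture fit of counterpart deltaIQR values."""

    direction: str
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    cutoff: float

    def __post_init__(self):
        if not self.means[0] < self.cutoff < self.means[1]:
            raise DegenerateModelError(
                f"cutoff {self.cutoff:.3f} not between component means {self.means}"
            )


def gaussian_mixture_intersection(
    m1: float, s1: float, w1: float, m2: float, s2: float, w2: float
) -> float:
    """Point between the two means where the weighted densities are equal."""
    if m2 < m1:
        m1, s1, w1, m2, s2, w2 = m2, s2, w2, m1, s1, w1
    if not m2 - m1 > 1e-9:
        raise DegenerateModelError("mixture components have identical means")

    def logdiff(x):
        return (np.log(w1) + sps.norm.logpdf(x, m1, s1)) - (
            np.log(w2) + sps.norm.logpdf(x, m2, s2)
        )

    lo, hi = m1, m2
    if logdiff(lo) * logdiff(hi) > 0:
        raise DegenerateModelError(
            "no density intersection between component means"
        )
    return float(optimize.brentq(logdiff, lo, hi, xtol=1e-10))


def fit_delta_gmm(
    deltas,
    direction: str = "hypo",
    seed: int = 0,
    n_restarts: int = 10,
    trim_quantile: float | None = 0.98,
) -> GmmCutoff:
    """Fit a 2-component Gaussian mixture to counterpart deltaIQR values by EM.

    The returned ``cutoff`` — where the two weighted component densities
    intersect between their means — separates the replicating mode from the
    artifact mode and is the model-based analogue of the fixed 1.5 boundary.

    deltaIQR distributions have extended upper tails (tiny-IQR probes can
    produce deltas of hundreds) that would capture a mixture component of
    their own; values beyond ``trim_quantile`` are dropped before fitting.
    """
    x = np.asarray(deltas, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 50:
        raise ValidationError(f"need >= 50 deltaIQR values, got {len(x)}")
    if trim_quantile is not None:
        x = x[x <= np.quantile(x, trim_quantile)]
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_restarts,
        random_state=seed,
        max_iter=500,
    ).fit(x[:, None])
    if not gm.converged_:
        raise ConvergenceError("EM failed to converge across all restarts")
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    cutoff = gaussian_mixture_intersection(
        means[0], sds[0], weights[0], means[1], sds[1], weights[1]
    )
    return GmmCutoff(
        direction=direction,
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# shared proportions
# ---------------------------------------------------------------------------


def shared_proportion(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, pairs: pd.DataFrame,
    retained_only: bool = False,
) -> pd.DataFrame:
    """Per-replicate proportion of SEM calls shared with the partner replicate.

    For replicate r of a subject: |calls_r intersect calls_other| / |calls_r|,
    computed per direction; a replicate with no calls yields NaN.  The
    subject summary is the mean of the two replicate proportions.
    """
    if retained_only:
        calls_a = calls_a[calls_a["retained"].astype(bool)]
        calls_b = calls_b[calls_b["retained"].astype(bool)]
    a_map = dict(zip(pairs["sample_a"], pairs["subject_id"]))
    b_map = dict(zip(pairs["sample_b"], pairs["subject_id"]))

    def _sets(calls, mapping):
        out: dict[tuple[str, str], set[str]] = {}
        for (sample, direction), grp in calls.groupby(["sample_id", "direction"]):
            out[(mapping[sample], direction)] = set(grp["probe_id"])
        return out

    sa = _sets(calls_a, a_map)
    sb = _sets(calls_b, b_map)
    rows = []
    for subject in pairs["subject_id"]:
        for direction in DIRECTIONS:
            A = sa.get((subject, direction), set())
            B = sb.get((subject, direction), set())
            pa = len(A & B) / len(A) if A else np.nan
            pb = len(A & B) / len(B) if B else np.nan
            mean = np.nanmean([pa, pb]) if not (np.isnan(pa) and np.isnan(pb)) else np.nan
            rows.append((subject, direction, pa, pb, mean))
    return pd.DataFrame(
        rows, columns=["subject_id", "direction", "prop_a", "prop_b", "prop_mean"]
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


@dataclass
class IccResult:
    """ICC(2,1): single-rater, absolute-agreement, two-way random effects."""

    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int = 2
    adjusted_for: str | None = None

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
            "adjusted_for": self.adjusted_for,
        }


def icc_2_1(values, confidence: float = 0.95) -> IccResult:
    """ICC(2,1) of an n_subjects x k_raters table (no missing cells).

    Computed from the two-way ANOVA decomposition:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),
    with the standard F-based confidence interval for this form.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("need an n x k table with k >= 2 raters")
    n, k = x.shape
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    if np.isnan(x).any():
        raise ValidationError("missing cells are not allowed in the ICC table")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValidationError("zero total variance; ICC undefined")

    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # Shrout & Fleiss F-based interval for ICC(2,1)
    alpha = 1.0 - confidence
    fj = msc / mse if mse > 0 else np.inf
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
    else:  # perfect agreement; the interval collapses
        lower = upper = icc
    return IccResult(
        estimate=float(icc),
        ci_low=float(min(lower, icc)),
        ci_high=float(max(upper, icc)),
        n_subjects=n,
        n_raters=k,
    )


def adjusted_icc(values, covariate, confidence: float = 0.95) -> IccResult:
    """ICC(2,1) after residualizing both replicate columns on a covariate.

    Values are stacked, regressed on the covariate by least squares (with
    intercept), and the residuals re-form the n x 2 table.  A constant
    covariate falls back to the unadjusted ICC with a warning.
    """
    x = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if x.ndim != 2 or len(c) != x.shape[0]:
        raise ValidationError("covariate must align with the subject rows")
    if np.ptp(c) == 0:
        warnings.warn("constant covariate; falling back to unadjusted ICC")
        return icc_2_1(x, confidence=confidence)
    n, k = x.shape
    design = np.column_stack([np.ones(n * k), np.tile(c, k)])
    stacked = x.T.ravel()
    coef, *_ = np.linalg.lstsq(design, stacked, rcond=None)
    resid = (stacked - design @ coef).reshape(k, n).T
    out = icc_2_1(resid, confidence=confidence)
    out.adjusted_for = "covariate"
    return out


def load_icc(
    loads_a: pd.DataFrame,
    loads_b: pd.DataFrame,
    pairs: pd.DataFrame,
    direction: str,
    subtype: str = "total",
    scale: str = "log10",
    covariate: pd.Series | None = None,
) -> IccResult:
    """ICC(2,1) of per-subject SEM loads between replicates.

    Operates on log10 loads by default (zero counts handled as log10(n+1)
    so the table has no missing cells); ``scale="count"`` uses raw counts.
    """
    def _col(loads, sample_col):
        sub = loads[(loads["direction"] == direction) & (loads["subtype"] == subtype)]
        per_sample = sub.set_index("sample_id")["count"]
        counts = per_sample.loc[pairs[sample_col]].to_numpy(dtype=float)
        return np.log10(counts + 1.0) if scale == "log10" else counts

    table = np.column_stack([_col(loads_a, "sample_a"), _col(loads_b, "sample_b")])
    if covariate is not None:
        cov = covariate.loc[pairs["subject_id"]].to_numpy(dtype=float)
        res = adjusted_icc(table, cov)
        res.adjusted_for = covariate.name or "covariate"
        return res
    return icc_2_1(table)


# ---------------------------------------------------------------------------
# reference-size sweep
# ---------------------------------------------------------------------------


def reference_size_curve(
    reference: pd.DataFrame,
    betas_a: pd.DataFrame,
    betas_b: pd.DataFrame,
    pairs: pd.DataFrame,
    sizes,
    n_draws: int = 3,
    seed: int = 0,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Reliability as a function of reference-cohort size.

    For each size, ``n_draws`` random sample subsets of the reference are
    drawn; the full detect-and-match pipeline runs on each draw and the
    mean shared proportion and load ICC per direction are averaged over
    draws.  Sizes below 10 are rejected (quartiles too unstable).
    """
    sizes = list(sizes)
    if any(s < 10 for s in sizes):
        raise ValidationError("reference sizes below 10 are not supported")
    if max(sizes) > reference.shape[1]:
        raise ValidationError("requested size exceeds the reference sample count")
    rng = np.random.default_rng(seed)
    all_samples = np.asarray(reference.columns)
    rows = []
    for size in sizes:
        acc = {d: {"shared": [], "icc": []} for d in DIRECTIONS}
        for _ in range(n_draws):
            cols = rng.choice(all_samples, size=size, replace=False)
            ref = reference.loc[:, cols]
            stats = compute_reference_stats(ref)
            try:
                stats = attach_methylation_class(stats, seed=seed)
            except Exception:
                pass  # class labels are incidental to the sweep
            ca = detect_sems(betas_a, stats, threshold=threshold)
            cb = detect_sems(betas_b, stats, threshold=threshold)
            props = shared_proportion(ca, cb, pairs)
            la = compute_loads(ca, betas_a.columns)
            lb = compute_loads(cb, betas_b.columns)
            for d in DIRECTIONS:
                p = props.loc[props["direction"] == d, "prop_mean"].mean()
                acc[d]["shared"].append(p)
                try:
                    acc[d]["icc"].append(
                        load_icc(la, lb, pairs, direction=d).estimate
                    )
                except ValidationError:
                    acc[d]["icc"].append(np.nan)
        for d in DIRECTIONS:
            rows.append(
                (
                    size,
                    d,
                    float(np.nanmean(acc[d]["shared"])),
                    float(np.nanmean(acc[d]["icc"])),
                    n_draws,
                )
            )
    return pd.DataFrame(
        rows, columns=["size", "direction", "mean_shared_proportion", "mean_icc", "n_draws"]
    )
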