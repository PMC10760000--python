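"""Per-probe reference statistics and methylation-status classification.

The reference cohort defines, for every CpG probe, the location and spread
of its beta-value distribution.  Quartiles use linear interpolation between
order statistics (R's default "type 7" convention), because the outlier
fences Q1 - 3*IQR and Q3 + 3*IQR inherit directly from them.  Skewness and
kurtosis are plain moment ratios (m3 / m2^1.5 and m4 / m2^2, kurtosis not
excess-centered), matching the convention of R's ``moments`` package.

Probes are classified into unmethylated / intermediate / methylated status
by k-means on their reference mean beta; clusters are relabelled by
ascending center so the mapping is deterministic.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DegenerateModelError, ValidationError

STAT_COLUMNS = [
    "n_ref", "mean", "median", "q1", "q3", "iqr", "sd", "mad",
    "min", "max", "range", "sum", "cv", "skewness", "kurtosis",
]

METHYLATION_CLASSES = ["unmethylated", "intermediate", "methylated"]


def compute_reference_stats(reference: pd.DataFrame) -> pd.DataFrame:
    """Compute per-probe summary statistics of a reference beta matrix.

    Parameters
    ----------
    reference
        Probes x samples beta matrix; missing values are excluded probe-wise.

    Returns
    -------
    DataFrame indexed by probe_id with :data:`STAT_COLUMNS` plus a boolean
    ``usable`` column (n_ref >= 2 and IQR > 0); SEMs are undefined on
    probes that fail it.
    """
    if reference.shape[0] == 0 or reference.shape[1] == 0:
        raise ValidationError("reference matrix is empty")
    x = reference.to_numpy(dtype=float)
    n_ref = np.sum(~np.isnan(x), axis=1)

    with warnings.catch_warnings():
        # all-NaN probes legitimately produce NaN statistics
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=1)
        q1, median, q3 = np.nanquantile(x, [0.25, 0.5, 0.75], axis=1)
        sd = np.nanstd(x, axis=1, ddof=1)
        mn = np.nanmin(x, axis=1)
        mx = np.nanmax(x, axis=1)
        total = np.nansum(x, axis=1)
        # median absolute deviation with the 1.4826 consistency constant
        mad = 1.4826 * np.nanmedian(np.abs(x - median[:, None]), axis=1)
        centered = x - mean[:, None]
        m2 = np.nanmean(centered**2, axis=1)
        m3 = np.nanmean(centered**3, axis=1)
        m4 = np.nanmean(centered**4, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            skewness = m3 / m2**1.5
            kurtosis = m4 / m2**2
            cv = sd / mean

    stats = pd.DataFrame(
        {
            "n_ref": n_ref,
            "mean": mean,
            "median": median,
            "q1": q1,
            "q3": q3,
            "iqr": q3 - q1,
            "sd": sd,
            "mad": mad,
            "min": mn,
            "max": mx,
            "range": mx - mn,
            "sum": total,
            "cv": cv,
            "skewness": skewness,
            "kurtosis": kurtosis,
        },
        index=reference.index.copy(),
    )
    stats.index.name = "probe_id"
    stats["usable"] = (stats["n_ref"] >= 2) & (stats["iqr"] > 0)
    return stats


def cluster_methylation_status(
    stats: pd.DataFrame,
    k: int = 3,
    features: Sequence[str] = ("mean",),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[pd.Series, np.ndarray]:
    """Assign each probe a methylation-status class by k-means.

    Clustering runs on the reference mean beta by default (additional
    summary-statistic features may be supplied).  Clusters are relabelled in
    ascending order of their center along the first feature; with the
    default k = 3 the labels are unmethylated < intermediate < methylated.

    Returns
    -------
    (labels, centers)
        ``labels`` is a Series indexed like ``stats``; ``centers`` is the
        (k, n_features) array after reordering.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(stats) == 0:
        raise ValidationError("empty reference statistics")
    X = stats.loc[:, list(features)].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    if np.unique(X[ok], axis=0).shape[0] < k:
        raise DegenerateModelError(
            f"fewer than k={k} distinct probe feature vectors; cannot cluster"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X[ok])
    order = np.argsort(km.cluster_centers_[:, 0])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    names = METHYLATION_CLASSES if k == 3 else [f"class_{i}" for i in range(k)]
    labels = pd.Series(pd.NA, index=stats.index, dtype="object", name="methylation_class")
    labels.iloc[np.flatnonzero(ok)] = [names[relabel[c]] for c in raw]
    centers = km.cluster_centers_[order]
    return labels, centers


def attach_methylation_class(
    stats: pd.DataFrame, k: int = 3, features: Sequence[str] = ("mean",), seed: int = 0
) -> pd.DataFrame:
    """Convenience: return ``stats`` with a ``methylation_class`` column."""
    labels, _ = cluster_methylation_status(stats, k=k, features=features, seed=seed)
    out = stats.copy()
    out["methylation_class"] = labels
    return out


def export_consensus_probe_sets(
    stats_list: Sequence[pd.DataFrame],
) -> dict[str, set[str]]:
    """Intersect per-class probe assignments across several reference datasets.

    Each input must carry a ``methylation_class`` column.  For every class
    the result holds the probes assigned that class in *every* input, the
    basis for a portable reference probe set.
    """
    if len(stats_list) < 2:
        raise ValidationError("need at least two ReferenceStats tables")
    for s in stats_list:
        if "methylation_class" not in s.columns:
            raise ValidationError("stats table lacks methylation_class; cluster first")
    universe = set(stats_list[0].index)
    for s in stats_list[1:]:
        universe &= set(s.index)
    if not universe:
        warnings.warn("probe universes are disjoint; consensus sets are empty")
    classes = sorted(
        set().union(*(set(s["methylation_class"].dropna()) for s in stats_list))
    )
    out: dict[str, set[str]] = {}
    for cls in classes:
        sets = [
            set(s.index[s["methylation_class"] == cls]) & universe
            for s in stats_list
        ]
        out[cls] = set.intersection(*sets) if sets else set()
    return out
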