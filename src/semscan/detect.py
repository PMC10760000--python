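"""SEM calling against a reference and aggregation into per-sample loads.

A stochastic epigenetic mutation (SEM) is a beta value falling strictly
beyond the Tukey-style fence at ``threshold`` interquartile ranges outside
the reference box: hypoSEM below Q1 - t*IQR, hyperSEM above Q3 + t*IQR.
Probes with IQR = 0 carry no information about outliers and are excluded
before calling.  The signed distance beyond the box in IQR units is the
"deltaIQR": (Q1 - beta)/IQR for the hypo direction, (beta - Q3)/IQR for
hyper; values inside the box are negative.

Calls are invariant to probe/sample ordering and to the number of parallel
workers: probe chunks are processed independently and the merged table is
sorted by (sample_id, probe_id, direction).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .errors import ValidationError
from .io import CALL_COLUMNS

DIRECTIONS = ["hypo", "hyper"]
SUBTYPES = ["total", "unmethylated", "intermediate", "methylated"]


def delta_iqr(beta, q1, q3, iqr, direction: str):
    """Distance of ``beta`` beyond the reference box, in IQR units.

    hypo: (q1 - beta) / iqr;  hyper: (beta - q3) / iqr.  Accepts scalars or
    aligned arrays; negative values mean the beta sits inside the box.
    """
    iqr = np.asarray(iqr, dtype=float)
    if np.any(iqr <= 0):
        raise ValidationError("deltaIQR is undefined for probes with IQR <= 0")
    beta = np.asarray(beta, dtype=float)
    if direction == "hypo":
        out = (np.asarray(q1, dtype=float) - beta) / iqr
    elif direction == "hyper":
        out = (beta - np.asarray(q3, dtype=float)) / iqr
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if out.ndim == 0 else out


def _snp_probe_mask(annotation: pd.DataFrame) -> pd.Series:
    flags = annotation[["snp_at_sbe", "snp_at_cpg", "snp_in_probe"]]
    return flags.fillna(False).any(axis=1)


def _detect_chunk(
    betas: np.ndarray,
    q1: np.ndarray,
    q3: np.ndarray,
    iqr: np.ndarray,
    probe_ids: np.ndarray,
    sample_ids: np.ndarray,
    classes: np.ndarray,
    threshold: float,
) -> pd.DataFrame:
    lo = q1 - threshold * iqr
    hi = q3 + threshold * iqr
    with np.errstate(invalid="ignore"):
        hypo = betas < lo[:, None]
        hyper = betas > hi[:, None]
    frames = []
    for direction, mask in (("hypo", hypo), ("hyper", hyper)):
        pi, si = np.nonzero(mask)
        if len(pi) == 0:
            continue
        b = betas[pi, si]
        d = (q1[pi] - b) / iqr[pi] if direction == "hypo" else (b - q3[pi]) / iqr[pi]
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids[si],
                    "probe_id": probe_ids[pi],
                    "direction": direction,
                    "beta": b,
                    "delta_iqr": d,
                    "methylation_class": classes[pi],
                    "rf_probability": np.nan,
                    "retained": True,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def detect_sems(
    query: pd.DataFrame,
    stats: pd.DataFrame,
    threshold: float = 3.0,
    exclude_snp_probes: bool = False,
    annotation: pd.DataFrame | None = None,
    n_workers: int = 1,
    chunk_size: int = 20_000,
) -> pd.DataFrame:
    """Call hypo/hyperSEMs in ``query`` against reference ``stats``.

    Parameters
    ----------
    query
        Probes x samples beta matrix to screen.
    stats
        Reference statistics from :func:`compute_reference_stats`
        (optionally with a ``methylation_class`` column).
    threshold
        Fence width in IQR units (default 3); a call requires the beta to be
        *strictly* beyond the fence.
    exclude_snp_probes
        Drop probes whose annotation flags a SNP at the SBE, CpG, or
        anywhere in the probe body before calling (requires ``annotation``).
    n_workers
        Probe chunks processed in parallel; the output is identical for any
        worker count.

    Returns
    -------
    Long-format call table with one row per (sample, probe, direction)
    event, sorted by (sample_id, probe_id, direction).
    """
    if threshold <= 0:
        raise ValidationError("detection threshold must be positive")
    common = query.index.intersection(stats.index)
    skipped = len(query.index) - len(common)
    if skipped:
        warnings.warn(f"{skipped} query probes absent from reference stats; skipped")
    stats = stats.loc[common]
    usable = stats["usable"] if "usable" in stats.columns else stats["iqr"] > 0
    usable = usable.fillna(False) & (stats["iqr"] > 0)
    if exclude_snp_probes:
        if annotation is None:
            raise ValidationError("SNP probe exclusion requires an annotation table")
        snp = _snp_probe_mask(annotation)
        snp = snp.reindex(common).fillna(False)
        usable &= ~snp
    keep = common[usable.to_numpy(dtype=bool)]
    if len(keep) == 0:
        raise ValidationError("no usable probes (all IQR = 0, missing, or excluded)")

    betas = query.loc[keep].to_numpy(dtype=float)
    q1 = stats.loc[keep, "q1"].to_numpy(dtype=float)
    q3 = stats.loc[keep, "q3"].to_numpy(dtype=float)
    iqr = stats.loc[keep, "iqr"].to_numpy(dtype=float)
    if "methylation_class" in stats.columns:
        classes = stats.loc[keep, "methylation_class"].astype("object").to_numpy()
    else:
        classes = np.full(len(keep), None, dtype=object)
    probe_ids = keep.to_numpy(dtype=object)
    sample_ids = query.columns.to_numpy(dtype=object)

    chunks = range(0, len(keep), chunk_size)
    args = [
        (
            betas[i : i + chunk_size],
            q1[i : i + chunk_size],
            q3[i : i + chunk_size],
            iqr[i : i + chunk_size],
            probe_ids[i : i + chunk_size],
            sample_ids,
            classes[i : i + chunk_size],
            threshold,
        )
        for i in chunks
    ]
    if n_workers > 1 and len(args) > 1:
        frames = Parallel(n_jobs=n_workers, prefer="threads")(
            delayed(_detect_chunk)(*a) for a in args
        )
    else:
        frames = [_detect_chunk(*a) for a in args]
    calls = pd.concat(frames, ignore_index=True)
    calls = calls.sort_values(
        ["sample_id", "probe_id", "direction"], kind="mergesort"
    ).reset_index(drop=True)
    return calls[CALL_COLUMNS]


def compute_loads(
    calls: pd.DataFrame,
    samples: Sequence[str],
    zero_log10: str = "na",
    retained_only: bool = False,
) -> pd.DataFrame:
    """Aggregate SEM calls into per-sample loads by direction and subtype.

    Every (sample, direction, subtype) combination is present with an
    explicit zero when no calls exist.  Subtype ``total`` counts all calls
    in that direction; the three methylation-status subtypes partition it
    when probe classes are available.

    ``zero_log10`` controls log10 of a zero count: ``"na"`` (undefined,
    default) or ``"plus_one"`` (log10(count + 1) for every count).
    """
    if zero_log10 not in ("na", "plus_one"):
        raise ValueError("zero_log10 must be 'na' or 'plus_one'")
    samples = [str(s) for s in samples]
    extra = set(calls["sample_id"].astype(str)) - set(samples)
    if extra:
        raise ValidationError(f"calls reference unknown sample(s) {sorted(extra)[:5]}")
    if retained_only:
        calls = calls[calls["retained"].astype(bool)]

    idx = pd.MultiIndex.from_product(
        [samples, DIRECTIONS, SUBTYPES], names=["sample_id", "direction", "subtype"]
    )
    counts = pd.Series(0, index=idx, dtype=int)
    if len(calls):
        total = calls.groupby(["sample_id", "direction"]).size()
        for (s, d), c in total.items():
            counts.loc[(s, d, "total")] = c
        by_cls = calls.dropna(subset=["methylation_class"]).groupby(
            ["sample_id", "direction", "methylation_class"]
        ).size()
        for (s, d, cls), c in by_cls.items():
            if cls in SUBTYPES:
                counts.loc[(s, d, cls)] = c
    loads = counts.rename("count").reset_index()
    if zero_log10 == "plus_one":
        loads["log10_count"] = np.log10(loads["count"] + 1.0)
    else:
        with np.errstate(divide="ignore"):
            loads["log10_count"] = np.where(
                loads["count"] > 0, np.log10(loads["count"].clip(lower=1)), np.nan
            )
    return loads
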