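"""Readers and writers for the tabular artifacts used throughout semscan.

All tables travel as delimited text (tab or comma; the delimiter is sniffed
from the header line and can be overridden).  Beta matrices are held
internally as :class:`pandas.DataFrame` with probes in rows and samples in
columns regardless of the orientation on disk, because every downstream
statistic is per-probe.

Validation is strict and total: any malformed input raises a typed error
from :mod:`semscan.errors` and never yields a partial object.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, PairingError, ValidationError

NA_TOKENS = ["", "NA", "NaN", "nan", "N/A", "null"]

#: canonical column order for SEM call tables written to disk
CALL_COLUMNS = [
    "sample_id",
    "probe_id",
    "direction",
    "beta",
    "delta_iqr",
    "methylation_class",
    "rf_probability",
    "retained",
]

#: canonical column order for SEM load tables written to disk
LOAD_COLUMNS = ["sample_id", "direction", "subtype", "count", "log10_count"]

ANNOTATION_FLAGS = [
    "snp_at_sbe",
    "snp_at_cpg",
    "snp_in_probe",
    "dmr_overlap",
    "dhs",
    "enhancer",
]
ANNOTATION_CATEGORICALS = {
    "color_channel": ["red", "green", "both"],
    "genomic_location": ["island", "shore", "shelf", "open_sea", "unknown"],
    "regulatory_feature": [
        "promoter",
        "gene_body",
        "intergenic",
        "unclassified",
        "unknown",
    ],
}
CELL_TYPES = ["CD8T", "CD4T", "NK", "B", "Mono", "Gran"]


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, "rt") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file or blank header line")
    # tab wins if present; GEO series matrices are tab-separated even when
    # identifiers contain commas
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path, delimiter: str | None, **kwargs) -> pd.DataFrame:
    sep = delimiter or _sniff_delimiter(path)
    try:
        return pd.read_csv(
            path, sep=sep, na_values=NA_TOKENS, keep_default_na=False, **kwargs
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------


def validate_beta_matrix(betas: pd.DataFrame, name: str = "beta matrix") -> pd.DataFrame:
    """Check range, uniqueness and dtype invariants of a probes x samples frame."""
    if betas.shape[0] == 0 or betas.shape[1] == 0:
        raise ValidationError(f"{name}: matrix is empty ({betas.shape})")
    if betas.index.has_duplicates:
        dup = betas.index[betas.index.duplicated()][:5].tolist()
        raise ValidationError(f"{name}: duplicated probe ids, e.g. {dup}")
    if betas.columns.has_duplicates:
        dup = betas.columns[betas.columns.duplicated()][:5].tolist()
        raise ValidationError(f"{name}: duplicated sample ids, e.g. {dup}")
    values = betas.to_numpy(dtype=float, copy=False)
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{name}: beta value {values[i, j]!r} outside [0, 1] at "
            f"probe {betas.index[i]!r}, sample {betas.columns[j]!r}"
        )
    return betas.astype(float)


def read_beta_matrix(
    path: str | Path,
    orientation: str = "probes_in_rows",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a beta matrix from delimited text.

    Parameters
    ----------
    path
        Delimited text file with one header row of identifiers and one
        identifier column (first column).
    orientation
        ``"probes_in_rows"`` (default) or ``"samples_in_rows"``; the result
        is always probes x samples.
    delimiter
        Explicit delimiter; auto-detected among tab/comma when ``None``.
    """
    if orientation not in ("probes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, delimiter, index_col=0)
    if df.columns.size == 0:
        raise FormatError(f"{path}: no data columns after the identifier column")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(
            f"{path}: non-numeric values in column(s) {non_numeric[:3]}"
        )
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "probe_id"
    df.columns.name = "sample_id"
    return validate_beta_matrix(df, name=str(path))


def write_beta_matrix(betas: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    validate_beta_matrix(betas)
    betas.to_csv(path, sep=delimiter, index_label="probe_id")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------


def _parse_flag(series: pd.Series, name: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "t": True, "f": False,
        "1": True, "0": False, "yes": True, "no": False,
    }
    out = []
    for v in series:
        if pd.isna(v):
            out.append(pd.NA)
        elif isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        else:
            key = str(v).strip().lower()
            if key not in mapping:
                raise ValidationError(f"annotation column {name!r}: bad flag {v!r}")
            out.append(mapping[key])
    return pd.Series(out, index=series.index, dtype="boolean")


def read_annotation(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a probe annotation table (Illumina-manifest-like).

    Requires a ``probe_id`` column.  Missing optional columns are created and
    filled with ``unknown`` (categoricals) or NA (flags); unknown extra
    columns are preserved untouched.
    """
    df = _read_table(path, delimiter)
    if "probe_id" not in df.columns:
        raise FormatError(f"{path}: annotation table lacks a 'probe_id' column")
    df["probe_id"] = df["probe_id"].astype(str)
    if df["probe_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated probe_id in annotation")
    df = df.set_index("probe_id")
    for col in ANNOTATION_FLAGS:
        if col in df.columns:
            df[col] = _parse_flag(df[col], col)
        else:
            df[col] = pd.Series(pd.NA, index=df.index, dtype="boolean")
    for col, levels in ANNOTATION_CATEGORICALS.items():
        if col in df.columns:
            vals = df[col].astype("string").str.lower().fillna("unknown")
            bad = sorted(set(vals) - set(levels))
            if bad:
                warnings.warn(
                    f"annotation column {col!r}: unknown level(s) {bad} mapped "
                    "to 'unknown'"
                )
                vals = vals.where(vals.isin(levels), "unknown")
        else:
            vals = pd.Series("unknown", index=df.index, dtype="string")
        df[col] = pd.Categorical(vals, categories=levels)
    if "n_cpgs_in_probe" in df.columns:
        n = pd.to_numeric(df["n_cpgs_in_probe"], errors="coerce")
        if (n.dropna() < 0).any():
            raise ValidationError(f"{path}: negative n_cpgs_in_probe")
        df["n_cpgs_in_probe"] = n
    else:
        df["n_cpgs_in_probe"] = np.nan
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    annotation.to_csv(path, sep=delimiter, index_label="probe_id")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------


def read_sample_sheet(
    path: str | Path,
    delimiter: str | None = None,
    require_pairs: bool = False,
) -> pd.DataFrame:
    """Read a sample sheet with optional replicate pairing and covariates."""
    df = _read_table(path, delimiter)
    return validate_sample_sheet(df, require_pairs=require_pairs, name=str(path))


def validate_sample_sheet(
    df: pd.DataFrame, require_pairs: bool = False, name: str = "sample sheet"
) -> pd.DataFrame:
    for col in ("sample_id", "subject_id"):
        if col not in df.columns:
            raise FormatError(f"{name}: missing required column {col!r}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{name}: duplicated sample_id")
    if "replicate_index" in df.columns and df["replicate_index"].notna().any():
        idx = pd.to_numeric(df["replicate_index"], errors="coerce")
        if not idx.dropna().isin([1, 2]).all():
            raise ValidationError(f"{name}: replicate_index must be 1 or 2")
        df["replicate_index"] = idx.astype("Int64")
        counts = df.groupby("subject_id")["sample_id"].size()
        if (counts > 2).any():
            bad = counts[counts > 2].index[:5].tolist()
            raise PairingError(
                f"{name}: subject(s) with >2 samples under replicate pairing: {bad}"
            )
    elif require_pairs:
        raise PairingError(f"{name}: replicate analysis requires replicate_index")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    present_cells = [c for c in CELL_TYPES if c in df.columns]
    for col in present_cells:
        vals = pd.to_numeric(df[col], errors="coerce")
        out = vals.dropna()[(vals.dropna() < 0) | (vals.dropna() > 1)]
        if len(out):
            raise ValidationError(
                f"{name}: cell proportion {col}={out.iloc[0]} outside [0, 1]"
            )
        df[col] = vals
    if len(present_cells) == len(CELL_TYPES):
        totals = df[CELL_TYPES].sum(axis=1, skipna=False).dropna()
        off = totals[(totals - 1.0).abs() > 0.05]
        if len(off):
            raise ValidationError(
                f"{name}: cell proportions sum to {off.iloc[0]:.3f} "
                f"(outside 1.0 +/- 0.05) for sample {off.index[0]}"
            )
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    sheet.to_csv(path, sep=delimiter, index=False)


def replicate_pairs(sheet: pd.DataFrame) -> pd.DataFrame:
    """Extract one row per subject with its two replicate sample ids.

    Returns a frame with columns ``subject_id``, ``sample_a`` (replicate 1)
    and ``sample_b`` (replicate 2).  Subjects without both replicates raise.
    """
    if "replicate_index" not in sheet.columns:
        raise PairingError("sample sheet has no replicate_index column")
    rows = []
    for subject, grp in sheet.groupby("subject_id", sort=True):
        idx = grp.set_index("replicate_index")["sample_id"]
        if not {1, 2}.issubset(set(idx.index.dropna())):
            raise PairingError(f"subject {subject!r} lacks a complete replicate pair")
        rows.append((subject, idx.loc[1], idx.loc[2]))
    return pd.DataFrame(rows, columns=["subject_id", "sample_a", "sample_b"])


# ---------------------------------------------------------------------------
# call / load tables
# ---------------------------------------------------------------------------


def write_calls(calls: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValidationError(f"call table missing column(s) {missing}")
    calls[CALL_COLUMNS].to_csv(path, sep=delimiter, index=False)


def read_calls(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    df = _read_table(path, delimiter)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: call table missing column(s) {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["probe_id"] = df["probe_id"].astype(str)
    bad = set(df["direction"]) - {"hypo", "hyper"}
    if bad:
        raise ValidationError(f"{path}: unknown direction value(s) {sorted(bad)}")
    if "retained" in df.columns:
        df["retained"] = _parse_flag(df["retained"], "retained").fillna(True).astype(bool)
    return df[CALL_COLUMNS]


def write_loads(loads: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    loads[LOAD_COLUMNS].to_csv(path, sep=delimiter, index=False)


def write_probe_sets(sets: dict[str, Iterable[str]], out_dir: str | Path) -> list[Path]:
    """Write one plain-text probe-id list per methylation class."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for cls, probes in sets.items():
        p = out_dir / f"consensus_{cls}_probes.txt"
        p.write_text("\n".join(sorted(map(str, probes))) + "\n")
        written.append(p)
    return written
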