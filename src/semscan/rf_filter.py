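"""Random-forest filtering of unreliable SEM calls.

Whether a SEM replicates in a second technical measurement is predictable
from probe-level statistics (IQR, standard deviation, mean, ...), the
deltaIQR of the calling replicate, sample cell-type composition, and probe
annotation (SNP overlap, color channel, genomic context).  Two independent
classifiers are trained — one per SEM direction — with shared and
almost-shared events as the positive (reliable) class and unshared events
as the negative class.  Applying a trained model attaches a reliability
probability to every call and flags calls below a probability cutoff as
not retained; calls are never deleted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .errors import SchemaError, ValidationError
from .io import ANNOTATION_CATEGORICALS, ANNOTATION_FLAGS, CELL_TYPES
from .probe_stats import STAT_COLUMNS

NUMERIC_PROBE_FEATURES = [c for c in STAT_COLUMNS if c != "n_ref"]
NUMERIC_FEATURES = (
    NUMERIC_PROBE_FEATURES + ["delta_iqr", "n_cpgs_in_probe"] + CELL_TYPES
)
CATEGORICAL_FEATURES = (
    ANNOTATION_FLAGS + list(ANNOTATION_CATEGORICALS) + ["methylation_class"]
)
FEATURE_COLUMNS = NUMERIC_FEATURES + CATEGORICAL_FEATURES

#: tie-break priority when pruning clusters of mutually correlated features;
#: earlier wins (mean over median, SNP at the extension base over SNP at CpG)
FEATURE_PRIORITY = [
    "mean", "median", "iqr", "sd", "q1", "q3", "range", "min", "max",
    "delta_iqr", "snp_at_sbe", "snp_at_cpg", "snp_in_probe",
]

DEFAULT_TUNING_GRID = {
    "max_features": ["sqrt", 0.33, 0.5],
    "max_samples": [0.5, 0.8, None],
    "n_estimators": [250, 500, 1000],
}


def label_ground_truth(records: pd.DataFrame) -> pd.Series:
    """Binary reliability labels: shared + almost_shared -> 1, unshared -> 0.

    Almost-shared events are grouped with shared ones: the counterpart
    replicate crossed the 1.5-IQR boundary, so the event is directionally
    replicated even though it missed the full detection fence.
    """
    if "category" not in records.columns:
        raise ValidationError("records lack a 'category' column; classify first")
    labels = records["category"].isin(["shared", "almost_shared"]).astype(int)
    if labels.nunique() < 2:
        warnings.warn("ground-truth labels are single-class; training will fail")
    return labels.rename("reliable")


def assemble_features(
    calls: pd.DataFrame,
    stats: pd.DataFrame,
    annotation: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    impute_cells: bool = False,
) -> pd.DataFrame:
    """Build one feature row per SEM call, in a deterministic column order.

    Joins probe statistics and annotation by probe_id, cell-type
    proportions by sample_id, and carries the deltaIQR of the calling
    replicate.  Missing cell proportions raise unless ``impute_cells``
    fills them with the cohort median.
    """
    missing_probes = set(calls["probe_id"]) - set(annotation.index)
    if missing_probes:
        raise ValidationError(
            f"unannotated probe(s) in calls: {sorted(missing_probes)[:5]}"
        )
    feats = calls[["sample_id", "probe_id", "direction", "delta_iqr"]].copy()
    feats = feats.join(stats[NUMERIC_PROBE_FEATURES], on="probe_id")
    if "methylation_class" in calls.columns and calls["methylation_class"].notna().any():
        feats["methylation_class"] = calls["methylation_class"].astype("object")
    elif "methylation_class" in stats.columns:
        feats["methylation_class"] = (
            stats["methylation_class"].reindex(feats["probe_id"]).to_numpy()
        )
    else:
        feats["methylation_class"] = "unknown"

    ann_cols = ANNOTATION_FLAGS + list(ANNOTATION_CATEGORICALS) + ["n_cpgs_in_probe"]
    feats = feats.join(annotation[ann_cols], on="probe_id")

    sheet = sample_sheet.set_index("sample_id")
    have = [c for c in CELL_TYPES if c in sheet.columns]
    if len(have) < len(CELL_TYPES):
        raise ValidationError(f"sample sheet lacks cell proportion column(s)")
    cells = sheet[CELL_TYPES].reindex(feats["sample_id"])
    if cells.isna().any().any():
        if not impute_cells:
            raise ValidationError(
                "missing cell proportions; pass impute_cells=True to fill medians"
            )
        cells = cells.fillna(sheet[CELL_TYPES].median())
    for c in CELL_TYPES:
        feats[c] = cells[c].to_numpy()

    for col in ANNOTATION_FLAGS:
        feats[col] = (
            feats[col].map({True: "yes", False: "no"}).fillna("unknown").astype("object")
        )
    for col in ANNOTATION_CATEGORICALS:
        feats[col] = feats[col].astype("object").fillna("unknown")
    feats["n_cpgs_in_probe"] = feats["n_cpgs_in_probe"].fillna(0).astype(float)
    bad = feats[NUMERIC_FEATURES].isna().any()
    if bad.any():
        raise ValidationError(
            f"non-finite numeric feature(s): {list(bad.index[bad])[:5]}"
        )
    order = ["sample_id", "probe_id", "direction"] + FEATURE_COLUMNS
    return feats[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def _cramers_v(x: pd.Series, y: pd.Series) -> float:
    table = pd.crosstab(x, y)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    chi2 = sps.chi2_contingency(table.to_numpy(), correction=False)[0]
    n = table.to_numpy().sum()
    r, c = table.shape
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def _point_biserial(x: pd.Series, y: pd.Series) -> float:
    x = x.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    return float(abs(sps.pointbiserialr(y.to_numpy(), x)[0]))


def feature_associations(features: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Association strength of every feature with the binary label.

    Point-biserial correlation (absolute value) for numeric features,
    Cramer's V for categorical ones; both live on [0, 1].
    """
    assoc = {}
    for col in FEATURE_COLUMNS:
        if col not in features.columns:
            continue
        if col in NUMERIC_FEATURES:
            assoc[col] = _point_biserial(features[col], labels)
        else:
            assoc[col] = _cramers_v(features[col].astype(str), labels)
    return pd.Series(assoc, name="association")


def _encode(features: pd.DataFrame, columns, levels: dict[str, list[str]] | None = None):
    """One-hot encode categorical columns; numeric pass through.

    Returns (matrix DataFrame, levels dict) with a stable column order.
    """
    levels = dict(levels) if levels else {}
    blocks = []
    for col in columns:
        if col in NUMERIC_FEATURES:
            blocks.append(features[[col]].astype(float))
        else:
            vals = features[col].astype(str)
            if col not in levels:
                levels[col] = sorted(vals.unique())
            for lev in levels[col]:
                blocks.append((vals == lev).astype(float).rename(f"{col}={lev}").to_frame())
    X = pd.concat(blocks, axis=1)
    return X, levels


def _priority_key(name: str) -> tuple[int, str]:
    try:
        return (FEATURE_PRIORITY.index(name), name)
    except ValueError:
        return (len(FEATURE_PRIORITY), name)


def select_features(
    features: pd.DataFrame,
    labels: pd.Series,
    min_assoc: float = 0.1,
    redundancy_threshold: float = 0.8,
) -> list[str]:
    """Association-driven feature selection with redundancy pruning.

    Features whose association with the label exceeds ``min_assoc`` survive.
    Redundancy is then pruned greedily: survivors are visited in descending
    association order (ties broken by the declared priority list, then
    name) and a feature is kept only if no already-kept feature is
    correlated with it above ``redundancy_threshold`` (|Pearson| between
    any pair of their one-hot-encoded columns) — so each cluster of
    mutually associated features contributes its strongest member, e.g.
    mean survives and median falls to it.  The result is sorted by feature
    name, hence invariant to input column order.
    """
    if labels.nunique() < 2:
        raise ValidationError("feature selection needs both label classes")
    assoc = feature_associations(features, labels)
    survivors = sorted(assoc.index[assoc > min_assoc])
    if not survivors:
        return []
    X, _ = _encode(features, survivors)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    col_feature = np.array([c.split("=", 1)[0] for c in X.columns])
    order = sorted(survivors, key=lambda f: (-assoc[f], _priority_key(f)))
    kept: list[str] = []
    for f in order:
        cols_f = np.flatnonzero(col_feature == f)
        redundant = False
        for g in kept:
            cols_g = np.flatnonzero(col_feature == g)
            r = corr[np.ix_(cols_f, cols_g)]
            if np.nanmax(np.abs(r)) > redundancy_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(f)
    return sorted(kept)


# ---------------------------------------------------------------------------
# training and application
# ---------------------------------------------------------------------------


@dataclass
class RFModel:
    """A trained direction-specific SEM reliability classifier."""

    direction: str
    estimator: RandomForestClassifier
    feature_names: list[str]
    encoded_columns: list[str]
    levels: dict[str, list[str]]
    hyperparameters: dict
    holdout_auc: float
    importances: pd.Series = field(repr=False)

    @property
    def schema(self) -> dict:
        return {
            "direction": self.direction,
            "features": self.feature_names,
            "encoded_columns": self.encoded_columns,
            "levels": self.levels,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(
            {
                "format_version": 1,
                "schema": json.dumps(self.schema),
                "hyperparameters": self.hyperparameters,
                "holdout_auc": self.holdout_auc,
                "importances": self.importances,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "RFModel":
        blob = joblib.load(path)
        schema = json.loads(blob["schema"])
        return cls(
            direction=schema["direction"],
            estimator=blob["estimator"],
            feature_names=schema["features"],
            encoded_columns=schema["encoded_columns"],
            levels=schema["levels"],
            hyperparameters=blob["hyperparameters"],
            holdout_auc=blob["holdout_auc"],
            importances=blob["importances"],
        )


def train_filter(
    features: pd.DataFrame,
    labels: pd.Series,
    direction: str = "hypo",
    split: float = 0.8,
    folds: int = 5,
    seed: int = 0,
    tuning_grid: dict | None = None,
    selected: list[str] | None = None,
    min_assoc: float = 0.1,
) -> RFModel:
    """Train a reliability classifier on labelled SEM events.

    A stratified ``split``/(1-split) train/test partition is drawn; the
    tuning grid (features per split, per-tree sample fraction, tree count)
    is searched by ``folds``-fold cross-validated ROC AUC on the training
    part; the best forest is refit on the full training part and its AUC on
    the held-out part recorded, along with per-feature Gini importances.
    Fully reproducible given ``seed``.
    """
    if len(features) < 200:
        raise ValidationError(f"need >= 200 labelled SEMs, got {len(features)}")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels are single-class")
    if selected is None:
        selected = select_features(features, pd.Series(y), min_assoc=min_assoc)
    if not selected:
        raise ValidationError("no features passed the association filter")
    X, levels = _encode(features, selected)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, random_state=seed, stratify=y
    )
    if min(np.bincount(y_tr)) < folds:
        raise ValidationError(
            "a class would be absent from some cross-validation fold"
        )
    grid = tuning_grid or DEFAULT_TUNING_GRID
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed, n_jobs=1),
        param_grid=grid,
        scoring="roc_auc",
        cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    search.fit(X_tr, y_tr)
    best: RandomForestClassifier = search.best_estimator_
    auc = float(roc_auc_score(y_te, best.predict_proba(X_te)[:, 1]))
    importances = pd.Series(
        best.feature_importances_, index=X.columns, name="gini_importance"
    ).sort_values(ascending=False)
    return RFModel(
        direction=direction,
        estimator=best,
        feature_names=list(selected),
        encoded_columns=list(X.columns),
        levels=levels,
        hyperparameters=dict(search.best_params_),
        holdout_auc=auc,
        importances=importances,
    )


def predict_reliability(model: RFModel, features: pd.DataFrame) -> np.ndarray:
    """Reliability probability for each feature row under ``model``."""
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise SchemaError(f"feature table lacks column(s) {missing}")
    X, _ = _encode(features, model.feature_names, levels=model.levels)
    X = X.reindex(columns=model.encoded_columns, fill_value=0.0)
    return model.estimator.predict_proba(X)[:, 1]


def apply_filter(
    model: RFModel, calls: pd.DataFrame, features: pd.DataFrame,
    prob_threshold: float = 0.5,
) -> pd.DataFrame:
    """Attach reliability probabilities and retained flags to a call table.

    Calls with probability >= ``prob_threshold`` are retained; others are
    flagged out but stay in the table.
    """
    if not 0.0 <= prob_threshold <= 1.0:
        raise ValidationError("prob_threshold must lie in [0, 1]")
    if len(features) != len(calls):
        raise SchemaError("features and calls are not row-aligned")
    probs = predict_reliability(model, features)
    out = calls.copy()
    out["rf_probability"] = probs
    out["retained"] = probs >= prob_threshold
    return out


def evaluate_filter(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Before/after-filter comparison on a replicate-paired call set.

    Reports, per direction: mean shared proportion before and after
    filtering, and the fraction of calls removed per methylation-status
    subtype.
    """
    from .reliability import shared_proportion

    before = shared_proportion(calls_a, calls_b, pairs)
    after = shared_proportion(calls_a, calls_b, pairs, retained_only=True)
    both = pd.concat([calls_a, calls_b], ignore_index=True)
    rows = []
    for direction in ("hypo", "hyper"):
        pre = before.loc[before["direction"] == direction, "prop_mean"].mean()
        post = after.loc[after["direction"] == direction, "prop_mean"].mean()
        sub = both[both["direction"] == direction]
        removed_total = 1.0 - sub["retained"].mean() if len(sub) else np.nan
        row = {
            "direction": direction,
            "shared_before": pre,
            "shared_after": post,
            "shared_gain": post - pre,
            "removed_fraction_total": removed_total,
        }
        for cls in ("unmethylated", "intermediate", "methylated"):
            cls_sub = sub[sub["methylation_class"] == cls]
            row[f"removed_fraction_{cls}"] = (
                1.0 - cls_sub["retained"].mean() if len(cls_sub) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
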