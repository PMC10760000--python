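"""Feature assembly, association-based selection, RF training and filtering."""

import numpy as np
import pandas as pd
import pytest

import semscan as ss
from semscan.errors import SchemaError, ValidationError
from semscan.rf_filter import (
    DEFAULT_TUNING_GRID,
    FEATURE_COLUMNS,
    NUMERIC_FEATURES,
    feature_associations,
)

from conftest import TEST_GRID


@pytest.fixture(scope="module")
def training_data(cohort):
    """Replicate-A hypoSEM calls with replicate-derived reliability labels."""
    rec = cohort["records"]
    labels = ss.label_ground_truth(rec)
    a_map = dict(zip(cohort["pairs"]["sample_a"], cohort["pairs"]["subject_id"]))
    calls = cohort["calls_a"][cohort["calls_a"]["direction"] == "hypo"].copy()
    calls["subject_id"] = calls["sample_id"].map(a_map)
    key = rec.assign(reliable=labels).query("direction == 'hypo'").set_index(
        ["subject_id", "probe_id"]
    )["reliable"]
    y = key.reindex(
        pd.MultiIndex.from_frame(calls[["subject_id", "probe_id"]])
    ).to_numpy().astype(int)
    feats = ss.assemble_features(
        calls.drop(columns="subject_id"), cohort["stats"], cohort["annotation"],
        cohort["sim"].sample_sheet,
    )
    return feats, pd.Series(y)


class TestLabels:
    @pytest.mark.parametrize("category,expect",
                             [("shared", 1), ("almost_shared", 1), ("unshared", 0)])
    def test_category_to_label(self, category, expect):
        rec = pd.DataFrame({"category": [category]})
        assert ss.label_ground_truth(rec).iloc[0] == expect

    def test_label_counts_match_category_counts(self, cohort):
        labels = ss.label_ground_truth(cohort["records"])
        cats = cohort["records"]["category"]
        assert labels.sum() == cats.isin(["shared", "almost_shared"]).sum()
        assert (1 - labels).sum() == (cats == "unshared").sum()

    def test_single_class_warns(self):
        rec = pd.DataFrame({"category": ["shared", "shared"]})
        with pytest.warns(UserWarning, match="single-class"):
            ss.label_ground_truth(rec)


class TestAssembleFeatures:
    def test_values_pass_through_verbatim(self, cohort, training_data):
        feats, _ = training_data
        row = feats.iloc[0]
        assert row["iqr"] == cohort["stats"].loc[row["probe_id"], "iqr"]
        sheet = cohort["sim"].sample_sheet.set_index("sample_id")
        assert row["CD8T"] == sheet.loc[row["sample_id"], "CD8T"]

    def test_row_count_equals_call_count(self, cohort, training_data):
        feats, _ = training_data
        n_hypo = (cohort["calls_a"]["direction"] == "hypo").sum()
        assert len(feats) == n_hypo

    def test_unannotated_probe_rejected(self, cohort):
        calls = cohort["calls_a"].head(5)
        ann = cohort["annotation"].drop(index=calls["probe_id"].iloc[0])
        with pytest.raises(ValidationError, match="unannotated"):
            ss.assemble_features(calls, cohort["stats"], ann,
                                 cohort["sim"].sample_sheet)

    def test_missing_cell_proportions_need_imputation_flag(self, cohort):
        sheet = cohort["sim"].sample_sheet.copy()
        sheet.loc[0, "CD8T"] = np.nan
        calls = cohort["calls_a"].head(20)
        with pytest.raises(ValidationError, match="cell proportions"):
            ss.assemble_features(calls, cohort["stats"], cohort["annotation"], sheet)
        feats = ss.assemble_features(calls, cohort["stats"], cohort["annotation"],
                                     sheet, impute_cells=True)
        assert feats["CD8T"].notna().all()


class TestSelectFeatures:
    def _frame(self, rng, n=2000):
        base = {c: rng.normal(size=n) for c in NUMERIC_FEATURES}
        frame = pd.DataFrame(base)
        for c in FEATURE_COLUMNS:
            if c not in frame.columns:
                frame[c] = rng.choice(["x", "y"], size=n)
        return frame

    def test_label_copy_feature_always_selected(self, rng):
        frame = self._frame(rng)
        labels = pd.Series(rng.integers(0, 2, len(frame)))
        frame["methylation_class"] = np.where(labels == 1, "methylated", "unmethylated")
        chosen = ss.select_features(frame, labels)
        assert "methylation_class" in chosen
        assert feature_associations(frame, labels)["methylation_class"] == pytest.approx(1.0)

    def test_independent_feature_dropped(self, rng):
        n = 10_000
        frame = self._frame(rng, n)
        labels = pd.Series(rng.integers(0, 2, n))
        frame["mean"] = rng.normal(size=n)  # independent of the label
        frame["iqr"] = labels + rng.normal(0, 0.5, n)  # informative
        chosen = ss.select_features(frame, labels)
        assert "mean" not in chosen
        assert "iqr" in chosen

    def test_duplicated_feature_keeps_priority_member(self, rng):
        n = 3000
        frame = self._frame(rng, n)
        labels = pd.Series(rng.integers(0, 2, n))
        signal = labels + rng.normal(0, 1.0, n)
        frame["mean"] = signal
        frame["median"] = signal  # perfect duplicate of mean
        chosen = ss.select_features(frame, labels)
        assert "mean" in chosen
        assert "median" not in chosen

    def test_invariant_to_column_order(self, training_data):
        feats, labels = training_data
        shuffled = feats[list(reversed(feats.columns))]
        assert ss.select_features(feats, labels) == ss.select_features(shuffled, labels)

    def test_single_class_labels_rejected(self, training_data):
        feats, _ = training_data
        with pytest.raises(ValidationError):
            ss.select_features(feats, pd.Series(np.ones(len(feats))))


class TestTrainFilter:
    def _separable(self, rng, n=2000):
        labels = pd.Series(rng.integers(0, 2, n))
        frame = pd.DataFrame({c: rng.normal(size=n) for c in NUMERIC_FEATURES})
        frame["iqr"] = labels * 2.0 + rng.normal(0, 0.01, n)
        for c in FEATURE_COLUMNS:
            if c not in frame.columns:
                frame[c] = "x"
        return frame, labels

    def test_separable_labels_reach_high_auc(self, rng):
        frame, labels = self._separable(rng)
        model = ss.train_filter(frame, labels, seed=0, tuning_grid=TEST_GRID)
        assert model.holdout_auc > 0.99
        assert (model.importances >= 0).all()

    def test_random_labels_give_chance_auc(self, rng):
        aucs = []
        for seed in range(10):
            n = 600
            labels = pd.Series(rng.integers(0, 2, n))
            frame = pd.DataFrame({c: rng.normal(size=n) for c in NUMERIC_FEATURES})
            for c in FEATURE_COLUMNS:
                if c not in frame.columns:
                    frame[c] = "x"
            model = ss.train_filter(frame, labels, seed=seed, tuning_grid=TEST_GRID,
                                    selected=["iqr", "mean", "sd"])
            aucs.append(model.holdout_auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_same_seed_identical_model(self, training_data):
        feats, labels = training_data
        m1 = ss.train_filter(feats, labels, seed=3, tuning_grid=TEST_GRID)
        m2 = ss.train_filter(feats, labels, seed=3, tuning_grid=TEST_GRID)
        assert m1.holdout_auc == m2.holdout_auc
        assert m1.hyperparameters == m2.hyperparameters
        pd.testing.assert_series_equal(m1.importances, m2.importances)
        p1 = ss.predict_reliability(m1, feats)
        p2 = ss.predict_reliability(m2, feats)
        assert np.array_equal(p1, p2)

    def test_tuning_grid_knobs_are_searched(self, training_data):
        feats, labels = training_data
        model = ss.train_filter(feats, labels, seed=0, tuning_grid=TEST_GRID)
        assert set(model.hyperparameters) == set(DEFAULT_TUNING_GRID)

    def test_too_few_events_rejected(self, training_data):
        feats, labels = training_data
        with pytest.raises(ValidationError):
            ss.train_filter(feats.head(50), labels.head(50), tuning_grid=TEST_GRID)

    def test_save_load_round_trip(self, tmp_path, training_data):
        feats, labels = training_data
        model = ss.train_filter(feats, labels, seed=1, tuning_grid=TEST_GRID)
        model.save(tmp_path / "m.joblib")
        back = ss.RFModel.load(tmp_path / "m.joblib")
        assert back.feature_names == model.feature_names
        assert back.holdout_auc == model.holdout_auc
        assert np.array_equal(
            ss.predict_reliability(back, feats), ss.predict_reliability(model, feats)
        )


@pytest.fixture(scope="module")
def fitted(cohort, training_data):
    feats, labels = training_data
    model = ss.train_filter(feats, labels, seed=2, tuning_grid=TEST_GRID)
    calls = cohort["calls_a"][cohort["calls_a"]["direction"] == "hypo"]
    return model, calls.reset_index(drop=True), feats


class TestApplyFilter:
    def test_threshold_bounds(self, fitted):
        model, calls, feats = fitted
        assert ss.apply_filter(model, calls, feats, 0.0)["retained"].all()
        probs = ss.predict_reliability(model, feats)
        if (probs < 1.0).all():
            assert not ss.apply_filter(model, calls, feats, 1.0)["retained"].any()

    def test_retained_monotone_in_threshold(self, fitted):
        model, calls, feats = fitted
        kept = [
            ss.apply_filter(model, calls, feats, t)["retained"].sum()
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_filtering_never_deletes_calls(self, fitted):
        model, calls, feats = fitted
        out = ss.apply_filter(model, calls, feats, 0.5)
        assert len(out) == len(calls)
        assert out["rf_probability"].between(0, 1).all()

    def test_schema_mismatch_rejected(self, fitted):
        model, calls, feats = fitted
        with pytest.raises(SchemaError):
            ss.predict_reliability(model, feats.drop(columns=model.feature_names[:1]))
        with pytest.raises(SchemaError):
            ss.apply_filter(model, calls.head(3), feats, 0.5)


class TestEvaluateFilter:
    def test_identity_filter_zero_deltas(self, cohort):
        out = ss.evaluate_filter(cohort["calls_a"], cohort["calls_b"], cohort["pairs"])
        assert (out["shared_gain"].abs() < 1e-12).all()
        assert (out["removed_fraction_total"] == 0).all()

    def test_oracle_filter_yields_perfect_sharing(self, cohort):
        # retain exactly the events the truth says are shared in both replicates
        rec = cohort["records"]
        shared = rec[rec["category"] == "shared"]
        shared_keys = set(zip(shared["subject_id"], shared["probe_id"],
                              shared["direction"]))
        def mark(calls, mapping):
            out = calls.copy()
            keys = list(zip(out["sample_id"].map(mapping), out["probe_id"],
                            out["direction"]))
            out["retained"] = [k in shared_keys for k in keys]
            return out
        a_map = dict(zip(cohort["pairs"]["sample_a"], cohort["pairs"]["subject_id"]))
        b_map = dict(zip(cohort["pairs"]["sample_b"], cohort["pairs"]["subject_id"]))
        out = ss.evaluate_filter(mark(cohort["calls_a"], a_map),
                                 mark(cohort["calls_b"], b_map), cohort["pairs"])
        assert (out["shared_after"] > 0.999).all()

    def test_subtype_removals_consistent(self, cohort, training_data):
        feats, labels = training_data
        model = ss.train_filter(feats, labels, seed=4, tuning_grid=TEST_GRID)
        calls = cohort["calls_a"][cohort["calls_a"]["direction"] == "hypo"]
        filtered = ss.apply_filter(model, calls.reset_index(drop=True), feats, 0.5)
        removed = (~filtered["retained"]).sum()
        by_class = (~filtered["retained"]).groupby(
            filtered["methylation_class"]).sum()
        assert by_class.sum() == removed
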