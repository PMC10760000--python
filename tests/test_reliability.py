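"""Replicate matching, category logic, GMM cutoffs, ICC and size sweeps."""

import numpy as np
import pandas as pd
import pytest

import semscan as ss
from semscan.errors import DegenerateModelError, PairingError, ValidationError
from semscan.reliability import gaussian_mixture_intersection


def _records(rows):
    return pd.DataFrame(rows, columns=["subject_id", "probe_id", "direction",
                                       "delta_iqr_a", "delta_iqr_b"])


class TestMatching:
    def test_union_size_matches_brute_force(self, cohort):
        rec = cohort["records"]
        a_map = dict(zip(cohort["pairs"]["sample_a"], cohort["pairs"]["subject_id"]))
        b_map = dict(zip(cohort["pairs"]["sample_b"], cohort["pairs"]["subject_id"]))
        union = set()
        for calls, mapping in ((cohort["calls_a"], a_map), (cohort["calls_b"], b_map)):
            for _, r in calls.iterrows():
                union.add((mapping[r["sample_id"]], r["probe_id"], r["direction"]))
        assert len(rec) == len(union)
        got = set(zip(rec["subject_id"], rec["probe_id"], rec["direction"]))
        assert got == union

    def test_both_replicate_event_yields_single_record(self, cohort):
        rec = cohort["records"]
        assert not rec.duplicated(["subject_id", "probe_id", "direction"]).any()

    def test_counterpart_delta_can_be_negative(self, cohort):
        # an event called in one replicate while the partner sits inside the box
        rec = cohort["records"]
        weaker = np.minimum(rec["delta_iqr_a"], rec["delta_iqr_b"])
        assert (weaker < 0).any()
        assert (np.maximum(rec["delta_iqr_a"], rec["delta_iqr_b"]) > 3).all()

    def test_unpaired_sample_rejected(self, cohort):
        bad = cohort["calls_a"].copy()
        bad.loc[bad.index[0], "sample_id"] = "not_in_sheet"
        with pytest.raises(PairingError):
            ss.match_replicate_events(
                bad, cohort["calls_b"], cohort["sim"].betas_a,
                cohort["sim"].betas_b, cohort["stats"], cohort["pairs"],
            )

    def test_recorded_deltas_match_direct_computation(self, cohort):
        rec = cohort["records"].iloc[:50]
        pair_idx = cohort["pairs"].set_index("subject_id")
        for _, r in rec.iterrows():
            sample_a = pair_idx.loc[r["subject_id"], "sample_a"]
            beta = cohort["sim"].betas_a.loc[r["probe_id"], sample_a]
            st = cohort["stats"].loc[r["probe_id"]]
            expect = ss.delta_iqr(beta, st["q1"], st["q3"], st["iqr"], r["direction"])
            assert r["delta_iqr_a"] == pytest.approx(expect)


class TestClassification:
    @pytest.mark.parametrize(
        "da,db,expect",
        [
            (3.5, 3.2, "shared"),
            (3.5, 2.0, "almost_shared"),
            (3.5, 0.4, "unshared"),
            (3.2, 3.5, "shared"),
            (4.0, 1.5, "unshared"),   # boundary: must *exceed* 1.5
            (4.0, 3.0, "almost_shared"),  # boundary: must exceed 3
        ],
    )
    def test_category_assignment(self, da, db, expect):
        rec = ss.classify_records(_records([("s", "p", "hypo", da, db)]))
        assert rec["category"].iloc[0] == expect

    def test_categories_partition_records(self, cohort):
        rec = cohort["records"]
        counts = rec["category"].value_counts()
        assert counts.sum() == len(rec)
        assert set(counts.index) <= {"shared", "almost_shared", "unshared"}

    def test_lowering_cutoff_is_monotone(self, cohort):
        strict = ss.classify_records(cohort["records"], lower=1.5)
        lax = ss.classify_records(cohort["records"], lower=0.5)
        # lowering `lower` can only move unshared -> almost_shared
        moved = strict["category"] != lax["category"]
        assert (strict.loc[moved, "category"] == "unshared").all()
        assert (lax.loc[moved, "category"] == "almost_shared").all()

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            ss.classify_records(_records([]), lower=3.0, upper=1.5)


class TestGmm:
    def test_cutoff_recovers_density_intersection(self, rng):
        x = np.concatenate([rng.normal(0.5, 0.2, 2500), rng.normal(4.0, 1.0, 2500)])
        fit = ss.fit_delta_gmm(x, seed=0)
        expected = gaussian_mixture_intersection(0.5, 0.2, 0.5, 4.0, 1.0, 0.5)
        assert fit.cutoff == pytest.approx(expected, abs=0.1)
        assert fit.means[0] < fit.cutoff < fit.means[1]
        assert sum(fit.weights) == pytest.approx(1.0)

    def test_identical_components_degenerate(self):
        with pytest.raises(DegenerateModelError):
            gaussian_mixture_intersection(2.0, 0.5, 0.5, 2.0, 0.5, 0.5)

    def test_dominated_component_has_no_intersection(self):
        # one component's weighted density exceeds the other's everywhere
        # between the means: no valid cutoff
        with pytest.raises(DegenerateModelError):
            gaussian_mixture_intersection(0.0, 5.0, 0.99, 0.5, 5.0, 0.01)

    def test_cutoff_stable_across_seeds(self, rng):
        x = np.concatenate([rng.normal(0.5, 0.2, 1500), rng.normal(4.0, 1.0, 1500)])
        cuts = [ss.fit_delta_gmm(x, seed=s).cutoff for s in range(5)]
        assert max(cuts) - min(cuts) < 0.02

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            ss.fit_delta_gmm(np.arange(10.0))

    def test_counterpart_deltas_convention(self):
        rec = _records([("s", "p1", "hypo", 4.0, 1.0),   # detected in A
                        ("s", "p2", "hypo", 0.5, 4.2),   # detected in B only
                        ("s", "p3", "hypo", 3.5, 3.8)])  # detected in both
        cp = ss.counterpart_deltas(rec)
        assert list(cp) == [1.0, 0.5, 3.8]


class TestSharedProportion:
    def _pairs(self):
        return pd.DataFrame({"subject_id": ["S0"], "sample_a": ["a"], "sample_b": ["b"]})

    def _calls(self, sample, probes, direction="hypo"):
        return pd.DataFrame({
            "sample_id": sample, "probe_id": list(probes), "direction": direction,
            "beta": 0.1, "delta_iqr": 4.0, "methylation_class": "methylated",
            "rf_probability": np.nan, "retained": True,
        })

    def test_identical_sets_give_one(self):
        props = ss.shared_proportion(
            self._calls("a", ["p1", "p2"]), self._calls("b", ["p1", "p2"]), self._pairs()
        )
        hypo = props[props.direction == "hypo"].iloc[0]
        assert hypo["prop_a"] == 1.0 and hypo["prop_b"] == 1.0

    def test_disjoint_sets_give_zero(self):
        props = ss.shared_proportion(
            self._calls("a", ["p1"]), self._calls("b", ["p2"]), self._pairs()
        )
        hypo = props[props.direction == "hypo"].iloc[0]
        assert hypo["prop_mean"] == 0.0

    def test_partial_overlap_set_arithmetic(self):
        props = ss.shared_proportion(
            self._calls("a", ["p1", "p2", "p3"]),
            self._calls("b", ["p2", "p3", "p4"]),
            self._pairs(),
        )
        hypo = props[props.direction == "hypo"].iloc[0]
        assert hypo["prop_a"] == pytest.approx(2 / 3)
        assert hypo["prop_b"] == pytest.approx(2 / 3)

    def test_empty_call_set_is_nan(self):
        props = ss.shared_proportion(
            self._calls("a", ["p1"]), self._calls("b", []), self._pairs()
        )
        hypo = props[props.direction == "hypo"].iloc[0]
        assert np.isnan(hypo["prop_b"])


def icc_oracle(x):
    """Brute-force two-way ANOVA mean squares -> ICC(2,1)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement_is_one(self):
        res = ss.icc_2_1([[1, 1], [2, 2], [3, 3]])
        assert res.estimate == pytest.approx(1.0)

    def test_constant_offset_case_matches_oracle(self):
        x = np.array([[1, 2], [2, 3], [3, 4]], dtype=float)
        res = ss.icc_2_1(x)
        assert res.estimate == pytest.approx(icc_oracle(x), abs=1e-12)

    def test_matches_anova_oracle_on_random_tables(self, rng):
        for _ in range(25):
            x = rng.normal(size=(50, 2)) + rng.normal(size=(50, 1)) * 2
            res = ss.icc_2_1(x)
            assert res.estimate == pytest.approx(icc_oracle(x), abs=1e-10)
            assert res.ci_low <= res.estimate <= res.ci_high

    def test_rater_symmetry(self, rng):
        x = rng.normal(size=(30, 2))
        assert ss.icc_2_1(x).estimate == pytest.approx(
            ss.icc_2_1(x[:, ::-1]).estimate
        )

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=(40, 2)) + rng.normal(size=(40, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(40), 2),
            "rater": np.tile([0, 1], 40),
            "y": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="y").set_index("Type")
        res = ss.icc_2_1(x)
        # ICC(A,1): absolute agreement, single rater, two-way random effects
        assert res.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]  # reported to 2 decimals
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            ss.icc_2_1(np.full((5, 2), 3.0))


class TestAdjustedIcc:
    def test_uncorrelated_covariate_changes_little(self, rng):
        subj = rng.normal(0, 2, 200)
        x = np.column_stack([subj + rng.normal(0, 0.5, 200),
                             subj + rng.normal(0, 0.5, 200)])
        cov = rng.normal(size=200)
        plain = ss.icc_2_1(x).estimate
        adj = ss.adjusted_icc(x, cov).estimate
        assert adj == pytest.approx(plain, abs=0.02)

    def test_values_equal_covariate_undefined(self):
        cov = np.arange(10.0)
        x = np.column_stack([cov, cov])
        with pytest.raises(ValidationError):
            ss.adjusted_icc(x, cov)

    def test_strong_covariate_reduces_icc(self, rng):
        cov = rng.normal(50, 10, 100)
        subj = 0.8 * cov + rng.normal(0, 1, 100)
        x = np.column_stack([subj + rng.normal(0, 1, 100),
                             subj + rng.normal(0, 1, 100)])
        assert ss.adjusted_icc(x, cov).estimate <= ss.icc_2_1(x).estimate

    def test_constant_covariate_falls_back(self, rng):
        x = rng.normal(size=(20, 2)) + rng.normal(size=(20, 1))
        with pytest.warns(UserWarning, match="constant covariate"):
            res = ss.adjusted_icc(x, np.full(20, 7.0))
        assert res.estimate == pytest.approx(ss.icc_2_1(x).estimate)


class TestReferenceSizeCurve:
    def test_full_reference_single_draw_equals_direct_pipeline(self, cohort):
        ref = cohort["reference"]
        sim = cohort["sim"]
        curve = ss.reference_size_curve(
            ref, sim.betas_a, sim.betas_b, cohort["pairs"],
            sizes=[ref.shape[1]], n_draws=1, seed=0,
        )
        direct = ss.shared_proportion(cohort["calls_a"], cohort["calls_b"],
                                      cohort["pairs"])
        for d in ("hypo", "hyper"):
            want = direct.loc[direct.direction == d, "prop_mean"].mean()
            got = curve.loc[curve.direction == d, "mean_shared_proportion"].iloc[0]
            assert got == pytest.approx(want, abs=1e-12)

    def test_row_count_and_size_validation(self, cohort):
        sim = cohort["sim"]
        curve = ss.reference_size_curve(
            cohort["reference"], sim.betas_a, sim.betas_b, cohort["pairs"],
            sizes=[20, 40], n_draws=1, seed=1,
        )
        assert len(curve) == 4  # two sizes x two directions
        with pytest.raises(ValidationError):
            ss.reference_size_curve(
                cohort["reference"], sim.betas_a, sim.betas_b, cohort["pairs"],
                sizes=[5], n_draws=1, seed=1,
            )
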