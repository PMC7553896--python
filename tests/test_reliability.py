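import numpy as np
import pandas as pd
import pytest

from radharm import (
    ICCResult,
    RatingsMatrix,
    classify_reliability,
    generate_ratings,
    icc_absolute_agreement,
    reliability_study,
    theoretical_icc,
)
from radharm.reliability import anova_mean_squares
from tests.oracles import anova_mean_squares_long


def make_result(ci_low, ci_high, estimate=None):
    est = estimate if estimate is not None else (ci_low + ci_high) / 2
    res = ICCResult(est, ci_low, ci_high, 1, 1, 1, 10, 3)
    return res


class TestAnovaEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_mean_squares_match_ols_anova(self, seed):
        """Two-way mean squares agree with an independent OLS ANOVA to 1e-10."""
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(5, 3))
        msr, msc, mse = anova_mean_squares(v)
        msr2, msc2, mse2 = anova_mean_squares_long(v)
        assert msr == pytest.approx(msr2, abs=1e-10)
        assert msc == pytest.approx(msc2, abs=1e-10)
        assert mse == pytest.approx(mse2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_full_icc_matches_pingouin(self, seed):
        """Estimate and 95% CI agree with pingouin's ICC2 (single-rater,
        absolute-agreement) implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(100 + seed)
        v = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
        res = icc_absolute_agreement(RatingsMatrix(v))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "rater": np.tile(np.arange(4), 12),
            "y": v.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="y").set_index("Type")
        assert res.estimate == pytest.approx(float(ref.loc["ICC(A,1)", "ICC"]), abs=1e-8)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        # ours applies the truncation-at-zero rule before reporting
        assert res.ci_low == pytest.approx(max(float(lo), 0.0), abs=5e-3)
        assert res.ci_high == pytest.approx(min(float(hi), 1.0), abs=5e-3)


class TestIccBehaviour:
    def test_identical_raters_give_one(self):
        col = np.arange(10, dtype=float)
        res = icc_absolute_agreement(RatingsMatrix(np.column_stack([col, col, col])))
        assert res.estimate == 1.0
        assert res.category == "excellent"

    def test_negative_estimate_truncated_to_zero(self):
        col = np.arange(8, dtype=float)
        noise = np.random.default_rng(0).normal(scale=0.1, size=8)
        res = icc_absolute_agreement(RatingsMatrix(np.column_stack([col, -col + noise])))
        assert res.estimate == 0.0
        assert res.ci_low == 0.0
        assert 0 <= res.ci_low <= res.estimate <= res.ci_high <= 1

    def test_variance_component_recovery(self):
        # subject SD 1, no rater bias, noise SD 1 -> theoretical ICC 0.5
        v = generate_ratings(1000, 4, subject_sd=1, rater_bias_sd=0, noise_sd=1, seed=7)
        res = icc_absolute_agreement(RatingsMatrix(v))
        assert theoretical_icc(1, 0, 1) == 0.5
        assert res.estimate == pytest.approx(0.5, abs=0.05)
        assert res.ci_low < 0.5 < res.ci_high

    def test_constant_matrix_flagged_one(self):
        res = icc_absolute_agreement(RatingsMatrix(np.full((5, 3), 2.5)))
        assert res.constant
        assert (res.estimate, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_listwise_deletion_of_incomplete_subjects(self):
        v = np.random.default_rng(1).normal(size=(6, 3))
        v[2, 1] = np.nan
        r = RatingsMatrix(v)
        assert r.n == 5
        assert r.n_dropped == 1

    def test_added_noise_decreases_icc_in_expectation(self):
        drops = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = generate_ratings(60, 4, 1.0, 0.0, 0.3, seed=seed)
            noisy = base.copy()
            noisy[:, 0] += rng.normal(scale=1.0, size=60)
            a = icc_absolute_agreement(RatingsMatrix(base)).estimate
            b = icc_absolute_agreement(RatingsMatrix(noisy)).estimate
            drops += b < a
        assert drops >= 9

    def test_ci_coverage_near_nominal(self):
        """95% CI covers the theoretical ICC in 90-99% of replicates."""
        true_icc = theoretical_icc(1, 0.3, 0.8)
        hits = 0
        reps = 500
        for seed in range(reps):
            v = generate_ratings(40, 4, 1.0, 0.3, 0.8, seed=10_000 + seed)
            res = icc_absolute_agreement(RatingsMatrix(v))
            hits += res.ci_low <= true_icc <= res.ci_high
        assert 0.90 <= hits / reps <= 0.99


class TestClassification:
    @pytest.mark.parametrize("ci,expected", [
        ((0.992, 1.0), "excellent"),
        ((0.30, 0.60), "poor"),
        ((0.75, 0.75), "moderate"),   # boundary falls in the lower band
        ((0.5, 0.5), "poor"),
        ((0.9, 0.9), "good"),
        ((0.76, 0.89), "good"),
        ((0.51, 0.74), "moderate"),
    ])
    def test_lower_bound_rule(self, ci, expected):
        assert classify_reliability(make_result(*ci)) == expected

    def test_straddling_ci_flagged(self):
        col = np.arange(8, dtype=float)
        noisy = col + np.random.default_rng(3).normal(scale=1.5, size=8)
        res = icc_absolute_agreement(RatingsMatrix(np.column_stack([col, noisy])))
        if res.category != res.straddles and res.ci_low <= 0.9 < res.ci_high:
            assert res.straddles


class TestReliabilityStudy:
    def _table(self, values_by_profile):
        rows = []
        for prof, vals in values_by_profile.items():
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"s{i}", "profile": prof, "feat": v})
        return pd.DataFrame(rows)

    def test_duplicated_rater_perfect_agreement(self):
        vals = list(np.random.default_rng(0).normal(size=8))
        table = self._table({"a": vals, "b": vals})
        out = reliability_study(table, ["a", "b"])
        assert out.loc[0, "estimate"] == 1.0
        assert out.loc[0, "category"] == "excellent"

    def test_constant_feature_flagged(self):
        table = self._table({"a": [1.0] * 5, "b": [1.0] * 5})
        out = reliability_study(table, ["a", "b"])
        assert out.loc[0, "category"] == "constant"
        assert np.isnan(out.loc[0, "estimate"])

    def test_requires_two_raters(self):
        table = self._table({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two profiles"):
            reliability_study(table, ["a"])

    def test_missing_profile_rejected(self):
        table = self._table({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="absent"):
            reliability_study(table, ["a", "zz"])
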