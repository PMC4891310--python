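"""Bland-Altman statistics, percentage error, paired tests, HR back-calculation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coagree import (
    MethodComparison, back_calculate_hr, bland_altman, differences,
    paired_comparison, percentage_error, percentage_error_from_loa,
)
from coagree.exceptions import InsufficientDataError

from conftest import samples_from_pairs

finite = st.floats(min_value=0.5, max_value=50.0, allow_nan=False)
pair_lists = st.lists(st.tuples(finite, finite), min_size=3, max_size=25)


class TestDifferences:
    def test_hand_example(self):
        table = differences(samples_from_pairs([(4.5, 4.0), (4.0, 3.6)]))
        assert table.loc[0, "diff"] == pytest.approx(0.5)
        assert table.loc[0, "pair_mean"] == pytest.approx(4.25)
        assert table.loc[0, "pct_diff"] == pytest.approx(11.111, abs=0.001)

    def test_identical_methods_give_zero_differences(self):
        table = differences(samples_from_pairs([(4.0, 4.0), (5.0, 5.0)]))
        assert (table["diff"] == 0).all()

    def test_sign_convention_is_reference_minus_test(self):
        table = differences(samples_from_pairs([(4.0, 4.5), (4.0, 4.5)]))
        assert table["diff"].to_numpy() == pytest.approx([-0.5, -0.5])

    def test_single_pair_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            differences(samples_from_pairs([(4.0, 4.5)]))


class TestBlandAltman:
    def test_hand_example_bias_sd_loa(self):
        # differences -1, 0, +1 around a pair mean near 4.33
        pairs = [(3.83, 4.83), (4.33, 4.33), (4.83, 3.83)]
        result = bland_altman(samples_from_pairs(pairs))
        assert result.bias == pytest.approx(0.0)
        assert result.sd_diff == pytest.approx(1.0)
        assert result.loa == pytest.approx((-1.96, 1.96))

    def test_identity_collapses_loa_to_bias(self):
        result = bland_altman(samples_from_pairs([(4.0, 4.0), (5.0, 5.0), (6.0, 6.0)]))
        assert result.bias == 0.0
        assert result.loa == (0.0, 0.0)
        assert result.pct_error == 0.0

    def test_cv_is_sd_over_mean(self):
        result = bland_altman(samples_from_pairs([(4.0, 4.0), (5.0, 5.0), (6.0, 6.0)]))
        assert result.cv_ref == pytest.approx(20.0)  # sd 1, mean 5

    def test_ci_of_bias_uses_t_quantile(self):
        from scipy import stats
        pairs = [(4.0, 3.5), (5.0, 4.2), (6.0, 5.9), (4.4, 4.0)]
        result = bland_altman(samples_from_pairs(pairs))
        half = stats.t.ppf(0.975, result.n - 1) * result.sd_diff / math.sqrt(result.n)
        assert result.ci_bias == pytest.approx((result.bias - half, result.bias + half))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(pair_lists)
    def test_matches_naive_two_pass_oracle(self, pairs):
        result = bland_altman(samples_from_pairs(pairs))
        diffs = [r - t for r, t in pairs]
        n = len(diffs)
        mean = sum(diffs) / n
        sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))
        assert result.bias == pytest.approx(mean, abs=1e-12)
        assert result.sd_diff == pytest.approx(sd, abs=1e-12)
        assert result.loa[0] == pytest.approx(mean - 1.96 * sd, abs=1e-12)
        assert result.loa[1] == pytest.approx(mean + 1.96 * sd, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(pair_lists)
    def test_method_swap_antisymmetry(self, pairs):
        fwd = bland_altman(samples_from_pairs(pairs))
        rev = bland_altman(samples_from_pairs([(t, r) for r, t in pairs]))
        assert rev.bias == pytest.approx(-fwd.bias, abs=1e-10)
        assert rev.loa == pytest.approx((-fwd.loa[1], -fwd.loa[0]), abs=1e-10)
        assert rev.pct_error == pytest.approx(fwd.pct_error, abs=1e-10)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(pair_lists, st.floats(min_value=0.1, max_value=20.0))
    def test_scale_equivariance(self, pairs, c):
        base = bland_altman(samples_from_pairs(pairs))
        scaled = bland_altman(samples_from_pairs([(c * r, c * t) for r, t in pairs]))
        assert scaled.bias == pytest.approx(c * base.bias, rel=1e-9, abs=1e-9)
        assert scaled.loa[0] == pytest.approx(c * base.loa[0], rel=1e-9, abs=1e-9)
        assert scaled.pct_error == pytest.approx(base.pct_error, rel=1e-9, abs=1e-9)
        assert scaled.cv_ref == pytest.approx(base.cv_ref, rel=1e-9)


class TestPercentageError:
    def test_hand_example(self):
        pe = percentage_error(sd_diff=1.0, mean_ref=4.333, mean_test=4.333)
        assert pe.value == pytest.approx(45.2, abs=0.05)
        assert not pe.acceptable

    def test_zero_sd_is_acceptable(self):
        pe = percentage_error(sd_diff=0.0, mean_ref=4.0, mean_test=4.0)
        assert pe.value == 0.0 and pe.acceptable

    def test_nonpositive_pooled_mean_is_error(self):
        with pytest.raises(ValueError):
            percentage_error(sd_diff=1.0, mean_ref=1.0, mean_test=-3.0)

    def test_reconstruction_from_published_loa(self):
        # bias 0.5, LoA (-2.9, 4.0), means 4.5 / 4.0 -> half-width 3.45 over 4.25
        pe = percentage_error_from_loa(-2.9, 4.0, 4.5, 4.0)
        assert pe.value == pytest.approx(81.2, abs=0.05)
        assert not pe.acceptable


class TestPairedComparison:
    def test_constant_shift_is_perfectly_correlated(self):
        pairs = [(1, 1.1), (2, 2.1), (3, 3.1), (4, 4.1)]
        result = paired_comparison(samples_from_pairs(pairs))
        assert result.mean_difference == pytest.approx(-0.1)
        assert result.r == pytest.approx(1.0)

    def test_identity_gives_p_one_under_t_branch(self):
        result = paired_comparison(samples_from_pairs([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]))
        assert result.location_test_used == "paired_t"
        assert result.location_p == 1.0
        assert result.mean_difference == 0.0

    def test_rank_reversal_gives_r_minus_one(self):
        pairs = [(1, 4), (2, 3), (3, 2), (4, 1)]
        result = paired_comparison(samples_from_pairs(pairs))
        assert result.r == pytest.approx(-1.0)

    def test_normality_gate_routes_to_nonparametric(self):
        rng = np.random.default_rng(4)
        ref = np.exp(rng.normal(0, 1.5, 60)) + 0.5  # heavily skewed
        test = ref * np.exp(rng.normal(0, 0.3, 60))
        result = MethodComparison(ref, test, variable="ci").fit()
        assert result.location_test_used == "wilcoxon"
        assert result.correlation_method == "spearman"

    def test_gate_is_auditable(self):
        result = paired_comparison(samples_from_pairs([(4.0, 3.9), (5.0, 4.8), (6.0, 6.1), (4.5, 4.4)]))
        assert result.normality_p_ref is not None
        assert result.normal in (True, False)


class TestBackCalculateHr:
    def test_formula(self):
        assert back_calculate_hr(3.0, 30.0) == pytest.approx(100.0)
        assert back_calculate_hr(4.0, 31.2) == pytest.approx(128.2, abs=0.01)
        assert back_calculate_hr(0.0, 30.0) == 0.0

    def test_nonpositive_svi_rejected(self):
        with pytest.raises(ValueError):
            back_calculate_hr(4.0, 0.0)

    def test_dataset_level_wrapper_compares_against_reference_hr(self):
        from conftest import make_sample
        # test CI 4.0, SVI 32 -> calculated HR 125; reference HR 150
        samples = [
            make_sample(subject=f"S{i}", ref={"hr": 150.0},
                        test={"ci": 4.0, "svi": 32.0})
            for i in range(4)
        ]
        result = bland_altman(samples, "hr_calc")
        assert result.mean_test == pytest.approx(125.0)
        assert result.bias == pytest.approx(25.0)
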