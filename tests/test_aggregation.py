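"""Unit and property tests of the p-value combiners.

Expected values tagged as derived were computed with independent oracles:
chi-square tail probabilities by numerical integration of the hand-coded
density (``_chi2_sf_quad``) and quantiles by bisection on that integral,
not by the scipy calls the implementation itself uses.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import gammaln

from featde.aggregation import (
    BrownCorrection,
    brown_combine,
    brown_correction,
    empirical_brown_combine,
    fisher_combine,
    lancaster_combine,
)


def _chi2_pdf(x, k):
    return np.exp((k / 2 - 1) * np.log(x) - x / 2
                  - (k / 2) * np.log(2) - gammaln(k / 2))


def _chi2_sf_quad(x, k):
    """Upper-tail chi-square probability by numerical integration."""
    val, _ = quad(_chi2_pdf, x, np.inf, args=(k,), limit=200)
    return val


def _chi2_isf_bisect(p, k, lo=1e-12, hi=1e4):
    """Upper-tail quantile by bisection on the integrated survival function."""
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _chi2_sf_quad(mid, k) > p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestFisher:
    def test_all_ones_gives_statistic_zero(self):
        res = fisher_combine([1.0, 1.0])
        assert res.statistic == 0.0
        assert res.p_combined == 1.0
        assert res.dof == 4 and res.scale == 1.0

    def test_single_p_is_identity(self):
        assert fisher_combine([0.3]).p_combined == 0.3

    def test_matches_numerical_integration_oracle(self):
        res = fisher_combine([0.05, 0.05])
        expected_stat = -2 * np.log(0.05) * 2
        assert res.statistic == pytest.approx(11.982929094215963, rel=1e-12)
        assert res.p_combined == pytest.approx(
            _chi2_sf_quad(expected_stat, 4), rel=1e-8
        )

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError, match="no features"):
            fisher_combine([])

    def test_zero_p_is_clamped_not_nan(self):
        res = fisher_combine([0.0, 0.5])
        assert np.isfinite(res.statistic)
        assert 0.0 <= res.p_combined <= 1.0

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 1.5])
        with pytest.raises(ValueError):
            fisher_combine([0.5, -0.1])


class TestLancaster:
    def test_weights_of_two_recover_fisher(self, rng):
        for _ in range(50):
            k = rng.integers(1, 20)
            p = rng.uniform(1e-6, 1, size=k)
            f = fisher_combine(p)
            l = lancaster_combine(p, np.full(k, 2.0))
            assert l.p_combined == pytest.approx(f.p_combined, abs=1e-10)

    def test_single_feature_identity(self):
        assert lancaster_combine([0.5], [2.0]).p_combined == 0.5
        assert lancaster_combine([0.07], [11.3]).p_combined == 0.07

    def test_matches_bisection_oracle(self):
        # statistic = Q_10(0.01) + Q_3(0.2); reference tail with 13 dof
        q1 = _chi2_isf_bisect(0.01, 10)
        q2 = _chi2_isf_bisect(0.2, 3)
        res = lancaster_combine([0.01, 0.2], [10, 3])
        assert res.dof == 13
        assert res.statistic == pytest.approx(q1 + q2, rel=1e-6)
        assert res.p_combined == pytest.approx(
            _chi2_sf_quad(q1 + q2, 13), rel=1e-6
        )

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError, match="length"):
            lancaster_combine([0.1, 0.2], [2.0])

    def test_nonpositive_weight_raises(self):
        with pytest.raises(ValueError, match="positive"):
            lancaster_combine([0.1, 0.2], [2.0, 0.0])


class TestBrownCorrection:
    def test_independence_reduces_to_fisher(self):
        corr = brown_correction(4.0 * np.eye(3))
        assert corr.c == 1.0
        assert corr.f == 6.0

    def test_perfect_correlation_closed_form(self):
        # all off-diagonals 4: Var = 4K^2, E = 2K -> c = K, f = 2
        for k in (2, 5, 9):
            cov = np.full((k, k), 4.0)
            corr = brown_correction(cov)
            assert corr.c == pytest.approx(k)
            assert corr.f == pytest.approx(2.0)

    def test_hand_computed_intermediate_case(self):
        # K=2, off-diagonal 2: Var = 8 + 4 = 12, E = 4 -> c = 1.5, f = 8/3
        corr = brown_correction([[4.0, 2.0], [2.0, 4.0]])
        assert corr.c == pytest.approx(1.5)
        assert corr.f == pytest.approx(8.0 / 3.0)

    def test_degenerate_covariance_raises(self):
        cov = np.array([[4.0, -8.0], [-8.0, 4.0]])
        with pytest.raises(ValueError, match="degenerate"):
            brown_correction(cov)

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError, match="symmetric"):
            brown_correction([[4.0, 1.0], [2.0, 4.0]])


class TestBrownCombine:
    def test_independence_limit_equals_fisher(self, rng):
        for _ in range(20):
            k = rng.integers(2, 15)
            p = rng.uniform(1e-8, 1, size=k)
            f = fisher_combine(p)
            b = brown_combine(p, BrownCorrection(c=1.0, f=2.0 * k))
            assert b.p_combined == pytest.approx(f.p_combined, abs=1e-12)

    def test_duplicated_features_collapse_to_single_p(self):
        # K identical p with c = K, f = 2: statistic/c = -2 ln p*
        for k, p_star in ((4, 0.03), (8, 0.4)):
            res = brown_combine([p_star] * k, BrownCorrection(c=float(k), f=2.0))
            assert res.p_combined == pytest.approx(p_star, rel=1e-9)

    def test_rescaled_tail_matches_oracle(self):
        res = brown_combine([0.05, 0.05], BrownCorrection(c=1.5, f=8.0 / 3.0))
        stat = -4 * np.log(0.05)
        assert res.p_combined == pytest.approx(
            _chi2_sf_quad(stat / 1.5, 8.0 / 3.0), rel=1e-6
        )


class TestEmpiricalBrown:
    def test_single_feature_identity(self, rng):
        res = empirical_brown_combine([0.07], rng.normal(size=(1, 30)))
        assert res.p_combined == 0.07
        assert res.scale == 1.0 and res.dof == 2.0

    def test_duplicated_rows_approach_single_p(self, rng):
        # two identical rows and identical p: closed form is (c=2, f=2),
        # recovered up to the ECDF bias at finite S
        row = rng.normal(size=(1, 400))
        data = np.vstack([row, row])
        for p_star in (0.04, 0.3, 0.8):
            res = empirical_brown_combine([p_star, p_star], data)
            assert res.p_combined == pytest.approx(p_star, abs=0.02)
            assert res.scale == pytest.approx(2.0, abs=0.1)

    def test_independent_rows_recover_fisher_null(self, rng):
        cs, fs = [], []
        for _ in range(30):
            data = rng.normal(size=(10, 500))
            res = empirical_brown_combine(rng.uniform(size=10), data)
            cs.append(res.scale)
            fs.append(res.dof)
        assert 0.9 < np.mean(cs) < 1.1
        assert 18.0 < np.mean(fs) < 22.0

    def test_constant_rows_treated_as_independent(self, rng):
        data = np.vstack([np.full(50, 3.0), rng.normal(size=50)])
        res = empirical_brown_combine([0.1, 0.2], data)
        f_ref = fisher_combine([0.1, 0.2])
        assert res.scale == pytest.approx(1.0)
        assert res.p_combined == pytest.approx(f_ref.p_combined, rel=1e-9)

    def test_row_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="rows"):
            empirical_brown_combine([0.1, 0.2, 0.3], rng.normal(size=(2, 10)))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.integers(2, 12),
    st.integers(0, 10**6),
    st.sampled_from(["fisher", "lancaster", "brown", "ebm"]),
)
def test_p_combined_is_monotone_in_each_p(k, seed, method):
    """Decreasing any single p_i never increases the combined p-value."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 1.0, size=k)
    i = int(rng.integers(k))
    p_lower = p.copy()
    p_lower[i] *= 0.5
    if method == "fisher":
        hi, lo = fisher_combine(p), fisher_combine(p_lower)
    elif method == "lancaster":
        w = rng.uniform(0.5, 20, size=k)
        hi, lo = lancaster_combine(p, w), lancaster_combine(p_lower, w)
    elif method == "brown":
        corr = BrownCorrection(c=1.7, f=1.3 * k)
        hi, lo = brown_combine(p, corr), brown_combine(p_lower, corr)
    else:
        data = rng.normal(size=(k, 40))
        hi = empirical_brown_combine(p, data)
        lo = empirical_brown_combine(p_lower, data)
    assert lo.p_combined <= hi.p_combined + 1e-12
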