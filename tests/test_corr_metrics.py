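import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from attractorscape import (bicor, corr, estimate_mi, mi_correlation,
                            temporal_series)
from attractorscape.corr_metrics import rank_bins
from conftest import make_expr


def bicor_oracle(x, y):
    """Direct evaluation of the biweight midcorrelation formulas."""
    def tilde(p):
        med = np.median(p)
        mad = np.median(np.abs(p - med))
        u = (p - med) / (9 * mad)
        w = (1 - u**2) ** 2 * ((1 - np.abs(u)) > 0)
        num = (p - med) * w
        return num / np.sqrt(np.sum(num**2))
    return float(np.sum(tilde(np.asarray(x, float)) * tilde(np.asarray(y, float))))


def mi_oracle(bx, by, k):
    """Brute-force MI via explicit loops over the K×K contingency table."""
    n = len(bx)
    joint = np.zeros((k, k))
    for i in range(n):
        joint[bx[i], by[i]] += 1
    joint /= n
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    mi = 0.0
    for a in range(k):
        for b in range(k):
            if joint[a, b] > 0:
                mi += joint[a, b] * np.log(joint[a, b])
    for a in range(k):
        if px[a] > 0:
            mi -= px[a] * np.log(px[a])
        if py[a] > 0:
            mi -= py[a] * np.log(py[a])
    return mi


class TestCorr:
    @pytest.mark.parametrize("method", ["pearson", "spearman", "bicor"])
    def test_identity_is_one(self, method):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0])
        assert corr(x, x, method) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_antisymmetry_is_minus_one(self, method):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert corr(x, -x, method) == pytest.approx(-1.0)

    def test_bicor_matches_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_bicor_robust_to_one_outlier_pearson_is_not(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        y = x + 0.05 * rng.normal(size=10_000)
        assert abs(bicor(x, y) - corr(x, y, "pearson")) < 1e-2
        y2 = y.copy()
        y2[0] = 100 * (y.max() - y.min())
        assert abs(corr(x, y2, "pearson") - corr(x, y, "pearson")) > 0.1
        assert abs(bicor(x, y2) - bicor(x, y)) < 1e-3

    def test_constant_vector_signals_error(self):
        with pytest.raises(ZeroDivisionError):
            corr(np.ones(5), np.arange(5.0), "pearson")
        with pytest.raises(ZeroDivisionError):
            bicor(np.ones(5), np.arange(5.0))

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.7, 0.9, 2.4, 3.3, 0.1, 1.1])
        y = np.array([1.0, 0.2, 2.2, 1.4, 2.9, 0.7, 0.4])
        for method in ("pearson", "spearman", "bicor"):
            assert corr(a * x + b, y, method) == pytest.approx(
                corr(x, y, method), abs=1e-9)


class TestEstimateMI:
    def test_self_mi_equals_log_k(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        est = estimate_mi(x, x, k=10)
        assert est.raw_mi == pytest.approx(np.log(10), abs=1e-12)

    def test_independent_corrected_mi_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=1000), rng.normal(size=1000)
            vals.append(estimate_mi(x, y, k=10, seed=seed).corrected_mi)
        assert np.mean(vals) <= 0.02

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=137)
        y = 0.5 * x + rng.normal(size=137)
        k = 10
        est = estimate_mi(x, y, k=k)
        assert est.raw_mi == pytest.approx(
            mi_oracle(rank_bins(x, k), rank_bins(y, k), k), abs=1e-12)

    def test_epsilon_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        perm = rng.permutation(300)
        a = estimate_mi(x, y, seed=9)
        b = estimate_mi(x[perm], y[perm], seed=9)
        # same rank multiset -> same bin histograms -> same epsilon
        assert a.epsilon == pytest.approx(b.epsilon, abs=1e-12)

    def test_corrected_mi_invariant(self):
        est = estimate_mi(np.arange(50.0), np.arange(50.0) ** 2, k=5)
        assert est.corrected_mi == pytest.approx(
            max(est.raw_mi - est.epsilon, 0.0))
        assert est.raw_mi >= 0 and est.epsilon >= 0


class TestMiCorrelation:
    def test_zero_maps_to_zero(self):
        assert mi_correlation(0.0) == 0.0

    def test_log10_maps_to_sqrt_099(self):
        assert mi_correlation(np.log(10)) == pytest.approx(np.sqrt(0.99))

    def test_strictly_increasing(self):
        grid = np.linspace(0, 5, 200)
        vals = [mi_correlation(v) for v in grid]
        assert np.all(np.diff(vals) > 0)


class TestTemporalSeries:
    def test_t0_self_correlation_is_one(self, small_tpm):
        expr, _ = small_tpm
        s = temporal_series(expr, "pearson")
        assert np.allclose(s.values.loc[0.0], 1.0)

    def test_monotone_drift_gives_nonincreasing_pearson(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(3, 1, size=300)
        times = [0, 0.5, 1, 2, 5, 10]
        drift = rng.normal(size=300)
        cols = [base * np.exp(0.25 * i * drift) for i in range(len(times))]
        em = make_expr(np.column_stack(cols), times, ["a"])
        s = temporal_series(em, "pearson")
        vals = s.values["a"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)

    def test_missing_t0_rejected(self):
        em = make_expr(np.ones((5, 2)), [1, 2], ["a"])
        with pytest.raises(ValueError, match="t=0"):
            temporal_series(em, "pearson")
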