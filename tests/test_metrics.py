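"""Statistics battery: r², IIC, CII, CCC, Q² family, F, RMSE/MAE, leverage."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcqsar.metrics import (
    PairedSeries,
    ccc,
    cii,
    correlation_r2,
    fisher_f,
    iic,
    pearson_r,
    q2_external,
    q2_loo,
    rmse_mae,
    signed_mae,
    williams_data,
)

rng = np.random.default_rng(987)


def series(obs, calc):
    return PairedSeries(np.asarray(obs, float), np.asarray(calc, float))


def random_series(n, spread=1.0):
    o = rng.normal(0, 1, n)
    return series(o, o + rng.normal(0, spread, n))


# ---------------------------------------------------------------------------
# independent oracles


def r2_oracle(o, c):
    """Direct covariance-formula r² (population moments)."""
    o, c = np.asarray(o, float), np.asarray(c, float)
    cov = ((o - o.mean()) * (c - c.mean())).mean()
    denom = o.var() * c.var()
    return 0.0 if denom == 0 else cov * cov / denom


def cii_oracle(s):
    """From-scratch n-pass leave-one-out recomputation."""
    r2 = r2_oracle(s.observed, s.calculated)
    total = 0.0
    for k in range(s.n):
        o = np.delete(s.observed, k)
        c = np.delete(s.calculated, k)
        total += max(0.0, r2_oracle(o, c) - r2)
    return 1.0 - total


def q2_loo_oracle(x, y):
    """n explicit univariate refits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    press = 0.0
    for k in range(x.size):
        xr, yr = np.delete(x, k), np.delete(y, k)
        b = ((xr - xr.mean()) * (yr - yr.mean())).sum() / ((xr - xr.mean()) ** 2).sum()
        a = yr.mean() - b * xr.mean()
        press += (y[k] - (a + b * x[k])) ** 2
    return 1.0 - press / ((y - y.mean()) ** 2).sum()


# ---------------------------------------------------------------------------


class TestCorrelation:
    def test_identity_and_antiidentity(self):
        o = [0.0, 1, 2, 3]
        assert correlation_r2(series(o, o)) == pytest.approx(1.0)
        assert correlation_r2(series(o, [-v for v in o])) == pytest.approx(1.0)

    def test_against_direct_formula(self):
        o, c = [0, 1, 2, 3], [0, 1, 2, 10]
        assert correlation_r2(series(o, c)) == pytest.approx(r2_oracle(o, c), abs=1e-12)

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert correlation_r2(series([1, 1, 1], [0, 1, 2])) == 0.0


class TestSignedMae:
    def test_two_per_class(self):
        s = series([0, 1, 2, 3], [0.1, 0.9, 2.1, 2.9])
        assert signed_mae(s) == (pytest.approx(0.1), pytest.approx(0.1))

    def test_all_zero_residuals(self):
        assert signed_mae(series([1, 2, 3], [1, 2, 3])) == (0.0, 0.0)

    def test_empty_positive_class(self):
        s = series([0.0, 0.0], [0.3, 0.1])  # both deltas negative
        mae_neg, mae_pos = signed_mae(s)
        assert mae_neg == pytest.approx(0.2)
        assert mae_pos == 0.0


class TestIic:
    def test_symmetric_residuals_give_r(self):
        s = series([0, 1, 2, 3], [0.1, 0.9, 2.1, 2.9])
        assert iic(s) == pytest.approx(pearson_r(s.observed, s.calculated))

    def test_perfect_fit(self):
        assert iic(series([0, 1, 2], [0, 1, 2])) == pytest.approx(1.0)

    def test_one_sided_residuals_give_zero(self):
        s = series([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])  # all deltas positive
        assert iic(s) == 0.0

    def test_bounded_by_correlation(self):
        for _ in range(200):
            s = random_series(int(rng.integers(4, 40)))
            assert abs(iic(s)) <= abs(pearson_r(s.observed, s.calculated)) + 1e-12

    def test_shift_invariance(self):
        s = random_series(20)
        shifted = series(s.observed + 3.7, s.calculated + 3.7)
        assert iic(shifted) == pytest.approx(iic(s), abs=1e-12)


class TestCii:
    def test_collinear_series(self):
        o = np.arange(6.0)
        assert cii(series(o, 2 * o + 1)) == pytest.approx(1.0)

    def test_against_loo_oracle_example(self):
        s = series([0, 1, 2, 3, 10], [0, 1, 2, 3, 4])
        assert cii(s) == pytest.approx(cii_oracle(s), abs=1e-12)

    def test_against_loo_oracle_random(self):
        for _ in range(200):
            s = random_series(int(rng.integers(4, 51)))
            assert cii(s) == pytest.approx(cii_oracle(s), abs=1e-12)

    def test_duplicated_perfect_fit(self):
        o = np.r_[np.arange(4.0), np.arange(4.0)]
        assert cii(series(o, o)) == pytest.approx(1.0)

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            cii(series([0, 1, 2], [0, 1, 2]))


class TestCcc:
    def test_perfect_agreement(self):
        o = [0.0, 1, 2, 3]
        assert ccc(series(o, o)) == pytest.approx(1.0)

    def test_location_shift(self):
        # population variance 1.25 each, cov 1.25, mean shift 1
        s = series([0, 1, 2, 3], [1, 2, 3, 4])
        assert ccc(s) == pytest.approx(2 * 1.25 / (2 * 1.25 + 1), abs=1e-9)

    def test_anticoncordance(self):
        s = series([-1.5, -0.5, 0.5, 1.5], [1.5, 0.5, -0.5, -1.5])
        assert ccc(s) == pytest.approx(-1.0)

    def test_ccc_is_one_only_for_identity(self):
        s = series([0, 1, 2, 3], [0, 1, 2, 3.01])
        assert ccc(s) < 1.0


class TestQ2Loo:
    def test_exact_linear_relationship(self):
        x = np.array([0.0, 1, 2, 3, 4])
        assert q2_loo(x, 2 + 3 * x) == pytest.approx(1.0)

    def test_against_explicit_refits(self):
        x, y = np.array([0.0, 1, 2, 3]), np.array([0.0, 1, 2, 4])
        assert q2_loo(x, y) == pytest.approx(q2_loo_oracle(x, y), abs=1e-10)

    def test_shortcut_equals_refits_random(self):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.normal(0, 1, n)
            y = 1 + 2 * x + rng.normal(0, 0.5, n)
            assert q2_loo(x, y) == pytest.approx(q2_loo_oracle(x, y), abs=1e-10)

    def test_q2_below_r2(self):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0, 1, n)
            assert q2_loo(x, y) <= r2_oracle(x, y) + 1e-12


class TestQ2External:
    def test_perfect_predictions(self):
        s = series([1.0, 2, 3], [1.0, 2, 3])
        assert q2_external(s, np.array([0.0, 2, 4])) == (
            pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))

    def test_equal_means_make_f1_equal_f2(self):
        s = series([0.0, 2.0], [0.5, 1.0])
        f1, f2, _ = q2_external(s, np.array([-1.0, 3.0]))  # same mean 1
        assert f1 == pytest.approx(f2)

    def test_toy_hand_computation(self):
        s = series([1.0, 3.0], [1.0, 2.0])
        f1, f2, f3 = q2_external(s, np.array([0.0, 2.0]))
        assert f1 == pytest.approx(0.75)
        assert f2 == pytest.approx(0.5)
        assert f3 == pytest.approx(0.5)

    def test_degenerate_rejected(self):
        s = series([1.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            q2_external(s, np.array([1.0, 1.0]))


class TestFisherF:
    @pytest.mark.parametrize(
        "r2,n,expected",
        [
            # published univariate-model rows: (R², n) -> integer F
            (0.5552, 28, 32), (0.6911, 28, 58), (0.9101, 29, 273),
            (0.8548, 29, 159), (0.8893, 28, 209), (0.8680, 28, 171),
            (0.5347, 28, 30), (0.5607, 28, 33), (0.8374, 28, 134),
            (0.5067, 28, 27), (0.6341, 28, 45), (0.9143, 29, 288),
            (0.5253, 29, 30), (0.6806, 28, 55), (0.9494, 28, 488),
            (0.5870, 28, 37), (0.6347, 28, 45), (0.8773, 28, 186),
        ],
    )
    def test_reproduces_printed_integers(self, r2, n, expected):
        assert round(fisher_f(r2, n)) == expected

    def test_zero_correlation(self):
        assert fisher_f(0.0, 30) == 0.0

    def test_r2_one_rejected(self):
        with pytest.raises(ValueError):
            fisher_f(1.0, 10)


class TestRmseMae:
    def test_perfect(self):
        assert rmse_mae(series([1, 2], [1, 2])) == (0.0, 0.0)

    def test_unit_residuals(self):
        assert rmse_mae(series([1.0, -1.0], [0.0, 0.0])) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_hand_arithmetic(self):
        r, m = rmse_mae(series([0.1, 0.3], [0.0, 0.0]))
        assert r == pytest.approx(np.sqrt(0.05), abs=1e-4)
        assert m == pytest.approx(0.2)


class TestWilliams:
    def test_centered_point_minimum_leverage(self):
        train = np.array([0.0, 1, 2, 3])
        s = series([1.0, 2.0], [1.0, 1.5])
        h, _, h_star = williams_data(np.array([1.5, 1.5]), s, train, train_rmse=1.0)
        assert h[0] == pytest.approx(0.25)
        assert h_star == pytest.approx(1.5)

    def test_hand_arithmetic(self):
        train = np.array([0.0, 1, 2, 3])
        s = series([1.0, 2.0], [1.0, 1.5])
        h, std_resid, _ = williams_data(np.array([0.0, 1.5]), s, train, train_rmse=0.5)
        assert h[0] == pytest.approx(0.25 + 2.25 / 5)
        assert std_resid[1] == pytest.approx(1.0)

    def test_training_leverages_sum_to_two(self):
        train = rng.normal(0, 1, 12)
        s = series(np.zeros(12), np.zeros(12) + 0.1)
        h, _, _ = williams_data(train, s, train, train_rmse=0.5)
        assert h.sum() == pytest.approx(2.0)

    def test_degenerate_training_rejected(self):
        with pytest.raises(ValueError):
            williams_data(np.array([1.0]), series([1.0], [1.0]), np.array([2.0, 2.0]), 1.0)


@given(st.integers(4, 40), st.floats(0.01, 2.0))
@settings(max_examples=50, deadline=None)
def test_cii_iic_defined_on_noisy_series(n, spread):
    """Whole-battery smoke property: indices stay in their ranges."""
    local = np.random.default_rng(n * 1000 + int(spread * 100))
    o = local.normal(0, 1, n)
    s = series(o, o + local.normal(0, spread, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert cii(s) <= 1.0 + 1e-12
        assert abs(iic(s)) <= 1.0 + 1e-12
        assert -1.0 - 1e-12 <= ccc(s) <= 1.0 + 1e-12
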