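"""Paramagnetic T1P, occupancy, the sixth-root distance law, and errors."""

import math

import numpy as np
import pytest

from hemedist import (
    InputError,
    NoParamagneticEffectError,
    OccupancyParams,
    RelaxationPair,
    TemperatureSeries,
    alpha_m,
    compute_distance,
    compute_t1p,
    fast_exchange_check,
    monte_carlo_distance_se,
    propagate_distance_error,
)

TAU_C = 3.38e-10


def pair(t1f, sef, t1co, seco, label="p"):
    return RelaxationPair(label, t1f, sef, t1co, seco)


class TestComputeT1p:
    @pytest.mark.parametrize(
        "t1f, t1co",
        [(1.54, 1.85), (2.43, 4.10), (1.62, 1.69)],
    )
    def test_matches_rate_difference_arithmetic(self, t1f, t1co):
        expected = 1.0 / (1.0 / t1f - 1.0 / t1co)
        est = compute_t1p(pair(t1f, 0.1, t1co, 0.1))
        assert est.t1p == pytest.approx(expected, rel=1e-12)

    def test_wt_och2_value(self):
        assert compute_t1p(pair(1.54, 0.15, 1.85, 0.18)).t1p == pytest.approx(
            9.19, abs=0.005
        )

    def test_l382v_och2_value(self):
        assert compute_t1p(pair(2.43, 0.18, 4.10, 0.07)).t1p == pytest.approx(
            5.97, abs=0.005
        )

    def test_equal_t1s_have_no_paramagnetic_effect(self):
        with pytest.raises(NoParamagneticEffectError, match="'p'"):
            compute_t1p(pair(2.0, 0.1, 2.0, 0.1))


class TestAlphaM:
    @pytest.mark.parametrize(
        "p450, s, ks, expected",
        [
            (0.017, 171.0, 17.1, 0.017 / 188.1),
            (0.011, 102.0, 10.2, 0.011 / 112.2),
        ],
    )
    def test_footnote_concentrations(self, p450, s, ks, expected):
        occ = OccupancyParams(p450_conc=p450, substrate_conc=s, ks=ks)
        assert alpha_m(occ) == pytest.approx(expected, rel=1e-12)

    def test_dilute_enzyme_limit(self):
        occ = OccupancyParams(p450_conc=1e-12, substrate_conc=100.0, ks=10.0)
        assert alpha_m(occ) == pytest.approx(0.0, abs=1e-12)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(InputError):
            OccupancyParams(p450_conc=0.0, substrate_conc=1.0, ks=1.0)


class TestComputeDistance:
    def test_wt_och2_distance(self):
        t1p = compute_t1p(pair(1.54, 0.15, 1.85, 0.18)).t1p
        r = compute_distance(t1p, 0.017 / 188.1, 2.91, TAU_C)
        assert r == pytest.approx(6.55, abs=0.1)

    def test_sixth_root_scaling_is_exact(self):
        r1 = compute_distance(9.19, 9.04e-5, 2.91, TAU_C)
        r2 = compute_distance(64.0 * 9.19, 9.04e-5, 2.91, TAU_C)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_n312l_och2_distance_from_components(self):
        r = compute_distance(39.12, 9.80e-5, 1.87, TAU_C)
        assert r == pytest.approx(7.87, abs=0.05)

    def test_monotone_in_every_factor(self):
        base = compute_distance(9.19, 9.04e-5, 2.91, TAU_C)
        for k, args in [
            (1.5, (1.5 * 9.19, 9.04e-5, 2.91, TAU_C)),
            (1.5, (9.19, 1.5 * 9.04e-5, 2.91, TAU_C)),
            (1.5, (9.19, 9.04e-5, 1.5 * 2.91, TAU_C)),
            (1.5, (9.19, 9.04e-5, 2.91, 1.5 * TAU_C)),
        ]:
            assert compute_distance(*args) == pytest.approx(
                base * k ** (1 / 6), rel=1e-12
            )

    def test_non_positive_input_rejected(self):
        with pytest.raises(InputError):
            compute_distance(-1.0, 9e-5, 2.91, TAU_C)


class TestPropagateDistanceError:
    def test_zero_ses_give_zero(self):
        p = pair(1.54, 0.0, 1.85, 0.0)
        r = compute_distance(compute_t1p(p).t1p, 9.04e-5, 2.91, TAU_C)
        assert propagate_distance_error(p, r) == 0.0

    def test_first_order_linearity_in_ses(self):
        p1 = pair(1.54, 0.15, 1.85, 0.18)
        p2 = pair(1.54, 0.30, 1.85, 0.36)
        r = compute_distance(compute_t1p(p1).t1p, 9.04e-5, 2.91, TAU_C)
        assert propagate_distance_error(p2, r) == pytest.approx(
            2.0 * propagate_distance_error(p1, r), rel=1e-12
        )

    def test_agrees_with_monte_carlo_at_moderate_t1p_error(self):
        """First-order and Monte-Carlo SEs agree within 15% when the
        relative T1P error is moderate (~20%, double-mutant methylene)."""
        p = pair(1.98, 0.12, 2.90, 0.09)
        am = 0.004 / 38.5
        t1p = compute_t1p(p).t1p
        r = compute_distance(t1p, am, 2.11, TAU_C)
        analytic = propagate_distance_error(p, r)
        mc = monte_carlo_distance_se(
            p, am, 2.11, TAU_C, n_draws=20000,
            rng=np.random.default_rng(1),
        )
        assert abs(analytic - mc) / mc < 0.15

    def test_analytic_se_tracks_relative_t1p_error(self):
        p = pair(1.54, 0.15, 1.85, 0.18)
        t1p_est = compute_t1p(p)
        r = compute_distance(t1p_est.t1p, 9.04e-5, 2.91, TAU_C)
        r_se = propagate_distance_error(p, r)
        assert r_se == pytest.approx(
            (r / 6.0) * t1p_est.se / t1p_est.t1p, rel=1e-12
        )


def _ols_oracle(x, y):
    # closed-form simple regression, independent of the implementation
    x, y = np.asarray(x), np.asarray(y)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - ybar) ** 2)
    return slope, intercept, r2


class TestFastExchangeCheck:
    def test_noiseless_positive_slope_passes(self):
        T = np.array([283.0, 298.0, 310.0])
        inv_t1p = 0.01 + 30.0 / T
        diag = fast_exchange_check(
            TemperatureSeries(temperatures=T, t1p_values=1.0 / inv_t1p)
        )
        assert diag.passed
        assert diag.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_negative_slope_fails(self):
        T = np.array([283.0, 298.0, 310.0])
        inv_t1p = 0.2 - 30.0 / T
        diag = fast_exchange_check(
            TemperatureSeries(temperatures=T, t1p_values=1.0 / inv_t1p)
        )
        assert not diag.passed
        assert diag.slope < 0

    def test_noisy_line_below_r2_threshold_fails(self):
        rng = np.random.default_rng(42)
        T = np.linspace(280.0, 320.0, 10)
        inv_t1p = 0.01 + 30.0 / T + rng.normal(0.0, 1.5e-3, T.size)
        ts = TemperatureSeries(temperatures=T, t1p_values=1.0 / inv_t1p)
        diag = fast_exchange_check(ts)
        slope, intercept, r2 = _ols_oracle(1.0 / T, inv_t1p)
        assert diag.slope == pytest.approx(slope, abs=1e-10 * abs(slope))
        assert diag.intercept == pytest.approx(intercept, rel=1e-10)
        assert diag.r_squared == pytest.approx(r2, abs=1e-12)
        assert diag.slope > 0 and diag.r_squared < 0.95
        assert not diag.passed

    def test_two_temperatures_rejected(self):
        with pytest.raises(InputError, match=">= 3"):
            TemperatureSeries(
                temperatures=np.array([283.0, 298.0]),
                t1p_values=np.array([5.0, 6.0]),
            )
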