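"""Tests of the four cell-cycle / mode-of-division estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cyclefate as cf
from cyclefate.errors import (
    EstimationError,
    InsufficientDataError,
    InvalidParameterError,
    PeakNotBracketedError,
)


def _curve(exposures, fractions, se=0.0):
    exposures = np.asarray(exposures, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    se_arr = np.full_like(fractions, se)
    return cf.CumulativeCurve(exposures, fractions, se_arr, np.full_like(fractions, 500))


class TestC1:
    def test_exact_labeling_index_gamma_072(self):
        # f(t) = 0.24 + 0.036 t capped at 0.72 -> gamma 0.72, T = 0.72/0.036 = 20
        t = np.arange(1.0, 31.0, 2.0)
        f = np.minimum(0.24 + 0.036 * t, 0.72)
        res = cf.c1_fit(_curve(t, f))
        assert np.isclose(res.gamma_hat, 0.72)
        assert np.isclose(res.slope, 0.036)
        assert np.isclose(res.T_hat, 20.0)

    def test_exact_labeling_index_full_growth_fraction(self):
        t = np.arange(1.0, 31.0, 2.0)
        f = np.minimum(1 / 3 + 0.05 * t, 1.0)
        res = cf.c1_fit(_curve(t, f))
        assert np.isclose(res.T_hat, 20.0, rtol=1e-9)
        assert np.isclose(res.gamma_hat, 1.0)

    def test_all_plateau_is_estimation_failure(self):
        t = np.arange(1.0, 17.0, 2.0)
        with pytest.raises(EstimationError):
            cf.c1_fit(_curve(t, np.full_like(t, 0.7)))

    def test_error_propagation_into_T(self):
        t = np.arange(1.0, 31.0, 2.0)
        f = np.minimum(0.24 + 0.036 * t, 0.72)
        res = cf.c1_fit(_curve(t, f, se=0.0))
        assert res.slope_se == 0.0 and res.T_se == 0.0


class TestC2:
    def test_exact_dual_curve(self):
        # f(d) = 1/3 + 0.05 d with gamma=1: T = 20, T_S = intercept*T = 6.67
        d = np.arange(1.0, 9.0, 2.0)
        res = cf.c2_fit(_curve(d, 1 / 3 + 0.05 * d), gamma=1.0)
        assert np.isclose(res.T_hat, 20.0)
        assert np.isclose(res.T_S_hat, 20.0 / 3, rtol=1e-6)

    def test_zero_intercept_gives_zero_TS(self):
        d = np.arange(1.0, 9.0, 2.0)
        res = cf.c2_fit(_curve(d, 0.05 * d), gamma=1.0)
        assert np.isclose(res.T_S_hat, 0.0, atol=1e-12)

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            cf.c2_fit(_curve([1.0, 3.0], [0.4, 0.5]))


class TestPC:
    def test_synthetic_dip_then_peak(self):
        # trough near 8 h, re-entry peak at exactly 20 h
        t = np.arange(2.0, 31.0, 2.0)
        y = 0.25 * np.exp(-((t - 20.0) ** 2) / 40.0) + 0.3 * np.exp(-t / 4.0)
        res = cf.pc_fit(_curve(t, y))
        assert abs(res.T_hat - 20.0) < 2.0

    def test_monotone_rising_curve_not_bracketed(self):
        t = np.arange(2.0, 31.0, 2.0)
        with pytest.raises(PeakNotBracketedError):
            cf.pc_fit(_curve(t, np.linspace(0.0, 0.5, len(t))))

    def test_flat_zero_curve_fails(self):
        t = np.arange(2.0, 31.0, 2.0)
        with pytest.raises(EstimationError):
            cf.pc_fit(_curve(t, np.zeros_like(t)))


class TestBP:
    def test_homeostasis_closed_form(self):
        # P = 500, dD = 300 over 12 h, gamma=1, no death:
        # ppdd = 0, T = 500*12/300 = 20
        fP = lambda t: np.full_like(np.asarray(t, dtype=float), 500.0)  # noqa: E731
        fD = lambda t: 25.0 * np.asarray(t, dtype=float)  # noqa: E731
        est = cf.bp_estimate((fP, fD), 1.0, 0.0, span=(0.0, 12.0), grid=[0.0, 12.0])
        assert np.isclose(est.ppdd_hat[0], 0.0, atol=1e-12)
        assert np.isclose(est.T_hat[0], 20.0, rtol=1e-9)

    def test_pure_proliferation_gives_ppdd_one(self):
        fP = lambda t: 100.0 * np.exp(0.05 * np.asarray(t, dtype=float))  # noqa: E731
        fD = lambda t: np.zeros_like(np.asarray(t, dtype=float))  # noqa: E731
        est = cf.bp_estimate((fP, fD), 1.0, 0.0, span=(0.0, 20.0), grid=[0.0, 20.0])
        assert np.isclose(est.ppdd_hat[0], 1.0)

    def test_exponential_ode_oracle(self):
        # dP/dt = 0.025 P (ppdd=0.5, T=20, gamma=1): P 100 -> 271.8 over 40 h
        fP = lambda t: 100.0 * np.exp(0.025 * np.asarray(t, dtype=float))  # noqa: E731
        fD = lambda t: 100.0 * (np.exp(0.025 * np.asarray(t, dtype=float)) - 1.0)  # noqa: E731
        est = cf.bp_estimate(
            (fP, fD), 1.0, 0.0, span=(0.0, 40.0), grid=np.linspace(0, 40, 5), _sub=400
        )
        assert np.allclose(est.ppdd_hat, 0.5, atol=1e-6)
        assert np.allclose(est.T_hat, 20.0, rtol=1e-6)

    def test_exact_recovery_with_apoptosis_and_quiescence(self):
        # forward ODE with gamma=0.8, apoptosis 0.01/h, ppdd=0.5, T=20
        g, a, ppdd, T = 0.8, 0.01, 0.5, 20.0
        r = ppdd * g / T - a
        fP = lambda t: 400.0 * np.exp(r * np.asarray(t, dtype=float))  # noqa: E731
        fD = lambda t: 400.0 * (1 - ppdd) * g / T / r * (  # noqa: E731
            np.exp(r * np.asarray(t, dtype=float)) - 1.0
        )
        est = cf.bp_estimate(
            (fP, fD), g, a, span=(0.0, 40.0), grid=np.linspace(0, 40, 6), _sub=400
        )
        assert np.allclose(est.ppdd_hat, ppdd, atol=1e-5)
        assert np.allclose(est.T_hat, T, rtol=1e-5)

    def test_no_division_mass_masks_window(self):
        # shrinking P with constant D: denominator dP + dD <= 0
        fP = lambda t: 500.0 - 10.0 * np.asarray(t, dtype=float)  # noqa: E731
        fD = lambda t: np.zeros_like(np.asarray(t, dtype=float))  # noqa: E731
        est = cf.bp_estimate((fP, fD), 1.0, 0.0, span=(0.0, 10.0), grid=[0.0, 10.0])
        assert np.isnan(est.ppdd_hat[0]) and np.isnan(est.T_hat[0])
        with pytest.raises(EstimationError):
            est.mean_T()

    def test_out_of_range_estimate_clipped_with_warning(self):
        # D decreasing (impossible biologically) pushes ppdd above 1
        fP = lambda t: 500.0 + 20.0 * np.asarray(t, dtype=float)  # noqa: E731
        fD = lambda t: -5.0 * np.asarray(t, dtype=float) + 100.0  # noqa: E731
        with pytest.warns(UserWarning, match="clipped"):
            est = cf.bp_estimate((fP, fD), 1.0, 0.0, span=(0.0, 10.0), grid=[0.0, 10.0])
        assert est.ppdd_hat[0] == 1.0

    def test_stochastic_round_trip_pooled_runs(self, pooled_counts):
        counts, truth = pooled_counts
        est = cf.bp_estimate(
            counts, truth["gamma"], truth["apoptosis_rate"], grid=np.linspace(0, 48, 9)
        )
        assert abs(est.mean_T() - truth["T"]) / truth["T"] <= 0.10
        assert abs(est.mean_ppdd() - truth["ppdd"]) <= 0.10


class TestCI50:
    def _sigmoidal_data(self, noise=0.0, seed=0):
        t = np.linspace(0, 48, 13)
        P = 200 + 800 / (1 + np.exp(-(t - 20) / 6))
        D = 1200 / (1 + np.exp(-(t - 30) / 8))
        rng = np.random.default_rng(seed)
        Pn = P * (1 + noise * rng.standard_normal(len(t)))
        Dn = D * (1 + noise * rng.standard_normal(len(t)))
        return t, Pn, np.abs(P) * noise, Dn, np.abs(D) * noise

    def test_zero_se_band_collapses(self):
        t, P, _, D, _ = self._sigmoidal_data()
        est = cf.propagate_ci50(t, P, np.zeros_like(P), D, np.zeros_like(D))
        ok = np.isfinite(est.ppdd_hat)
        assert np.allclose(est.ppdd_lo[ok], est.ppdd_hat[ok], atol=1e-6)
        assert np.allclose(est.T_hi[ok], est.T_hat[ok], rtol=1e-5)

    def test_band_widens_with_se(self):
        t, P, _, D, _ = self._sigmoidal_data()
        narrow = cf.propagate_ci50(t, P, 0.01 * P, D, 0.01 * np.maximum(D, 1))
        wide = cf.propagate_ci50(t, P, 0.05 * P, D, 0.05 * np.maximum(D, 1))
        ok = np.isfinite(narrow.T_hat) & np.isfinite(wide.T_hat)
        assert np.all(
            (wide.T_hi[ok] - wide.T_lo[ok]) >= (narrow.T_hi[ok] - narrow.T_lo[ok]) - 1e-9
        )


class TestDecomposeModes:
    @pytest.mark.parametrize(
        "ppdd,expected",
        [
            (0.0, (0.25, 0.50, 0.25)),
            (1.0, (1.0, 0.0, 0.0)),
            (-1.0, (0.0, 0.0, 1.0)),
            (0.5, (0.5625, 0.375, 0.0625)),
        ],
    )
    def test_known_values(self, ppdd, expected):
        r = cf.decompose_modes(ppdd)
        assert np.allclose((r.pp, r.pd, r.dd), expected)

    @given(st.floats(-1.0, 1.0))
    @settings(max_examples=101, derandomize=True)
    def test_identity_and_normalization(self, ppdd):
        r = cf.decompose_modes(ppdd)
        assert np.isclose(r.pp + r.pd + r.dd, 1.0, atol=1e-12)
        assert np.isclose(r.ppdd, ppdd, atol=1e-12)
        assert min(r.pp, r.pd, r.dd) >= 0

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            cf.decompose_modes(1.01)
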