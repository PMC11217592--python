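"""Non-compartmental parameter estimation: trapezoids, terminal slope,
extrapolation and derived IV parameters."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolpk import (
    NCA,
    InsufficientDataError,
    NoTerminalPhaseError,
    ValidationError,
    auc_last,
    auc_segment,
    back_extrapolate_c0,
    derive_iv_params,
    extrapolate,
    fit_lambda_z,
    mrt,
    observed_landmarks,
)
from poolpk.nca import LambdaZFit, _loglinear

from .conftest import profile_from_arrays

LN2 = math.log(2)


class TestAucSegment:
    @pytest.mark.parametrize(
        "seg, rule, expected",
        [
            ((0, 10, 1, 10), "linear", 10.0),
            ((0, 10, 1, 5), "log", 5.0 / LN2),
            ((0, 10, 1, 0), "linear", 5.0),
        ],
    )
    def test_closed_forms(self, seg, rule, expected):
        assert auc_segment(*seg, rule=rule) == pytest.approx(expected)

    def test_degenerate_log_falls_back_to_linear(self, caplog):
        with caplog.at_level(logging.INFO, logger="poolpk.nca"):
            assert auc_segment(0, 10, 1, 10, rule="log") == pytest.approx(10.0)
        assert any("falling back to linear" in m for m in caplog.messages)

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            auc_segment(1, 10, 1, 5)
        with pytest.raises(ValidationError):
            auc_segment(0, -1, 1, 5)

    @given(
        c1=st.floats(0.01, 1e3),
        ratio=st.floats(0.01, 0.99),
        dt=st.floats(0.01, 100),
    )
    @settings(deadline=None, derandomize=True)
    def test_log_never_exceeds_linear_on_decline(self, c1, ratio, dt):
        """The exponential interpolant lies below the chord, so the log-rule
        area cannot exceed the linear-rule area on a declining segment."""
        c2 = c1 * ratio
        log_area = auc_segment(0, c1, dt, c2, rule="log")
        lin_area = auc_segment(0, c1, dt, c2, rule="linear")
        assert log_area <= lin_area * (1 + 1e-12)

    def test_additive_over_partition(self):
        """Splitting a segment at a point on the interpolant leaves AUC and
        AUMC unchanged (both rules)."""
        c = lambda t: 10.0 * math.exp(-0.2 * t)
        whole = _loglinear(1.0, c(1.0), 3.0, c(3.0))
        parts = np.add(
            _loglinear(1.0, c(1.0), 2.0, c(2.0)), _loglinear(2.0, c(2.0), 3.0, c(3.0))
        )
        assert whole == pytest.approx(tuple(parts))
        lin = lambda t: 10.0 - 2.0 * t
        assert auc_segment(0, lin(0), 4, lin(4)) == pytest.approx(
            auc_segment(0, lin(0), 1, lin(1)) + auc_segment(1, lin(1), 4, lin(4))
        )


class TestAucLast:
    def test_linear_up_log_down_mixed(self):
        profile = profile_from_arrays("IM", [0, 1, 2], [0, 10, 5])
        auc, _ = auc_last(profile, method="linear_up_log_down")
        assert auc == pytest.approx(5.0 + 5.0 / LN2)

    def test_dialects_agree_without_decline(self):
        profile = profile_from_arrays("IM", [0, 1, 2, 3], [0, 1, 2, 4])
        a1, m1 = auc_last(profile, method="linear_log")
        a2, m2 = auc_last(profile, method="linear_up_log_down")
        assert a1 == pytest.approx(a2)
        assert m1 == pytest.approx(m2)

    def test_single_point_insufficient(self):
        profile = profile_from_arrays("IM", [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        short = profile_from_arrays("IM", [1.0], [1.0])
        auc_last(profile)  # fine
        with pytest.raises(InsufficientDataError):
            auc_last(short)


class TestLambdaZ:
    def test_exact_monoexponential(self, monoexp_profile):
        fit = fit_lambda_z(monoexp_profile)
        assert fit.lambda_z == pytest.approx(0.1, rel=1e-10)
        assert fit.t_half == pytest.approx(6.931, abs=5e-4)
        assert fit.adj_r_squared == pytest.approx(1.0, abs=1e-12)
        # perfect fit: ties resolve to the longest window
        assert fit.n_points == 6
        assert (fit.window_start, fit.window_end) == (4.0, 24.0)

    def test_half_life_slope_identity(self, monoexp_profile):
        fit = fit_lambda_z(monoexp_profile)
        assert fit.t_half * fit.lambda_z == pytest.approx(LN2, rel=1e-12)

    def test_printed_iv_half_life_consistent_with_lambda(self):
        # lambda_z of 0.19975/h corresponds to the reported 3.47 h
        assert LN2 / 0.19975 == pytest.approx(3.47, abs=5e-3)

    def test_extravascular_window_excludes_tmax(self):
        t = np.array([0, 0.5, 1, 2, 4, 6, 8])
        c = np.array([0, 2, 5, 4, 2.5, 1.5, 0.9])
        fit = fit_lambda_z(profile_from_arrays("IM", t, c))
        assert fit.window_start > 1.0  # Tmax at 1 h is not eligible

    def test_rising_profile_has_no_terminal_phase(self):
        with pytest.raises((NoTerminalPhaseError, InsufficientDataError)):
            fit_lambda_z(profile_from_arrays("IV", [1, 2, 4, 8], [1, 2, 3, 4]))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_lambda_z(profile_from_arrays("IM", [0, 1, 2, 3], [0, 5, 4, 2]))

    def test_manual_window(self, monoexp_profile):
        fit = fit_lambda_z(monoexp_profile, strategy="manual_window", window=(8, 24))
        assert fit.n_points == 4
        assert fit.lambda_z == pytest.approx(0.1, rel=1e-9)

    def test_matches_brute_force_on_noisy_profile(self):
        """Window selection equals an exhaustive search over all terminal
        suffixes of >= 3 points (independent statsmodels-based oracle)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        t = np.array([1, 2, 4, 6, 8, 10, 12, 24], dtype=float)
        c = 12.0 * np.exp(-0.15 * t) * np.exp(rng.normal(0, 0.1, t.size))
        fit = fit_lambda_z(profile_from_arrays("IV", t, c))

        best = None  # (adj_r2, n, lambda)
        i_max = int(np.argmax(c))  # IV windows start no earlier than Tmax
        for first in range(i_max, len(t) - 2):
            tw, cw = t[first:], c[first:]
            res = sm.OLS(np.log(cw), sm.add_constant(tw)).fit()
            if res.params[1] >= 0:
                continue
            key = (round(res.rsquared_adj, 10), len(tw))
            if best is None or key > best[0]:
                best = (key, -res.params[1], (tw[0], tw[-1]))
        assert fit.lambda_z == pytest.approx(best[1], rel=1e-9)
        assert (fit.window_start, fit.window_end) == best[2]


class TestExtrapolation:
    @pytest.mark.parametrize(
        "auc_l, tail, expected_pct",
        [(70.18, 0.47, 0.67), (60.07, 0.60, 0.99)],  # IV and IM columns
    )
    def test_extrapolated_fraction_matches_printed(self, auc_l, tail, expected_pct):
        lz = 0.2
        fit = LambdaZFit(lz, LN2 / lz, 0.0, 10, 24, 3, 1.0)
        c_last = tail * lz
        auc_inf, _, pct = extrapolate(auc_l, 100.0, c_last, 24.0, fit)
        assert auc_inf == pytest.approx(auc_l + tail)
        assert round(pct, 2) == expected_pct

    def test_vanishing_tail_limit(self):
        fit = LambdaZFit(0.2, LN2 / 0.2, 0.0, 10, 24, 3, 1.0)
        auc_inf, aumc_inf, pct = extrapolate(50.0, 100.0, 1e-12, 24.0, fit)
        assert auc_inf == pytest.approx(50.0)
        assert pct == pytest.approx(0.0, abs=1e-10)

    def test_aumc_tail_closed_form(self):
        lz, c_last, t_last = 0.25, 2.0, 12.0
        fit = LambdaZFit(lz, LN2 / lz, 0.0, 4, 12, 4, 1.0)
        _, aumc_inf, _ = extrapolate(0.0, 0.0, c_last, t_last, fit)
        assert aumc_inf == pytest.approx(c_last * t_last / lz + c_last / lz**2)


class TestDerivedParams:
    def test_iv_triple_rounds_to_printed_values(self):
        cl_t, v_dss = derive_iv_params(2.0, 70.65, 3.11)
        assert round(cl_t, 2) == 0.03
        assert round(v_dss, 2) == 0.09
        assert v_dss == pytest.approx(cl_t * 3.11, rel=1e-15)

    def test_mrt_is_moment_ratio(self):
        assert mrt(70.65, 219.72) == pytest.approx(3.11, abs=5e-3)
        assert mrt(10.0, 0.0) == 0.0

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            derive_iv_params(2.0, 0.0, 3.0)
        with pytest.raises(ValidationError):
            mrt(0.0, 1.0)


class TestLandmarks:
    def test_cmax_tmax_read_off_curve(self):
        profile = profile_from_arrays("IM", [0, 0.25, 1, 2], [0, 2.88, 8.82, 5.0])
        c_max, t_max, c_025 = observed_landmarks(profile)
        assert (c_max, t_max) == (8.82, 1.0)
        assert c_025 == pytest.approx(2.88)

    def test_monotone_decline_tmax_first_sample(self):
        profile = profile_from_arrays("IV", [0.25, 0.5, 1], [38.3, 30.0, 20.0])
        _, t_max, _ = observed_landmarks(profile)
        assert t_max == 0.25

    def test_tie_takes_earliest(self):
        profile = profile_from_arrays("IM", [0.5, 1, 2, 4], [1.0, 7.0, 7.0, 2.0])
        _, t_max, c_025 = observed_landmarks(profile)
        assert t_max == 1.0
        assert c_025 is None


class TestIvC0:
    def test_back_extrapolation_recovers_bolus_c0(self):
        t = np.array([0.25, 0.5, 1, 2, 4])
        profile = profile_from_arrays("IV", t, 22.22 * np.exp(-0.3 * t))
        assert back_extrapolate_c0(profile) == pytest.approx(22.22, rel=1e-9)

    def test_iv_nca_includes_initial_segment(self):
        k, c0 = 0.3, 22.22
        t = np.array([0, 0.25, 0.5, 1, 2, 4, 6, 8, 10, 12, 24])
        conc = c0 * np.exp(-k * t)
        conc[0] = 0.0  # pre-dose control sample
        res = NCA(dose=2.0).fit(profile_from_arrays("IV", t, conc)).result_
        # monoexponential: exact interpolation makes AUCinf = C0/k
        assert res.auc_inf == pytest.approx(c0 / k, rel=1e-6)
        assert res.mrt_inf == pytest.approx(1 / k, rel=1e-6)
        assert res.v_dss == pytest.approx(res.cl_t * res.mrt_inf, rel=1e-12)
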