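"""Non-compartmental analysis (NCA) on a naive-pooled concentration profile.

Estimates the standard single-dose parameter set without assuming a
compartmental model: terminal elimination rate constant (lambda_z) and
half-life by log-linear regression, AUC/AUMC by trapezoidal integration in
two dialects, extrapolation to infinity, mean residence time, and -- for IV
dosing -- total body clearance ClT = Dose/AUCinf and steady-state volume of
distribution Vdss = ClT * MRT.

Trapezoidal dialects
--------------------
``linear_log``
    linear rule for segments at or before Tmax, log rule for declining
    segments after Tmax (the classic "linear/log trapezoidal" used for IV
    profiles, where the decline starts immediately).
``linear_up_log_down``
    linear rule whenever the concentration rises or is flat, log rule
    whenever it falls (the standard choice for extravascular profiles).

For both dialects, the moment curve t*C(t) is integrated with the matching
rule: linear trapezoid on t*C, or the exact log-interpolation moment formula
    AUMC_seg = dt*(t1*C1 - t2*C2)/ln(C1/C2) + dt^2*(C1 - C2)/ln(C1/C2)^2.

Degenerate log segments (a zero or equal endpoint) fall back to the linear
rule; every fallback is logged.

The lambda_z window is chosen, by default, as the suffix of the post-Tmax
quantifiable points (>= ``min_points``, ending at t_last) that maximizes the
adjusted R^2 of the log-linear fit, ties broken toward more points -- the
de-facto standard of commercial NCA software.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator

from ._exceptions import InsufficientDataError, NoTerminalPhaseError, ValidationError
from .io import PooledProfile

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

AucMethod = Literal["linear_log", "linear_up_log_down"]

#: Default trapezoidal dialect per administration route.
DEFAULT_METHOD: dict[str, str] = {
    "IV": "linear_log",
    "IM": "linear_up_log_down",
    "ORAL": "linear_up_log_down",
}


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float  # 1/h
    t_half: float  # h, ln2/lambda_z
    intercept: float  # ln(ug/mL) at t = 0
    window_start: float  # h
    window_end: float  # h
    n_points: int
    adj_r_squared: float


@dataclass(frozen=True)
class NCAResult:
    """Per-route NCA parameter set."""

    route: str
    t_half: float  # h
    auc_last: float  # h*ug/mL
    auc_inf: float  # h*ug/mL
    auc_extrap_pct: float  # %
    aumc_inf: float  # h^2*ug/mL
    mrt_inf: float  # h
    cl_t: float | None  # L/h/kg, IV only
    v_dss: float | None  # L/kg, IV only
    c_max: float  # ug/mL
    t_max: float  # h
    c_025: float | None  # ug/mL at 0.25 h, None if not sampled
    lambda_fit: LambdaZFit


# ---------------------------------------------------------------------------
# segment-level integration


def _loglinear(t1, c1, t2, c2):
    """(AUC, AUMC) of the exact exponential interpolant through two points."""
    dt = t2 - t1
    lncr = math.log(c1 / c2)
    auc = dt * (c1 - c2) / lncr
    aumc = dt * (t1 * c1 - t2 * c2) / lncr + dt * dt * (c1 - c2) / (lncr * lncr)
    return auc, aumc


def _linear(t1, c1, t2, c2):
    dt = t2 - t1
    return dt * (c1 + c2) / 2.0, dt * (t1 * c1 + t2 * c2) / 2.0


def auc_segment(
    t1: float, c1: float, t2: float, c2: float, rule: Literal["linear", "log"] = "linear"
) -> float:
    """Area of one trapezoidal segment.

    ``linear`` -> dt*(C1+C2)/2; ``log`` -> dt*(C1-C2)/ln(C1/C2).  A log
    request with a zero or equal endpoint falls back to the linear rule and
    logs the fallback.
    """
    if t2 <= t1:
        raise ValidationError(f"segment times must increase (t1={t1}, t2={t2})")
    if c1 < 0 or c2 < 0:
        raise ValidationError("segment concentrations must be >= 0")
    if rule == "log":
        if c1 <= 0 or c2 <= 0 or c1 == c2:
            logger.info(
                "log trapezoid degenerate on [%g, %g] (C1=%g, C2=%g); falling back to linear",
                t1, t2, c1, c2,
            )
            return _linear(t1, c1, t2, c2)[0]
        return _loglinear(t1, c1, t2, c2)[0]
    if rule != "linear":
        raise ValidationError(f"unknown trapezoid rule {rule!r}")
    return _linear(t1, c1, t2, c2)[0]


def _segment(t1, c1, t2, c2, want_log: bool) -> tuple[float, float, bool]:
    """(AUC, AUMC, fell_back) for one segment under the requested rule."""
    if want_log:
        if c1 <= 0 or c2 <= 0 or c1 == c2:
            logger.info(
                "log trapezoid degenerate on [%g, %g] (C1=%g, C2=%g); falling back to linear",
                t1, t2, c1, c2,
            )
            auc, aumc = _linear(t1, c1, t2, c2)
            return auc, aumc, True
        auc, aumc = _loglinear(t1, c1, t2, c2)
        return auc, aumc, False
    auc, aumc = _linear(t1, c1, t2, c2)
    return auc, aumc, False


def auc_last(
    profile: PooledProfile, method: AucMethod = "linear_up_log_down"
) -> tuple[float, float]:
    """(AUC0-last, AUMC0-last) of a pooled profile by the chosen dialect."""
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.mean_conc, dtype=float)
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 points for trapezoidal integration")
    if method not in ("linear_log", "linear_up_log_down"):
        raise ValidationError(f"unknown AUC method {method!r}")
    t_max = t[int(np.argmax(c))]
    auc = aumc = 0.0
    for i in range(len(t) - 1):
        t1, c1, t2, c2 = t[i], c[i], t[i + 1], c[i + 1]
        if method == "linear_up_log_down":
            want_log = c2 < c1
        else:  # linear_log
            want_log = t1 >= t_max and c2 < c1
        a, m, _ = _segment(t1, c1, t2, c2, want_log)
        auc += a
        aumc += m
    return auc, aumc


# ---------------------------------------------------------------------------
# terminal slope


def _ols_loglinear(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and adjusted R^2 of log-conc vs time."""
    n = len(t)
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - np.mean(logc)) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), float(adj)


class LambdaZRegressor(BaseEstimator):
    """Terminal-slope estimator: log-linear regression with window selection.

    Parameters
    ----------
    min_points : int
        Minimum points in the regression window (>= 3).
    strategy : {"best_adj_r2", "manual_window"}
        ``best_adj_r2`` searches all suffixes of the post-Tmax quantifiable
        points ending at t_last and keeps the window with the highest
        adjusted R^2 (ties -> more points).  ``manual_window`` uses
        ``window`` as given.
    window : tuple of (start, end) hours, inclusive
        Required for ``manual_window``.
    exclude_tmax : bool
        Drop the Tmax point itself from the candidate set (standard for
        extravascular profiles, where Tmax still carries absorption).

    Attributes
    ----------
    lambda_z_ : float
        Terminal elimination rate constant (1/h).
    t_half_ : float
        ln 2 / lambda_z_ (h).
    fit_ : LambdaZFit
        Full regression record.
    """

    def __init__(
        self,
        min_points: int = 3,
        strategy: str = "best_adj_r2",
        window: tuple[float, float] | None = None,
        exclude_tmax: bool = True,
    ):
        self.min_points = min_points
        self.strategy = strategy
        self.window = window
        self.exclude_tmax = exclude_tmax

    def fit(self, t, c, y=None):
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
        if self.min_points < 3:
            raise ValidationError("min_points must be >= 3")
        quant = c > 0
        t, c = t[quant], c[quant]
        if len(t) < 2:
            raise InsufficientDataError("fewer than 2 quantifiable points")
        i_max = int(np.argmax(c))
        start = i_max + 1 if self.exclude_tmax else i_max
        tc, cc = t[start:], c[start:]

        if self.strategy == "manual_window":
            if self.window is None:
                raise ValidationError("manual_window strategy requires window=(start, end)")
            lo, hi = self.window
            mask = (tc >= lo) & (tc <= hi)
            tw, cw = tc[mask], cc[mask]
            if len(tw) < self.min_points:
                raise InsufficientDataError(
                    f"window [{lo}, {hi}] contains {len(tw)} points (< {self.min_points})"
                )
            slope, intercept, adj = _ols_loglinear(tw, np.log(cw))
            if slope >= 0:
                raise NoTerminalPhaseError("non-negative terminal slope in manual window")
            self.fit_ = LambdaZFit(
                lambda_z=-slope,
                t_half=LN2 / -slope,
                intercept=intercept,
                window_start=float(tw[0]),
                window_end=float(tw[-1]),
                n_points=len(tw),
                adj_r_squared=adj,
            )
        elif self.strategy == "best_adj_r2":
            if len(tc) < self.min_points:
                raise InsufficientDataError(
                    f"{len(tc)} post-Tmax quantifiable points (< {self.min_points})"
                )
            best: LambdaZFit | None = None
            # candidate windows are suffixes ending at t_last; adjusted R^2
            # ties (within 1e-10) go to the longer window
            for first in range(len(tc) - self.min_points + 1):
                tw, cw = tc[first:], cc[first:]
                slope, intercept, adj = _ols_loglinear(tw, np.log(cw))
                if slope >= 0:
                    continue
                is_better = best is None or adj > best.adj_r_squared + 1e-10
                is_tie_longer = (
                    best is not None
                    and abs(adj - best.adj_r_squared) <= 1e-10
                    and len(tw) > best.n_points
                )
                if is_better or is_tie_longer:
                    best = LambdaZFit(
                        lambda_z=-slope,
                        t_half=LN2 / -slope,
                        intercept=intercept,
                        window_start=float(tw[0]),
                        window_end=float(tw[-1]),
                        n_points=len(tw),
                        adj_r_squared=adj,
                    )
            if best is None:
                raise NoTerminalPhaseError("no declining terminal window found")
            self.fit_ = best
        else:
            raise ValidationError(f"unknown strategy {self.strategy!r}")

        self.lambda_z_ = self.fit_.lambda_z
        self.t_half_ = self.fit_.t_half
        return self

    def predict(self, t):
        """Predicted concentration at times ``t`` from the terminal fit."""
        t = np.asarray(t, dtype=float)
        return np.exp(self.fit_.intercept - self.fit_.lambda_z * t)


def fit_lambda_z(
    profile: PooledProfile,
    min_points: int = 3,
    strategy: str = "best_adj_r2",
    window: tuple[float, float] | None = None,
) -> LambdaZFit:
    """Fit the terminal slope of a pooled profile (see :class:`LambdaZRegressor`)."""
    reg = LambdaZRegressor(
        min_points=min_points,
        strategy=strategy,
        window=window,
        exclude_tmax=profile.route != "IV",
    )
    reg.fit(profile.times, profile.mean_conc)
    return reg.fit_


# ---------------------------------------------------------------------------
# derived parameters


def extrapolate(
    auc_last_: float, aumc_last_: float, c_last: float, t_last: float, fit: LambdaZFit
) -> tuple[float, float, float]:
    """Extend AUC/AUMC from t_last to infinity using the terminal slope.

    Returns (AUC0-inf, AUMC0-inf, AUCextrap%).
    """
    if c_last <= 0:
        raise ValidationError("c_last must be > 0 for extrapolation")
    lz = fit.lambda_z
    auc_inf = auc_last_ + c_last / lz
    aumc_inf = aumc_last_ + c_last * t_last / lz + c_last / lz**2
    extrap_pct = 100.0 * (auc_inf - auc_last_) / auc_inf
    return auc_inf, aumc_inf, extrap_pct


def mrt(auc_inf: float, aumc_inf: float) -> float:
    """Mean residence time AUMCinf/AUCinf (h)."""
    if auc_inf <= 0:
        raise ValidationError("auc_inf must be > 0")
    return aumc_inf / auc_inf


def derive_iv_params(dose: float, auc_inf: float, mrt_inf: float) -> tuple[float, float]:
    """IV-only parameters: ClT = Dose/AUCinf, Vdss = ClT * MRT.

    With dose in mg/kg and AUC in h*ug/mL the units come out as L/h/kg and
    L/kg with no conversion factor (1 mg/kg per h*ug/mL = 1 L/h/kg).
    """
    if auc_inf <= 0 or mrt_inf <= 0:
        raise ValidationError("auc_inf and mrt_inf must be > 0")
    cl_t = dose / auc_inf
    return cl_t, cl_t * mrt_inf


def observed_landmarks(profile: PooledProfile) -> tuple[float, float, float | None]:
    """(Cmax, Tmax, C0.25h) read directly off the mean curve.

    Tmax takes the earliest time on ties; C0.25h is None when 0.25 h was not
    sampled.
    """
    if len(profile) == 0:
        raise InsufficientDataError("empty profile")
    c = profile.mean_conc
    i = int(np.argmax(c))  # argmax returns the first maximum -> earliest time
    c_025 = None
    at = np.where(np.isclose(profile.times, 0.25))[0]
    if at.size:
        c_025 = float(profile.mean_conc[at[0]])
    return float(c[i]), float(profile.times[i]), c_025


def back_extrapolate_c0(profile: PooledProfile) -> float:
    """IV bolus C0 from a log-linear line through the first two quantifiable points."""
    mask = profile.mean_conc > 0
    t, c = profile.times[mask], profile.mean_conc[mask]
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 quantifiable points to back-extrapolate C0")
    t1, t2 = t[0], t[1]
    c1, c2 = c[0], c[1]
    if c2 >= c1:  # no initial decline; fall back to the first observation
        logger.info("IV profile not declining over first two points; C0 set to C(t1)")
        return float(c1)
    slope = (math.log(c2) - math.log(c1)) / (t2 - t1)
    return float(math.exp(math.log(c1) - slope * t1))


class NCA(BaseEstimator):
    """Full non-compartmental analysis of one pooled profile.

    Parameters
    ----------
    dose : float
        Administered dose (mg/kg).
    method : {"auto", "linear_log", "linear_up_log_down"}
        Trapezoidal dialect; ``auto`` selects linear/log for IV and
        linear-up/log-down for extravascular routes.
    lambda_z_strategy : {"best_adj_r2", "manual_window"}
    min_points : int
        Minimum lambda_z regression points.
    lambda_z_window : (start, end) hours or None
        Manual window, used with ``manual_window``.
    iv_back_extrapolate : bool
        For IV profiles, replace the t=0 pre-dose zero with a back-
        extrapolated C0 so the 0 -> first-sample segment enters the AUC.

    Attributes (after fit)
    ----------------------
    lambda_z_, t_half_, auc_last_, aumc_last_, auc_inf_, aumc_inf_,
    auc_extrap_pct_, mrt_inf_, c_max_, t_max_, c_025_, cl_t_, v_dss_,
    c0_ (IV), lambda_fit_, result_
    """

    def __init__(
        self,
        dose: float = 2.0,
        method: str = "auto",
        lambda_z_strategy: str = "best_adj_r2",
        min_points: int = 3,
        lambda_z_window: tuple[float, float] | None = None,
        iv_back_extrapolate: bool = True,
    ):
        self.dose = dose
        self.method = method
        self.lambda_z_strategy = lambda_z_strategy
        self.min_points = min_points
        self.lambda_z_window = lambda_z_window
        self.iv_back_extrapolate = iv_back_extrapolate

    def fit(self, profile: PooledProfile, y=None):
        route = profile.route
        method = DEFAULT_METHOD[route] if self.method == "auto" else self.method
        if method not in ("linear_log", "linear_up_log_down"):
            raise ValidationError(f"unknown AUC method {method!r}")

        self.c_max_, self.t_max_, self.c_025_ = observed_landmarks(profile)

        self.lambda_fit_ = fit_lambda_z(
            profile,
            min_points=self.min_points,
            strategy=self.lambda_z_strategy,
            window=self.lambda_z_window,
        )
        self.lambda_z_ = self.lambda_fit_.lambda_z
        self.t_half_ = self.lambda_fit_.t_half

        working = profile
        self.c0_ = None
        if route == "IV" and self.iv_back_extrapolate:
            self.c0_ = back_extrapolate_c0(profile)
            times = profile.times.copy()
            conc = profile.mean_conc.copy()
            sd = profile.sd_conc.copy()
            n = profile.n.copy()
            if times[0] == 0.0:
                conc = conc.copy()
                conc[0] = self.c0_
            else:
                times = np.insert(times, 0, 0.0)
                conc = np.insert(conc, 0, self.c0_)
                sd = np.insert(sd, 0, 0.0)
                n = np.insert(n, 0, 0)
            working = PooledProfile(route=route, times=times, mean_conc=conc, sd_conc=sd, n=n)
            logger.info("IV C0 back-extrapolated to %.4g ug/mL", self.c0_)

        self.auc_last_, self.aumc_last_ = auc_last(working, method=method)
        quant = working.mean_conc > 0
        c_last = float(working.mean_conc[quant][-1])
        t_last = float(working.times[quant][-1])
        self.auc_inf_, self.aumc_inf_, self.auc_extrap_pct_ = extrapolate(
            self.auc_last_, self.aumc_last_, c_last, t_last, self.lambda_fit_
        )
        self.mrt_inf_ = mrt(self.auc_inf_, self.aumc_inf_)

        self.cl_t_ = self.v_dss_ = None
        if route == "IV":
            self.cl_t_, self.v_dss_ = derive_iv_params(self.dose, self.auc_inf_, self.mrt_inf_)

        self.method_ = method
        self.route_ = route
        self.result_ = NCAResult(
            route=route,
            t_half=self.t_half_,
            auc_last=self.auc_last_,
            auc_inf=self.auc_inf_,
            auc_extrap_pct=self.auc_extrap_pct_,
            aumc_inf=self.aumc_inf_,
            mrt_inf=self.mrt_inf_,
            cl_t=self.cl_t_,
            v_dss=self.v_dss_,
            c_max=self.c_max_,
            t_max=self.t_max_,
            c_025=self.c_025_,
            lambda_fit=self.lambda_fit_,
        )
        return self


def run_nca(profile: PooledProfile, dose: float, **kwargs) -> NCAResult:
    """One-call NCA: fit an :class:`NCA` estimator and return its result."""
    return NCA(dose=dose, **kwargs).fit(profile).result_
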