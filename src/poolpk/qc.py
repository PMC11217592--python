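"""Bioanalytical method-validation statistics.

Calibration linearity, extraction recovery, precision (coefficient of
variation), accuracy (bias) and LLOQ acceptance, in the style of EMA
bioanalytical guidance: an assay passes at the LLOQ when replicate CV < 20%
and bias lies within +/-15%; other QC levels use CV <= 15% and bias within
+/-15% unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import InsufficientDataError, ValidationError


class CalibrationCurve(BaseEstimator, RegressorMixin):
    """Ordinary (optionally weighted) least-squares calibration line.

    Parameters
    ----------
    weighting : {None, "1/x", "1/x2"}
        Residual weighting by inverse nominal concentration; None fits
        unweighted.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted response = slope * nominal + intercept.
    r_squared_ : float
        Coefficient of determination (weighted when weighting is used).
    """

    def __init__(self, weighting: str | None = None):
        self.weighting = weighting

    def _weights(self, x: np.ndarray) -> np.ndarray:
        if self.weighting is None:
            return np.ones_like(x)
        if self.weighting == "1/x":
            return 1.0 / x
        if self.weighting == "1/x2":
            return 1.0 / x**2
        raise ValidationError(f"unknown weighting {self.weighting!r}")

    def fit(self, nominal, response, y=None):
        x = np.asarray(nominal, dtype=float)
        r = np.asarray(response, dtype=float)
        if len(x) < 3:
            raise InsufficientDataError("calibration needs >= 3 standards")
        if len(np.unique(x)) < 3:
            raise InsufficientDataError("calibration needs >= 3 distinct nominal values")
        if np.ptp(r) == 0:
            raise ValidationError("constant responses: degenerate calibration fit")
        w = self._weights(x)
        # polyfit weights multiply residuals, i.e. w_i ~ 1/sigma_i
        slope, intercept = np.polyfit(x, r, 1, w=np.sqrt(w))
        fitted = slope * x + intercept
        ss_res = float(np.sum(w * (r - fitted) ** 2))
        ss_tot = float(np.sum(w * (r - np.average(r, weights=w)) ** 2))
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r_squared_ = 1.0 - ss_res / ss_tot
        return self

    def predict(self, nominal):
        x = np.asarray(nominal, dtype=float)
        return self.slope_ * x + self.intercept_

    def invert(self, response):
        """Back-calculate concentration from an instrument response."""
        r = np.asarray(response, dtype=float)
        return (r - self.intercept_) / self.slope_


def calibration_linearity(
    nominal: Sequence[float], response: Sequence[float], weighting: str | None = None
) -> tuple[float, tuple[float, float]]:
    """R^2 and (slope, intercept) of the calibration line."""
    curve = CalibrationCurve(weighting=weighting).fit(nominal, response)
    return curve.r_squared_, (curve.slope_, curve.intercept_)


def bias_pct(calculated: float, theoretical: float) -> float:
    """Accuracy: 100 * (calculated - theoretical) / theoretical, signed."""
    if theoretical <= 0:
        raise ValidationError("theoretical concentration must be > 0")
    return 100.0 * (calculated - theoretical) / theoretical


def cv_pct(values: Sequence[float]) -> float:
    """Precision: 100 * sample SD / mean."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise InsufficientDataError("CV needs >= 2 values")
    m = float(np.mean(vals))
    if m <= 0:
        raise ValidationError("CV undefined for non-positive mean")
    return 100.0 * float(np.std(vals, ddof=1)) / m


def recovery_pct(observed: float, spiked: float) -> float:
    """Extraction recovery: 100 * observed / spiked."""
    if spiked <= 0:
        raise ValidationError("spiked concentration must be > 0")
    return 100.0 * observed / spiked


@dataclass(frozen=True)
class ValidationReport:
    """Per-level precision/accuracy summary with LLOQ pass/fail."""

    recovery_pct: Mapping[float, float]  # level -> mean recovery %
    intra_cv_pct: Mapping[float, float]  # level -> worst within-day CV
    inter_cv_pct: Mapping[float, float]  # level -> across-day CV
    intra_bias_pct: Mapping[float, float]  # level -> worst-|.| within-day bias (signed)
    inter_bias_pct: Mapping[float, float]  # level -> overall bias
    lloq_pass: bool | None  # None when the LLOQ level was not run
    r_squared: float | None = None
    lloq_level: float | None = None
    cv_limit_pct: float = 15.0
    lloq_cv_limit_pct: float = 20.0
    bias_limit_pct: float = 15.0

    def passes(self, level: float) -> bool:
        cv_lim = self.lloq_cv_limit_pct if level == self.lloq_level else self.cv_limit_pct
        return (
            self.inter_cv_pct[level] < cv_lim
            and self.intra_cv_pct[level] < cv_lim
            and abs(self.inter_bias_pct[level]) <= self.bias_limit_pct
            and abs(self.intra_bias_pct[level]) <= self.bias_limit_pct
        )

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "lloq_level": self.lloq_level,
            "lloq_pass": self.lloq_pass,
            "levels": {
                str(lvl): {
                    "recovery_pct": self.recovery_pct.get(lvl),
                    "intra_cv_pct": self.intra_cv_pct[lvl],
                    "inter_cv_pct": self.inter_cv_pct[lvl],
                    "intra_bias_pct": self.intra_bias_pct[lvl],
                    "inter_bias_pct": self.inter_bias_pct[lvl],
                    "pass": self.passes(lvl),
                }
                for lvl in self.inter_cv_pct
            },
        }


def validate_qc_runs(
    runs: pd.DataFrame,
    lloq_level: float | None = None,
    r_squared: float | None = None,
) -> ValidationReport:
    """Summarize QC runs into a validation report.

    ``runs`` needs columns ``day, level, nominal, measured``.  Intra-day CV
    and bias are the worst (largest-magnitude) within-day replicate
    statistics per level; inter-day statistics pool every day's replicates.
    Recovery per level is the mean measured/nominal ratio.
    """
    required = {"day", "level", "nominal", "measured"}
    missing = required - set(runs.columns)
    if missing:
        raise ValidationError(f"QC table missing column(s) {sorted(missing)}")

    recovery: dict[float, float] = {}
    intra_cv: dict[float, float] = {}
    inter_cv: dict[float, float] = {}
    intra_bias: dict[float, float] = {}
    inter_bias: dict[float, float] = {}
    for level, grp in runs.groupby("level"):
        nominal = float(grp["nominal"].iloc[0])
        vals = grp["measured"].to_numpy(dtype=float)
        recovery[level] = float(np.mean([recovery_pct(v, nominal) for v in vals]))
        inter_cv[level] = cv_pct(vals)
        inter_bias[level] = bias_pct(float(np.mean(vals)), nominal)
        day_cvs, day_biases = [], []
        for _, day_grp in grp.groupby("day"):
            dvals = day_grp["measured"].to_numpy(dtype=float)
            if len(dvals) >= 2:
                day_cvs.append(cv_pct(dvals))
            day_biases.append(bias_pct(float(np.mean(dvals)), nominal))
        intra_cv[level] = max(day_cvs) if day_cvs else 0.0
        intra_bias[level] = max(day_biases, key=abs)

    report = ValidationReport(
        recovery_pct=recovery,
        intra_cv_pct=intra_cv,
        inter_cv_pct=inter_cv,
        intra_bias_pct=intra_bias,
        inter_bias_pct=inter_bias,
        lloq_pass=None,
        r_squared=r_squared,
        lloq_level=lloq_level,
    )
    if lloq_level is not None and lloq_level in inter_cv:
        object.__setattr__(report, "lloq_pass", report.passes(lloq_level))
    return report
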