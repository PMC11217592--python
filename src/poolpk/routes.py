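"""Cross-route derived parameters.

Absolute bioavailability F = 100 * AUCinf(extravascular) / AUCinf(IV),
mean absorption time MAT = MRTinf(extravascular) - MRTinf(IV), and the
flip-flop diagnosis: when absorption is slower than elimination the terminal
phase reflects absorption, which manifests as MAT exceeding the IV MRT.

F and MAT are computed from the 0-to-infinity quantities, not 0-to-last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from ._exceptions import ValidationError
from .nca import NCAResult


@dataclass(frozen=True)
class RouteComparison:
    route: str  # IM or ORAL
    f_pct: float  # absolute bioavailability, %
    mat: float  # mean absorption time, h
    flip_flop: bool


def bioavailability(auc_ext: float, auc_iv: float) -> float:
    """Absolute bioavailability in percent; may exceed 100."""
    if auc_iv <= 0:
        raise ValidationError("IV AUC must be > 0")
    return 100.0 * auc_ext / auc_iv


def mean_absorption_time(mrt_ext: float, mrt_iv: float) -> float:
    """MAT = MRT(extravascular) - MRT(IV), hours.

    A negative MAT (possible with noisy pooled data) is reported as-is with
    a warning.
    """
    if mrt_ext <= 0 or mrt_iv <= 0:
        raise ValidationError("MRT values must be > 0")
    mat = mrt_ext - mrt_iv
    if mat < 0:
        warnings.warn(
            f"negative MAT ({mat:.3g} h): extravascular MRT below IV MRT; "
            "likely noise in the pooled profiles",
            stacklevel=2,
        )
    return mat


def diagnose_flip_flop(mat: float, mrt_iv: float) -> bool:
    """True iff absorption is rate-limiting (MAT > MRT after IV dosing)."""
    return bool(mat > mrt_iv)


def compare_routes(ext: NCAResult, iv: NCAResult) -> RouteComparison:
    """Bioavailability, MAT and flip-flop flag of one extravascular route vs IV."""
    if iv.route != "IV":
        raise ValidationError(f"reference result must be IV, got {iv.route}")
    if ext.route == "IV":
        raise ValidationError("extravascular result must be IM or ORAL")
    f = bioavailability(ext.auc_inf, iv.auc_inf)
    mat = mean_absorption_time(ext.mrt_inf, iv.mrt_inf)
    return RouteComparison(
        route=ext.route,
        f_pct=f,
        mat=mat,
        flip_flop=diagnose_flip_flop(mat, iv.mrt_inf),
    )
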