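"""Plasma protein binding by ultrafiltration.

Free (unbound) drug passes a molecular-weight-cutoff filter; the bound
fraction is inferred from total (spiked plasma) and free (ultrafiltrate)
concentrations:

    binding % = 100 * (total - free) / total

A study measures several spiking levels in replicate.  The summary reports a
per-level mean +/- SD and an overall mean +/- SD taken across the level
means (each level weighted equally), and classifies the binding as
concentration dependent when the range of the level means exceeds a
threshold (default 5 percentage points).  No formal ANOVA is attempted: with
three replicates per level a range criterion is the transparent choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._exceptions import InsufficientDataError, ValidationError


@dataclass(frozen=True)
class BindingMeasurement:
    """One ultrafiltration replicate at one spiking level."""

    total_conc: float  # ug/mL, nominal spiked plasma concentration
    free_conc: float  # ug/mL, ultrafiltrate
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.total_conc <= 0:
            raise ValidationError("total_conc must be > 0")
        if not 0 <= self.free_conc <= self.total_conc:
            raise ValidationError(
                f"free_conc {self.free_conc} outside [0, total={self.total_conc}]: "
                "ultrafiltrate exceeding plasma signals assay failure"
            )


@dataclass(frozen=True)
class BindingResult:
    per_level: Mapping[float, tuple[float, float]]  # level -> (mean %, SD %)
    overall_mean_pct: float
    overall_sd_pct: float
    concentration_dependent: bool | None  # None when a single level was run

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level_ug_ml": lvl, "mean_binding_pct": m, "sd_binding_pct": s}
            for lvl, (m, s) in self.per_level.items()
        ]
        rows.append(
            {
                "level_ug_ml": "overall",
                "mean_binding_pct": self.overall_mean_pct,
                "sd_binding_pct": self.overall_sd_pct,
            }
        )
        return pd.DataFrame(rows)


def binding_percent(total: float, free: float) -> float:
    """Percent of drug bound to plasma protein, 100*(total - free)/total."""
    if total <= 0:
        raise ValidationError("total concentration must be > 0")
    if free < 0 or free > total:
        raise ValidationError(
            "free concentration outside [0, total]: ultrafiltrate exceeding "
            "plasma signals assay failure"
        )
    return 100.0 * (total - free) / total


def summarize_binding(
    measurements: Iterable[BindingMeasurement],
    dependence_threshold_pct: float = 5.0,
    overall_over: str = "level_means",
) -> BindingResult:
    """Per-level and overall binding summary.

    ``overall_over="level_means"`` (default) averages the per-level means,
    weighting each spiking level equally; ``"replicates"`` averages every
    individual replicate instead.  SDs are sample SDs (n-1 denominator).
    """
    by_level: dict[float, list[float]] = {}
    for m in measurements:
        by_level.setdefault(m.total_conc, []).append(binding_percent(m.total_conc, m.free_conc))
    if not by_level:
        raise InsufficientDataError("no binding measurements")
    if overall_over not in ("level_means", "replicates"):
        raise ValidationError(f"unknown overall_over {overall_over!r}")

    per_level: dict[float, tuple[float, float]] = {}
    for lvl in sorted(by_level):
        vals = np.asarray(by_level[lvl], dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        per_level[lvl] = (float(np.mean(vals)), sd)

    level_means = np.array([m for m, _ in per_level.values()])
    if overall_over == "level_means":
        pool = level_means
    else:
        pool = np.concatenate([np.asarray(v, dtype=float) for v in by_level.values()])
    overall_mean = float(np.mean(pool))
    overall_sd = float(np.std(pool, ddof=1)) if len(pool) > 1 else 0.0

    if len(per_level) < 2:
        dependent: bool | None = None
    else:
        dependent = bool(np.ptp(level_means) > dependence_threshold_pct)

    return BindingResult(
        per_level=per_level,
        overall_mean_pct=overall_mean,
        overall_sd_pct=overall_sd,
        concentration_dependent=dependent,
    )


def read_binding_csv(path) -> list[BindingMeasurement]:
    """Read measurements from a CSV with columns level_ug_ml, replicate, total_conc, free_conc."""
    df = pd.read_csv(path)
    required = {"total_conc", "free_conc"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    reps = df["replicate"] if "replicate" in df.columns else range(len(df))
    return [
        BindingMeasurement(total_conc=t, free_conc=f, replicate=int(r))
        for t, f, r in zip(df["total_conc"], df["free_conc"], reps)
    ]
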