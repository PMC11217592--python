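"""Study data model and I/O for destructive-sampling concentration-time studies.

A destructive design samples each animal once: six fish per timepoint, one
plasma concentration each.  The naive-pooled approach averages the per-timepoint
concentrations into a single mean profile per route, which then feeds
non-compartmental analysis (:mod:`poolpk.nca`).

Below-LLOQ (lower limit of quantification) handling follows standard NCA
practice for pooled profiles:

* before the first quantifiable timepoint, censored values count as 0 in the
  mean (pre-absorption samples are true zeros to within assay sensitivity);
* at or after the first quantifiable timepoint, censored values are excluded
  from the mean;
* a timepoint where every fish is censored after Tmax terminates the profile
  (trailing all-BLQ points are dropped, not zeroed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import FormatError, InsufficientDataError, ValidationError

ROUTES = ("IV", "IM", "ORAL")

_REQUIRED_COLUMNS = ("subject_id", "route", "dose", "time", "concentration")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One fish x one timepoint plasma measurement.

    Parameters
    ----------
    subject_id : str
        Unique animal identifier.
    route : str
        Administration route, one of ``IV``, ``IM``, ``ORAL``.
    dose : float
        Administered dose in mg/kg body weight.
    time : float
        Sampling time in hours post dose (>= 0).
    concentration : float
        Plasma concentration in ug/mL (>= 0).
    below_lloq : bool
        True iff the measured value is below the study LLOQ (censored).
    """

    subject_id: str
    route: str
    dose: float
    time: float
    concentration: float
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValidationError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        if self.time < 0:
            raise ValidationError(f"negative sampling time {self.time} for {self.subject_id}")
        if self.concentration < 0:
            raise ValidationError(
                f"negative concentration {self.concentration} for {self.subject_id}"
            )
        if self.dose <= 0:
            raise ValidationError(f"non-positive dose {self.dose} for {self.subject_id}")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a single-dose destructive-sampling study."""

    dose: float  # mg/kg
    lloq: float  # ug/mL
    sample_times: tuple[float, ...]  # hours, strictly increasing, first 0
    n_per_timepoint: int
    temperature_c: float | None = None  # metadata only

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sample_times)
        object.__setattr__(self, "sample_times", times)
        if self.dose <= 0:
            raise ValidationError("dose must be > 0")
        if self.lloq <= 0:
            raise ValidationError("lloq must be > 0")
        if len(times) < 2 or times[0] != 0:
            raise ValidationError("sample_times must start at 0 and contain >= 2 points")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("sample_times must be strictly increasing")
        if self.n_per_timepoint < 1:
            raise ValidationError("n_per_timepoint must be >= 1")


#: The study design emulated throughout: 2 mg/kg, 13 sampling times over 72 h,
#: 6 fish per timepoint (destructive), LLOQ 0.04 ug/mL, water at 13 C.
TROUT_DESIGN = StudyDesign(
    dose=2.0,
    lloq=0.04,
    sample_times=(0, 0.25, 0.5, 1, 2, 4, 6, 8, 10, 12, 24, 48, 72),
    n_per_timepoint=6,
    temperature_c=13.0,
)


@dataclass(frozen=True)
class PooledProfile:
    """Per-route mean concentration-time series (the naive-pooled NCA input)."""

    route: str
    times: np.ndarray  # hours, strictly increasing
    mean_conc: np.ndarray  # ug/mL
    sd_conc: np.ndarray  # ug/mL (sample SD; 0 where n < 2)
    n: np.ndarray  # animals contributing to each mean

    def __post_init__(self) -> None:
        for name in ("times", "mean_conc", "sd_conc", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "n", self.n.astype(int))
        if self.route not in ROUTES:
            raise ValidationError(f"unknown route {self.route!r}")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("profile times must be strictly increasing")
        if not (len(self.times) == len(self.mean_conc) == len(self.sd_conc) == len(self.n)):
            raise ValidationError("profile arrays must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "route": self.route,
                "time_h": self.times,
                "mean_conc": self.mean_conc,
                "sd_conc": self.sd_conc,
                "n": self.n,
            }
        )


def read_study(path: str | Path, design: StudyDesign) -> list[ConcentrationRecord]:
    """Read a concentrations CSV and censor values below ``design.lloq``.

    The file must contain columns ``subject_id, route, dose, time,
    concentration`` (comma-separated, header row, UTF-8, decimal point).
    Malformed rows raise :class:`ValidationError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[ConcentrationRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            conc = float(row["concentration"])
            records.append(
                ConcentrationRecord(
                    subject_id=str(row["subject_id"]),
                    route=str(row["route"]).upper(),
                    dose=float(row["dose"]),
                    time=float(row["time"]),
                    concentration=conc,
                    below_lloq=conc < design.lloq,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    return records


def write_study(records: Iterable[ConcentrationRecord], path: str | Path) -> None:
    """Write records as the concentrations CSV consumed by :func:`read_study`."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable[ConcentrationRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def pool_profile(records: Sequence[ConcentrationRecord], route: str) -> PooledProfile:
    """Naive-pool destructive-sampling records into one mean profile per route.

    Censored (below-LLOQ) values are handled per the module rules; see the
    module docstring.  Requires at least one record for ``route`` at >= 3
    distinct times.
    """
    if route not in ROUTES:
        raise ValidationError(f"unknown route {route!r}")
    subset = [r for r in records if r.route == route]
    if not subset:
        raise InsufficientDataError(f"no records for route {route}")
    by_time: dict[float, list[ConcentrationRecord]] = {}
    for rec in subset:
        by_time.setdefault(rec.time, []).append(rec)
    times = sorted(by_time)
    if len(times) < 3:
        raise InsufficientDataError(
            f"route {route}: need >= 3 distinct sampling times, got {len(times)}"
        )

    quant_times = [t for t in times if any(not r.below_lloq for r in by_time[t])]
    first_quant = quant_times[0] if quant_times else None

    out_t: list[float] = []
    out_mean: list[float] = []
    out_sd: list[float] = []
    out_n: list[int] = []
    all_blq_after_first: list[float] = []
    for t in times:
        recs = by_time[t]
        if first_quant is None or t < first_quant:
            vals = [0.0 if r.below_lloq else r.concentration for r in recs]
        else:
            vals = [r.concentration for r in recs if not r.below_lloq]
            if not vals:
                all_blq_after_first.append(t)
                continue
        out_t.append(t)
        out_mean.append(float(np.mean(vals)))
        out_sd.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        out_n.append(len(vals))  # animals contributing to the mean

    # an all-BLQ timepoint after Tmax terminates the profile
    if all_blq_after_first and out_mean:
        t_max = out_t[int(np.argmax(out_mean))]
        cutoffs = [t for t in all_blq_after_first if t > t_max]
        if cutoffs:
            cut = min(cutoffs)
            keep = [i for i, t in enumerate(out_t) if t < cut]
            out_t = [out_t[i] for i in keep]
            out_mean = [out_mean[i] for i in keep]
            out_sd = [out_sd[i] for i in keep]
            out_n = [out_n[i] for i in keep]

    return PooledProfile(
        route=route,
        times=np.array(out_t),
        mean_conc=np.array(out_mean),
        sd_conc=np.array(out_sd),
        n=np.array(out_n),
    )


def write_profile(profile: PooledProfile, path: str | Path) -> None:
    """Write a pooled profile CSV (route, time_h, mean_conc, sd_conc, n)."""
    profile.to_frame().to_csv(path, index=False)
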