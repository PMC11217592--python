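"""Synthetic concentration-time data emulating a destructive-sampling PK study.

The generator draws one- or two-compartment disposition with optional
first-order absorption, then emulates the sampling design: at each design
timepoint an independent cohort of fish is sampled once, each fish's
concentration being the model value times a mean-1 lognormal deviate
(inter-fish plus assay variability combined, since each fish contributes a
single sample).  Values below the assay LLOQ are flagged censored.  The
t = 0 sample is a pre-dose control and is always 0.

Absorption slower than elimination (ka < k) puts the extravascular curves in
the flip-flop regime, where the terminal slope reflects absorption and the
apparent half-life lengthens -- the regime the default scenario emulates.

Closed-form reference values (:func:`closed_form_truth`) provide an analytic
oracle for every downstream estimate: AUCinf = F*Dose/CL, MRT(IV) = 1/k
(one-compartment), MRT(extravascular) = 1/k + 1/ka, MAT = 1/ka,
terminal half-life = ln2/min(k, ka).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from ._exceptions import ValidationError
from .io import ConcentrationRecord, StudyDesign, TROUT_DESIGN

LN2 = math.log(2.0)

EXTRAVASCULAR = ("IM", "ORAL")
ROUTE_ORDER = ("IV", "IM", "ORAL")


@dataclass(frozen=True)
class SimParams:
    """Kinetic and design parameters of one simulated treatment arm.

    Rates are first-order (1/h), volumes apparent (L/kg), clearances L/h/kg.
    ``iiv_cv`` is the fractional coefficient of variation of the mean-1
    lognormal multiplicative noise applied to each fish's concentration.
    """

    cl: float  # total clearance, L/h/kg
    v_central: float  # central volume, L/kg
    n_compartments: int = 1
    cl_distribution: float | None = None  # inter-compartmental clearance Q, L/h/kg
    v_peripheral: float | None = None  # L/kg
    ka: float | None = None  # absorption rate constant, 1/h (extravascular)
    f_abs: float = 1.0  # fraction absorbed, (0, 1]
    dose: float = 2.0  # mg/kg
    iiv_cv: float = 0.15
    seed: int = 0
    design: StudyDesign = TROUT_DESIGN

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v_central <= 0:
            raise ValidationError("cl and v_central must be > 0")
        if not 0 < self.f_abs <= 1:
            raise ValidationError("f_abs must be in (0, 1]")
        if self.dose <= 0:
            raise ValidationError("dose must be > 0")
        if self.iiv_cv < 0:
            raise ValidationError("iiv_cv must be >= 0")
        if self.n_compartments not in (1, 2):
            raise ValidationError("n_compartments must be 1 or 2")
        if self.n_compartments == 2 and (
            self.cl_distribution is None or self.v_peripheral is None
        ):
            raise ValidationError("2-compartment model needs cl_distribution and v_peripheral")
        if self.ka is not None and self.ka <= 0:
            raise ValidationError("ka must be > 0")

    @property
    def k_el(self) -> float:
        """Elimination rate constant from the central compartment, cl/v_central."""
        return self.cl / self.v_central


def _disposition_terms(params: SimParams, route: str) -> list[tuple[float, float]]:
    """C(t) = sum(coef * exp(-rate * t)) representation; requires distinct rates."""
    D, V, f = params.dose, params.v_central, params.f_abs
    if params.n_compartments == 1:
        k = params.k_el
        if route == "IV":
            return [(D / V, k)]
        ka = params.ka
        if ka is None:
            raise ValidationError(f"route {route} requires ka")
        if math.isclose(ka, k):
            raise ValidationError("ka == k: use concentration_at (limit form)")
        a = f * D * ka / (V * (ka - k))
        return [(a, k), (-a, ka)]
    # two compartments
    k10 = params.cl / V
    k12 = params.cl_distribution / V
    k21 = params.cl_distribution / params.v_peripheral
    s = k10 + k12 + k21
    p = k10 * k21
    disc = math.sqrt(s * s - 4 * p)
    alpha = (s + disc) / 2
    beta = (s - disc) / 2
    if route == "IV":
        A = (D / V) * (alpha - k21) / (alpha - beta)
        B = (D / V) * (k21 - beta) / (alpha - beta)
        return [(A, alpha), (B, beta)]
    ka = params.ka
    if ka is None:
        raise ValidationError(f"route {route} requires ka")
    for lam in (alpha, beta):
        if math.isclose(ka, lam):
            raise ValidationError("ka equals a disposition rate; perturb ka slightly")
    pref = f * D * ka / V
    return [
        (pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha)), alpha),
        (pref * (k21 - beta) / ((ka - beta) * (alpha - beta)), beta),
        (pref * (k21 - ka) / ((alpha - ka) * (beta - ka)), ka),
    ]


def concentration_at(params: SimParams, route: str, t) -> np.ndarray | float:
    """Model plasma concentration (ug/mL) at time(s) ``t`` hours.

    For IV the value at t = 0 is the bolus C0 = Dose/V (the t = 0+ limit);
    the simulated study instead records a pre-dose 0 at the control time.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be >= 0")
    if params.n_compartments == 1 and route in EXTRAVASCULAR and params.ka is not None:
        k = params.k_el
        if math.isclose(params.ka, k):  # limit form as ka -> k
            out = params.f_abs * params.dose * k / params.v_central * t_arr * np.exp(-k * t_arr)
            return float(out) if np.isscalar(t) else out
    terms = _disposition_terms(params, route)
    out = sum(c * np.exp(-r * t_arr) for c, r in terms)
    return float(out) if np.isscalar(t) else out


def closed_form_truth(params: SimParams, route: str) -> dict[str, float]:
    """Analytic reference parameters of the generating model.

    Keys: ``auc_inf``, ``aumc_inf``, ``mrt``, ``t_half`` (terminal),
    ``f_pct``; extravascular adds ``mat``; IV adds ``c0``, ``cl``, ``v_ss``.
    """
    f = params.f_abs if route in EXTRAVASCULAR else 1.0
    auc = f * params.dose / params.cl
    if params.n_compartments == 1 and route in EXTRAVASCULAR and math.isclose(
        params.ka or -1.0, params.k_el
    ):
        k = params.k_el
        mrt_val = 2.0 / k
        aumc = auc * mrt_val
        rates = [k]
    else:
        terms = _disposition_terms(params, route)
        aumc = sum(c / r**2 for c, r in terms)
        mrt_val = aumc / auc
        rates = [r for _, r in terms]
    out = {
        "auc_inf": auc,
        "aumc_inf": aumc,
        "mrt": mrt_val,
        "t_half": LN2 / min(rates),
        "f_pct": 100.0 * f,
    }
    if route == "IV":
        out["c0"] = params.dose / params.v_central
        out["cl"] = params.cl
        out["v_ss"] = params.cl * mrt_val
    else:
        iv_mrt = closed_form_truth(params, "IV")["mrt"]
        out["mat"] = mrt_val - iv_mrt
    return out


def simulate_study(
    params: SimParams, route: str, seed: int | None = None
) -> list[ConcentrationRecord]:
    """Draw one destructive-sampling study arm, reproducible from the seed.

    At every design timepoint, ``n_per_timepoint`` fish are sampled once;
    each concentration is the model value times an independent mean-1
    lognormal deviate with CV ``iiv_cv``.  The t = 0 control is 0.  Values
    below the design LLOQ keep their simulated value but are flagged
    ``below_lloq``.
    """
    design = params.design
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sigma = math.sqrt(math.log(1.0 + params.iiv_cv**2))
    records: list[ConcentrationRecord] = []
    for ti, t in enumerate(design.sample_times):
        model_c = 0.0 if t == 0 else float(concentration_at(params, route, t))
        for fish in range(design.n_per_timepoint):
            if params.iiv_cv > 0 and model_c > 0:
                c = model_c * float(np.exp(rng.normal(-sigma**2 / 2.0, sigma)))
            else:
                c = model_c
            records.append(
                ConcentrationRecord(
                    subject_id=f"{route}-t{ti:02d}-f{fish + 1}",
                    route=route,
                    dose=params.dose,
                    time=float(t),
                    concentration=c,
                    below_lloq=c < design.lloq,
                )
            )
    return records


# ---------------------------------------------------------------------------
# scenarios

#: Default illustrative scenario: clearance, dose and LLOQ match the trout
#: study (ClT 0.03 L/h/kg, 2 mg/kg, 0.04 ug/mL); the remaining kinetic
#: constants are synthetic, chosen to land the extravascular arms in the
#: flip-flop regime (ka < k) with IM/oral bioavailabilities of 86%/25%.
DEFAULT_SCENARIO_KINETICS: dict[str, dict] = {
    "IV": dict(cl=0.03, v_central=0.09, f_abs=1.0),
    "IM": dict(cl=0.03, v_central=0.09, ka=0.10, f_abs=0.86),
    "ORAL": dict(cl=0.03, v_central=0.09, ka=0.075, f_abs=0.25),
}


def default_scenario(seed: int = 0, iiv_cv: float = 0.15) -> dict[str, SimParams]:
    """Per-route :class:`SimParams` of the default scenario."""
    return {
        route: SimParams(
            **kin,
            dose=TROUT_DESIGN.dose,
            iiv_cv=iiv_cv,
            seed=seed * 10 + i,
            design=TROUT_DESIGN,
        )
        for i, (route, kin) in enumerate(DEFAULT_SCENARIO_KINETICS.items())
    }


def save_scenario(scenario: dict[str, SimParams], path: str | Path) -> None:
    """Write a scenario as a plain-text YAML config."""
    any_params = next(iter(scenario.values()))
    d = any_params.design
    payload = {
        "design": {
            "dose": d.dose,
            "lloq": d.lloq,
            "sample_times": list(d.sample_times),
            "n_per_timepoint": d.n_per_timepoint,
            "temperature_c": d.temperature_c,
        },
        "routes": {},
    }
    for route, p in scenario.items():
        entry = {
            "n_compartments": p.n_compartments,
            "cl": p.cl,
            "v_central": p.v_central,
            "f_abs": p.f_abs,
            "dose": p.dose,
            "iiv_cv": p.iiv_cv,
            "seed": p.seed,
        }
        if p.ka is not None:
            entry["ka"] = p.ka
        if p.n_compartments == 2:
            entry["cl_distribution"] = p.cl_distribution
            entry["v_peripheral"] = p.v_peripheral
        payload["routes"][route] = entry
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_scenario(path: str | Path) -> dict[str, SimParams]:
    """Read a scenario YAML written by :func:`save_scenario`."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "routes" not in payload:
        raise ValidationError(f"{path}: not a scenario config (missing 'routes')")
    dd = payload.get("design", {})
    design = StudyDesign(
        dose=dd.get("dose", TROUT_DESIGN.dose),
        lloq=dd.get("lloq", TROUT_DESIGN.lloq),
        sample_times=tuple(dd.get("sample_times", TROUT_DESIGN.sample_times)),
        n_per_timepoint=dd.get("n_per_timepoint", TROUT_DESIGN.n_per_timepoint),
        temperature_c=dd.get("temperature_c"),
    )
    out: dict[str, SimParams] = {}
    entries = {r.upper(): e for r, e in payload["routes"].items()}
    # canonical route order regardless of YAML key ordering
    for route in sorted(entries, key=lambda r: (r not in ROUTE_ORDER, ROUTE_ORDER.index(r) if r in ROUTE_ORDER else 0)):
        out[route] = SimParams(design=design, **entries[route])
    return out
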