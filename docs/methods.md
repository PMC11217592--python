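# Methods

## The analysis problem

Fish PK studies cannot sample one animal repeatedly: each blood draw is
terminal, so the design assigns an independent cohort (here six fish) to
each sampling time. The *naive-pooled* approach treats the per-timepoint
mean concentrations as a single profile per route and runs ordinary
non-compartmental analysis (NCA) on it. The package implements that
pipeline end to end, plus the two satellite computations such a study
reports: ultrafiltration protein binding and bioanalytical method
validation.

Study conditions carried throughout (and used as simulator defaults): dose
2 mg/kg; routes IV, IM, oral; sampling at 0 (pre-dose control), 0.25, 0.5,
1, 2, 4, 6, 8, 10, 12, 24, 48, 72 h; 6 fish per timepoint (3 × 78 = 234
animals); assay LLOQ 0.04 µg/mL; water temperature 13 °C (metadata only —
no rate scaling is modelled).

## Pooling and below-LLOQ handling

Concentrations below the LLOQ are censored, and how they enter a pooled
mean is a genuine design choice (conventions differ between labs). Rules
used here:

- before the first quantifiable timepoint, censored values count as 0
  (pre-absorption samples are true zeros to within assay sensitivity);
- at or after the first quantifiable timepoint, censored values are
  excluded from that timepoint's mean;
- a timepoint at which *all* animals are censored after Tmax terminates the
  profile: trailing all-BLQ points are dropped, not zeroed, which avoids
  biasing the terminal slope.

Per-timepoint SDs are sample SDs (n − 1); `n` reports the animals actually
contributing to each mean. Partially censored late timepoints keep only
their quantifiable animals, which mildly biases those means upward — an
inherent property of pooled designs, not corrected here.

## NCA

**Terminal slope.** λz is the negative slope of an ordinary least-squares
fit of ln C vs t. The regression window is selected automatically (the
de-facto standard of commercial NCA software): among all suffixes of the
post-Tmax quantifiable points ending at t_last with ≥ 3 points
(`min_points`, configurable), the window maximizing adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2) wins; ties within 1e-10 go to the longer
window; windows with non-negative slope are ineligible. For extravascular
routes the Tmax point itself is excluded (it still carries absorption); for
IV it is eligible. A manual window strategy is available. t½ = ln 2/λz by
construction.

**Trapezoids.** Two dialects, assigned per route (IV → linear/log,
extravascular → linear-up/log-down, overridable): the linear rule
Δt·(C₁+C₂)/2 and the log rule Δt·(C₁−C₂)/ln(C₁/C₂). The moment curve t·C(t)
uses the matching rule; for log segments the exact exponential-interpolant
moment, Δt·(t₁C₁−t₂C₂)/ln(C₁/C₂) + Δt²·(C₁−C₂)/ln²(C₁/C₂). Log segments
with a zero or equal endpoint fall back to linear and are logged. Both
dialects agree on non-declining profiles; on a declining segment the log
area never exceeds the linear area (the exponential lies below the chord) —
a property test asserts this.

**IV C0.** The first IV sample is at 0.25 h; the bolus concentration at
t = 0 is back-extrapolated from a log-linear line through the first two
quantifiable means, and the 0 → 0.25 h segment enters the AUC. If the
profile does not decline initially the first observation is used, logged.

**Extrapolation.** AUC∞ = AUC_last + C_last/λz and
AUMC∞ = AUMC_last + C_last·t_last/λz + C_last/λz², with C_last the last
observed quantifiable mean (not the λz-predicted value — simplest
convention, configurable in principle). AUC_extrap% = 100·(AUC∞ −
AUC_last)/AUC∞. MRT = AUMC∞/AUC∞.

**IV-only parameters.** Cl_T = Dose/AUC∞ and V_dss = Cl_T·MRT. With dose in
mg/kg and concentration in µg/mL these emerge in L/h/kg and L/kg with no
conversion factor. Landmarks (Cmax, Tmax — earliest time on ties — and the
0.25-h concentration) are read directly off the observed mean curve.

**Rounding.** Full floating point internally; the CLI serializes at 2
decimals, matching how such tables are reported.

## Route comparison

F and MAT are computed from the 0–∞ quantities (not 0–last):
F% = 100·AUC∞_ext/AUC∞_IV (may exceed 100), MAT = MRT_ext − MRT_IV. A
negative MAT — possible with noisy pooled profiles — is reported as-is with
a warning rather than clamped. Flip-flop (absorption rate-limiting, so the
extravascular terminal phase reflects ka) is flagged when MAT > MRT_IV.

## Protein binding

binding % = 100·(total − free)/total per replicate; a free concentration
exceeding total is rejected as assay failure. Per-level mean ± sample SD;
the overall mean ± SD is taken **across the level means** (each spiking
level weighted equally, the convention that matches how such studies
tabulate an overall figure); averaging across all replicates is available
as an option. "Concentration dependent" is operationalized as the range of
level means exceeding a threshold (default 5 percentage points) — a
transparent criterion chosen because three replicates per level cannot
support a meaningful ANOVA. With one level the flag is undefined (`None`).

## Assay validation

CV = 100·SD/mean (sample SD — replicate counts are small, typically 6),
bias = 100·(calculated − theoretical)/theoretical (signed), recovery =
100·observed/spiked. Calibration is fitted by unweighted OLS by default
(1/x and 1/x² weightings available); constant responses are a degenerate
fit and rejected. The validation report aggregates QC runs per level:
intra-day CV/bias are the worst within-day replicate statistics, inter-day
statistics pool all days. Acceptance follows EMA-style limits: CV < 20 %
and bias within ±15 % at the LLOQ, CV < 15 % elsewhere.

## Simulator

Disposition is a 1- or 2-compartment linear model; extravascular input is
first-order with fraction absorbed `f_abs`. One-compartment solutions are
used directly (with the ka → k limit form); two-compartment curves come
from the standard bi-exponential eigenvalues (α, β). Each simulated fish's
concentration is the model value multiplied by an independent **mean-1
lognormal** deviate with CV `iiv_cv` (default 0.15): in a destructive
design each fish contributes one sample, so between-fish and assay
variability are inseparable and modelled as a single multiplicative noise —
applied to concentrations, not parameters. The t = 0 control is always 0;
values below the LLOQ are flagged censored but keep their simulated value.
One seeded `numpy` Generator stream per `simulate_study` call makes every
arm reproducible; the CLI records seeds in the run metadata.

Default scenario: CL = 0.03 L/h/kg, dose and LLOQ as above (matching the
reported clearance/design of the motivating study); V = 0.09 L/kg hence
k ≈ 0.333 h⁻¹; ka = 0.10 h⁻¹ (IM, f_abs 0.86) and 0.075 h⁻¹ (oral, f_abs
0.25), i.e. both extravascular arms sit in the flip-flop regime (ka < k)
with bioavailabilities near the reported 86 %/25 %. The kinetic constants
beyond CL/dose/LLOQ are synthetic: the motivating analysis is
non-compartmental and publishes no compartmental parameters.

What the simulator does *not* emulate: temperature-dependent kinetics,
anaesthesia effects, assay error that grows near the LLOQ, between-batch
effects, or model misspecification (the data generator and the NCA's
implicit assumptions match by construction). Passing recovery tests
therefore validate the *estimator arithmetic and the pooling/censoring
logic* under the study design, not robustness to biological model error.

## Closed-form oracles and verification scales

`closed_form_truth` supplies analytic references: AUC∞ = f·Dose/CL;
one-compartment MRT_IV = 1/k, MRT_ext = 1/k + 1/ka, MAT = 1/ka, terminal
t½ = ln 2/min(k, ka); two-compartment moments from the exponential-term
representation (Σaᵢ/λᵢ, Σaᵢ/λᵢ²). The test suite checks, at these problem
sizes:

- dense noise-free grids (Δt = 0.01 h over 72 h) reproduce AUC∞, MRT, t½,
  F and MAT within 1 % and the two trapezoidal dialects agree within
  0.5 %;
- the sparse 13-time, n = 6, 15 %-CV design over 200 seeded replicates
  recovers F without material bias (≤ 3 percentage points) and flags
  flip-flop in ≥ 95 % of replicates;
- window selection matches an exhaustive brute-force adjusted-R² search on
  50 seeded noisy profiles (independent statsmodels-based oracle in tests).

These sizes keep the full suite under a minute on one core while leaving
Monte-Carlo error well below the asserted margins.

## Numerical notes and limitations

- λz windows need ≥ 3 points; profiles whose decline has < 3 quantifiable
  post-Tmax points raise `InsufficientDataError`, rising profiles raise
  `NoTerminalPhaseError` — no silent defaults.
- Adjusted-R² ties are resolved deterministically (longer window), so
  results are permutation- and platform-stable.
- Naive pooling yields one profile per route: no between-subject variance
  or inter-route inference is possible (Bailer-type sparse-sampling SEs are
  out of scope), and all reported parameters are point estimates.
- The concentration-dependence flag is a screening heuristic, not a test
  with controlled error rates.
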