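# Methods

This note documents the model, the numerical machinery and the design
choices behind `cardiowean`, in the spirit of a model-description chapter:
what is computed, under which assumptions, and what the synthetic
experiments do and do not demonstrate.

## Model and assumptions

The circulation is reduced to three stressed-volume compartments (heart,
arteries, veins) closed through three resistances, plus a constant
extracorporeal shunt `Q_d` from veins to arteries.  Assumptions inherited
from this minimal closed-loop family:

- no pulmonary circulation and no right–left ventricular interaction: the
  single ventricle lumps the systemic pumping function;
- valves are ideal diodes with series resistance — no inertance, no
  regurgitation (only resistances are identifiable from routine ICU data);
- the pump is represented purely by its imposed flow: no pressure–flow
  curve, no cannula dynamics;
- no respiratory modulation (the experimental protocol the synthetic data
  emulates records with ventilation paused) and no beat-to-beat heart-rate
  variability within a record.

The ventricular activation is a periodic Gaussian
`e(t) = exp(−W (mod(t,T) − κT)²)` with defaults `W = 80 s⁻²`, `κ = 0.375`.
The activation's exact functional form is a modelling choice of this
package (the minimal-model literature uses several near-equivalent bumps);
its two parameters are exposed through `DriverConfig`.  `W` controls the
systolic fraction (~`1/√W · 1/T` of the beat near full activation), `κ`
the timing of peak systole inside the beat.

Units are mmHg, ml, s everywhere.  Pump flows are stored in ml/s
internally and converted from the clinical l/min by the exact factor
1000/60 at the I/O boundary — the coefficient units (e.g. `E_Sl,h` in
mmHg·s/ml²) only cohere with Q_d in ml/s.

The model's stressed heart volume is compared directly with catheter
volumes (`max V_h`, SV), with no unstressed-volume offset: the fitted SBV
then absorbs any offset, which is the identifiable choice given that only
volume differences and maxima enter the observable vector.

### Parameters

| parameter | meaning | unit | default / source |
|---|---|---|---|
| `E_h` | end-systolic (ESPVR) elastance ~ contractility | mmHg/ml | identified |
| `A_h` | EDPVR exponential shape | 1/ml | identified |
| `E_a` | arterial elastance | mmHg/ml | identified |
| `R_s` | systemic resistance | mmHg·s/ml | identified |
| `SBV` | total stressed blood volume | ml | identified |
| `HR` | heart rate | 1/s | measured |
| `B_h` | EDPVR pre-exponential factor | mmHg | 0.35, literature |
| `E_v` | venous elastance | mmHg/ml | 0.014, literature |
| `R_i`, `R_o` | valve resistances | mmHg·s/ml | 0.015 / 0.03, literature |

`E_v` cannot be identified from a mean venous pressure alone, and `R_i`,
`R_o`, `B_h` are not identifiable without intraventricular pressure traces;
hence the literature constants.

## Limit-cycle computation

Observables are defined on the periodic steady state.  Beats are
integrated with adaptive RK45 (`scipy.solve_ivp`), step capped at `T/200`
so the valve-switching kinks (the `max(0,·)` diode laws; no event
detection) are always resolved; default tolerances 1e-7.

Plain beat-to-beat iteration converges very slowly here: the beat-return
map has a weakly contracting mode (eigenvalue ≈ 0.999, the venous
volume-redistribution mode with compliance `1/E_v ≈ 71 ml/mmHg`), so
reaching a tight tolerance would take hundreds of beats.  The simulator
therefore:

1. runs a short warm-up (≤12 beats, until the per-beat state change is
   below 1e-3·SBV) to contract the fast modes;
2. applies Newton shooting to the beat-return map in two free volumes
   (conservation eliminates the third), reusing one finite-difference
   Jacobian since the map is nearly linear near the cycle.  Because the
   fixed point is only located to ~residual/(1−λ), the residual is driven
   to the integration noise floor (5e-9 relative) rather than to a loose
   tolerance;
3. falls back to plain iteration with the consecutive-beat observable
   criterion (`convergence_tol`, default 1e-4 relative on all five
   observables) if shooting fails; non-convergence is reported via the
   `converged` flag, never an exception.

Initial state: SBV split in equal thirds (the limit cycle is independent
of initialization for feasible parameters; a user-supplied state is
projected onto the conservation manifold first).  Runaway states —
negative compartment volumes or an EDPVR exponent `A_h·V_sh > 50` — raise
`InfeasibleParameterError`.

The observable extractor applies the clinical MAP estimator
(⅓ systolic + ⅔ diastolic) to the *simulated* arterial trace as well, so
model and data observables are defined identically; the true time average
is exposed separately (`BeatTrace.P_a_time_average`) as a diagnostic.  The
mean venous pressure is a true time average.  Observables are read off a
fixed 241-point grid over one beat, which bounds extremum-location error
well below the measurement sigmas.

## Identification

Both fits minimize the σ-weighted residual sum with
`scipy.optimize.least_squares` (trust-region reflective) on
log-transformed positive quantities — positivity by construction, and
Gauss–Newton steps exploit the sum-of-squares structure, costing tens
rather than thousands of forward simulations.  Residual evaluations
warm-start the cycle search from a state frozen per optimizer start
(keeping the objective a deterministic function of the parameters) and
share the shooting Jacobian per flow level.  Infeasible parameter sets
return large finite residuals (1e4, plus a feasibility-distance term for
negative mapped parameters) so the optimizer can retreat.

- **Single flow** (5 parameters): multi-start (default 5 starts: a
  physiologic guess — the mean healthy porcine baseline — plus seeded
  log-uniform perturbations within ±50 %); finite-difference step 1e-3 in
  log-space, chosen an order of magnitude above the simulator's observable
  noise floor.
- **Weaning test** (10 coefficients, n ≥ 2 flow levels; n = 2 is exactly
  determined and warns): seeded by single-flow fits at the lowest and
  highest flows and the exact line through them, then jointly refined over
  all 5n residuals.  Slopes are parameterized as fractional change across
  the fitted flow range (scaled by the seed intercepts) for conditioning;
  intercepts in log-space.  Because the seed is data-driven, the default
  is a single start; extra jittered starts are available.

σ defaults are the study-level constants (2 ml max V_h, 0.4 mmHg PP_a,
0.2 mmHg P̄_a, 0.1 mmHg P̄_v, 3 ml SV); `NoiseWeights.from_beats`
recomputes them from per-beat data, and `NoiseWeights.unit()` supports
σ-less datasets (e.g. re-analyses of published observables where only a
4-component ventricular vector `(SBP, EDP, EDV, SV)` is available —
extracted by `summarize_ostadal`).

## Weaning prediction

Parameters at `Q_d = 0` are the fitted intercepts; the heart rate there is
extrapolated by ordinary least squares from the dataset's (Q_d, HR) pairs
(heart rate demonstrably varies with pump flow), with a fixed-HR override.
The simulated zero-flow beat yields MAP, `EF = SV/max V_h` and
`VTI = SV/(π(φ_LVOT/2)²)`.  All three criteria are strict inequalities;
the EF threshold defaults to 0.25 (the accepted band is 20–25 %, and the
verdict at 0.20 is always reported alongside).  `φ_LVOT` has no default —
it is echo-derived; without it VTI is reported unavailable and excluded
from the overall verdict with a warning.

Normalized flow-responses `Δ₁x/x = slope·(16.667 ml/s)/intercept` (the
fractional parameter change for a 0→1 l/min flow increase) are reported at
2 decimals, with a sign classification (|Δ| < 0.005 counts as near-zero).

## Synthetic data

The generator emulates the measurement protocol the analysis assumes: for
each scheduled flow, map the true coefficients through the linear laws,
simulate to the limit cycle at the profile heart rate, then add
independent Gaussian per-beat noise with the σ constants and average over
`n_beats_averaged` (default 10 — the per-record beat count is a protocol
detail not fixed by the data, chosen once).  Gaussian is the
maximum-entropy choice given only standard errors.  Ground truth
(coefficients, per-flow parameters and exact observables) is returned for
recovery scoring.

Stock scenarios: a healthy baseline (mean identified healthy porcine
parameters, single record at `Q_d = 0`, HR 1.32 /s), a cohort-mean
post-arrest weaning test (5 flows from 4 l/min, −15 % per step), a
representative single post-arrest weaning test (5 flows from 2 l/min —
the flow range porcine experiments actually reach; the 4 l/min schedule
would drive its strongly negative `R_s` slope out of the model's validity),
and a failing heart (zero-flow contractility quartered).  The heart-rate
profile `HR(Q_d) = 1.45 − 0.002·Q_d` (1/s, ml/s) rises as support is
withdrawn, matching the monotone trend seen experimentally; the healthy
scenario uses a constant rate.

**What passing synthetic tests shows — and does not.**  The synthetic data
share the analysis' own structural assumptions (exactly linear parameter
responses, Gaussian iid noise, no respiratory or rhythm artefacts, no
model discrepancy).  Recovery and error bounds on these data validate the
estimator and the numerics; they cannot certify the model against real
physiology, drug effects (noradrenaline is carried as metadata only) or
volume-catheter bias.

## Numerical choices and limitations

- Determinism: identical inputs and seeds reproduce results bit-for-bit;
  every stochastic path is driven by an explicit seed.
- Sample (n−1) standard deviation for all "mean ± σ" aggregations (it
  reproduces the published baseline summary row within printed rounding);
  a single value reports σ = 0 with a warning.
- Relative-error reports guard against zero experimental components and
  length mismatches; unsigned ≥ |signed| is enforced structurally.
- The linear control laws are local descriptions: extrapolating them to
  flows where a mapped parameter turns non-positive raises an error naming
  the parameter rather than simulating an unphysical circulation.
- Problem sizes: the shipped experiments use 5 flow levels, ~1 s beats,
  and fits costing ~10² limit-cycle solves; a full noisy weaning refit
  runs in about a minute on one CPU.
- Known limitations: single-ventricle model (no right-heart failure
  analysis), imposed constant pump flow, no confidence intervals (point
  estimates only, matching the descriptive-statistics design), and an
  activation waveform chosen by this package rather than fixed by data.
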