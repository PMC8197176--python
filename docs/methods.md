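# Methods

This note documents the model, the estimation machinery, the synthetic
data generator, and the numerical and design choices behind `ctldyn`.

## Model structure and assumptions

The tumour is treated as a well-mixed population — no spatial structure,
reasonable while tumours stay small (< 10 mm³ over the 15-day window
modelled here).  Untreated growth is exponential at a fixed mitosis rate
`g = 0.5 day⁻¹`; no carrying capacity is included because the tumours
never approach one on this timescale.

Transferred CTLs act on the tumour in two ways: killing at a constant
per-CTL rate `k_e` (CTL⁻¹ day⁻¹), and induction of a reversible quiescent
state at rate `k_q` (CTL⁻¹ day⁻¹) from which cells recover at `d_q`
(day⁻¹).  The constant per-CTL killing rate is the reduction of a
dual-saturation law in the regime where tumour cells greatly outnumber
CTLs; the saturation constants themselves are not identifiable from data
of this kind and are not free parameters.  The model is therefore only
valid while tumour cells are frequent — it will overstate killing in
regimes of deep regression.

Killing applies to proliferating and quiescent cells in proportion to
their frequencies, which makes total burden obey `dT/dt = g·T_p − k_e·E`
identically — this conservation identity is enforced by construction and
tested to 1e-10 over random states and parameters.

CTL influx is `s·T^(2/3)` (a constant rate per unit area of a spherical
tumour's boundary), zero before the transfer day.  Intratumoural CTL
population dynamics are driven by two E:T-ratio-driven first-order
variables: an auto-inductive stimulus `I` (mitosis) and a tumour
resistance factor `R` (apoptosis).  `I` and `R` are expressed directly in
events CTL⁻¹ day⁻¹, so no extra scaling parameters are needed.  The decay
`d_r` is fixed at 0: the experiments are too short for acquired
resistance to measurably wane, and freeing it produces values
indistinguishable from zero.

Initial conditions: `T_p = 1200`, everything else 0, at day 0
(inoculation).

## Numerical integration

`simulate` integrates with LSODA (`scipy.integrate.odeint`,
rtol = atol = 1e-8).  Three choices matter:

* **Restart at the transfer day.**  The step change in `s` is handled by
  splitting the integration at the transfer day and restarting the
  solver, rather than exposing a discontinuous right-hand side to the
  adaptive stepper.
* **Continuous clamp at small T.**  All `E/T` and `T_x/T` terms use the
  denominator `max(T, 1)`, so per-capita terms go to zero continuously as
  the tumour vanishes.  A hard cut-off ("terms are zero below one cell")
  makes the right-hand side discontinuous, and trajectories that hover
  near the threshold cause the adaptive stepper to chatter indefinitely;
  the clamp removes the singularity with no effect in fitted regimes
  (T ≥ O(10³) everywhere the model is trusted).
* **Blow-up guard.**  In extreme corners of the calibration search box
  the auto-inductive term (`dE ⊇ E·I`, `dI ⊇ k_i·E/T`) blows up in finite
  time.  Integration aborts with `IntegrationError` once any state
  exceeds 1e12 or the per-interval step budget is exhausted; the
  calibration objective converts this to a large finite penalty (1e6) so
  global optimisation can continue.

Self-convergence of the integrator (default vs tightened tolerances on a
10× finer grid) is tested to relative 1e-4; the exponential and
constant-CTL linear regimes are tested against closed forms.

## Observation model

All fitting happens in one currency (day⁻¹ for rates, dimensionless for
E:T).  From data: killing = TC apoptosis events/(duration × CTLs), TC
mitosis = events/(duration × tumour cells), CTL mitosis and apoptosis =
events/(duration × CTLs), E:T = CTL count/TC count, and volumetric growth
= ln(V₂/V₁)/(t₂−t₁) per successive measurement pair, placed at the
interval midpoint.  From the model: killing = `k_e`, TC mitosis =
`g·T_p/T`, CTL mitosis = `I`, CTL apoptosis = `R`, E:T = `E/T`, growth =
`(1/T)dT/dt`.

Per-CTL rates from positions containing zero CTLs are omitted (a 0/0
statistic carries no information), not recorded as zeros; E:T is still
emitted (genuinely zero).  Per-mouse averaging of E:T points before
fitting is available (`assemble_points(aggregate_et=True)`) but the
default is per-position, matching the convention that one data point is
one statistic from one position.

**Growth-rate matching in the objective.**  Although `model_predictions`
reports the instantaneous growth rate, the RMSE objective matches a
volumetric growth *data* point with the model's interval log-slope
`ln(T(t₂)/T(t₁))/(t₂−t₁)` over the same measurement interval.  Right
after transfer the growth rate changes quickly, and on 2–4-day intervals
the midpoint-instantaneous value differs from the interval average by up
to O(0.1) day⁻¹ — a like-for-like comparison removes that systematic
mismatch (and makes the objective exactly zero at the generating
parameters of a noise-free cohort).

## Poisson killing models

TC apoptosis counts per position are Poisson with intensity either
`λ·n_ctl·τ` (linear, λ in CTL⁻¹ day⁻¹) or `λ·n_ctl·n_tc·τ` (mass-action,
λ in CTL⁻¹ TC⁻¹ day⁻¹), with the imaging duration τ entering as explicit
exposure.  The MLE is the closed form Σcounts/Σexposure; tests verify it
against numerical likelihood maximisation.  Models are fitted pooled or
with one rate per treatment group and ranked by AIC and BIC.  Confidence
bands use exact Poisson inverse-CDF quantiles (smallest k with
CDF(k) ≥ q) — counts are small, so normal approximations are
inappropriate.

## Calibration

The objective is the unweighted root-mean-square error over every
calibration point — growth rates, the four process rates, and the
dimensionless E:T ratios together (a per-kind weight hook exists but
defaults to 1).  One parameter vector is fitted per treatment group, with
day-3 and day-7 transfer conditions simulated separately and jointly
scored; `g` (pre-set from untreated growth) and `d_r` (0) are fixed, so
seven parameters are searched: `s` in [0, 5], the rest in [0, 50].

Minimisation uses differential evolution with the current-to-best
("local-to-best") mutation strategy, F = 0.8, CR = 0.9, greedy immediate
replacement, no polishing step.  The full protocol is population 200,
500 generations, 5 independent repeats; recovery experiments in the test
suite use reduced budgets (population 24–40, 60–120 generations, 2–3
repeats) so the suite runs in minutes.  Starting populations are seeded
Latin hypercubes — at small population sizes these cover the box much
better than uniform draws.  One master seed spawns per-repeat seeds; the
whole fit is deterministic given the seed.  `FitConfig.seed_points`
optionally injects known parameter vectors into the starting population
(warm start); with elitist replacement this guarantees the returned
objective never exceeds the objective at an injected point.

## Synthetic cohorts

The generator emulates the study design: volumes on days 1, 3, 6, 9, 13
and 15 for every mouse; transfer on day 3 or day 7; four positions per
mouse on days 6 and 9, each imaged 1–3 h, recorded only after transfer.
Per mouse, the ODE is simulated and then:

* volumes are `T/cells_per_mm3` with lognormal noise (mean 1, CV 0.2).
  `cells_per_mm3 = 1.3e5` is a calibration convenience chosen so 1200
  cells at day 0 give a day-3 untreated volume near 0.04 mm³ — not a
  claim about true melanoma cell density;
* field tumour-cell counts have expectation
  `field_cell_scale·(T/field_ref_cells)` (defaults 300 at 1e5 cells)
  times a lognormal field-placement factor (σ = 0.5), reflecting how
  strongly per-field counts depend on where the imaging window lands;
  CTL counts have expectation `n_tc·(E/T)`; both are Poisson;
* event counts are Poisson given the counts:
  `tc_apoptosis ~ Poisson(k_e·n_ctl·τ)`,
  `tc_mitosis ~ Poisson(g·(T_p/T)·n_tc·τ)`,
  `ctl_mitosis ~ Poisson(I·n_ctl·τ)`,
  `ctl_apoptosis ~ Poisson(R·n_ctl·τ)`, τ in days.

With `noise=False` every draw is replaced by its expectation (fixed 2 h
duration, fractional counts retained), giving an exact round trip: the
observation model recovers the model's rates to machine precision.
Optional per-mouse parameter jitter is deliberately not included — the
generator emulates measurement and sampling noise around one shared
biology, not between-animal heterogeneity, so passing recovery tests say
nothing about mixed-effects settings.  Cohort tables are plain CSV plus a
YAML manifest recording design and seed.

## What the recovery experiments show — and a known identifiability limit

On noise-free cohorts the reduced-budget DE refit recovers all seven free
parameters essentially exactly (RMSE < 1e-3; `k_q` and `s` within a few
percent), and a ±20% local sensitivity analysis confirms the generating
point is a local optimum in every free direction.

Under the full noise model the picture is sharper for some parameters
than others.  `s`, `k_e` and `k_q` are recovered within 2× of truth in
≥ 80% of replicate cohorts at reduced budget.  The quiescence recovery
rate `d_q`, however, sits on a flat ridge with `k_q`: replicate noise can
move the *global* optimum of the noisy objective to points with `d_q`
2–3× below truth that genuinely score better than the generating
parameters (verified by re-evaluating truth on the same points).  This is
a property of the unweighted objective and the study design — only a few
late-time growth points carry information about recovery from quiescence,
and they are swamped by hundreds of noisier intravital points — not an
optimizer failure.  Conclusions that lean on the precise value of `d_q`
should therefore be treated with caution; conclusions about the
killing-vs-quiescence attribution are insensitive to it.

## Effect attribution

`scale_sweep` multiplies `k_e` or `k_q` by factors (default 0, 1, 3, 4)
holding everything else fixed, and summarises tumour control as final
burden at the horizon and area under log₁₀ burden.  With either fitted
parameter set, setting `k_e = 0` changes day-15 burden by less than a
factor 2, while `k_q = 0` releases the tumour 18–79-fold toward untreated
growth; increasing the killing factor monotonically improves control.
The antimitotic effect is the dominant control mechanism, and the
costimulated parameter set both relies on it more strongly and sustains a
higher E:T ratio at late times.

## Known limitations

* No spatial structure; events at the invading margin are not resolved.
* Only transferred CTLs are modelled; endogenous responses are absent.
* The constant per-CTL killing rate overstates killing once the tumour
  has deeply regressed.
* `d_q` is weakly identified from noisy cohorts (above).
* The generator makes all four event types Poisson given counts and
  rates; real event counts may be over-dispersed, so recovery
  performance here is an upper bound on what identical analyses achieve
  on real data.
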