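# Methods

## The population model

The simulator is an agent-based, discrete-time (default dt = 0.1 h) model of
a generic differentiating stem/progenitor population. Each cell carries:

* its own cycle length L, drawn at birth from a gamma distribution with
  mean T(t) (the schedule value at birth) and standard deviation cv·T(t)
  (shape 1/cv², scale T·cv²; cv = 0.30 by default, degenerate at cv = 0);
* an age (time since birth) and a phase derived from it — G1, S, G2M as
  equal thirds of L by default (`phase_fractions` allows unequal phases);
* a state: cycling, quiescent or terminally differentiated;
* a heritable, permanent set of binary labels (the thymidine-analog layer).

Per step, in order: (1) every progenitor (cycling or quiescent) dies with
probability 1 − exp(−∅_P(t)·dt); (2) cycling cells age by dt; (3) cells in S
phase while a label window is active become positive; (4) cells whose age
reaches L divide — the mother is replaced by two daughters of age 0 with
fresh cycle-length draws (mean T at division time) which inherit her labels,
and each daughter independently remains a progenitor with probability
p = (1 + ppdd(t))/2, otherwise differentiates terminally (a config switch
accepts explicit (pp, pd, dd) triplets instead); (5) quiescence occupancy is
adjusted toward the growth-fraction schedule γ(t).

The initial population is unsynchronized: ages uniform on [0, L), quiescent
with probability 1 − γ(0). All randomness flows through one seeded
numpy PCG64 generator; identical configs give bit-identical output.

**Quiescence mechanics.** Quiescence is modelled as minimal-flux target
tracking: at each step, if the cycling fraction of progenitors deviates from
γ(t), randomly chosen cells are moved between the cycling and quiescent
pools (re-activated cells restart at age 0 through G1 with a fresh cycle
draw). Under constant schedules the net flux is at the rounding level. The
alternative — sending each progenitor daughter to quiescence with
probability 1 − γ at division — keeps the same mean occupancy but
continuously churns the quiescent pool, which leaks label-positive cells
into it and drives the cumulative-labeling plateau visibly above γ (~+0.1
at γ = 0.7 over a 30 h exposure); since the plateau-equals-γ law is the
basis of growth-fraction measurement, we use the low-flux variant.

**Per-event versus per-cell variability.** Cell-to-cell variability enters
through the per-cell cycle-length draw; the fate, quiescence and death
probabilities are evaluated per event from the schedules. Making those
probabilities fixed per-cell traits instead would add clonal correlations
that none of the estimators uses; population-level moments are unchanged.

## The labeling layer

A label marks every cycling cell whose age interval during a step overlaps
its own S-phase interval while an exposure window is active. Labels are
binary, inherited by both daughters, never diluted or lost — quiescent and
differentiated cells never acquire new labels. Labeled fractions are always
reported against all progenitors (cycling + quiescent), matching how
progenitor-marker-positive cells are gated experimentally.

The three experiment drivers simulate one independent replicate per fixation
time (fresh child seed per replicate, mirroring "several identical
samples"): cumulative (one label, staggered fixations), dual cumulative
(shared first label, staggered second label, common fixation) and
pulse-chase (default 0.5 h pulse, detector = second 0.5 h pulse immediately
before fixation, or an instantaneous S-phase gate).

For a homeostatic population with constant T and uniform ages the labeled
fraction follows the classical labeling index γ·(T_S + t)/T capped at γ:
initial value γ·T_S/T (S-phase occupancy), slope γ/T, plateau γ at
t = T − T_S. These closed forms are the oracles for the C1/C2 fits.

## The four estimators

* **C1 (single cumulative):** OLS on the first 4 curve points gives the
  slope; the mean of the last 4 gives γ̂; T̂ = γ̂/slope. The slope
  uncertainty is half the difference between the slopes refitted to the
  points shifted by +SE and −SE; T's error follows by quadrature.
* **C2 (dual cumulative):** same index law in the second label's exposure δ
  (valid once the first label has saturated): T̂ = γ̂/slope and
  T̂_S = intercept·T̂/γ̂. γ̂ comes from the curve's plateau when reached,
  otherwise it must be supplied.
* **PC (pulse-chase):** the double-positive fraction versus chase time
  starts high (the pulsed cohort is still in S), dips while the cohort
  transits G2/M/G1, and peaks when it re-enters S one cycle after the pulse.
  The fit locates the first trough, then the maximum after it, refined by a
  quadratic through the three nearest points; T̂ is the vertex position.
  T̂_S is the rise amplitude divided by the slope of the 10–90% rising
  flank — a rough estimate, since per-cell cycle dispersion smears the
  flank.
* **BP (branching process):** per window [t₀, t₁],
  ppdd̂ = (ΔP + Φ)/(ΔP + ΔD + Φ) and T̂ = γ̄·I/(ΔP + ΔD + Φ), with
  I = ∫P dt and Φ = ∫∅_P·P dt by dense trapezoid quadrature and γ̄ the
  window-averaged growth fraction. These are the exact inverses of the
  forward rate model dP/dt = (ppdd·γ/T − ∅_P)P, dD/dt = (1−ppdd)·γ·P/T: on
  ODE-generated curves recovery is at numerical precision. Windows with
  non-positive division mass ΔP + ΔD + Φ are masked (no divisions to
  attribute), and ppdd̂ outside [−1, 1] is clipped with a warning.

  `bp_estimate` accepts raw counts (linear interpolation; the default in
  the simulation benchmark, where exact counts are recorded), sigmoid-fitted
  counts (the experimental workflow; a three-parameter logistic
  A/(1+exp(−(t−t₀)/τ)), multi-start initialized, τ < 0 allowed for
  shrinking pools), or arbitrary callables. The logistic family is only
  appropriate for saturating, monotone series — on linear or exponential
  data its tails distort the window estimates, which is why the benchmark
  uses the raw-counts route.

  The 50% confidence band shifts each count series by ± half its maximum
  standard error, refits the sigmoids, re-runs the equations on all four
  shift combinations and takes the envelope.

* **Mode decomposition:** under independent daughter fates,
  p = (1 + ppdd)/2 and (pp, pd, dd) = (p², 2p(1−p), (1−p)²) — exact
  identities, with pp − dd reproducing the input.

## Known bias: age structure in growing populations

The BP equations treat 1/T as a per-cycling-cell division *rate*. In a
population growing at Malthusian rate λ the stable age distribution is
biased toward young cells, so the realized per-capita division rate is
λ/ppdd, slightly below 1/T̄; the equations therefore overestimate T by the
factor ppdd·γ/ln(1 + ppdd·γ) to leading order — about +7% at ppdd = 0.15
and +13% at ppdd = 0.3 (cv 0.3). The mode estimate is immune: each division
contributes exactly ppdd net progenitors, so ppdd̂ is unbiased regardless of
age structure. The same asymmetry appears in the forward-consistency check:
feeding T̂ back into the age-structured simulator compounds the offset in D
in growing conditions, so the closure is exact at homeostasis and
approximate (order ppdd·γ) under growth. At homeostasis (pp−dd = 0) — the
regime of the headline benchmarks — there is no bias at all.

## Benchmark scenarios and sizes

Named scenarios fix everything given (name, seed): `constant`
(T = 20 h, ppdd = 0, γ = 1, ∅_P = 0, m = 500, 48 h), `growing`
(ppdd = 0.3), `variable_T` (T(t) = 20 + 6·cos(2πt/30) h over a 30 h run:
time-average exactly 20 h, range 14–26 h, dipping to 14 h mid-run),
`variable_mode` (ppdd ramping +0.5 → −0.5) and `variable_both`. Sampling
grids mirror the experimental cadence: cumulative fixations every 2 h to
30 h, second-label exposures 2–20 h with common fixation at 30 h,
pulse-chase every 2 h to 30 h. Each of the (default 10) runs simulates each
labeling arm and an unlabeled counts arm independently; the BP scalar
estimate averages ~6 h windows on the recorded counts. The true value under
a time-varying schedule is the time average of T(t) over the run.

Ten runs of 500 cells keep the whole four-method comparison under ~10 s per
scenario on one CPU while leaving the per-run estimator noise (binomial
sampling of labeled fractions at n ≈ 500) clearly visible — the run-to-run
dispersion of C1/C2 versus the tightness of BP is itself one of the
benchmark's findings.

## What the generator does and does not emulate

The simulator reproduces the statistical structure the estimators rely on:
unsynchronized age distributions, per-cell cycle dispersion, binomial
sampling noise at realistic cell counts, independent replicate dishes, and
permanent heritable S-phase labels. It does not model spatial organization,
label toxicity or cycle lengthening by the analog, antibody/detection noise,
label dilution over many divisions, or intermediate progenitor compartments.
Passing benchmarks therefore demonstrate the *methodological* properties of
the estimators (bias under time variation, dispersion, the value of the
label-free inversion), not the absence of these experimental confounds.

## Numerical choices

* dt = 0.1 h ≪ T; divisions are processed when age crosses L within a step.
* Trapezoid quadrature with 50 subdivisions per BP window (400 in exactness
  tests); the quadrature error is far below sampling noise.
* Sigmoid fits run from 8 starting points (data-driven, one near-linear
  high-amplitude start, jittered restarts) and keep the best residual sum.
* Linear fits with all-identical abscissae raise a singular-fit error; C1/C2
  treat slopes below 1e-9/h as estimation failures (an all-plateau curve
  must fail rather than return an astronomically large T).
* Degenerate inputs (empty populations, empty fixation lists, extinct
  progenitor pools) return empty/masked results or raise typed errors —
  never fabricated values.
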