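# cyclefate

Stochastic simulation and estimation of **cell-cycle length** and **mode of
division** in differentiating progenitor populations — for example neural
progenitors (radial glia) expanding and differentiating in culture.

Quantifying how fast progenitors cycle (T), how many of them actually cycle
(the growth fraction γ), and whether divisions self-renew or differentiate
(pp / pd / dd) is central to developmental biology, yet the standard
thymidine-analog assays give conflicting answers whenever the dynamics are
not constant. `cyclefate` provides:

* an **agent-based simulator** of a progenitor population: each cell carries
  its own gamma-distributed cycle length (CV 30% by default), a phase
  (G1/S/G2M as thirds of the cycle), a state (cycling, quiescent,
  differentiated), and a heritable set of binary labels; divisions send each
  daughter independently back into the cycle with probability
  p = (1 + (pp−dd))/2; quiescence occupancy tracks γ(t); apoptosis is a
  continuous hazard ∅_P(t);
* an **in-silico EdU/BrdU layer** implementing the three classical labeling
  designs: single cumulative (C1), dual cumulative (C2) and pulse-chase (PC);
* the **branching-process (BP) estimator**, which needs no label at all: over
  a time window [t₀, t], with ΔP and ΔD the changes in progenitor and
  differentiated counts, I = ∫P dt and Φ = ∫∅_P·P dt,

      pp − dd = (ΔP + Φ) / (ΔP + ΔD + Φ)
      T       = γ̄ · I / (ΔP + ΔD + Φ)

  inverting the population balance dP/dt = ((pp−dd)·γ/T − ∅_P)·P,
  dD/dt = (1−(pp−dd))·γ·P/T, with 50% confidence bands propagated through
  sigmoid refits of the count series;
* a **benchmark harness** comparing all four methods on named scenarios
  (constant, growing, variable cycle length, variable division mode), a
  forward-consistency check (simulate the estimates, compare the envelope to
  the observed counts), and a counterfactual factor decomposition (which of
  T, γ, pp−dd drives population expansion).

## Worked example

Estimate the division mode drift of a simulated culture without any labeling
(`examples/04_branching_process.py`): three replicate dishes of 500
progenitors are simulated for 48 h with pp−dd ramping from 0.4 to 0.0 at
T = 20 h, pooled, and inverted:

```
 time_h  ppdd     T
    3.0  0.41 19.45
    9.0  0.32 22.51
   15.0  0.26 23.21
   21.0  0.21 22.60
   27.0  0.20 21.27
   33.0  0.06 20.97
   39.0  0.07 20.97
   45.0 -0.01 19.58
```

The estimator recovers the programmed decline of self-renewal (0.4 → 0.0)
and a cycle length near the true 20 h; the mild upward drift of T in the
fastest-growing windows is the expected age-structure effect (see
`docs/methods.md`). The method comparison (`examples/05_method_benchmark.py`)
shows why this matters: with a time-varying cycle length averaging exactly
20 h, the single cumulative method drifts to 23.5 h (+18%) while pulse-chase
and branching process stay within a few percent:

```
=== variable_T scenario (true mean T = 20.0 h) ===
method  n_runs  n_failed  mean_T  sd_T  rel_err_of_mean
    C1       5         0  23.518 1.185            0.176
    C2       5         0  18.950 2.864            0.053
    PC       5         0  20.001 1.811            0.000
    BP       5         0  21.174 0.595            0.059
```

Each `examples/` script is a self-contained narrative: build a small input,
run one capability, print what the numbers mean. A thin CLI mirrors the
library (`cyclefate simulate|estimate|benchmark|decompose|fixture`).

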