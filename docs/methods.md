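# Methods

This note documents the models, conventions, and numerical choices behind
`neurofit`, and what the test suite does and does not establish.

## Units and containers

Time is in ms, membrane potential in mV, current in nA throughout; unit
conversions happen only at I/O boundaries. A `Trace` is a uniformly sampled
series with sample *i* at `t0 + i·dt`. When a model trace and a target trace
live on different grids, the model is linearly interpolated onto the target
grid restricted to the overlapping interval: the target is the fixed
experimental reference, so every error normalization stays tied to the
target data. Trace files are plain text, one or two whitespace-separated
columns with `#` comments, written at full double precision so a
write/read round trip is bit-exact.

## Spike detection and AP features

A spike is one maximal upward crossing of a detection threshold
(default 0 mV — biophysical action potentials overshoot 0, while
subthreshold fluctuations stay far below). Per spike:

* **AP threshold** — the voltage at the last sample before the peak where
  dV/dt first exceeds 20 mV/ms (a common electrophysiology convention for
  spike onset), falling back to the detection-crossing sample for slow
  upstrokes;
* **amplitude** — peak voltage minus AP threshold voltage;
* **base width** — the time between the two crossings of the AP-threshold
  voltage bracketing the peak, sub-sample interpolated;
* **AHP depth** — AP threshold voltage minus the minimum voltage before the
  next spike's onset (or the end of the trace).

All three conventions (detection threshold, slope criterion, and the ±5 ms
exclusion window used by the spike-excluding cost) are keyword-configurable;
none of them is a physical constant, and different labs use different
values.

## Cost functions

Trace-comparison costs are unitless, non-negative, and exactly zero for
identical traces. Point-by-point errors are normalized by the squared range
of the target (recomputed on the retained samples when spikes are
excluded); spike-timing errors by the trace duration; per-AP shape errors
by a target statistic (maximal amplitude, mean width, subthreshold range).
Design choices worth flagging:

* Per-AP features pair spikes in order up to the shorter count — count
  mismatch is the spike-count component's job, and "corresponding spikes"
  has no unique definition when counts differ.
* A model trace with no spikes scores the maximal penalty 1.0 on per-AP
  components (bounded, so a silent candidate is bad but comparable); an
  undefined model feature scores 250 on the z-score-style
  feature-statistics error (a conventionally huge z value). Both are
  configurable.
* The AHP component is computed as the mean of squared depth differences,
  consistent with the neighboring shape components.
* "Trace length" in timing normalizations means duration in ms, not sample
  count; this only fixes the scale of those components.
* Weights are normalized to sum to one, so the combination is a weighted
  average and rescaling all weights together changes nothing; raw component
  values are reported pre-weighting in every record.

## Benchmark models

**Hodgkin–Huxley.** Single isopotential compartment with the classic squid
Na⁺/K⁺/leak kinetics in the modern voltage convention (E_Na = 50 mV,
E_K = −77 mV, E_L = −54.3 mV, c_m = 1 µF/cm²), area of a 20 µm × 20 µm
cylinder (≈ 1.257e−5 cm²) so the 0.3 nA benchmark step (≈ 23.9 µA/cm²) is
comfortably suprathreshold. The true densities are the canonical
g_Na = 0.12, g_K = 0.036, g_L = 0.0003 S/cm²; bounds are 0.1× to 3× the
truth. Integration: exponential Euler for the gating variables and a
Crank–Nicolson update for V (second order; under dt halving at dt = 0.05 ms
the spike count is unchanged and peak times move < 0.5 ms over a
46-spike train). The initial state is the resting steady state at I = 0,
found per candidate by bisection. The benchmark uses dt = 0.05 ms; the
integrator accepts any dt ≤ 0.05 and is vectorized over whole candidate
populations (numba) because the optimizers evaluate 100 candidates per
generation.

**Voltage clamp.** An ideal clamp at −70 mV records leak plus synaptic
current; each presynaptic event contributes a bi-exponential conductance
g(t) = w·N·(e^(−t/τ_decay) − e^(−t/τ_rise)) scaled by N so the peak equals
the weight w, times the driving force (V_hold − E_syn), with E_syn = 0 mV.
The current is evaluated in closed form (no ODE), so the simulator *is* the
analytic solution; an independent high-accuracy ODE integration agrees to
< 1e-6 relative and the in-package evaluation to < 1e-9. Events at 100,
200, 300, 400 ms (10 Hz) in a 600 ms trace, dt = 0.1 ms. Truth: w = 0.01 µS,
τ_rise = 0.5 ms, τ_decay = 5 ms, delay = 2 ms; bounds span roughly one
order of magnitude around the truth (delay: [0.1, 10] ms). Candidates with
τ_rise ≥ τ_decay are invalid and score the failure sentinel. The constant
holding current is identical for every candidate (the leak is not
optimized), so it cancels in the mean-squared error and its normalization.

**AdEx.** Adaptive exponential integrate-and-fire:
C dV/dt = −g_L(V−E_L) + g_L·Δ_T·e^((V−V_T)/Δ_T) − w + I,
τ_w dw/dt = a(V−E_L) − w; at the cut-off V_T + 5Δ_T a spike is recorded,
V ← V_reset, w ← w + b, and V is clamped for t_ref while w keeps evolving.
The stored trace clips V at the cut-off: an integrate-and-fire model
carries no spike-shape information, so downstream feature extraction uses
the recorded event train, not threshold crossings of the clipped trace.
The truth is a regular-spiking adapting set (C = 200 pF, g_L = 12 nS,
E_L = −70 mV, V_T = −50 mV, V_reset = −58 mV, t_ref = 2 ms, Δ_T = 2 mV,
a = 2 nS, b = 60 pA, τ_w = 300 ms). Protocol: steps of 0.30/0.35/0.40/0.45
nA, 100 ms delay, 900 ms duration, 1100 ms traces sampled at 5 kHz
(0.2 ms), integrated internally at 0.05 ms by forward Euler. The error
(MSE excluding spikes, spike count during stimulus, latency; equal
weights) is averaged over the four protocols with equal protocol weights.
The targets are surrogate AdEx responses — truth recovery, not fit to an
experimental recording, is the measurable contract.

A candidate whose integration produces a non-finite state is reported as a
simulation failure and scored with the sentinel error 1e9 rather than
aborting the run, so a search algorithm can wander through pathological
parameter combinations and keep going.

## Search algorithms

All algorithms minimize over the normalized unit box (affine map to
physical bounds), so length-scale hyperparameters are stated in normalized
units — essential when one benchmark mixes parameters spanning five orders
of magnitude. Bound handling is clipping, except CMA-ES which resamples
out-of-box proposals up to 10 times before clipping. Defaults:

| algorithm | defaults |
| --- | --- |
| random | uniform i.i.d. over the box |
| nelder_mead | coefficients (1, 2, 0.5, 0.5), init step 0.1, restart on simplex collapse |
| ceo | binary tournament, blend crossover α = 0.1, per-gene Gaussian mutation p = 0.25, σ = 0.5, elites = pop/2 |
| cmaes | (µ/µ_w, λ): µ = λ/2, log weights, rank-1 + rank-µ updates, CSA; mean at box center, σ₀ = 0.3 |
| pso | ω = 0.7298, c1 = c2 = 1.49618 (constriction values), v clamped to half the box, generational gbest |
| de | DE/rand/1/bin, F = 0.8, CR = 0.9, greedy one-to-one replacement |
| nsga2 | SBX η = 15, polynomial mutation η = 20 at rate 1/d, crowded binary tournament |

The evolutionary-algorithm defaults (elites = half the population, mutation
rate 0.25, mutation σ 0.5) are the adjusted configuration under which this
class of algorithm optimizes effectively at the 100 × 100 budget; with no
elitism and weak mutation pressure it barely improves on random sampling.
Every run's effective hyperparameters are echoed into its JSON record.

The batch-evaluation contract: an optimizer submits a whole generation
through one entry point and receives results in submission order, with no
shared mutable state between evaluations — an objective is therefore free
to vectorize (as the built-in benchmarks do) or parallelize internally.
Budgets are exact: `pop_size × n_generations` evaluations, no more, no
fewer — unless the caller sets `target_error`, which stops the run at the
end of the first generation whose cumulative minimum reaches the target
(used when the measured quantity is precisely that first-hit time).

Multi-objective runs treat the raw error components as separate objectives;
the weighted sum remains defined for every evaluation and is still used to
pick a single preferred solution from the returned front (earliest
evaluation wins ties).

## Evaluation protocol

The study protocol is 10,000 evaluations per run split 100 × 100, repeated
with 10 distinct seeds. Scores: the final score is the lowest total error
of the run; the convergence score is the sum over generations of log₁₀ of
the cumulative-minimum error. The log base only rescales the score;
cumulative minima are floored at 1e-12 because surrogate benchmarks can
reach exactly zero. The convergence score is computed on the cumulative
minimum (rather than the per-generation best) so it is monotone and
well-defined for non-elitist algorithms; for elitist ones the two coincide.
Rankings use the median of a score across seeds, with tied medians sharing
the mean of the tied ranks; cross-benchmark summaries report median/min/max
rank per algorithm. Box plots use Tukey 1.5×IQR whiskers. The JSON run
record (schema version 1.0) holds parameter names/bounds/best values, the
best candidate's error components (name, raw, weight, weighted), the full
algorithm configuration and seed, and per-generation statistics; a TSV of
the generation statistics is written alongside.

## Problem sizes in the shipped tests

The test suite and the acceptance script keep desk-scale sizes: the
voltage-clamp benchmark runs at its full 10,000-evaluation budget
(closed-form model, milliseconds per generation); Hodgkin–Huxley
convergence runs stop at the error floor (reached near 1,600 evaluations,
median), and the three-algorithm ranking comparison on Hodgkin–Huxley uses
2,000 evaluations per run — at that budget the median final scores of
CMA-ES, PSO, and random search are separated by roughly two orders of
magnitude each, so the ordering is already settled. Classic test functions
(sphere, Rosenbrock) run at the full budget.

## What the surrogate benchmarks do and do not show

Surrogate targets are generated by the very model being fitted, at the same
step size: the global minimum is exactly zero, there is no model mismatch,
no measurement noise, and no experimental variability. Passing these
benchmarks demonstrates that the cost functions are implemented correctly
and that the search algorithms converge and recover parameters in a
realistic landscape geometry — it does not demonstrate that fitting a real
recording would recover "true" biological parameters, a problem that is
ill-posed in general. Absolute error values also depend on the chosen
parameter bounds (documented above and echoed into every run record), so
the comparable quantities across reimplementations are the algorithm
rankings and convergence orders, not raw error magnitudes.

## Known limitations

* Single-compartment models only; no morphologies, no external simulator
  coupling.
* The feature-statistics error ships without an automatic feature-extraction
  pipeline behind it; callers supply the model feature value.
* Nelder–Mead restarts use fresh uniform points, so its results are
  seed-dependent like the global methods.
* The AdEx benchmark's refractory clamp holds V while w evolves; other
  conventions (freezing w, or integrating V sub-threshold) exist and would
  change spike times slightly.
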