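# neurofit

Fitting the parameters of neuron models to electrophysiological data is a
global optimization problem: a candidate parameter vector is simulated, the
resulting voltage or current trace is compared with the target through one
or more cost functions, and a search algorithm proposes the next candidates.
`neurofit` packages the three ingredients of that workflow for desk-scale
experimentation and for benchmarking the search algorithms themselves:

* **Cost functions** for trace comparison — point-by-point (normalized mean
  squared error, with or without spike exclusion, derivative difference) and
  spike-feature based (spike count, count during stimulus, inter-spike-
  interval difference, latency to first spike, AP overshoot, AP base width,
  after-hyperpolarization depth), plus a z-score-style feature-statistics
  error. Components combine into a weighted average
  `E = Σᵢ wᵢ eᵢ / Σᵢ wᵢ`, or serve as separate objectives for
  multi-objective search.
* **Native search algorithms** over a bounded box: uniform random search,
  Nelder–Mead with restarts, a tournament/blend-crossover/Gaussian-mutation
  evolutionary algorithm with strong elitism, CMA-ES, generational particle
  swarm, differential evolution (DE/rand/1/bin), and NSGA-II. All work in
  normalized coordinates, evaluate whole generations as batches, respect an
  exact evaluation budget (default 100 × 100 = 10,000), and are
  bit-reproducible under a seed.
* **Surrogate benchmarks** with known ground truth: recovering the three
  Hodgkin–Huxley conductance densities (g_Na, g_K, g_L) from the response
  to a 0.3 nA step; recovering four synaptic parameters (peak conductance,
  rise/decay time constants, delay) from a voltage-clamp recording of
  bi-exponential synaptic currents evoked at 10 Hz; and recovering the ten
  parameters of an adaptive exponential integrate-and-fire neuron from four
  step responses. Because the target is generated by the same simulator, a
  zero-error solution exists and parameter recovery is measurable.
* **Evaluation protocol**: per-generation statistics, cumulative-minimum
  convergence curves, the *final score* (lowest error of a run), the
  *convergence score* (Σ over generations of log₁₀ of the cumulative
  minimum — the area under the logarithmic convergence curve), median-based
  rank statistics across algorithms and benchmarks, box-plot/convergence
  figures, and a versioned JSON record of every run.

## Worked example

Recover the four synaptic parameters from the voltage-clamp benchmark with
CMA-ES (population 100, 30 generations = 3,000 model evaluations):

```python
from neurofit import benchmark_vclamp, OptimizerConfig, final_score
from neurofit.optim import cmaes

bench = benchmark_vclamp()
run = cmaes(bench.make_problem(),
            OptimizerConfig("cmaes", pop_size=100, n_generations=30, seed=0))
print("best error:", final_score(run))
for name, value in zip(run.param_names, run.best_params):
    print(f"  {name:9s} {value:.6g}")
```

prints

```
best error: 5.147765223333517e-13
  weight    0.00999997
  tau_rise  0.499998
  tau_decay 5
  delay     2
```

The best error is the normalized mean squared difference between the
candidate's clamp current and the target current; 5e-13 means the traces
agree to round-off. The recovered parameters match the hidden truth
(weight 0.01 µS, tau_rise 0.5 ms, tau_decay 5 ms, delay 2 ms) to five
significant figures.

The same study from the shell, with per-run JSON records and figures:

```sh
neurofit-bench run --config study.yaml     # benchmark, algorithms, seeds
neurofit-bench report --scores results/    # score table, rankings, figures
```

## Layout

| module | contents |
| --- | --- |
| `neurofit.traces` | `Trace`, `StepStimulus`, `EventTrain`, text I/O, grid alignment |
| `neurofit.spikes` | spike detection and per-AP shape features |
| `neurofit.errors` | the cost functions and their weighted combination |
| `neurofit.models` | HH, voltage-clamp synapse, and AdEx simulators |
| `neurofit.optim` | the search algorithms and the `Problem` contract |
| `neurofit.benchmarks` | benchmark definitions and the repeated-run protocol |
| `neurofit.reporting` | scores, ranks, JSON records, figures |
| `neurofit.cli` | `neurofit-bench` entry points |

See `docs/methods.md` for the models, conventions, and numerical choices.
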