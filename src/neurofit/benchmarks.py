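"""The three surrogate-data benchmark problems and the repeated-run protocol.

Each benchmark bundles a model, a stimulation protocol, a box of parameter
bounds, the hidden "true" parameter vector used to generate the target
data, and the composite error specification. Because the target is produced
by the same simulator at the same step size, the objective at the truth is
zero up to round-off, the global minimum is known, and parameter recovery
is measurable.

The parameter bounds are this package's documented choices (order-of-
magnitude boxes around the truth): quantitative error values are internal
to these boxes, and the bounds are echoed into every run's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import models
from .errors import ErrorComponentSpec, ErrorVector, evaluate_error_vector
from .optim import (
    FAILURE_SENTINEL,
    MULTI_OBJECTIVE,
    OptimizerConfig,
    ParameterSpace,
    Problem,
    run_optimizer,
)
from .reporting import RunResult, read_metadata, run_from_metadata, write_metadata
from .spikes import analysis_from_events, detect_spikes
from .traces import EventTrain, StepStimulus, Trace

__all__ = [
    "BenchmarkDefinition",
    "StudyProtocol",
    "benchmark_hh",
    "benchmark_vclamp",
    "benchmark_adex",
    "get_benchmark",
    "run_study",
    "BENCHMARKS",
]


@dataclass(frozen=True)
class BenchmarkDefinition:
    id: str
    space: ParameterSpace
    true_params: np.ndarray
    protocol: object
    error_spec: tuple[ErrorComponentSpec, ...]
    n_objectives: int
    objective: object = field(repr=False)  # callable (n, d) -> list[ErrorVector]
    targets: tuple = field(repr=False, default=())

    def make_problem(self) -> Problem:
        return Problem(self.space, self.objective, n_objectives=self.n_objectives)

    def evaluate_at(self, params: np.ndarray) -> ErrorVector:
        return self.objective(np.asarray(params, dtype=float)[None, :])[0]


@dataclass(frozen=True)
class StudyProtocol:
    """The repeated-run evaluation protocol: 100 x 100 split of a 10,000-
    evaluation budget, repeated with 10 distinct seeds."""

    budget: int = 10000
    pop_size: int = 100
    n_generations: int = 100
    n_repeats: int = 10
    seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.pop_size * self.n_generations != self.budget:
            raise ValueError(
                f"pop_size * n_generations must equal the budget: "
                f"{self.pop_size} * {self.n_generations} != {self.budget}"
            )
        seeds = self.seeds if self.seeds is not None else tuple(range(self.n_repeats))
        object.__setattr__(self, "seeds", tuple(int(s) for s in seeds))
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need exactly n_repeats seeds")


def _sentinel_vector(spec: tuple[ErrorComponentSpec, ...]) -> ErrorVector:
    wsum = sum(c.weight for c in spec)
    comps = tuple(
        (c.name, FAILURE_SENTINEL, c.weight / wsum, FAILURE_SENTINEL * c.weight / wsum)
        for c in spec
    )
    return ErrorVector(components=comps, total=FAILURE_SENTINEL)


# ---------------------------------------------------------------------------
# Use case: Hodgkin-Huxley conductance densities


def benchmark_hh(dt: float = 0.05) -> BenchmarkDefinition:
    """Recover the three HH conductance densities from a step response.

    Stimulus: 0.3 nA, delay 200 ms, duration 500 ms, 1000 ms trace. Error:
    spike count, AP overshoot, AP width, and MSE excluding spikes, with
    uniform weights (4 objectives in multi-objective mode). Bounds: 0.1x to
    3x the canonical truth densities.
    """
    truth = np.array([models.HH_TRUE.gna, models.HH_TRUE.gk, models.HH_TRUE.gl])
    space = ParameterSpace(
        names=("gna", "gk", "gl"), lower=0.1 * truth, upper=3.0 * truth
    )
    stim = StepStimulus(amplitude=0.3, delay=200.0, duration=500.0, total_duration=1000.0)
    spec = tuple(
        ErrorComponentSpec(name, 1.0)
        for name in ("spike_count", "ap_overshoot", "ap_width", "mse_excl_spikes")
    )
    target = models.simulate_hh(models.HH_TRUE, stim, dt=dt)
    target_analysis = detect_spikes(target)

    def objective(X: np.ndarray) -> list[ErrorVector]:
        v, ok = models.simulate_hh_batch(X, stim, dt=dt)
        out = []
        for i in range(X.shape[0]):
            if not ok[i]:
                out.append(_sentinel_vector(spec))
                continue
            trace = Trace(values=v[i], dt=dt, unit="mV", stimulus=stim)
            out.append(
                evaluate_error_vector(
                    trace, target, list(spec), stimulus=stim,
                    target_analysis=target_analysis,
                )
            )
        return out

    return BenchmarkDefinition(
        id="hh",
        space=space,
        true_params=truth,
        protocol=stim,
        error_spec=spec,
        n_objectives=4,
        objective=objective,
        targets=(target,),
    )


# ---------------------------------------------------------------------------
# Use case: voltage-clamped synaptic parameters


def benchmark_vclamp(dt: float = 0.1) -> BenchmarkDefinition:
    """Recover four synaptic parameters from a clamp current trace.

    Four presynaptic events at 10 Hz (100/200/300/400 ms) in a 600 ms
    recording; mean-squared-error objective on the current trace (single-
    objective only). Truth: weight 0.01 uS, tau_rise 0.5 ms, tau_decay 5 ms,
    delay 2 ms; bounds span one order of magnitude around the truth (delay
    bounds [0.1, 10] ms).
    """
    truth = np.array([0.01, 0.5, 5.0, 2.0])
    space = ParameterSpace(
        names=("weight", "tau_rise", "tau_decay", "delay"),
        lower=np.array([0.003, 0.15, 1.5, 0.1]),
        upper=np.array([0.03, 1.5, 15.0, 10.0]),
    )
    events = EventTrain(times=np.array([100.0, 200.0, 300.0, 400.0]))
    duration = 600.0
    spec = (ErrorComponentSpec("mse", 1.0),)
    target = models.simulate_vclamp(models.VCLAMP_TRUE, events, duration, dt=dt)

    def objective(X: np.ndarray) -> list[ErrorVector]:
        cur, ok = models.simulate_vclamp_batch(X, events.times, duration, dt=dt)
        out = []
        for i in range(X.shape[0]):
            if not ok[i]:
                out.append(_sentinel_vector(spec))
                continue
            trace = Trace(values=cur[i], dt=dt, unit="nA")
            out.append(evaluate_error_vector(trace, target, list(spec)))
        return out

    return BenchmarkDefinition(
        id="vclamp",
        space=space,
        true_params=truth,
        protocol=events,
        error_spec=spec,
        n_objectives=1,
        objective=objective,
        targets=(target,),
    )


# ---------------------------------------------------------------------------
# Use case: AdEx spiking model (surrogate targets)


def benchmark_adex(dt: float = 0.2) -> BenchmarkDefinition:
    """Recover ten AdEx parameters from four step responses.

    Steps of 0.30/0.35/0.40/0.45 nA, delay 100 ms, duration 900 ms, 1100 ms
    traces sampled at 5 kHz (0.2 ms). Error components (equal weights,
    averaged over the four protocols): MSE excluding spikes, spike count
    during the stimulus, and latency to first spike. Spike times come from
    the simulator's event train, not from threshold crossings of the
    clipped trace. The targets here are surrogate AdEx responses, so truth
    recovery replaces fit-to-experiment.
    """
    p = models.ADEX_TRUE
    truth = np.array(
        [p.C, p.g_L, p.E_L, p.V_T, p.V_reset, p.t_ref, p.Delta_T, p.a, p.b, p.tau_w]
    )
    space = ParameterSpace(
        names=("C", "g_L", "E_L", "V_T", "V_reset", "t_ref", "Delta_T", "a", "b", "tau_w"),
        lower=np.array([50.0, 2.0, -85.0, -60.0, -70.0, 0.0, 0.5, 0.0, 0.0, 30.0]),
        upper=np.array([500.0, 40.0, -55.0, -40.0, -45.0, 8.0, 6.0, 10.0, 200.0, 600.0]),
    )
    stims = [StepStimulus(a, 100.0, 900.0, 1100.0) for a in (0.30, 0.35, 0.40, 0.45)]
    spec = tuple(
        ErrorComponentSpec(name, 1.0)
        for name in ("mse_excl_spikes", "spike_count_during_stimulus", "latency")
    )
    targets = [models.simulate_adex(p, s, dt=dt) for s in stims]
    target_analyses = [analysis_from_events(ev) for _, ev in targets]

    def objective(X: np.ndarray) -> list[ErrorVector]:
        X = np.asarray(X, dtype=float).reshape(-1, 10)
        n = X.shape[0]
        raw = np.zeros((n, len(spec)))
        failed = np.zeros(n, dtype=bool)
        for (t_trace, _), t_analysis, stim in zip(targets, target_analyses, stims):
            v, trains, ok = models.simulate_adex_batch(X, stim, dt=dt)
            for i in range(n):
                if failed[i]:
                    continue
                if not ok[i]:
                    failed[i] = True
                    continue
                trace = Trace(values=v[i], dt=dt, unit="mV", stimulus=stim)
                m_analysis = analysis_from_events(EventTrain(times=trains[i]))
                ev = evaluate_error_vector(
                    trace,
                    t_trace,
                    list(spec),
                    stimulus=stim,
                    model_analysis=m_analysis,
                    target_analysis=t_analysis,
                )
                raw[i] += ev.raw
        raw /= len(stims)
        out = []
        w = 1.0 / len(spec)
        for i in range(n):
            if failed[i]:
                out.append(_sentinel_vector(spec))
            else:
                comps = tuple(
                    (c.name, float(r), w, float(r) * w) for c, r in zip(spec, raw[i])
                )
                out.append(ErrorVector(components=comps, total=float(raw[i].mean())))
        return out

    return BenchmarkDefinition(
        id="adex",
        space=space,
        true_params=truth,
        protocol=tuple(stims),
        error_spec=spec,
        n_objectives=3,
        objective=objective,
        targets=tuple(targets),
    )


BENCHMARKS = {"hh": benchmark_hh, "vclamp": benchmark_vclamp, "adex": benchmark_adex}


def get_benchmark(benchmark_id: str, **kwargs) -> BenchmarkDefinition:
    try:
        factory = BENCHMARKS[benchmark_id]
    except KeyError:
        raise ValueError(
            f"unknown benchmark {benchmark_id!r}; known: {sorted(BENCHMARKS)}"
        ) from None
    return factory(**kwargs)


# ---------------------------------------------------------------------------


def run_study(
    benchmark: BenchmarkDefinition,
    algorithm: str,
    protocol: StudyProtocol | None = None,
    hyperparams: dict | None = None,
    out_dir: str | Path | None = None,
) -> list[RunResult]:
    """Run `n_repeats` seeded optimizations of one algorithm on one benchmark.

    If ``out_dir`` is given, each run's JSON metadata is written as soon as
    the run finishes (named by benchmark/algorithm/seed), and runs whose
    record already exists are not repeated — an interrupted study resumes
    per-run.
    """
    protocol = protocol or StudyProtocol()
    if algorithm in MULTI_OBJECTIVE and benchmark.n_objectives < 2:
        raise ValueError(
            f"{algorithm} is multi-objective but benchmark {benchmark.id!r} "
            f"defines a single objective"
        )
    results: list[RunResult] = []
    for seed in protocol.seeds:
        path = None
        if out_dir is not None:
            path = Path(out_dir) / f"{benchmark.id}_{algorithm}_seed{seed}.json"
            if path.exists():
                results.append(run_from_metadata(read_metadata(path)))
                continue
        config = OptimizerConfig(
            algorithm=algorithm,
            pop_size=protocol.pop_size,
            n_generations=protocol.n_generations,
            seed=seed,
            hyperparams={"benchmark_id": benchmark.id, **(hyperparams or {})},
        )
        run = run_optimizer(benchmark.make_problem(), config)
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            write_metadata(run, path)
        results.append(run)
    return results
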