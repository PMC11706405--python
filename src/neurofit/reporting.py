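"""Run records, convergence curves, performance scores, and rank statistics.

A completed optimization run is summarized by a :class:`RunResult`: the full
evaluation history partitioned into generations, per-generation statistics
(best, median, cumulative minimum of the weighted total error), and the best
candidate found. Two scalar scores compare algorithms:

* final score — the lowest total error achieved during the run;
* convergence score — the sum over generations of log10 of the cumulative
  minimum error (the area under the logarithmic convergence curve); lower
  means faster convergence. Errors are floored at 1e-12 before the log so
  surrogate benchmarks that reach an exactly-zero fit stay finite.

Algorithms are ranked per benchmark by the median of a score across seeded
repeats (ties share the mean of the tied ranks), and summarized across
benchmarks by the median/min/max of those ranks. Every run can be serialized
to a versioned, machine-readable JSON record.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ErrorVector

__all__ = [
    "GenerationStats",
    "RunResult",
    "build_run_result",
    "cumulative_min_curve",
    "final_score",
    "convergence_score",
    "first_generation_below",
    "first_evaluation_below",
    "make_score_table",
    "rank_algorithms",
    "overall_rank_stats",
    "write_metadata",
    "read_metadata",
    "run_from_metadata",
    "plot_report",
    "CONVERGENCE_FLOOR",
    "SCHEMA_VERSION",
]

CONVERGENCE_FLOOR = 1e-12
SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class GenerationStats:
    index: int
    best: float
    median: float
    cummin: float


@dataclass
class RunResult:
    """Everything recorded about one optimization run."""

    benchmark_id: str
    algorithm: str
    seed: int
    param_names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    hyperparams: dict
    pop_size: int
    eval_log: list[tuple[np.ndarray, ErrorVector]]
    generations: list[GenerationStats]
    best_params: np.ndarray
    best_errors: ErrorVector
    started: float = field(default_factory=time.time)
    finished: float = field(default_factory=time.time)
    final_population: list | None = None  # Candidates; set by population methods
                                          # that return a front approximation

    @property
    def n_evals(self) -> int:
        return len(self.eval_log)

    @property
    def n_generations(self) -> int:
        return len(self.generations)


def build_run_result(
    benchmark_id: str,
    algorithm: str,
    seed: int,
    space,
    hyperparams: dict,
    pop_size: int,
    eval_log: list[tuple[np.ndarray, ErrorVector]],
    started: float,
    final_population: list | None = None,
) -> RunResult:
    """Partition an evaluation log into generations and compute run statistics."""
    if not eval_log:
        raise ValueError("empty evaluation history")
    totals = np.array([ev.total for _, ev in eval_log])
    gens: list[GenerationStats] = []
    cummin = np.inf
    for g in range(0, len(eval_log), pop_size):
        chunk = totals[g : g + pop_size]
        cummin = min(cummin, float(np.min(chunk)))
        gens.append(
            GenerationStats(
                index=g // pop_size,
                best=float(np.min(chunk)),
                median=float(np.median(chunk)),
                cummin=cummin,
            )
        )
    best_idx = int(np.argmin(totals))
    return RunResult(
        benchmark_id=benchmark_id,
        algorithm=algorithm,
        seed=seed,
        param_names=tuple(space.names),
        lower=np.asarray(space.lower, dtype=float),
        upper=np.asarray(space.upper, dtype=float),
        hyperparams=dict(hyperparams),
        pop_size=pop_size,
        eval_log=eval_log,
        generations=gens,
        best_params=eval_log[best_idx][0],
        best_errors=eval_log[best_idx][1],
        started=started,
        finished=time.time(),
        final_population=final_population,
    )


def run_from_metadata(doc: dict) -> RunResult:
    """Rebuild a run record from its JSON document.

    The full evaluation log is not serialized; the reconstructed run carries
    only the best candidate, which is enough for scores, curves, ranks and
    plots.
    """
    best_errors = ErrorVector(
        components=tuple(
            (c["name"], c["value"], c["weight"], c["weighted_value"])
            for c in doc["error_components"]
        ),
        total=sum(c["weighted_value"] for c in doc["error_components"]),
    )
    best_params = np.array([p["best"] for p in doc["parameters"]])
    return RunResult(
        benchmark_id=doc["benchmark"],
        algorithm=doc["algorithm"],
        seed=doc["seed"],
        param_names=tuple(p["name"] for p in doc["parameters"]),
        lower=np.array([p["lower"] for p in doc["parameters"]]),
        upper=np.array([p["upper"] for p in doc["parameters"]]),
        hyperparams=doc["hyperparameters"],
        pop_size=doc["population_size"],
        eval_log=[(best_params, best_errors)],
        generations=[
            GenerationStats(
                index=g["index"],
                best=g["best"],
                median=g["median"],
                cummin=g["cumulative_minimum"],
            )
            for g in doc["generations"]
        ],
        best_params=best_params,
        best_errors=best_errors,
        started=doc["started"],
        finished=doc["finished"],
    )


def cumulative_min_curve(run: RunResult) -> np.ndarray:
    """Cumulative minimum of the total error after each generation."""
    return np.array([g.cummin for g in run.generations])


def final_score(run: RunResult) -> float:
    """Lowest total error achieved during the entire run."""
    return float(run.generations[-1].cummin)


def convergence_score(run: RunResult, floor: float = CONVERGENCE_FLOOR) -> float:
    """Sum over generations of log10(cumulative minimum), floored at `floor`."""
    curve = np.maximum(cumulative_min_curve(run), floor)
    return float(np.sum(np.log10(curve)))


def first_generation_below(run: RunResult, threshold: float) -> int | None:
    """Index of the first generation whose cumulative minimum is <= threshold."""
    for g in run.generations:
        if g.cummin <= threshold:
            return g.index
    return None


def first_evaluation_below(run: RunResult, threshold: float) -> int | None:
    """1-based evaluation count at which the running best first reaches threshold."""
    for i, (_, ev) in enumerate(run.eval_log):
        if ev.total <= threshold:
            return i + 1
    return None


def make_score_table(runs: list[RunResult]) -> pd.DataFrame:
    """One row per run: (benchmark, algorithm, seed, final_score, convergence_score)."""
    rows = [
        {
            "benchmark": r.benchmark_id,
            "algorithm": r.algorithm,
            "seed": r.seed,
            "final_score": final_score(r),
            "convergence_score": convergence_score(r),
        }
        for r in runs
    ]
    return pd.DataFrame(rows)


def rank_algorithms(
    scores: pd.DataFrame, benchmark: str, metric: str = "final_score"
) -> pd.Series:
    """Rank algorithms on one benchmark by the median of `metric` across seeds.

    Rank 1 is best (lowest median); tied medians share the mean of the tied
    ranks.
    """
    sub = scores[scores["benchmark"] == benchmark]
    if sub["algorithm"].nunique() < 2:
        raise ValueError(f"need >= 2 algorithms with runs on {benchmark!r}")
    medians = sub.groupby("algorithm")[metric].median()
    ranks = rankdata(medians.values, method="average")
    return pd.Series(ranks, index=medians.index, name="rank").sort_values()


def overall_rank_stats(
    scores: pd.DataFrame, benchmarks: list[str], metric: str = "final_score"
) -> pd.DataFrame:
    """Per-algorithm median/min/max of per-benchmark ranks."""
    algos = sorted(scores["algorithm"].unique())
    per_bench = {}
    for b in benchmarks:
        have = set(scores.loc[scores["benchmark"] == b, "algorithm"])
        missing = [a for a in algos if a not in have]
        if missing:
            raise ValueError(f"no runs for {missing} on benchmark {b!r}")
        per_bench[b] = rank_algorithms(scores, b, metric)
    table = pd.DataFrame(per_bench)
    return pd.DataFrame(
        {
            "median_rank": table.median(axis=1),
            "min_rank": table.min(axis=1),
            "max_rank": table.max(axis=1),
        }
    ).sort_values("median_rank")


def run_to_dict(run: RunResult) -> dict:
    """The versioned machine-readable record of a run (no full eval log)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "artifact": "neurofit",
        "benchmark": run.benchmark_id,
        "algorithm": run.algorithm,
        "seed": run.seed,
        "hyperparameters": run.hyperparams,
        "population_size": run.pop_size,
        "n_evaluations": run.n_evals,
        "parameters": [
            {
                "name": n,
                "lower": float(lo),
                "upper": float(hi),
                "best": float(v),
            }
            for n, lo, hi, v in zip(
                run.param_names, run.lower, run.upper, run.best_params
            )
        ],
        "error_components": [
            {"name": n, "value": raw, "weight": w, "weighted_value": wv}
            for n, raw, w, wv in run.best_errors.components
        ],
        "final_score": final_score(run),
        "convergence_score": convergence_score(run),
        "generations": [
            {
                "index": g.index,
                "best": g.best,
                "median": g.median,
                "cumulative_minimum": g.cummin,
            }
            for g in run.generations
        ],
        "started": run.started,
        "finished": run.finished,
    }


def write_metadata(run: RunResult, path: str | Path) -> dict:
    """Write the JSON run record; returns the document that was written."""
    doc = run_to_dict(run)
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    # per-generation statistics also as TSV next to the JSON
    tsv = path.with_suffix(".tsv")
    pd.DataFrame(doc["generations"]).to_csv(tsv, sep="\t", index=False)
    return doc


def read_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def plot_report(
    scores: pd.DataFrame, runs: list[RunResult], outdir: str | Path
) -> list[Path]:
    """Write convergence-curve and score box-plot figures for a study.

    Convergence curves show the median cumulative-minimum error across seeds
    per algorithm; box plots show the distribution of final and convergence
    scores (Tukey 1.5*IQR whiskers), sorted by median.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for benchmark in sorted({r.benchmark_id for r in runs}):
        bruns = [r for r in runs if r.benchmark_id == benchmark]
        algos = sorted({r.algorithm for r in bruns})

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for algo in algos:
            curves = [cumulative_min_curve(r) for r in bruns if r.algorithm == algo]
            n = min(c.size for c in curves)
            median = np.median(np.vstack([c[:n] for c in curves]), axis=0)
            evals = (np.arange(n) + 1) * bruns[0].pop_size
            ax.plot(evals, np.maximum(median, CONVERGENCE_FLOOR), label=algo)
        ax.set_yscale("log")
        ax.set_xlabel("model evaluations")
        ax.set_ylabel("cumulative minimum error (median of runs)")
        ax.set_title(benchmark)
        ax.legend()
        p = outdir / f"{benchmark}_convergence.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

        sub = scores[scores["benchmark"] == benchmark]
        for metric in ("final_score", "convergence_score"):
            order = sub.groupby("algorithm")[metric].median().sort_values().index
            data = [sub.loc[sub["algorithm"] == a, metric].values for a in order]
            fig, ax = plt.subplots(figsize=(7, 4.5))
            ax.boxplot(data, tick_labels=list(order), whis=1.5)
            if metric == "final_score" and all(np.all(d > 0) for d in data):
                ax.set_yscale("log")
            ax.set_ylabel(metric.replace("_", " "))
            ax.set_title(benchmark)
            plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
            fig.tight_layout()
            p = outdir / f"{benchmark}_{metric}.svg"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
    return written
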