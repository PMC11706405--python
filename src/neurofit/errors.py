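"""Trace- and feature-based cost functions and their weighted combination.

Each trace-comparison function takes a model trace and a target trace,
aligns the model onto the target's time grid, and returns a unitless
non-negative scalar that is exactly zero when the traces agree. The
normalizations follow the conventions of feature-based neuronal model
fitting: point-by-point errors are normalized by the (squared) range of the
target data, spike-timing errors by the trace duration, and per-AP shape
errors by the corresponding target statistic, so that components with very
different physical units can be combined into a single weighted score.

Components that compare per-AP shape features pair spikes in order up to
the shorter spike count; mismatched counts are the job of the spike-count
component. A model trace with no spikes at all scores the configurable
maximal penalty (1.0) on per-AP components, and a model feature that is
undefined scores a large z-score-like penalty (250) on the
feature-statistics error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .spikes import (
    DEFAULT_DETECT_THRESHOLD,
    DEFAULT_EXCLUSION_HALF_WIDTH,
    DEFAULT_SLOPE_CRITERION,
    SpikeAnalysis,
    detect_spikes,
    isi_sequence,
    latency_to_first_spike,
    merge_windows,
)
from .traces import StepStimulus, Trace, align_traces

__all__ = [
    "ErrorComponentSpec",
    "FeatureTarget",
    "ErrorVector",
    "DegenerateTargetError",
    "NotApplicableError",
    "mse",
    "mse_excl_spikes",
    "derivative_difference",
    "spike_count_error",
    "spike_count_during_stimulus",
    "isi_difference",
    "latency_error",
    "ap_overshoot_error",
    "ap_width_error",
    "ahp_depth_error",
    "feature_stat_error",
    "evaluate_error_vector",
    "COMPONENT_NAMES",
    "SILENT_MODEL_PENALTY",
    "FEATURE_PENALTY",
]

SILENT_MODEL_PENALTY = 1.0
FEATURE_PENALTY = 250.0


class DegenerateTargetError(ValueError):
    """Target has zero range where a range-based normalization is needed."""


class NotApplicableError(ValueError):
    """Component undefined for the supplied target (e.g. spike-free target)."""


@dataclass(frozen=True)
class ErrorComponentSpec:
    """One named component of a composite objective."""

    name: str
    weight: float = 1.0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")
        if self.name not in COMPONENT_NAMES:
            raise ValueError(
                f"unknown error component {self.name!r}; known: {sorted(COMPONENT_NAMES)}"
            )


@dataclass(frozen=True)
class FeatureTarget:
    """Experimental mean/std target for a named feature (z-score error)."""

    feature_name: str
    exp_mean: float
    exp_std: float
    stimulus_amplitude: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.exp_std <= 0:
            raise ValueError(f"exp_std must be > 0, got {self.exp_std}")


@dataclass(frozen=True)
class ErrorVector:
    """Raw, weighted, and combined error values of one candidate evaluation."""

    components: tuple[tuple[str, float, float, float], ...]  # (name, raw, weight, weighted)
    total: float

    @property
    def raw(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.components)


def _range(x: np.ndarray) -> float:
    return float(np.max(x) - np.min(x))


def mse(model: Trace, target: Trace, **_: object) -> float:
    """Mean squared point-by-point difference / squared range of the target."""
    m, t = align_traces(model, target)
    rng = _range(t)
    if rng == 0:
        raise DegenerateTargetError("constant target trace has zero range")
    return float(np.mean((m - t) ** 2) / rng**2)


def _excluded_mask(times: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for lo, hi in windows:
        mask |= (times >= lo) & (times <= hi)
    return mask


def mse_excl_spikes(
    model: Trace,
    target: Trace,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
    **opts: object,
) -> float:
    """MSE restricted to samples outside the AP vicinity of either trace.

    The exclusion windows of the two traces are unioned; the normalization
    range is recomputed on the retained target samples.
    """
    ma = model_analysis if model_analysis is not None else _detect(model, opts)
    ta = target_analysis if target_analysis is not None else _detect(target, opts)
    m, t = align_traces(model, target)
    times = target.times[-t.size :] if t.size != len(target) else target.times
    windows = merge_windows(list(ma.exclusion_windows) + list(ta.exclusion_windows))
    keep = ~_excluded_mask(times, windows)
    if not keep.any():
        raise NotApplicableError("all samples fall inside exclusion windows")
    m, t = m[keep], t[keep]
    rng = _range(t)
    if rng == 0:
        raise DegenerateTargetError("retained target samples have zero range")
    return float(np.mean((m - t) ** 2) / rng**2)


def derivative_difference(model: Trace, target: Trace, **_: object) -> float:
    """MSE of finite-difference temporal derivatives / squared target-derivative range."""
    m, t = align_traces(model, target)
    if t.size < 3:
        raise ValueError("derivative difference needs at least 3 aligned samples")
    dm = np.diff(m) / target.dt
    dt_ = np.diff(t) / target.dt
    rng = _range(dt_)
    if rng == 0:
        raise DegenerateTargetError("target derivative has zero range")
    return float(np.mean((dm - dt_) ** 2) / rng**2)


def spike_count_error(
    model: Trace,
    target: Trace,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
    **opts: object,
) -> float:
    """|n_model - n_target| / (n_model + n_target); 0 when both are silent."""
    nm = (model_analysis if model_analysis is not None else _detect(model, opts)).count
    nt = (target_analysis if target_analysis is not None else _detect(target, opts)).count
    if nm + nt == 0:
        return 0.0
    return abs(nm - nt) / (nm + nt)


def spike_count_during_stimulus(
    model: Trace,
    target: Trace,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
    stimulus: StepStimulus | None = None,
    **opts: object,
) -> float:
    """Spike-count error restricted to peaks inside the stimulus window."""
    stim = stimulus or target.stimulus or model.stimulus
    if stim is None:
        raise ValueError("spike_count_during_stimulus needs a stimulus definition")
    ma = model_analysis if model_analysis is not None else _detect(model, opts)
    ta = target_analysis if target_analysis is not None else _detect(target, opts)

    def in_window(a: SpikeAnalysis) -> int:
        pk = a.peak_times
        return int(np.sum((pk >= stim.delay) & (pk <= stim.end)))

    nm, nt = in_window(ma), in_window(ta)
    if nm + nt == 0:
        return 0.0
    return abs(nm - nt) / (nm + nt)


def isi_difference(
    model: Trace,
    target: Trace,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
    **opts: object,
) -> float:
    """Sum of |ISI differences| (unpaired ISIs count whole) / trace duration."""
    ma = model_analysis if model_analysis is not None else _detect(model, opts)
    ta = target_analysis if target_analysis is not None else _detect(target, opts)
    mi, ti = isi_sequence(ma), isi_sequence(ta)
    n = min(mi.size, ti.size)
    total = float(np.sum(np.abs(mi[:n] - ti[:n])))
    total += float(np.sum(mi[n:])) + float(np.sum(ti[n:]))
    return total / target.duration


def latency_error(
    model: Trace,
    target: Trace,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
    stimulus: StepStimulus | None = None,
    **opts: object,
) -> float:
    """Squared latency-to-first-spike difference / squared trace duration."""
    stim = stimulus or target.stimulus or model.stimulus
    if stim is None:
        raise ValueError("latency_error needs a stimulus definition")
    ma = model_analysis if model_analysis is not None else _detect(model, opts)
    ta = target_analysis if target_analysis is not None else _detect(target, opts)
    lm = latency_to_first_spike(ma, stim)
    lt = latency_to_first_spike(ta, stim)
    return (lm - lt) ** 2 / target.duration**2


def _paired_shape_error(
    ma: SpikeAnalysis,
    ta: SpikeAnalysis,
    attr: Callable,
    norm: float,
    penalty: float,
) -> float:
    if ta.count == 0:
        raise NotApplicableError("target trace has no spikes")
    if ma.count == 0:
        return penalty
    n = min(ma.count, ta.count)
    mv = np.array([attr(s) for s in ma.spikes[:n]])
    tv = np.array([attr(s) for s in ta.spikes[:n]])
    return float(np.mean((mv - tv) ** 2) / norm**2)


def ap_overshoot_error(
    model: Trace,
    target: Trace,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
    penalty: float = SILENT_MODEL_PENALTY,
    **opts: object,
) -> float:
    """MSE of ordered-paired AP amplitudes / squared maximal target amplitude."""
    ma = model_analysis if model_analysis is not None else _detect(model, opts)
    ta = target_analysis if target_analysis is not None else _detect(target, opts)
    if ta.count == 0:
        raise NotApplicableError("target trace has no spikes")
    norm = max(s.amplitude for s in ta.spikes)
    if norm == 0:
        raise DegenerateTargetError("target AP amplitudes are all zero")
    return _paired_shape_error(ma, ta, lambda s: s.amplitude, norm, penalty)


def ap_width_error(
    model: Trace,
    target: Trace,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
    penalty: float = SILENT_MODEL_PENALTY,
    **opts: object,
) -> float:
    """MSE of ordered-paired AP base widths / squared mean target width."""
    ma = model_analysis if model_analysis is not None else _detect(model, opts)
    ta = target_analysis if target_analysis is not None else _detect(target, opts)
    if ta.count == 0:
        raise NotApplicableError("target trace has no spikes")
    norm = float(np.mean([s.base_width for s in ta.spikes]))
    if norm == 0:
        raise DegenerateTargetError("target AP widths are all zero")
    return _paired_shape_error(ma, ta, lambda s: s.base_width, norm, penalty)


def ahp_depth_error(
    model: Trace,
    target: Trace,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
    penalty: float = SILENT_MODEL_PENALTY,
    **opts: object,
) -> float:
    """MSE of ordered-paired AHP depths / squared subthreshold target range.

    The normalization range is taken over the target samples outside the
    spike exclusion windows (the subthreshold portion of the trace).
    """
    ma = model_analysis if model_analysis is not None else _detect(model, opts)
    ta = target_analysis if target_analysis is not None else _detect(target, opts)
    if ta.count == 0:
        raise NotApplicableError("target trace has no spikes")
    keep = ~_excluded_mask(target.times, ta.exclusion_windows)
    if not keep.any():
        raise DegenerateTargetError("no subthreshold samples in target")
    rng = _range(target.values[keep])
    if rng == 0:
        raise DegenerateTargetError("subthreshold target range is zero")
    return _paired_shape_error(ma, ta, lambda s: s.ahp_depth, rng, penalty)


def feature_stat_error(
    value: float | None, target: FeatureTarget, penalty: float = FEATURE_PENALTY
) -> float:
    """|value - exp_mean| / exp_std; undefined model feature scores `penalty`."""
    if value is None or not np.isfinite(value):
        return penalty
    return abs(value - target.exp_mean) / target.exp_std


_TRACE_COMPONENTS: dict[str, Callable] = {
    "mse": mse,
    "mse_excl_spikes": mse_excl_spikes,
    "derivative_difference": derivative_difference,
    "spike_count": spike_count_error,
    "spike_count_during_stimulus": spike_count_during_stimulus,
    "isi_difference": isi_difference,
    "latency": latency_error,
    "ap_overshoot": ap_overshoot_error,
    "ap_width": ap_width_error,
    "ahp_depth": ahp_depth_error,
}

COMPONENT_NAMES = frozenset(_TRACE_COMPONENTS) | {"feature_stat"}

_NEEDS_SPIKES = frozenset(
    [
        "mse_excl_spikes",
        "spike_count",
        "spike_count_during_stimulus",
        "isi_difference",
        "latency",
        "ap_overshoot",
        "ap_width",
        "ahp_depth",
    ]
)


def _detect(trace: Trace, opts: dict) -> SpikeAnalysis:
    return detect_spikes(
        trace,
        detect_threshold=float(opts.get("detect_threshold", DEFAULT_DETECT_THRESHOLD)),
        slope_criterion=float(opts.get("slope_criterion", DEFAULT_SLOPE_CRITERION)),
        exclusion_half_width=float(
            opts.get("exclusion_half_width", DEFAULT_EXCLUSION_HALF_WIDTH)
        ),
    )


def evaluate_error_vector(
    model: Trace,
    target: Trace,
    spec: list[ErrorComponentSpec],
    stimulus: StepStimulus | None = None,
    model_analysis: SpikeAnalysis | None = None,
    target_analysis: SpikeAnalysis | None = None,
) -> ErrorVector:
    """Evaluate the named components and combine them into a weighted total.

    Weights are normalized to sum to one (the combination is a weighted
    average), so rescaling all weights by a common positive factor leaves
    the total unchanged; raw component values are reported pre-weighting.
    Spike detection runs once per trace and is shared across components.
    """
    if not spec:
        raise ValueError("empty error specification")
    wsum = sum(c.weight for c in spec)
    if wsum <= 0:
        raise ValueError("component weights sum to zero")

    needs_spikes = any(c.name in _NEEDS_SPIKES for c in spec)
    if needs_spikes:
        opts = spec[0].options
        if model_analysis is None:
            model_analysis = _detect(model, opts)
        if target_analysis is None:
            target_analysis = _detect(target, opts)

    components = []
    total = 0.0
    for comp in spec:
        fn = _TRACE_COMPONENTS.get(comp.name)
        if fn is None:
            raise ValueError(
                "feature_stat components are evaluated via feature_stat_error, "
                "not through trace comparison"
            )
        kwargs = dict(comp.options)
        if comp.name in _NEEDS_SPIKES:
            kwargs["model_analysis"] = model_analysis
            kwargs["target_analysis"] = target_analysis
        if comp.name in ("spike_count_during_stimulus", "latency"):
            kwargs.setdefault("stimulus", stimulus)
        try:
            raw = float(fn(model, target, **kwargs))
        except (DegenerateTargetError, NotApplicableError, ValueError) as exc:
            raise type(exc)(f"component {comp.name!r}: {exc}") from exc
        w = comp.weight / wsum
        weighted = raw * w
        total += weighted
        components.append((comp.name, raw, w, weighted))
    return ErrorVector(components=tuple(components), total=total)
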