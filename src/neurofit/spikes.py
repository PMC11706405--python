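"""Spike detection and per-action-potential shape features.

A spike is a maximal upward excursion of the voltage above a detection
threshold. For each spike the module measures the features consumed by the
trace-comparison cost functions: peak, AP threshold (slope criterion),
amplitude (peak minus threshold), base width (duration at the threshold
voltage, sub-sample interpolated), and AHP depth (how far the voltage falls
below the AP threshold before the next spike).

The detection conventions are deliberate choices, not physical constants,
and every one of them is a keyword argument: the detection threshold
(default 0 mV, sensible for biophysical spikes that overshoot 0), the
dV/dt onset criterion (default 20 mV/ms, a common electrophysiology
convention), and the half-width of the exclusion window placed around each
peak (default 5 ms) used by the "excluding spikes" costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import EventTrain, StepStimulus, Trace

__all__ = [
    "APShape",
    "SpikeAnalysis",
    "detect_spikes",
    "analysis_from_events",
    "latency_to_first_spike",
    "isi_sequence",
    "merge_windows",
    "DEFAULT_DETECT_THRESHOLD",
    "DEFAULT_SLOPE_CRITERION",
    "DEFAULT_EXCLUSION_HALF_WIDTH",
]

DEFAULT_DETECT_THRESHOLD = 0.0  # mV
DEFAULT_SLOPE_CRITERION = 20.0  # mV/ms
DEFAULT_EXCLUSION_HALF_WIDTH = 5.0  # ms


@dataclass(frozen=True)
class APShape:
    """Shape features of a single detected action potential."""

    peak_time: float
    peak_v: float
    threshold_v: float
    threshold_time: float
    base_width: float
    ahp_depth: float

    @property
    def amplitude(self) -> float:
        """Peak voltage minus AP threshold voltage, mV."""
        return self.peak_v - self.threshold_v


@dataclass(frozen=True)
class SpikeAnalysis:
    """Detected spikes of one trace plus the exclusion windows around them."""

    spikes: tuple[APShape, ...]
    detect_threshold: float
    exclusion_windows: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    @property
    def count(self) -> int:
        return len(self.spikes)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([s.peak_time for s in self.spikes])


def merge_windows(windows: list[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    """Merge overlapping/touching (start, end) intervals."""
    if not windows:
        return ()
    windows = sorted(windows)
    merged = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


def _crossing_time(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    # linear sub-sample interpolation of the time where v crosses `level`
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_spikes(
    trace: Trace,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    slope_criterion: float = DEFAULT_SLOPE_CRITERION,
    exclusion_half_width: float = DEFAULT_EXCLUSION_HALF_WIDTH,
) -> SpikeAnalysis:
    """Detect action potentials and measure their shape features.

    One spike is reported per maximal upward crossing of ``detect_threshold``;
    the peak is the largest sample between the upward and the subsequent
    downward crossing. The AP threshold is the voltage at the last sample
    before the peak where dV/dt first exceeds ``slope_criterion`` (falling
    back to the detection-threshold crossing sample when the slope criterion
    is never met). The base width is the time between the two crossings of
    the AP-threshold voltage that bracket the peak, with sub-sample linear
    interpolation. The AHP depth is the AP threshold minus the minimum
    voltage between this peak and the next spike's threshold crossing (or
    the end of the trace).
    """
    if trace.unit != "mV":
        raise TypeError(f"spike detection needs a voltage trace, got unit {trace.unit!r}")
    v = trace.values
    t = trace.times
    above = v >= detect_threshold
    # indices where the trace goes from below to >= threshold
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        up = np.concatenate([[0], up])
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1

    dvdt = np.empty_like(v)
    dvdt[1:] = np.diff(v) / trace.dt
    dvdt[0] = dvdt[1]

    spikes: list[APShape] = []
    regions: list[tuple[int, int, int]] = []  # (start, peak, end) sample indices
    for i, u in enumerate(up):
        d_candidates = down[down > u]
        d = int(d_candidates[0]) if d_candidates.size else v.size
        peak = u + int(np.argmax(v[u:d]))
        regions.append((u, peak, d))

    for k, (u, peak, d) in enumerate(regions):
        search_start = regions[k - 1][2] if k > 0 else 0
        # last onset (upward crossing of the slope criterion) before the peak
        seg = dvdt[search_start : peak + 1]
        fast = seg >= slope_criterion
        thr_idx = None
        if fast.any():
            onsets = np.flatnonzero(fast & ~np.concatenate([[True], fast[:-1]]))
            j = int(onsets[-1]) if onsets.size else int(np.flatnonzero(fast)[0])
            thr_idx = search_start + max(j - 1, 0)
        if thr_idx is None:
            thr_idx = max(u - 1, 0)
        thr_v = v[thr_idx]
        thr_t = t[thr_idx]

        # base width: crossings of thr_v bracketing the peak
        left = peak
        while left > 0 and v[left - 1] > thr_v:
            left -= 1
        if left > 0:
            t_left = _crossing_time(t[left - 1], t[left], v[left - 1], v[left], thr_v)
        else:
            t_left = t[0]
        right = peak
        while right < v.size - 1 and v[right + 1] > thr_v:
            right += 1
        if right < v.size - 1:
            t_right = _crossing_time(t[right], t[right + 1], v[right], v[right + 1], thr_v)
        else:
            t_right = t[-1]
        base_width = max(t_right - t_left, trace.dt)

        # AHP: minimum voltage between this peak and the next spike's onset
        ahp_end = regions[k + 1][0] if k + 1 < len(regions) else v.size
        ahp_min = float(np.min(v[peak:ahp_end])) if ahp_end > peak else v[peak]
        ahp_depth = thr_v - ahp_min

        spikes.append(
            APShape(
                peak_time=float(t[peak]),
                peak_v=float(v[peak]),
                threshold_v=float(thr_v),
                threshold_time=float(thr_t),
                base_width=float(base_width),
                ahp_depth=float(ahp_depth),
            )
        )

    windows = merge_windows(
        [
            (s.peak_time - exclusion_half_width, s.peak_time + exclusion_half_width)
            for s in spikes
        ]
    )
    return SpikeAnalysis(
        spikes=tuple(spikes), detect_threshold=detect_threshold, exclusion_windows=windows
    )


def analysis_from_events(
    events: EventTrain,
    exclusion_half_width: float = DEFAULT_EXCLUSION_HALF_WIDTH,
    detect_threshold: float = 0.0,
) -> SpikeAnalysis:
    """Build a count/timing-only analysis from an explicit spike-time train.

    Used for hybrid models whose spike times are a simulator output rather
    than threshold crossings of the (clipped) voltage trace. Shape features
    carry no information and are set to degenerate values; only peak times,
    counts, and exclusion windows are meaningful.
    """
    spikes = tuple(
        APShape(
            peak_time=float(ts),
            peak_v=0.0,
            threshold_v=0.0,
            threshold_time=float(ts),
            base_width=1e-9,
            ahp_depth=0.0,
        )
        for ts in np.asarray(events.times, dtype=float)
    )
    windows = merge_windows(
        [
            (s.peak_time - exclusion_half_width, s.peak_time + exclusion_half_width)
            for s in spikes
        ]
    )
    return SpikeAnalysis(
        spikes=spikes, detect_threshold=detect_threshold, exclusion_windows=windows
    )


def latency_to_first_spike(
    analysis: SpikeAnalysis, stimulus: StepStimulus
) -> float:
    """Time from stimulus onset to the first spike at or after it, ms.

    A trace with no such spike returns the total recording duration — a
    large but bounded sentinel, so the normalized latency error between a
    silent and a spiking trace stays finite.
    """
    for s in analysis.spikes:
        if s.peak_time >= stimulus.delay:
            return s.peak_time - stimulus.delay
    return stimulus.total_duration


def isi_sequence(analysis: SpikeAnalysis) -> np.ndarray:
    """Successive differences of spike peak times; empty below 2 spikes."""
    peaks = analysis.peak_times
    if peaks.size < 2:
        return np.empty(0)
    return np.diff(peaks)
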