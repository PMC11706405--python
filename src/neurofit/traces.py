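"""Core time-series containers and plain-text trace I/O.

Conventions used throughout the package: time in ms, membrane potential in
mV, current in nA. A :class:`Trace` is a uniformly sampled series; sample
``i`` occurs at ``t0 + i * dt``. Step-current stimuli are described by
:class:`StepStimulus` and attached to the trace they were applied to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StepStimulus",
    "Trace",
    "EventTrain",
    "TraceFormatError",
    "AlignmentError",
    "read_trace",
    "write_trace",
    "align_traces",
]


class TraceFormatError(ValueError):
    """Raised for unparseable or non-uniformly-sampled trace files."""


class AlignmentError(ValueError):
    """Raised when two traces share no overlapping time interval."""


@dataclass(frozen=True)
class StepStimulus:
    """A rectangular current step.

    Parameters
    ----------
    amplitude : float
        Step amplitude in nA.
    delay : float
        Onset time relative to the start of the trace, ms.
    duration : float
        Step length, ms.
    total_duration : float
        Length of the whole recording, ms.
    """

    amplitude: float
    delay: float
    duration: float
    total_duration: float

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError(f"stimulus delay must be >= 0, got {self.delay}")
        if self.duration <= 0:
            raise ValueError(f"stimulus duration must be > 0, got {self.duration}")
        if self.delay + self.duration > self.total_duration + 1e-9:
            raise ValueError(
                "stimulus extends past the recording: "
                f"delay {self.delay} + duration {self.duration} > total {self.total_duration}"
            )

    @property
    def end(self) -> float:
        """Offset time of the step, ms."""
        return self.delay + self.duration


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled voltage (mV) or current (nA) trace."""

    values: np.ndarray
    dt: float
    t0: float = 0.0
    unit: str = "mV"
    stimulus: StepStimulus | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a trace needs a 1-D array of at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace contains non-finite samples")
        if self.unit not in ("mV", "nA"):
            raise ValueError(f"unit must be 'mV' or 'nA', got {self.unit!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.values.size - 1)

    @property
    def duration(self) -> float:
        """Time span covered by the samples, ms."""
        return self.dt * (self.values.size - 1)

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class EventTrain:
    """Strictly increasing event (spike) times, ms."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("event times must be 1-D")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def read_trace(
    path: str | Path,
    dt: float | None = None,
    unit: str = "mV",
    stimulus: StepStimulus | None = None,
) -> Trace:
    """Read a one- or two-column whitespace-separated text trace.

    One-column files hold the sample values and require ``dt``. Two-column
    files hold (time, value) rows; ``dt`` is inferred from the first two rows
    and the sampling must be uniform to a relative tolerance of 1e-6.
    Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise TraceFormatError(f"non-numeric content in {path}: {exc}") from exc
    if data.size == 0:
        raise TraceFormatError(f"{path} holds no samples")
    if data.shape[1] == 1:
        if dt is None:
            raise TraceFormatError("one-column trace files need an explicit dt")
        return Trace(values=data[:, 0], dt=dt, unit=unit, stimulus=stimulus)
    if data.shape[1] != 2:
        raise TraceFormatError(f"{path}: expected 1 or 2 columns, got {data.shape[1]}")
    t, v = data[:, 0], data[:, 1]
    if t.size < 2:
        raise TraceFormatError(f"{path}: need at least 2 rows to infer dt")
    inferred = t[1] - t[0]
    if inferred <= 0:
        raise TraceFormatError(f"{path}: time column not increasing")
    steps = np.diff(t)
    if np.any(np.abs(steps - inferred) > 1e-6 * abs(inferred)):
        raise TraceFormatError(f"{path}: non-uniform sampling")
    if dt is not None and abs(inferred - dt) > 1e-6 * dt:
        raise TraceFormatError(
            f"{path}: inferred dt {inferred} disagrees with requested dt {dt}"
        )
    return Trace(values=v, dt=inferred, t0=t[0], unit=unit, stimulus=stimulus)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as two-column (time, value) text at full double precision."""
    path = Path(path)
    data = np.column_stack([trace.times, trace.values])
    header = f"unit={trace.unit} dt={trace.dt!r} t0={trace.t0!r}"
    np.savetxt(path, data, fmt="%.17g", header=header)


def align_traces(model: Trace, target: Trace) -> tuple[np.ndarray, np.ndarray]:
    """Pair model samples with target samples on the target's time grid.

    Equal grids (same dt, t0, length) pair samples directly. Otherwise the
    model trace is linearly interpolated onto the portion of the target grid
    that lies inside the model's time span; the target is the fixed reference
    so error normalizations stay tied to the target data.

    Returns
    -------
    (model_values, target_values) : ndarray pair of equal length.
    """
    if model.unit != target.unit:
        raise ValueError(f"unit mismatch: {model.unit} vs {target.unit}")
    if (
        len(model) == len(target)
        and abs(model.dt - target.dt) <= 1e-9 * target.dt
        and abs(model.t0 - target.t0) <= 1e-9 * max(1.0, abs(target.t0))
    ):
        return model.values, target.values
    lo = max(model.t0, target.t0)
    hi = min(model.t_end, target.t_end)
    if hi < lo:
        raise AlignmentError(
            f"no temporal overlap: model [{model.t0}, {model.t_end}] vs "
            f"target [{target.t0}, {target.t_end}]"
        )
    tt = target.times
    keep = (tt >= lo - 1e-9 * target.dt) & (tt <= hi + 1e-9 * target.dt)
    tt = tt[keep]
    if tt.size < 2:
        raise AlignmentError("overlap shorter than two target samples")
    mv = np.interp(tt, model.times, model.values)
    return mv, target.values[keep]
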