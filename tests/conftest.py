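import numpy as np
import pytest
from hypothesis import settings

from neurofit.traces import StepStimulus, Trace

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


def spike_train_trace(
    peak_times,
    total_duration=1000.0,
    dt=0.25,
    baseline=-65.0,
    peak_v=40.0,
    half_width=1.0,
    stimulus=None,
):
    """Synthetic voltage trace with triangular spikes at given peak times.

    Spikes rise from baseline to ``peak_v`` over ``half_width`` ms and fall
    back symmetrically — steep enough (>20 mV/ms for the defaults) to
    trigger the slope-based AP-threshold criterion. A slow 2 mV sine rides
    on the baseline so the subthreshold portion has a nonzero range, as any
    physiological trace does.
    """
    n = int(round(total_duration / dt)) + 1
    t = np.arange(n) * dt
    v = baseline + 2.0 * np.sin(2 * np.pi * t / total_duration)
    for pk in peak_times:
        tri = peak_v - (peak_v - baseline) * np.abs(t - pk) / half_width
        v = np.maximum(v, tri)
    return Trace(values=v, dt=dt, unit="mV", stimulus=stimulus)


@pytest.fixture
def flat_trace():
    return Trace(values=np.full(101, -65.0), dt=1.0, unit="mV")


@pytest.fixture(scope="session")
def hh_step():
    return StepStimulus(amplitude=0.3, delay=200.0, duration=500.0, total_duration=1000.0)
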