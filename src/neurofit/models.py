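"""Deterministic simulators for the desk-scale benchmark neuron models.

Three models back the surrogate-data benchmarks:

* a single-compartment Hodgkin-Huxley neuron (squid-axon Na/K/leak kinetics,
  modern voltage convention with rest near -65 mV) driven by a somatic
  current step — the classic conductance-density recovery problem;
* an ideal voltage-clamp recording of a bi-exponential conductance synapse
  (closed-form current, no ODE) — the synaptic-parameter recovery problem;
* an adaptive exponential integrate-and-fire (AdEx) neuron with spike-
  triggered and subthreshold adaptation — the phenomenological
  spiking-model problem.

Integration is fixed-step: exponential Euler for HH gating variables with a
Crank-Nicolson voltage update (stable and second-order at dt <= 0.05 ms),
forward Euler with an internal fine step for AdEx. Both integrators are vectorized over a
population of candidate parameter sets (compiled with numba) because the
search algorithms evaluate whole generations at a time. A candidate whose
state becomes non-finite is flagged as a simulation failure rather than
raising, so an optimizer can map it to a maximal-error sentinel and keep
running.
"""

from __future__ import annotations

from dataclasses import dataclass, astuple

import numpy as np
from numba import njit

from .traces import EventTrain, StepStimulus, Trace

__all__ = [
    "HHParams",
    "SynParams",
    "AdExParams",
    "SimulationFailure",
    "simulate_hh",
    "simulate_hh_batch",
    "simulate_vclamp",
    "simulate_vclamp_batch",
    "simulate_adex",
    "simulate_adex_batch",
    "make_surrogate_target",
    "HH_TRUE",
    "VCLAMP_TRUE",
    "ADEX_TRUE",
    "HH_AREA",
]

# ---------------------------------------------------------------------------
# Hodgkin-Huxley

# fixed constants (mV, uF/cm2); compartment area of a 20 um x 20 um cylinder
HH_ENA = 50.0
HH_EK = -77.0
HH_EL = -54.3
HH_CM = 1.0
HH_AREA = np.pi * 20e-4 * 20e-4  # cm^2, ~1.2566e-5


class SimulationFailure(RuntimeError):
    """Integration produced a non-finite state."""


@dataclass(frozen=True)
class HHParams:
    """Conductance densities in S/cm^2 (the three free benchmark parameters)."""

    gna: float = 0.12
    gk: float = 0.036
    gl: float = 0.0003

    def __post_init__(self) -> None:
        if min(self.gna, self.gk, self.gl) < 0:
            raise ValueError("conductance densities must be >= 0")


HH_TRUE = HHParams()


@njit(cache=True)
def _hh_rates(v):
    x = v + 40.0
    if abs(x) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    y = v + 55.0
    if abs(y) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * y / (1.0 - np.exp(-y / 10.0))
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _hh_membrane_current(v, gna, gk, gl):
    # steady-state ionic current density (uA/cm^2) at voltage v
    am, bm, ah, bh, an, bn = _hh_rates(v)
    m = am / (am + bm)
    h = ah / (ah + bh)
    n = an / (an + bn)
    ina = 1e3 * gna * m**3 * h * (v - HH_ENA)
    ik = 1e3 * gk * n**4 * (v - HH_EK)
    il = 1e3 * gl * (v - HH_EL)
    return ina + ik + il


@njit(cache=True)
def _hh_rest(gna, gk, gl):
    # bisection for the I=0 resting potential in [-90, -40] mV
    lo, hi = -90.0, -40.0
    flo = _hh_membrane_current(lo, gna, gk, gl)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fm = _hh_membrane_current(mid, gna, gk, gl)
        if (fm > 0.0) == (flo > 0.0):
            lo = mid
            flo = fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def _hh_integrate(params, dt, n_steps, stim_density, stim_on, stim_off):
    """Population HH integration.

    params : (n, 3) conductance densities; stim_density in uA/cm^2.
    Returns (voltages (n, n_steps+1), ok flags (n,)).
    """
    n = params.shape[0]
    out = np.empty((n, n_steps + 1))
    ok = np.ones(n, dtype=np.bool_)
    for c in range(n):
        gna, gk, gl = params[c, 0], params[c, 1], params[c, 2]
        v = _hh_rest(gna, gk, gl)
        am, bm, ah, bh, an, bn = _hh_rates(v)
        m = am / (am + bm)
        h = ah / (ah + bh)
        nn = an / (an + bn)
        out[c, 0] = v
        for i in range(n_steps):
            t = i * dt
            istim = stim_density if (t >= stim_on and t < stim_off) else 0.0
            am, bm, ah, bh, an, bn = _hh_rates(v)
            # exponential Euler gate updates
            tm = 1.0 / (am + bm)
            m = am * tm + (m - am * tm) * np.exp(-dt / tm)
            th = 1.0 / (ah + bh)
            h = ah * th + (h - ah * th) * np.exp(-dt / th)
            tn = 1.0 / (an + bn)
            nn = an * tn + (nn - an * tn) * np.exp(-dt / tn)
            # Crank-Nicolson voltage update with conductances frozen at the
            # half step (second-order accurate; keeps multi-spike phase drift
            # small under dt refinement)
            gna_t = 1e3 * gna * m**3 * h
            gk_t = 1e3 * gk * nn**4
            gl_t = 1e3 * gl
            gtot = gna_t + gk_t + gl_t
            ge = gna_t * HH_ENA + gk_t * HH_EK + gl_t * HH_EL
            num = v * (1.0 - 0.5 * dt * gtot / HH_CM) + dt / HH_CM * (ge + istim)
            den = 1.0 + 0.5 * dt * gtot / HH_CM
            v = num / den
            if not np.isfinite(v):
                ok[c] = False
                out[c, i + 1 :] = 0.0
                break
            out[c, i + 1] = v
    return out, ok


def simulate_hh_batch(
    params: np.ndarray, stim: StepStimulus, dt: float = 0.025
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a population of HH candidates; returns (voltages, ok flags)."""
    if dt > 0.05 + 1e-12:
        raise ValueError(f"HH integration requires dt <= 0.05 ms, got {dt}")
    params = np.ascontiguousarray(np.asarray(params, dtype=float).reshape(-1, 3))
    n_steps = int(round(stim.total_duration / dt))
    stim_density = stim.amplitude * 1e-3 / HH_AREA  # nA -> uA/cm^2
    return _hh_integrate(params, dt, n_steps, stim_density, stim.delay, stim.end)


def simulate_hh(params: HHParams, stim: StepStimulus, dt: float = 0.025) -> Trace:
    """Simulate one HH candidate and return its voltage trace."""
    arr = np.array([astuple(params)])
    v, ok = simulate_hh_batch(arr, stim, dt)
    if not ok[0]:
        raise SimulationFailure("HH integration diverged")
    return Trace(values=v[0], dt=dt, unit="mV", stimulus=stim)


# ---------------------------------------------------------------------------
# Voltage clamp of a bi-exponential synapse (closed form)

VC_E_SYN = 0.0  # mV
VC_HOLD = -70.0  # mV
VC_G_LEAK = HH_AREA * 0.0003 * 1e6  # uS; leak of the clamped compartment


@dataclass(frozen=True)
class SynParams:
    """Bi-exponential synaptic conductance parameters.

    weight is the peak conductance in uS; tau_rise < tau_decay in ms;
    delay is the conduction delay after each presynaptic event, ms.
    """

    weight: float = 0.01
    tau_rise: float = 0.5
    tau_decay: float = 5.0
    delay: float = 2.0

    def __post_init__(self) -> None:
        if self.weight < 0 or self.delay < 0:
            raise ValueError("weight and delay must be >= 0")
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError(
                f"need 0 < tau_rise < tau_decay, got {self.tau_rise}, {self.tau_decay}"
            )


VCLAMP_TRUE = SynParams()


def syn_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time-to-peak of the bi-exponential conductance after event+delay."""
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    )


def simulate_vclamp_batch(
    params: np.ndarray, events: np.ndarray, duration: float, dt: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form clamp currents for a population of synapse candidates.

    params : (n, 4) columns (weight, tau_rise, tau_decay, delay).
    Returns (currents (n, nt) in nA, ok flags); candidates violating
    tau_rise < tau_decay are flagged instead of raising.
    """
    params = np.asarray(params, dtype=float).reshape(-1, 4)
    n = params.shape[0]
    t = np.arange(int(round(duration / dt)) + 1) * dt
    i_hold = VC_G_LEAK * (VC_HOLD - HH_EL)
    out = np.full((n, t.size), i_hold)
    ok = (params[:, 1] > 0) & (params[:, 1] < params[:, 2]) & (params[:, 0] >= 0)
    w, tr, td, dl = params[:, 0], params[:, 1], params[:, 2], params[:, 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        tpk = tr * td / (td - tr) * np.log(td / tr)
        norm = 1.0 / (np.exp(-tpk / td) - np.exp(-tpk / tr))
    for c in range(n):
        if not ok[c]:
            continue
        g = np.zeros(t.size)
        for ev in events:
            s = t - ev - dl[c]
            live = s >= 0
            g[live] += (
                w[c] * norm[c] * (np.exp(-s[live] / td[c]) - np.exp(-s[live] / tr[c]))
            )
        out[c] += g * (VC_HOLD - VC_E_SYN)
    return out, ok


def simulate_vclamp(
    params: SynParams, events: EventTrain, duration: float, dt: float = 0.1
) -> Trace:
    """Ideal-clamp current trace (nA) during synaptic stimulation.

    The recorded current is the constant leak holding current plus, for each
    presynaptic event, a bi-exponential conductance transient scaled so its
    peak equals ``weight``, times the driving force (hold_v - e_syn). Event
    contributions sum linearly.
    """
    ev = np.asarray(events.times, dtype=float)
    if ev.size and (ev.min() < 0 or ev.max() > duration):
        raise ValueError("events must lie within [0, duration]")
    arr = np.array([astuple(params)])
    cur, ok = simulate_vclamp_batch(arr, ev, duration, dt)
    if not ok[0]:
        raise ValueError("invalid synaptic parameters")
    return Trace(values=cur[0], dt=dt, unit="nA")


# ---------------------------------------------------------------------------
# Adaptive exponential integrate-and-fire

ADEX_CUTOFF_FACTOR = 5.0  # spike cut-off at V_T + 5 * Delta_T
_ADEX_MAX_SPIKES = 4000


@dataclass(frozen=True)
class AdExParams:
    """AdEx parameters: pF, nS, mV, ms, pA as appropriate.

    Defaults are a regular-spiking, adapting cortical-neuron parameter set.
    """

    C: float = 200.0  # pF
    g_L: float = 12.0  # nS
    E_L: float = -70.0  # mV
    V_T: float = -50.0  # mV
    V_reset: float = -58.0  # mV
    t_ref: float = 2.0  # ms
    Delta_T: float = 2.0  # mV
    a: float = 2.0  # nS
    b: float = 60.0  # pA
    tau_w: float = 300.0  # ms

    def __post_init__(self) -> None:
        if min(self.C, self.g_L, self.tau_w, self.Delta_T) <= 0:
            raise ValueError("C, g_L, tau_w, Delta_T must be > 0")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")

    @property
    def cutoff(self) -> float:
        return self.V_T + ADEX_CUTOFF_FACTOR * self.Delta_T


ADEX_TRUE = AdExParams()


@njit(cache=True)
def _adex_integrate(params, dt_int, n_int, record_every, i_pa, stim_on, stim_off):
    """Population AdEx integration (forward Euler at dt_int).

    params : (n, 10) rows (C, g_L, E_L, V_T, V_reset, t_ref, Delta_T, a, b, tau_w).
    Records voltage every `record_every` internal steps; the stored voltage is
    clipped at the spike cut-off V_T + 5*Delta_T.
    Returns (voltages, spike_times, spike_counts, ok flags).
    """
    n = params.shape[0]
    n_rec = n_int // record_every + 1
    out = np.empty((n, n_rec))
    spikes = np.zeros((n, _ADEX_MAX_SPIKES))
    counts = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=np.bool_)
    for c in range(n):
        C, gL, EL = params[c, 0], params[c, 1], params[c, 2]
        VT, Vr, tref = params[c, 3], params[c, 4], params[c, 5]
        DT, a, b, tauw = params[c, 6], params[c, 7], params[c, 8], params[c, 9]
        cutoff = VT + ADEX_CUTOFF_FACTOR * DT
        v = EL
        w = 0.0
        ref_until = -1.0
        out[c, 0] = v if v < cutoff else cutoff
        rec = 1
        for i in range(n_int):
            t = i * dt_int
            istim = i_pa if (t >= stim_on and t < stim_off) else 0.0
            if t < ref_until:
                v = Vr
                dw = (a * (v - EL) - w) / tauw
                w += dt_int * dw
            else:
                ex = (v - VT) / DT
                if ex > 30.0:  # overflow guard; counts as a spike below
                    ex = 30.0
                dv = (-gL * (v - EL) + gL * DT * np.exp(ex) - w + istim) / C
                dw = (a * (v - EL) - w) / tauw
                v += dt_int * dv
                w += dt_int * dw
                if not (np.isfinite(v) and np.isfinite(w)):
                    ok[c] = False
                    break
                if v >= cutoff:
                    if counts[c] < _ADEX_MAX_SPIKES:
                        spikes[c, counts[c]] = t + dt_int
                    counts[c] += 1
                    v = Vr
                    w += b
                    ref_until = t + dt_int + tref
            if (i + 1) % record_every == 0:
                out[c, rec] = v if v < cutoff else cutoff
                rec += 1
        if not ok[c]:
            out[c, :] = 0.0
    return out, spikes, counts, ok


def simulate_adex_batch(
    params: np.ndarray,
    stim: StepStimulus,
    dt: float = 0.2,
    dt_internal: float = 0.05,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Simulate a population of AdEx candidates.

    Integrates at ``dt_internal`` and records at the coarser sampling
    interval ``dt`` (which must be a multiple of ``dt_internal``).
    Returns (voltages (n, nt), list of spike-time arrays, ok flags).
    """
    if dt_internal > 0.1 + 1e-12:
        raise ValueError(f"AdEx integration requires dt <= 0.1 ms, got {dt_internal}")
    record_every = int(round(dt / dt_internal))
    if abs(record_every * dt_internal - dt) > 1e-9:
        raise ValueError("dt must be an integer multiple of dt_internal")
    params = np.ascontiguousarray(np.asarray(params, dtype=float).reshape(-1, 10))
    n_int = int(round(stim.total_duration / dt_internal))
    i_pa = stim.amplitude * 1e3  # nA -> pA
    out, spikes, counts, ok = _adex_integrate(
        params, dt_internal, n_int, record_every, i_pa, stim.delay, stim.end
    )
    trains = [spikes[c, : min(counts[c], _ADEX_MAX_SPIKES)].copy() for c in range(params.shape[0])]
    return out, trains, ok


def simulate_adex(
    params: AdExParams,
    stim: StepStimulus,
    dt: float = 0.2,
    dt_internal: float = 0.05,
) -> tuple[Trace, EventTrain]:
    """Simulate one AdEx candidate; returns (clipped voltage trace, spike train)."""
    arr = np.array([astuple(params)])
    v, trains, ok = simulate_adex_batch(arr, stim, dt, dt_internal)
    if not ok[0]:
        raise SimulationFailure("AdEx integration diverged")
    return (
        Trace(values=v[0], dt=dt, unit="mV", stimulus=stim),
        EventTrain(times=trains[0]),
    )


# ---------------------------------------------------------------------------
# Surrogate targets


def make_surrogate_target(
    benchmark_id: str, true_params=None, protocol=None
) -> tuple[list, np.ndarray]:
    """Generate the surrogate target data for a benchmark.

    Simulates the benchmark's model at its stimulation protocol(s) with the
    known "true" parameters and returns ``(targets, truth_vector)``. Because
    the same simulator at the same step size produces the target, the
    objective evaluated at the truth is zero up to round-off, and parameter
    recovery is measurable against the returned truth.
    """
    if benchmark_id == "hh":
        p = true_params if true_params is not None else HH_TRUE
        stim = protocol if protocol is not None else StepStimulus(0.3, 200.0, 500.0, 1000.0)
        trace = simulate_hh(p, stim, dt=0.05)
        return [trace], np.array(astuple(p))
    if benchmark_id == "vclamp":
        p = true_params if true_params is not None else VCLAMP_TRUE
        events = protocol if protocol is not None else EventTrain(
            times=np.array([100.0, 200.0, 300.0, 400.0])
        )
        trace = simulate_vclamp(p, events, duration=600.0, dt=0.1)
        return [trace], np.array(astuple(p))
    if benchmark_id == "adex":
        p = true_params if true_params is not None else ADEX_TRUE
        stims = protocol if protocol is not None else [
            StepStimulus(amp, 100.0, 900.0, 1100.0) for amp in (0.30, 0.35, 0.40, 0.45)
        ]
        targets = [simulate_adex(p, s, dt=0.2) for s in stims]
        return targets, np.array(astuple(p))
    raise ValueError(f"unknown benchmark id {benchmark_id!r}")
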