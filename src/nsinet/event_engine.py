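"""Event-driven engine: asynchronous NSI and a two-neuron half-center.

The event-driven counterpart of the non-spiking interneuron keeps no
clock.  Its state is a snapshot ``(V_m, V_rest, decay, C, t_updated)``:
on each input event the membrane potential first decays exponentially
over the elapsed interval and then receives the event's charge increment
``I_input / C``; between events anyone holding a snapshot can reconstruct
the exact membrane potential at an arbitrary later time,

.. math:: V_m(t) = V_{rest} + (V_m - V_{rest}) \\cdot decay^{\\,t - t_{updated}}

without touching the neuron — the synapse side of the contract.  The
per-ms decay factor relates to the clock-driven time constant through
``decay = exp(-1 ms / tau_m)``.

The demo network is a half-center of two mutually inhibitory AdEx
neurons whose spike threshold ``V_th`` is slaved to the NSI membrane
potential through a clamped affine map.  Neurons never read the NSI
directly: the NSI publishes a parameter-update message on every input
event, and the synapses reconstruct ``V_m`` as needed.  The AdEx pair is
integrated clock-driven between events (the exponential-and-fire dynamics
have no closed form); no noise is used in this engine.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace

import numpy as np

from nsinet.neurons import AdExParams

__all__ = [
    "EventNSIState",
    "EventMessage",
    "VthMapping",
    "OutOfOrderEventError",
    "event_update",
    "reconstruct_vm",
    "map_vm_to_vth",
    "run_event_demo",
    "EventDemoResult",
]


class OutOfOrderEventError(ValueError):
    """An event arrived with a timestamp before the last processed one."""


@dataclass(frozen=True)
class EventNSIState:
    """Snapshot of the event-driven NSI; self-contained for reconstruction."""

    V_m: float           # mV at t_updated
    V_rest: float = -60.0
    decay: float = float(math.exp(-1.0 / 20.0))  # per-ms factor, exp(-1ms/tau_m)
    C: float = 200.0     # pF
    t_updated: float = 0.0  # ms of the last processed input event

    def __post_init__(self) -> None:
        if not (0.0 < self.decay < 1.0):
            raise ValueError("decay must be in (0, 1)")
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass(frozen=True)
class EventMessage:
    """A message on the event bus: an input spike or a parameter update."""

    kind: str            # "spike" | "parameter_update"
    time: float          # ms
    source: str = ""
    payload: EventNSIState | None = None


@dataclass(frozen=True)
class VthMapping:
    """Clamped affine map from NSI membrane potential to AdEx ``V_th``.

    Defaults tie the threshold range to the clock-driven manipulation
    endpoints: the NSI at rest (-60 mV) maps to V_th = -56 mV and the
    fully displaced NSI (-45 mV) to V_th = -51 mV.
    """

    V_m_low: float = -60.0
    V_m_high: float = -45.0
    V_th_low: float = -56.0
    V_th_high: float = -51.0

    def __post_init__(self) -> None:
        if not self.V_m_low < self.V_m_high:
            raise ValueError("V_m_low must be < V_m_high")


def event_update(state: EventNSIState, event_time: float, I_input: float) -> EventNSIState:
    """Process one input event: decay over the elapsed time, then add charge.

    ``I_input / C`` is the membrane-potential increment delivered by the
    event (pA·ms / pF = mV for a unit-time current pulse).
    """
    if event_time < state.t_updated:
        raise OutOfOrderEventError(
            f"event at {event_time} ms precedes last update at {state.t_updated} ms"
        )
    dt = event_time - state.t_updated
    v = state.V_rest + (state.V_m - state.V_rest) * state.decay**dt
    v += I_input / state.C
    return replace(state, V_m=v, t_updated=event_time)


def reconstruct_vm(snapshot: EventNSIState, t: float) -> float:
    """Membrane potential at time ``t`` from a snapshot alone (pure)."""
    if t < snapshot.t_updated:
        raise OutOfOrderEventError(
            f"cannot reconstruct at {t} ms before snapshot time {snapshot.t_updated} ms"
        )
    return snapshot.V_rest + (snapshot.V_m - snapshot.V_rest) * snapshot.decay ** (
        t - snapshot.t_updated
    )


def map_vm_to_vth(mapping: VthMapping, V_m: float) -> float:
    """Affine interpolation of ``V_th`` from ``V_m``, clamped at both limits."""
    frac = (V_m - mapping.V_m_low) / (mapping.V_m_high - mapping.V_m_low)
    frac = min(max(frac, 0.0), 1.0)
    return mapping.V_th_low + frac * (mapping.V_th_high - mapping.V_th_low)


class _SnapshotSynapse:
    """Synapse-side endpoint: holds the latest published NSI snapshot.

    This is the only channel through which the AdEx side sees the NSI;
    it never reads the neuron object itself.
    """

    def __init__(self, initial: EventNSIState):
        self._snapshot = initial
        self.log: list[EventMessage] = []

    def deliver(self, msg: EventMessage) -> None:
        if msg.kind != "parameter_update" or msg.payload is None:
            raise ValueError("snapshot synapse only accepts parameter updates")
        self._snapshot = msg.payload
        self.log.append(msg)

    def vm_at(self, t: float) -> float:
        return reconstruct_vm(self._snapshot, t)


@dataclass(frozen=True)
class EventDemoResult:
    """Traces and spike trains of the event-driven half-center demo."""

    t_ms: np.ndarray
    nsi_vm: np.ndarray
    vth_left: np.ndarray
    vth_right: np.ndarray
    spikes_left: np.ndarray
    spikes_right: np.ndarray
    event_log: list


def run_event_demo(
    input_spike_times,
    mapping: VthMapping | None = None,
    duration: float = 6000.0,
    input_charge: float = 150.0,  # pA*ms per input event; per-event kick = charge/C mV
    adex: AdExParams | None = None,
    I_e: float = 200.0,
    w_inh: float = -400.0,   # mutual-inhibition current jump, pA/spike
    tau_syn: float = 5.0,
    dt: float = 0.1,
    nsi: EventNSIState | None = None,
) -> EventDemoResult:
    """Drive the two-neuron event-driven half-center from a spike train.

    The input spikes (e.g. from :func:`nsinet.codecs.bsa_encode`) charge
    the event-driven NSI; each published snapshot lets the synapses of
    the two AdEx neurons reconstruct the NSI membrane potential and remap
    their ``V_th``.  Higher input spike frequency raises the NSI
    potential, raises ``V_th`` toward the default threshold and thereby
    raises the bursting frequency; the two neurons burst in antiphase by
    mutual inhibition.  Deterministic: the engine is noise-free and the
    left/right symmetry is broken by the initial membrane potentials.
    """
    mapping = mapping or VthMapping()
    adex = adex or AdExParams(V_reset=-46.0)
    state = nsi or EventNSIState(V_m=-60.0)

    events = sorted(float(t) for t in np.asarray(input_spike_times, dtype=float))
    ev_idx = 0
    syn_left = _SnapshotSynapse(state)
    syn_right = _SnapshotSynapse(state)
    event_log: list[EventMessage] = []

    n_steps = int(round(duration / dt))
    rec_stride = int(round(1.0 / dt))
    n_ms = n_steps // rec_stride
    t_ms = np.arange(n_ms, dtype=float)
    nsi_vm = np.empty(n_ms)
    vth_l_rec = np.empty(n_ms)
    vth_r_rec = np.empty(n_ms)
    spikes_l: list[float] = []
    spikes_r: list[float] = []

    # two AdEx neurons, symmetric parameters, asymmetric start
    V = np.array([adex.E_L + 2.0, adex.E_L - 2.0])
    W = np.zeros(2)
    I_syn = np.zeros(2)
    decay_syn = math.exp(-dt / tau_syn)

    for step in range(n_steps):
        t = step * dt
        while ev_idx < len(events) and events[ev_idx] <= t:
            ev_t = events[ev_idx]
            event_log.append(EventMessage(kind="spike", time=ev_t, source="input"))
            state = event_update(state, ev_t, input_charge)
            msg = EventMessage(kind="parameter_update", time=ev_t, source="nsi", payload=state)
            syn_left.deliver(msg)
            syn_right.deliver(msg)
            event_log.append(msg)
            ev_idx += 1

        vth_l = map_vm_to_vth(mapping, syn_left.vm_at(t))
        vth_r = map_vm_to_vth(mapping, syn_right.vm_at(t))

        if step % rec_stride == 0:
            m = step // rec_stride
            nsi_vm[m] = reconstruct_vm(state, t)
            vth_l_rec[m] = vth_l
            vth_r_rec[m] = vth_r

        for i, vth_i in ((0, vth_l), (1, vth_r)):
            v, w = V[i], W[i]
            ea = min((v - vth_i) / adex.Delta_T, 20.0)
            v_new = v + (
                -adex.g_L * (v - adex.E_L)
                + adex.g_L * adex.Delta_T * math.exp(ea)
                - w
                + I_e
                + I_syn[i]
            ) * (dt / adex.C)
            if v_new > adex.spike_cutoff:
                (spikes_l if i == 0 else spikes_r).append(t)
                v_new = adex.V_reset
                w = w + adex.b
                I_syn[1 - i] += w_inh
            else:
                w = w + (adex.a * (v - adex.E_L) - w) * (dt / adex.tau_w)
            V[i], W[i] = v_new, w
        I_syn *= decay_syn

    return EventDemoResult(
        t_ms=t_ms,
        nsi_vm=nsi_vm,
        vth_left=vth_l_rec,
        vth_right=vth_r_rec,
        spikes_left=np.asarray(spikes_l),
        spikes_right=np.asarray(spikes_r),
        event_log=event_log,
    )
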