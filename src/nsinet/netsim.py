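"""Network construction and clock-driven simulation.

The simulated network couples one non-spiking interneuron (NSI) into a
spiking central-pattern-generator (sCPG) circuit:

* two mutually inhibitory populations of five AdEx neurons each (the
  half-center oscillator producing antiphase bursts),
* a motor population (MNP) of five AdEx neurons receiving an excitatory
  projection from one half-center and an inhibitory projection from the
  other — its rate-coded spike count is the network output,
* the NSI, which receives the analog input current and communicates with
  the spiking populations through graded current injection and/or
  voltage-characteristic manipulation (see :mod:`nsinet.coupling`).

The experiment matrix enumerates which communication channels are active
(tests 1-12) and which populations they address with which polarity
(subcategories 0-5).  All trials run for 6 s with the input current
updated every second; Gaussian current noise is added to every neuron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from nsinet import _core
from nsinet.coupling import CouplingPolarity, FeedbackConfig, V_RESET_DEFAULT, V_TH_DEFAULT, VCM_MAX_MV
from nsinet.neurons import AdExParams, NSIParams, IntegrationBlowupError, SubthresholdContractError

__all__ = [
    "I_INPUT_MAX_PA",
    "STEP_INCREMENT_PA",
    "ExperimentSpec",
    "InputSchedule",
    "NetworkTopology",
    "NoiseConfig",
    "SpikeTrain",
    "SimResult",
    "build_experiment",
    "simulate",
    "run_feedback_loop",
    "feedback_input_levels",
]

#: Maximum analog input current to the NSI (pA); it displaces the NSI
#: membrane potential by the full 15 mV biological range.
I_INPUT_MAX_PA = 148.0
#: Stepping-schedule increment: six levels over six seconds.
STEP_INCREMENT_PA = I_INPUT_MAX_PA / 5.0

#: Maximum NSI output conductance (nS); larger weights produce "lifting"
#: (the rate-coded output no longer returns to zero between bursts).
W_MAX_NS = 70.0

DT_MS = 0.1
RECORD_MS = 1.0
DURATION_MS = 6000.0

_POP_SLICES = {"excitatory": (0, 5), "inhibitory": (5, 10), "mnp": (10, 15)}

# Test matrix: which channels are active per main test number.
_MNP_INJECTION_TESTS = {1, 3, 4, 5, 6, 8, 10, 12}
_SCPG_INJECTION_TESTS = {2, 3, 8, 10, 12}
_VOLTAGE_TARGETS = {
    4: "V_th", 5: "V_reset", 6: "V_m",
    7: "V_th", 8: "V_th",
    9: "V_reset", 10: "V_reset",
    11: "V_m", 12: "V_m",
}


@dataclass(frozen=True)
class InputSchedule:
    """Analog input-current schedule for the NSI.

    ``stepping`` ramps through six evenly spaced levels (0 to ``I_max``)
    held ``step_interval`` each; excitatory tests step up, inhibitory
    tests step down (the network is "excited" by reducing inhibition).
    ``toggling`` and ``feedback`` alternate/replay an explicit ``levels``
    sequence; ``constant`` holds ``I_max``.
    """

    kind: str = "stepping"  # constant | stepping | toggling | feedback
    I_max: float = I_INPUT_MAX_PA
    step_interval: float = 1000.0  # ms
    direction: str = "up"
    levels: tuple = ()  # explicit levels for toggling / feedback

    def resolve_levels(self, duration: float) -> np.ndarray:
        n_intervals = int(round(duration / self.step_interval))
        if self.kind == "constant":
            return np.full(n_intervals, self.I_max)
        if self.kind == "stepping":
            lv = self.I_max / 5.0 * np.arange(6)
            if self.direction == "down":
                lv = lv[::-1]
            if n_intervals != lv.size:
                raise ValueError("stepping schedule expects 6 intervals")
            return lv
        if self.kind in ("toggling", "feedback"):
            if not self.levels:
                raise ValueError(f"{self.kind} schedule needs explicit levels")
            lv = np.asarray(self.levels, dtype=float)
            if lv.size != n_intervals:
                raise ValueError("levels do not match duration/step_interval")
            return lv
        raise ValueError(f"unknown schedule kind {self.kind!r}")

    def per_ms(self, duration: float) -> np.ndarray:
        lv = self.resolve_levels(duration)
        return np.repeat(lv, int(round(self.step_interval / RECORD_MS)))


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian current noise, redrawn every ``update_interval`` ms."""

    nsi_std: float = 25.0     # pA
    neuron_std: float = 50.0  # pA
    mean: float = 0.0         # pA
    update_interval: float = DT_MS  # ms

    def __post_init__(self) -> None:
        if self.nsi_std < 0 or self.neuron_std < 0:
            raise ValueError("noise std must be >= 0")


@dataclass(frozen=True)
class NetworkTopology:
    """Populations, connections and calibrated free parameters.

    Synapses between spiking populations are current-based with
    exponential decay: each presynaptic spike adds ``weight`` pA to the
    synaptic current of every neuron of the target population after
    ``delay`` ms, and the current decays with ``tau_syn``.  Weights,
    delays and bias currents are calibration values (see
    ``docs/methods.md``), not literature constants.
    """

    n_per_pop: int = 5
    adex: AdExParams = field(default_factory=lambda: AdExParams(tau_w=180.0))
    adex_mnp: AdExParams | None = field(
        default_factory=lambda: AdExParams(C=48.0, b=50.0, tau_w=5.0)
    )
    nsi: NSIParams = field(default_factory=NSIParams)
    w_cc: float = -30.0       # mutual inhibition between sCPG populations, pA/spike
    w_within_exc: float = 0.0  # within-population excitation, excitatory half-center
    w_within_inh: float = 0.0  # within-population excitation, inhibitory half-center
    w_exc_mnp: float = 300.0  # excitatory population -> MNP, pA/spike
    w_exc_mnp_fast: float = 0.0   # fast component of the excitatory -> MNP projection
    tau_syn_exc_mnp_fast: float = 1.5  # ms, decay of the fast component
    w_inh_mnp: float = -10.0  # inhibitory population -> MNP, pA/spike
    tau_syn: float = 5.0      # ms, default synaptic decay
    tau_syn_exc_mnp: float | None = None  # decay of the excitatory->MNP projection
    tau_syn_inh_mnp: float | None = None  # decay of the inhibitory->MNP projection
    delay: float = 1.0        # ms
    I_e_scpg: float = 480.0   # bias current to sCPG neurons, pA
    I_e_mnp: float = -1100.0  # bias current to motor neurons, pA

    def __post_init__(self) -> None:
        if self.n_per_pop != _core.N_PER_POP:
            raise ValueError("the engine is built for populations of 5 neurons")
        if self.tau_syn <= 0 or self.delay <= 0:
            raise ValueError("tau_syn and delay must be > 0")

    @property
    def n_neurons(self) -> int:
        return 3 * self.n_per_pop + 1  # 16: three populations plus the NSI

    def connections(self) -> list[tuple[str, str, str, float, float]]:
        """Explicit (source, target, kind, weight, delay) connection list."""
        conns = [
            ("excitatory", "inhibitory", "spiking_synapse", self.w_cc, self.delay),
            ("inhibitory", "excitatory", "spiking_synapse", self.w_cc, self.delay),
            ("excitatory", "mnp", "spiking_synapse", self.w_exc_mnp, self.delay),
            ("inhibitory", "mnp", "spiking_synapse", self.w_inh_mnp, self.delay),
            ("nsi", "mnp", "current_injection", np.nan, 0.0),
            ("nsi", "excitatory", "current_injection", np.nan, 0.0),
            ("nsi", "inhibitory", "current_injection", np.nan, 0.0),
            ("nsi", "excitatory", "voltage_manipulation", np.nan, 0.0),
            ("nsi", "inhibitory", "voltage_manipulation", np.nan, 0.0),
        ]
        return conns

    def pop_weight_matrix(self) -> np.ndarray:
        Wpp = np.zeros((3, 3))
        Wpp[_core.POP_EXC, _core.POP_EXC] = self.w_within_exc
        Wpp[_core.POP_INH, _core.POP_INH] = self.w_within_inh
        Wpp[_core.POP_EXC, _core.POP_INH] = self.w_cc
        Wpp[_core.POP_INH, _core.POP_EXC] = self.w_cc
        Wpp[_core.POP_EXC, _core.POP_MNP] = self.w_exc_mnp
        Wpp[_core.POP_INH, _core.POP_MNP] = self.w_inh_mnp
        return Wpp

    def decay_matrix(self, dt: float) -> np.ndarray:
        tau = np.full((3, 3), self.tau_syn)
        if self.tau_syn_exc_mnp is not None:
            tau[_core.POP_EXC, _core.POP_MNP] = self.tau_syn_exc_mnp
        if self.tau_syn_inh_mnp is not None:
            tau[_core.POP_INH, _core.POP_MNP] = self.tau_syn_inh_mnp
        return np.exp(-dt / tau)

    def fast_bank(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Second synaptic bank: the fast component of the motor drive."""
        W2 = np.zeros((3, 3))
        W2[_core.POP_EXC, _core.POP_MNP] = self.w_exc_mnp_fast
        d2 = np.full((3, 3), np.exp(-dt / self.tau_syn_exc_mnp_fast))
        return d2, W2


@dataclass(frozen=True)
class ExperimentSpec:
    """One fully resolved cell of the test matrix (plus static variants)."""

    test_no: int
    subcategory: int
    mnp_injection: str            # "stepping" | "none" (follows the schedule when active)
    scpg_injection: str
    voltage_target: str           # "none" | "V_th" | "V_reset" | "V_m"
    polarity: CouplingPolarity
    scpg_targets: str = "both"    # both | excitatory_pop | inhibitory_pop
    duration: float = DURATION_MS
    input_schedule: InputSchedule = field(default_factory=InputSchedule)
    w_syn: float = W_MAX_NS       # NSI output conductance used for injections, nS
    seed: int | None = None

    @property
    def label(self) -> str:
        return f"{self.test_no}_{self.subcategory}"


@dataclass(frozen=True)
class SpikeTrain:
    """Timestamped spike events, with population labels.

    Times are on the 1 ms recording grid; ``populations`` maps a label to
    a half-open neuron-id range.
    """

    times: np.ndarray
    neuron_ids: np.ndarray
    duration: float
    populations: dict = field(default_factory=lambda: dict(_POP_SLICES))

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.neuron_ids, dtype=np.int64)
        if t.shape != i.shape:
            raise ValueError("times and neuron_ids must have the same shape")
        if t.size and (t.min() < 0 or t.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "neuron_ids", i)

    def all_times(self) -> np.ndarray:
        return np.sort(self.times)

    def for_population(self, label: str) -> np.ndarray:
        lo, hi = self.populations[label]
        return np.sort(self.times[(self.neuron_ids >= lo) & (self.neuron_ids < hi)])

    def for_neuron(self, neuron_id: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == neuron_id])

    def count(self, label: str | None = None) -> int:
        return int(self.times.size if label is None else self.for_population(label).size)

    def write_text(self, directory: str | Path) -> list[Path]:
        """One two-column (time_ms, neuron_id) text file per population."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for label, (lo, hi) in self.populations.items():
            m = (self.neuron_ids >= lo) & (self.neuron_ids < hi)
            order = np.argsort(self.times[m], kind="stable")
            data = np.column_stack([self.times[m][order], self.neuron_ids[m][order]])
            path = directory / f"spikes_{label}.txt"
            np.savetxt(path, data, fmt="%.3f %d", header="time_ms neuron_id")
            written.append(path)
        return written

    @classmethod
    def read_text(cls, paths, duration: float) -> "SpikeTrain":
        times, ids = [], []
        for path in paths:
            data = np.loadtxt(path, ndmin=2)
            if data.size:
                times.append(data[:, 0])
                ids.append(data[:, 1].astype(np.int64))
        t = np.concatenate(times) if times else np.empty(0)
        i = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
        return cls(times=t, neuron_ids=i, duration=duration)


@dataclass(frozen=True)
class SimResult:
    """Simulation output: spikes plus 1 ms-grid traces."""

    spikes: SpikeTrain
    traces: dict
    spec: ExperimentSpec
    seed: int


def build_experiment(test_no: int, subcategory: int) -> ExperimentSpec:
    """Resolve a (test, subcategory) pair of the test matrix.

    Main test numbers 1-12 select which communication channels are
    active; subcategories 0-5 select polarity (0-2 excitatory, 3-5
    inhibitory) and which sCPG populations are addressed (0/3 both, 1/4
    excitatory only, 2/5 inhibitory only).
    """
    if not (1 <= test_no <= 12):
        raise ValueError(f"test_no must be in 1..12, got {test_no}")
    if not (0 <= subcategory <= 5):
        raise ValueError(f"subcategory must be in 0..5, got {subcategory}")
    polarity = CouplingPolarity.EXCITATORY if subcategory <= 2 else CouplingPolarity.INHIBITORY
    targets = ("both", "excitatory_pop", "inhibitory_pop")[subcategory % 3]
    schedule = InputSchedule(
        kind="stepping",
        direction="up" if polarity is CouplingPolarity.EXCITATORY else "down",
    )
    return ExperimentSpec(
        test_no=test_no,
        subcategory=subcategory,
        mnp_injection="stepping" if test_no in _MNP_INJECTION_TESTS else "none",
        scpg_injection="stepping" if test_no in _SCPG_INJECTION_TESTS else "none",
        voltage_target=_VOLTAGE_TARGETS.get(test_no, "none"),
        polarity=polarity,
        scpg_targets=targets,
        input_schedule=schedule,
    )


def _target_mask(scpg_targets: str) -> np.ndarray:
    mask = np.zeros(_core.N_ADEX)
    if scpg_targets in ("both", "excitatory_pop"):
        mask[0:5] = 1.0
    if scpg_targets in ("both", "inhibitory_pop"):
        mask[5:10] = 1.0
    return mask


def _draw_noise(rng: np.random.Generator, n_steps: int, noise: NoiseConfig) -> tuple:
    k = max(1, int(round(noise.update_interval / DT_MS)))
    n_draw = -(-n_steps // k)
    na = noise.mean + noise.neuron_std * rng.standard_normal((n_draw, _core.N_ADEX))
    nn = noise.mean + noise.nsi_std * rng.standard_normal(n_draw)
    if k > 1:
        na = np.repeat(na, k, axis=0)[:n_steps]
        nn = np.repeat(nn, k)[:n_steps]
    return np.ascontiguousarray(na), np.ascontiguousarray(nn)


def _initial_state(topology: NetworkTopology) -> tuple[np.ndarray, np.ndarray]:
    # small deterministic asymmetry between the half-centers so the
    # antiphase rhythm starts from a defined leader
    V0 = np.full(_core.N_ADEX, topology.adex.E_L)
    V0[0:5] += 2.0
    V0[5:10] -= 2.0
    return V0, np.zeros(_core.N_ADEX)


def _run(
    spec: ExperimentSpec,
    topology: NetworkTopology,
    noise: NoiseConfig,
    seed: int,
    feedback: FeedbackConfig | None = None,
    vm_apply_every_ms: float = 1.0,
) -> SimResult:
    ad = topology.adex
    adm = topology.adex_mnp or ad
    n_steps = int(round(spec.duration / DT_MS))
    rec_stride = int(round(RECORD_MS / DT_MS))
    n_ms = n_steps // rec_stride

    def per_neuron(attr: str) -> np.ndarray:
        return np.concatenate(
            [np.full(10, getattr(ad, attr)), np.full(5, getattr(adm, attr))]
        )

    Ie = np.concatenate(
        [np.full(10, topology.I_e_scpg + ad.I_e), np.full(5, topology.I_e_mnp + adm.I_e)]
    )

    vth_base = per_neuron("V_th")
    vreset_base = per_neuron("V_reset")

    target_code = {
        "none": _core.TARGET_NONE,
        "V_th": _core.TARGET_VTH,
        "V_reset": _core.TARGET_VRESET,
        "V_m": _core.TARGET_VM,
    }[spec.voltage_target]
    if target_code == _core.TARGET_NONE:
        target_mask = np.zeros(_core.N_ADEX)
        vth_init, vreset_init = V_TH_DEFAULT, V_RESET_DEFAULT
    else:
        target_mask = _target_mask(spec.scpg_targets)
        if spec.polarity is CouplingPolarity.EXCITATORY:
            vth_init, vreset_init = -56.0, -41.0
        else:
            vth_init, vreset_init = V_TH_DEFAULT, V_RESET_DEFAULT
    char_dir = spec.polarity.sign

    inj_mask = np.zeros(_core.N_ADEX)
    if spec.scpg_injection != "none":
        inj_mask += _target_mask(spec.scpg_targets)
    if spec.mnp_injection != "none" or feedback is not None:
        inj_mask[10:15] = 1.0

    w_syn_per_ms = np.full(n_ms, float(spec.w_syn))
    nsi_I_per_ms = spec.input_schedule.per_ms(spec.duration)[:n_ms]
    if nsi_I_per_ms.size != n_ms:
        raise ValueError("input schedule does not cover the run duration")

    rng = np.random.default_rng(seed)
    noise_ad, noise_nsi = _draw_noise(rng, n_steps, noise)

    V0, w0 = _initial_state(topology)

    fb_on = feedback is not None
    fb = feedback or FeedbackConfig(desired_spike_number=0.0)

    out = _core._network_loop(
        n_steps,
        rec_stride,
        DT_MS,
        per_neuron("C"),
        per_neuron("g_L"),
        per_neuron("E_L"),
        per_neuron("Delta_T"),
        per_neuron("a"),
        per_neuron("b"),
        per_neuron("tau_w"),
        Ie,
        V0,
        w0,
        vth_base,
        vreset_base,
        target_code,
        target_mask,
        float(vth_init),
        float(vreset_init),
        float(char_dir),
        int(round(vm_apply_every_ms / DT_MS)),
        inj_mask,
        float(spec.polarity.sign),
        w_syn_per_ms,
        nsi_I_per_ms,
        topology.nsi.tau_m,
        topology.nsi.R_mv_per_pa,
        topology.nsi.V_rest,
        topology.nsi.guard_threshold,
        VCM_MAX_MV,
        topology.decay_matrix(DT_MS),
        int(round(topology.delay / DT_MS)),
        topology.pop_weight_matrix(),
        *topology.fast_bank(DT_MS),
        noise_ad,
        noise_nsi,
        fb_on,
        float(fb.desired_spike_number),
        float(fb.scaling_factor_excitatory),
        float(fb.scaling_factor_inhibitory),
        -1.0 if fb.weight_cap is None else float(fb.weight_cap),
        int(round(_rate_window_ms())),
    )
    (status, spike_steps, spike_counts, v_rec, vcm_rec, wsyn_rec, vth_rec, vreset_rec) = out

    if status == _core.STATUS_GUARD:
        raise SubthresholdContractError(
            "NSI crossed its guard threshold during the run"
        )
    if status == _core.STATUS_BLOWUP:
        raise IntegrationBlowupError(
            f"non-finite network state (dt={DT_MS} ms, spec={spec.label})"
        )

    times, ids = [], []
    for i in range(_core.N_ADEX):
        s = spike_steps[i, : spike_counts[i]]
        times.append(np.floor(s * DT_MS / RECORD_MS) * RECORD_MS)
        ids.append(np.full(s.size, i, dtype=np.int64))
    spikes = SpikeTrain(
        times=np.concatenate(times),
        neuron_ids=np.concatenate(ids),
        duration=spec.duration,
    )
    traces = {
        "t_ms": RECORD_MS * np.arange(n_ms),
        "V": v_rec[:, : _core.N_ADEX],
        "V_nsi": v_rec[:, _core.N_ADEX],
        "V_cm": vcm_rec,
        "w_syn_signed": wsyn_rec,
        "V_th_eff": vth_rec,
        "V_reset_eff": vreset_rec,
    }
    return SimResult(spikes=spikes, traces=traces, spec=spec, seed=seed)


def _rate_window_ms() -> float:
    from nsinet.codecs import RATE_WINDOW_MS

    return RATE_WINDOW_MS


def simulate(
    spec: ExperimentSpec,
    topology: NetworkTopology | None = None,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
) -> SimResult:
    """Run one clock-driven experiment.

    Deterministic for a fixed seed: all noise is pre-drawn from a
    ``numpy.random.default_rng(seed)`` stream.  ``seed`` falls back to
    ``spec.seed`` and then to 0.
    """
    topology = topology or NetworkTopology()
    noise = noise or NoiseConfig()
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    return _run(spec, topology, noise, int(seed))


def vth_drive_level(v_th: float, nsi: NSIParams | None = None) -> float:
    """NSI input current (pA) whose steady-state manipulation offset puts the
    excitatory V_th manipulation at ``v_th`` (clamped to the stable range)."""
    nsi = nsi or NSIParams()
    vcm = min(max(v_th - (-56.0), 0.0), VCM_MAX_MV)
    return 3.0 * vcm / nsi.R_mv_per_pa


def toggling_experiment(
    v_th_low: float = -54.9,
    v_th_high: float = -51.3,
    duration: float = DURATION_MS,
    constant_level: str = "high",
) -> tuple[ExperimentSpec, ExperimentSpec]:
    """Build the phase experiment: a run toggling between two burst
    frequencies every second versus a constant-frequency run.

    Frequency is set purely by an excitatory V_th manipulation of both
    half-centers (no current injection to the motor population), driven
    by NSI input levels that map to ``v_th_low`` / ``v_th_high``.  Both
    specs start at the same level, so same-seed runs are identical until
    the first toggle at t = 1 s and diverge afterwards.
    """
    hi, lo = vth_drive_level(v_th_high), vth_drive_level(v_th_low)
    n = int(round(duration / 1000.0))
    first = hi if constant_level == "high" else lo
    second = lo if constant_level == "high" else hi
    toggling = tuple(first if k % 2 == 0 else second for k in range(n))
    constant = tuple(first for _ in range(n))
    common = dict(
        test_no=7, subcategory=0, mnp_injection="none", scpg_injection="none",
        voltage_target="V_th", polarity=CouplingPolarity.EXCITATORY,
        scpg_targets="both", duration=duration,
    )
    spec_t = ExperimentSpec(
        input_schedule=InputSchedule(kind="toggling", step_interval=1000.0, levels=toggling),
        **common,
    )
    spec_c = ExperimentSpec(
        input_schedule=InputSchedule(kind="toggling", step_interval=1000.0, levels=constant),
        **common,
    )
    return spec_t, spec_c


def feedback_input_levels(
    v_th_low: float = -54.8,
    v_th_high: float = -51.0,
    n_divisions: int = 10,
) -> tuple[float, ...]:
    """NSI input levels whose manipulation offsets trace the closed-loop
    frequency schedule: V_th ramps from ``v_th_low`` up to ``v_th_high``
    over the first half of the divisions, holds, and ramps back down.
    """
    ramp = np.linspace(v_th_low, v_th_high, n_divisions // 2)
    vth = np.concatenate([ramp, ramp[::-1]])
    vcm = vth - (-56.0)  # excitatory V_th manipulation starts at -56 mV
    disp = 3.0 * vcm
    nsi = NSIParams()
    return tuple(float(d / nsi.R_mv_per_pa) for d in disp)


def run_feedback_loop(
    cfg: FeedbackConfig,
    topology: NetworkTopology | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    spec: ExperimentSpec | None = None,
    regulated: bool = True,
) -> tuple[SimResult, np.ndarray]:
    """Closed-loop amplitude regulation experiment.

    Every recording step the motor-population spike count of the latest
    rate window sets the NSI output conductance through the feedback rule
    (excitatory below the set point, inhibitory above); the resulting
    signed injection drives the MNP at the next step.  The burst
    frequency is swept by an excitatory V_th manipulation of both sCPG
    populations following a ramp-hold-ramp schedule of ten 1.2 s
    divisions.  With ``regulated=False`` the same run uses the fixed
    maximum conductance instead (the unregulated control).

    Returns the simulation result and the signed conductance trace (nS,
    one value per ms).
    """
    if spec is None:
        levels = feedback_input_levels()
        spec = ExperimentSpec(
            test_no=4,
            subcategory=0,
            mnp_injection="stepping",
            scpg_injection="none",
            voltage_target="V_th",
            polarity=CouplingPolarity.EXCITATORY,
            scpg_targets="both",
            duration=1200.0 * len(levels),
            input_schedule=InputSchedule(kind="feedback", step_interval=1200.0, levels=levels),
        )
    topology = topology or NetworkTopology()
    noise = noise or NoiseConfig()
    result = _run(spec, topology, noise, int(seed), feedback=cfg if regulated else None)
    return result, result.traces["w_syn_signed"]
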