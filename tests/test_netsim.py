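"""Network assembly and clock-driven simulation."""

import numpy as np
import pytest

from conftest import static_spec
from nsinet import _core
from nsinet.coupling import CouplingPolarity
from nsinet.codecs import rate_code
from nsinet.analysis import detect_peaks, phase_shift
from nsinet.neurons import AdExParams, AdExState, NSIParams, SubthresholdContractError, adex_step
from nsinet.netsim import (
    ExperimentSpec,
    InputSchedule,
    NetworkTopology,
    NoiseConfig,
    SpikeTrain,
    build_experiment,
    simulate,
    toggling_experiment,
)


class TestExperimentMatrix:
    def test_baseline_stepping_cell(self):
        spec = build_experiment(1, 0)
        assert spec.mnp_injection == "stepping"
        assert spec.scpg_injection == "none"
        assert spec.voltage_target == "none"
        assert spec.polarity is CouplingPolarity.EXCITATORY
        assert spec.input_schedule.direction == "up"

    def test_vth_only_inhibitory_cell(self):
        spec = build_experiment(7, 3)
        assert spec.mnp_injection == "none"
        assert spec.scpg_injection == "none"
        assert spec.voltage_target == "V_th"
        assert spec.polarity is CouplingPolarity.INHIBITORY
        assert spec.scpg_targets == "both"
        assert spec.input_schedule.direction == "down"

    @pytest.mark.parametrize("tn,sub", [(13, 0), (0, 0), (1, 6), (1, -1)])
    def test_out_of_range_rejected(self, tn, sub):
        with pytest.raises(ValueError):
            build_experiment(tn, sub)

    def test_total_over_valid_matrix(self):
        targets = {0: "both", 1: "excitatory_pop", 2: "inhibitory_pop"}
        for tn in range(1, 13):
            for sub in range(6):
                spec = build_experiment(tn, sub)
                assert spec.scpg_targets == targets[sub % 3]
                assert (spec.polarity is CouplingPolarity.EXCITATORY) == (sub <= 2)

    def test_stepping_increment(self):
        levels = InputSchedule(kind="stepping").resolve_levels(6000.0)
        assert np.allclose(np.diff(levels), 29.6)
        assert levels[0] == 0.0 and levels[-1] == 148.0
        down = InputSchedule(kind="stepping", direction="down").resolve_levels(6000.0)
        assert np.allclose(down, levels[::-1])


class TestSimulate:
    def test_determinism_bit_identical(self, topology):
        spec = build_experiment(1, 0)
        a = simulate(spec, topology=topology, seed=5)
        b = simulate(spec, topology=topology, seed=5)
        assert np.array_equal(a.spikes.times, b.spikes.times)
        assert np.array_equal(a.spikes.neuron_ids, b.spikes.neuron_ids)
        assert np.array_equal(a.traces["V"], b.traces["V"])

    def test_spike_train_invariants(self, baseline_run):
        st = baseline_run.spikes
        assert st.times.min() >= 0.0 and st.times.max() <= st.duration
        for nid in range(15):
            t = st.for_neuron(nid)
            assert np.all(np.diff(t) >= 0)
        assert st.count() == sum(st.count(p) for p in st.populations)

    def test_sixteen_neurons(self, topology):
        assert topology.n_neurons == 16
        kinds = {c[2] for c in topology.connections()}
        assert kinds == {"spiking_synapse", "current_injection", "voltage_manipulation"}
        # the motor population never receives voltage manipulation
        assert not any(c[1] == "mnp" and c[2] == "voltage_manipulation" for c in topology.connections())

    def test_antiphase_half_centers(self, baseline_run):
        rse = rate_code(baseline_run.spikes.for_population("excitatory"), duration=6000.0)
        rsi = rate_code(baseline_run.spikes.for_population("inhibitory"), duration=6000.0)
        pe = detect_peaks(rse, min_separation=40.0).in_segment(1000, 6000)
        pi = detect_peaks(rsi, min_separation=40.0).in_segment(1000, 6000)
        period = float(np.median(np.diff(pe.times)))
        shift = phase_shift(pe, pi, period)
        assert 160.0 <= shift <= 200.0

    def test_numba_and_python_cores_agree(self, topology):
        spec = ExperimentSpec(
            test_no=1, subcategory=0, mnp_injection="constant", scpg_injection="none",
            voltage_target="V_th", polarity=CouplingPolarity.EXCITATORY,
            scpg_targets="both", duration=500.0,
            input_schedule=InputSchedule(kind="constant", I_max=100.0, step_interval=500.0),
        )
        compiled = _core._network_loop
        try:
            res_jit = simulate(spec, topology=topology, seed=2)
            _core._network_loop = _core._network_loop_py
            res_py = simulate(spec, topology=topology, seed=2)
        finally:
            _core._network_loop = compiled
        assert np.array_equal(res_jit.spikes.times, res_py.spikes.times)
        assert np.allclose(res_jit.traces["V"], res_py.traces["V"], rtol=1e-12, atol=1e-12)

    def test_uncoupled_neuron_matches_scalar_steps(self):
        # with all synapses and noise off, a motor neuron is exactly the
        # scalar AdEx iteration under its bias current
        adex_mnp = AdExParams(C=48.0, b=50.0, tau_w=5.0, V_reset=-56.0)
        topo = NetworkTopology(
            w_cc=-1e-9, w_exc_mnp=0.0, w_inh_mnp=0.0, I_e_mnp=300.0, adex_mnp=adex_mnp
        )
        noise = NoiseConfig(nsi_std=0.0, neuron_std=0.0)
        spec = static_spec(0.0, inject=False, duration=300.0, I_input=0.0)
        res = simulate(spec, topology=topo, noise=noise, seed=0)
        state = AdExState(V_m=topo.adex.E_L)
        trace = [state.V_m]
        spikes = []
        for k in range(3000):
            state, spiked = adex_step(state, adex_mnp, 0.1, I_ext=300.0)
            if spiked:
                spikes.append(np.floor(k * 0.1))
            if (k + 1) % 10 == 0:
                trace.append(state.V_m)
        assert np.allclose(res.traces["V"][:, 10], trace[:300], rtol=1e-10)
        assert np.array_equal(res.spikes.for_neuron(10), np.array(spikes))

    def test_nsi_trace_matches_scalar_steps(self, topology):
        from nsinet.neurons import NSIState, nsi_step

        noise = NoiseConfig(nsi_std=0.0, neuron_std=0.0)
        spec = static_spec(0.0, inject=False, duration=200.0, I_input=148.0)
        res = simulate(spec, topology=topology, noise=noise, seed=0)
        p = topology.nsi
        s = NSIState(V_m=p.V_rest)
        trace = [s.V_m]
        for k in range(2000):
            s = nsi_step(s, p, 0.1, I_input=148.0)
            if (k + 1) % 10 == 0:
                trace.append(s.V_m)
        assert np.allclose(res.traces["V_nsi"], trace[:200], rtol=1e-10)

    def test_guard_violation_surfaces(self, topology):
        import dataclasses

        topo = dataclasses.replace(topology, nsi=NSIParams(guard_threshold=-58.0))
        with pytest.raises(SubthresholdContractError):
            simulate(static_spec(0.0, inject=False, duration=1000.0), topology=topo, seed=0)


class TestSpikeTrainIO:
    def test_text_round_trip(self, baseline_run, tmp_path):
        st = baseline_run.spikes
        st.write_text(tmp_path)
        paths = sorted(tmp_path.glob("spikes_*.txt"))
        assert len(paths) == 3
        back = SpikeTrain.read_text(paths, duration=st.duration)
        assert back.count() == st.count()
        for p in st.populations:
            assert np.array_equal(back.for_population(p), st.for_population(p))


class TestTogglingExperiment:
    def test_same_seed_identical_then_diverging(self, topology):
        spec_t, spec_c = toggling_experiment()
        rt = simulate(spec_t, topology=topology, seed=3)
        rc = simulate(spec_c, topology=topology, seed=3)
        t_first = rt.spikes.times[rt.spikes.times < 1000.0]
        c_first = rc.spikes.times[rc.spikes.times < 1000.0]
        assert np.array_equal(np.sort(t_first), np.sort(c_first))
        after_t = rate_code(rt.spikes.for_population("mnp"), duration=6000.0).values[1100:]
        after_c = rate_code(rc.spikes.for_population("mnp"), duration=6000.0).values[1100:]
        assert not np.array_equal(after_t, after_c)
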