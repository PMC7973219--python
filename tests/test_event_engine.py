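"""Event-driven NSI, asynchronous reconstruction, and the two-neuron demo."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsinet.codecs import bsa_encode, make_step_signal
from nsinet.event_engine import (
    EventNSIState,
    OutOfOrderEventError,
    VthMapping,
    event_update,
    map_vm_to_vth,
    reconstruct_vm,
    run_event_demo,
)


class TestEventUpdate:
    def test_zero_interval_zero_input_unchanged(self):
        s = EventNSIState(V_m=-50.0, t_updated=10.0)
        s2 = event_update(s, 10.0, 0.0)
        assert s2.V_m == pytest.approx(-50.0)
        assert s2.t_updated == 10.0

    def test_long_interval_decays_to_rest(self):
        s = EventNSIState(V_m=-45.0)
        s2 = event_update(s, 5000.0, 0.0)
        assert s2.V_m == pytest.approx(s.V_rest, abs=1e-9)

    def test_out_of_order_event_rejected(self):
        s = EventNSIState(V_m=-50.0, t_updated=10.0)
        with pytest.raises(OutOfOrderEventError):
            event_update(s, 9.0, 1.0)

    def test_charge_increment(self):
        s = EventNSIState(V_m=-60.0, C=200.0)
        s2 = event_update(s, 0.0, 400.0)
        assert s2.V_m == pytest.approx(-58.0)  # 400 / 200 = 2 mV kick

    def test_matches_exact_decay_with_impulse_drive(self):
        # event chain vs a fine-step clock integration where each event's
        # charge is delivered as a one-step current pulse
        tau_m = 20.0
        dt = 0.01
        state = EventNSIState(V_m=-60.0, decay=math.exp(-1.0 / tau_m), C=200.0)
        events = [(3.0, 500.0), (7.5, 300.0), (20.0, 800.0), (40.0, 0.0)]
        for t, q in events:
            state = event_update(state, t, q)
        # clock oracle
        v = -60.0
        ev = dict(events)
        n = int(40.0 / dt) + 1
        for k in range(n):
            t = k * dt
            q = ev.pop(round(t, 6), 0.0) if round(t, 6) in ev else 0.0
            I = q / dt  # pA such that I*dt/C = q/C
            v = v + (-(v + 60.0) + 0.0) * (dt / tau_m) + I * dt / 200.0
        assert state.V_m == pytest.approx(v, abs=2e-3)


class TestReconstruct:
    def test_snapshot_time_returns_stored_vm(self):
        s = EventNSIState(V_m=-47.0, t_updated=12.0)
        assert reconstruct_vm(s, 12.0) == -47.0

    def test_rest_is_fixed_point(self):
        s = EventNSIState(V_m=-60.0, t_updated=0.0)
        assert reconstruct_vm(s, 123.4) == pytest.approx(-60.0)

    def test_before_snapshot_rejected(self):
        with pytest.raises(OutOfOrderEventError):
            reconstruct_vm(EventNSIState(V_m=-50.0, t_updated=5.0), 4.0)

    @given(st.floats(-60.0, -45.0), st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    @settings(deadline=None)
    def test_semigroup_property(self, v0, dt1, dt2):
        s = EventNSIState(V_m=v0, t_updated=0.0)
        v_two_step = reconstruct_vm(
            EventNSIState(V_m=reconstruct_vm(s, dt1), t_updated=dt1), dt1 + dt2
        )
        v_one_step = reconstruct_vm(s, dt1 + dt2)
        assert v_two_step == pytest.approx(v_one_step, abs=1e-9)

    def test_matches_fine_step_clock_decay(self):
        # pure decay reconstruction vs Euler at dt = 0.01 ms; error
        # relative to the initial displacement stays below 1e-4
        tau_m = 20.0
        s = EventNSIState(V_m=-45.0, decay=math.exp(-1.0 / tau_m))
        dt = 0.01
        v = -45.0
        worst = 0.0
        for k in range(1, 10001):
            v = v + (-(v + 60.0)) * (dt / tau_m)
            worst = max(worst, abs(reconstruct_vm(s, k * dt) - v) / 15.0)
        assert worst < 1e-4


class TestVthMapping:
    def test_endpoints_and_midpoint(self):
        m = VthMapping()
        assert map_vm_to_vth(m, m.V_m_low) == m.V_th_low
        assert map_vm_to_vth(m, m.V_m_high) == m.V_th_high
        mid = 0.5 * (m.V_m_low + m.V_m_high)
        assert map_vm_to_vth(m, mid) == pytest.approx(0.5 * (m.V_th_low + m.V_th_high))

    def test_clamped_outside_range(self):
        m = VthMapping()
        assert map_vm_to_vth(m, -100.0) == m.V_th_low
        assert map_vm_to_vth(m, 0.0) == m.V_th_high

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            VthMapping(V_m_low=-45.0, V_m_high=-60.0)


@pytest.fixture(scope="module")
def step_demo():
    sig = make_step_signal([0.2, 1.0], 3000.0)
    return run_event_demo(bsa_encode(sig), duration=6000.0)


class TestEventDemo:
    def test_zero_input_vth_stays_low(self):
        res = run_event_demo(np.empty(0), duration=500.0)
        assert np.allclose(res.vth_left, VthMapping().V_th_low)

    def test_vth_tracks_nsi_membrane_potential(self, step_demo):
        m = VthMapping()
        expected = np.clip(step_demo.nsi_vm, m.V_m_low, m.V_m_high)
        expected = m.V_th_low + (expected - m.V_m_low) / (m.V_m_high - m.V_m_low) * (
            m.V_th_high - m.V_th_low
        )
        assert np.allclose(step_demo.vth_left, expected, atol=0.2)

    def test_left_right_vth_identical(self, step_demo):
        assert np.array_equal(step_demo.vth_left, step_demo.vth_right)

    def test_burst_frequency_rises_after_input_step(self, step_demo):
        def bursts(times, lo, hi):
            t = times[(times >= lo) & (times < hi)]
            return 0 if t.size == 0 else 1 + int(np.sum(np.diff(t) > 20.0))

        early = bursts(step_demo.spikes_left, 500.0, 2500.0) / 2.0
        late = bursts(step_demo.spikes_left, 4000.0, 6000.0) / 2.0
        assert late > early

    def test_antiphase_bursting(self, step_demo):
        def onsets(times):
            keep = [times[0]]
            for a, b in zip(times[:-1], times[1:]):
                if b - a > 20.0:
                    keep.append(b)
            return np.array(keep)

        ol = onsets(step_demo.spikes_left)
        orr = onsets(step_demo.spikes_right)
        period = np.median(np.diff(ol[-8:]))
        offsets = np.array([np.min(np.abs(orr - t)) for t in ol[3:]])
        frac = np.median(offsets) / period
        assert 0.35 <= frac <= 0.65  # half a period apart

    def test_synapses_only_see_snapshots(self, step_demo):
        kinds = {m.kind for m in step_demo.event_log}
        assert kinds == {"spike", "parameter_update"}
        updates = [m for m in step_demo.event_log if m.kind == "parameter_update"]
        assert all(m.payload is not None for m in updates)
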