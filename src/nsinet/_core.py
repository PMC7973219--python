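"""Inner integration loop of the clock-driven network engine.

The whole 16-neuron network (three populations of five AdEx neurons plus
one non-spiking interneuron) is advanced with explicit Euler at a fixed
step (0.1 ms by default).  The loop is written as a plain-NumPy function
and compiled with numba; ``_network_loop_py`` (the uncompiled version) is
kept callable so the two can be cross-checked bit-for-bit.

Population layout (fixed): neurons 0-4 excitatory CPG population,
5-9 inhibitory CPG population, 10-14 motor population (MNP).

Spiking synapses are current-based with exponential decay; because
connectivity is all-to-all between populations with uniform weights, the
synaptic current is tracked per *target population* and incremented by
the delayed per-population spike counts, which is exact.

Status codes returned by the loop: 0 = ok, 1 = NSI guard-threshold
violation (sub-threshold contract broken), 2 = non-finite state
(integration blow-up).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco(args[0]) if args and callable(args[0]) else deco


N_ADEX = 15
N_PER_POP = 5
N_POPS = 3
POP_EXC, POP_INH, POP_MNP = 0, 1, 2

TARGET_NONE, TARGET_VTH, TARGET_VRESET, TARGET_VM = 0, 1, 2, 3

STATUS_OK, STATUS_GUARD, STATUS_BLOWUP = 0, 1, 2

_EXP_ARG_MAX = 20.0


def _network_loop_py(
    n_steps,
    rec_stride,
    dt,
    # AdEx parameter arrays, shape (15,)
    C,
    gL,
    EL,
    DT,
    a_ad,
    b_ad,
    tau_w,
    Ie,
    V0,
    w0,
    vth_base,
    vreset_base,
    # voltage-characteristic manipulation
    target_code,
    target_mask,
    vth_init,
    vreset_init,
    char_dir,
    vm_apply_stride,
    # graded current injection
    inj_mask,
    inj_sign,
    w_syn_per_ms,
    # NSI
    nsi_I_per_ms,
    tau_m,
    R_gohm,
    v_rest,
    guard,
    vcm_max,
    # spiking synapses (two banks: e.g. fast and slow components)
    decay_pp,
    delay_steps,
    Wpp,
    decay_pp2,
    Wpp2,
    # pre-drawn noise, already scaled to pA
    noise_ad,
    noise_nsi,
    # feedback regulation
    fb_on,
    fb_desired,
    fb_scale_exc,
    fb_scale_inh,
    fb_cap,
    fb_window_ms,
):
    n_ms = n_steps // rec_stride
    v_rec = np.empty((n_ms, N_ADEX + 1))
    vcm_rec = np.empty(n_ms)
    wsyn_rec = np.empty(n_ms)
    vth_rec = np.empty(n_ms)
    vreset_rec = np.empty(n_ms)

    max_spk = n_steps // 2 + 2
    spike_steps = np.zeros((N_ADEX, max_spk), dtype=np.int64)
    spike_counts = np.zeros(N_ADEX, dtype=np.int64)
    mnp_ms_counts = np.zeros(n_ms + 1, dtype=np.int64)

    V = V0.copy()
    W = w0.copy()
    u = 0.0  # NSI displacement from rest
    I_syn = np.zeros((N_POPS, N_POPS))  # [source pop, target pop]
    I_syn2 = np.zeros((N_POPS, N_POPS))
    I_syn_tot = np.zeros(N_POPS)
    ring = np.zeros((delay_steps, N_POPS))
    ring_pos = 0

    w_now = w_syn_per_ms[0]
    sign_now = inj_sign
    status = STATUS_OK

    for t in range(n_steps):
        m = t // rec_stride
        if t % rec_stride == 0:
            ok = True
            for i in range(N_ADEX):
                if not (np.isfinite(V[i]) and np.isfinite(W[i])):
                    ok = False
            if not ok:
                status = STATUS_BLOWUP
                break
            for i in range(N_ADEX):
                v_rec[m, i] = V[i]
            v_rec[m, N_ADEX] = v_rest + u
            if fb_on:
                lo = m - fb_window_ms
                if lo < 0:
                    lo = 0
                cnt = 0
                for k in range(lo, m):
                    cnt += mnp_ms_counts[k]
                err = fb_desired - cnt
                if err > 0.0:
                    w_now = fb_scale_exc * err
                    sign_now = 1.0
                else:
                    w_now = fb_scale_inh * (-err)
                    sign_now = -1.0
                if fb_cap >= 0.0 and w_now > fb_cap:
                    w_now = fb_cap
            else:
                w_now = w_syn_per_ms[m]
                sign_now = inj_sign
            wsyn_rec[m] = sign_now * w_now

        # --- non-spiking interneuron ---
        I_nsi = nsi_I_per_ms[m] + noise_nsi[t]
        u = u + (-u + R_gohm * I_nsi) * (dt / tau_m)
        if v_rest + u > guard:
            status = STATUS_GUARD
            break
        disp = abs(u)
        vcm_mag = disp / 3.0
        if vcm_mag > vcm_max:
            vcm_mag = vcm_max
        I_inj = sign_now * w_now * disp

        # effective voltage characteristics of the targeted neurons
        vth_t = vth_init + char_dir * vcm_mag if target_code == TARGET_VTH else 0.0
        vreset_t = vreset_init - char_dir * vcm_mag if target_code == TARGET_VRESET else 0.0
        if t % rec_stride == 0:
            vcm_rec[m] = char_dir * vcm_mag
            vth_rec[m] = vth_t if target_code == TARGET_VTH else vth_base[0]
            vreset_rec[m] = vreset_t if target_code == TARGET_VRESET else vreset_base[0]

        apply_vm = target_code == TARGET_VM and (t % vm_apply_stride == 0)

        # --- AdEx populations ---
        c_exc = 0.0
        c_inh = 0.0
        c_mnp = 0.0
        for i in range(N_ADEX):
            p = i // N_PER_POP
            manipulated = target_mask[i] > 0.5
            if target_code == TARGET_VTH and manipulated:
                vth_i = vth_t
            else:
                vth_i = vth_base[i]
            if target_code == TARGET_VRESET and manipulated:
                vreset_i = vreset_t
            else:
                vreset_i = vreset_base[i]

            v = V[i]
            w = W[i]
            I_tot = Ie[i] + noise_ad[t, i] + I_syn_tot[p] + inj_mask[i] * I_inj
            ea = (v - vth_i) / DT[i]
            if ea > _EXP_ARG_MAX:
                ea = _EXP_ARG_MAX
            v_new = v + (
                -gL[i] * (v - EL[i]) + gL[i] * DT[i] * np.exp(ea) - w + I_tot
            ) * (dt / C[i])
            if v_new > 0.0:
                spike_steps[i, spike_counts[i]] = t
                spike_counts[i] += 1
                v_new = vreset_i
                w = w + b_ad[i]
                if p == POP_EXC:
                    c_exc += 1.0
                elif p == POP_INH:
                    c_inh += 1.0
                else:
                    c_mnp += 1.0
                    mnp_ms_counts[m] += 1
            else:
                w = w + (a_ad[i] * (v - EL[i]) - w) * (dt / tau_w[i])
            if apply_vm and manipulated:
                v_new += char_dir * vcm_mag
            V[i] = v_new
            W[i] = w

        # --- delayed current-based synapses (per source/target pair) ---
        for q in range(N_POPS):
            tot = 0.0
            for p in range(N_POPS):
                I_syn[p, q] = I_syn[p, q] * decay_pp[p, q] + ring[ring_pos, p] * Wpp[p, q]
                I_syn2[p, q] = I_syn2[p, q] * decay_pp2[p, q] + ring[ring_pos, p] * Wpp2[p, q]
                tot += I_syn[p, q] + I_syn2[p, q]
            I_syn_tot[q] = tot
        ring[ring_pos, POP_EXC] = c_exc
        ring[ring_pos, POP_INH] = c_inh
        ring[ring_pos, POP_MNP] = c_mnp
        ring_pos += 1
        if ring_pos == delay_steps:
            ring_pos = 0

    return (
        status,
        spike_steps,
        spike_counts,
        v_rec,
        vcm_rec,
        wsyn_rec,
        vth_rec,
        vreset_rec,
    )


if _HAVE_NUMBA:
    _network_loop = njit(cache=True)(_network_loop_py)
else:  # pragma: no cover
    _network_loop = _network_loop_py
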