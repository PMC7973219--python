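"""Clock-driven single-neuron dynamics.

Two neuron models are used throughout the package:

* The adaptive exponential integrate-and-fire (AdEx) neuron,

  .. math::

      C \\frac{dV_m}{dt} &= -g_L (V_m - E_L)
                            + g_L \\Delta_T e^{(V_m - V_{th})/\\Delta_T}
                            - w + I_e, \\\\
      \\tau_w \\frac{dw}{dt} &= a (V_m - E_L) - w,

  with the reset rule: when :math:`V_m > 0\\,\\mathrm{mV}` then
  :math:`V_m \\to V_{reset}` and :math:`w \\to w + b`.  Spike detection is
  deliberately at 0 mV rather than at ``V_th``: ``V_th`` only parameterises
  the exponential upstroke, which lets ``V_reset`` sit *above* ``V_th`` —
  the configuration that produces multi-spike bursts.

* A leaky integrator used as a non-spiking interneuron (NSI),

  .. math::  \\tau_m \\frac{du}{dt} = -u + R I_{input},

  written in displacement coordinates :math:`u = V_m - V_{rest}`.  Its
  threshold is set high enough that it never spikes; it communicates only
  through its graded membrane potential (see :mod:`nsinet.coupling`).

Both models are integrated with explicit Euler; the default step used by
the network engine is 0.1 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "AdExParams",
    "AdExState",
    "NSIParams",
    "NSIState",
    "IntegrationBlowupError",
    "SubthresholdContractError",
    "adex_step",
    "nsi_step",
]

#: Spike-detection voltage (mV).  Fixed: the reset rule fires when the
#: membrane potential exceeds 0 mV, not when it crosses V_th.
SPIKE_CUTOFF_MV = 0.0

# Exponent clamp for the AdEx upstroke term.  Once the argument exceeds
# this the neuron is far past the spike cutoff anyway; the clamp only
# prevents floating-point overflow inside a single Euler step.
_EXP_ARG_MAX = 20.0


class IntegrationBlowupError(RuntimeError):
    """Raised when a state variable becomes non-finite during integration."""


class SubthresholdContractError(RuntimeError):
    """Raised when the non-spiking interneuron crosses its guard threshold."""


@dataclass(frozen=True)
class AdExParams:
    """AdEx neuron parameters.

    Defaults follow the regular-bursting parameter set of Naud et al.'s
    AdEx taxonomy, with the threshold / reset pair used by the
    pattern-generator network (V_reset above V_th).
    """

    C: float = 200.0        # membrane capacitance, pF
    g_L: float = 10.0       # leak conductance, nS
    E_L: float = -58.0      # resting potential, mV
    Delta_T: float = 2.0    # sharpness factor, mV
    V_th: float = -51.0     # exponential-onset threshold, mV
    V_reset: float = -46.0  # post-spike reset, mV (above V_th -> bursting)
    a: float = 2.0          # sub-threshold adaptation conductance, nS
    b: float = 100.0        # spike-triggered adaptation increment, pA
    tau_w: float = 120.0    # adaptation time constant, ms
    I_e: float = 0.0        # constant bias current, pA
    spike_cutoff: float = SPIKE_CUTOFF_MV  # mV, fixed

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.g_L > 0 and self.tau_w > 0 and self.Delta_T > 0):
            raise ValueError("AdExParams requires C, g_L, tau_w, Delta_T > 0")
        if self.spike_cutoff != SPIKE_CUTOFF_MV:
            raise ValueError("spike_cutoff is fixed at 0 mV (reset fires when V_m > 0 mV)")


@dataclass(frozen=True)
class AdExState:
    """Dynamic state of one AdEx neuron.

    ``w_adapt`` is the spike-adaptation current (pA); it is named
    ``w_adapt`` to keep it distinct from the synaptic conductance weight
    ``w`` of the graded coupling rules.
    """

    V_m: float   # mV
    w_adapt: float = 0.0  # pA


@dataclass(frozen=True)
class NSIParams:
    """Parameters of the non-spiking leaky-integrator interneuron.

    ``R`` defaults to 15/148 GOhm (~101.35 MOhm) so that the steady-state
    displacement at the maximum input current of 148 pA is exactly the
    biologically plausible 15 mV fluctuation range.  ``tau_m`` is a
    configuration choice (20 ms, the leak time constant of the AdEx set).
    """

    tau_m: float = 20.0            # membrane time constant, ms
    R: float = 15.0 / 148.0 * 1e3  # membrane resistance, MOhm
    V_rest: float = -60.0          # rest potential, mV
    guard_threshold: float = -30.0  # contract-violation voltage, mV

    def __post_init__(self) -> None:
        if not (self.tau_m > 0 and self.R > 0):
            raise ValueError("NSIParams requires tau_m > 0 and R > 0")

    @property
    def R_mv_per_pa(self) -> float:
        """Resistance expressed so that R * I[pA] is in mV (i.e. GOhm)."""
        return self.R * 1e-3


@dataclass(frozen=True)
class NSIState:
    """Dynamic state of the non-spiking interneuron (membrane potential only)."""

    V_m: float  # mV


def adex_step(
    state: AdExState,
    params: AdExParams,
    dt: float,
    I_ext: float = 0.0,
    V_cm_target: str = "none",
    V_cm: float = 0.0,
) -> tuple[AdExState, bool]:
    """Advance one AdEx neuron by a single explicit-Euler step.

    Parameters
    ----------
    dt : float
        Integration step in ms (> 0).
    I_ext : float
        External current in pA added to the bias ``params.I_e`` (synaptic
        input, noise, graded injection).
    V_cm_target : {"none", "V_th", "V_reset", "V_m"}
        Which voltage characteristic the manipulation offset ``V_cm``
        applies to.  ``V_th``/``V_reset`` shift the effective value used
        this step; ``V_m`` adds the offset to the membrane potential after
        the integration (and any reset) of this step.
    V_cm : float
        Manipulation offset in mV.

    Returns
    -------
    (AdExState, bool)
        The updated state and a flag that is True if the neuron spiked
        (pre-reset membrane potential exceeded 0 mV).  On a spike the
        membrane potential is set to the effective reset value and
        ``w_adapt`` jumps by ``b`` (the spike event replaces the Euler
        update of the adaptation current for that step).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not math.isfinite(V_cm):
        raise ValueError("V_cm must be finite")

    v_th_eff = params.V_th + (V_cm if V_cm_target == "V_th" else 0.0)
    v_reset_eff = params.V_reset + (V_cm if V_cm_target == "V_reset" else 0.0)

    v, w = state.V_m, state.w_adapt
    exp_arg = min((v - v_th_eff) / params.Delta_T, _EXP_ARG_MAX)
    dv = (
        -params.g_L * (v - params.E_L)
        + params.g_L * params.Delta_T * math.exp(exp_arg)
        - w
        + params.I_e
        + I_ext
    ) * (dt / params.C)
    v_new = v + dv

    spiked = v_new > params.spike_cutoff
    if spiked:
        v_new = v_reset_eff
        w_new = w + params.b
    else:
        w_new = w + (params.a * (v - params.E_L) - w) * (dt / params.tau_w)

    if V_cm_target == "V_m":
        v_new += V_cm

    if not (math.isfinite(v_new) and math.isfinite(w_new)):
        raise IntegrationBlowupError(
            f"AdEx state non-finite after step (dt={dt} ms, params={params})"
        )
    return AdExState(V_m=v_new, w_adapt=w_new), spiked


def nsi_step(
    state: NSIState,
    params: NSIParams,
    dt: float,
    I_input: float,
) -> NSIState:
    """Advance the non-spiking interneuron by one explicit-Euler step.

    The RC dynamics are integrated in displacement coordinates
    ``u = V_m - V_rest``; the returned membrane potential relaxes
    exponentially toward ``V_rest + R * I_input``.

    Raises
    ------
    SubthresholdContractError
        If the membrane potential exceeds the guard threshold; the NSI
        must stay sub-threshold for the graded coupling to be valid.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    u = state.V_m - params.V_rest
    u = u + (-u + params.R_mv_per_pa * I_input) * (dt / params.tau_m)
    v_new = params.V_rest + u
    if v_new > params.guard_threshold:
        raise SubthresholdContractError(
            f"NSI membrane potential {v_new:.2f} mV crossed the guard "
            f"threshold {params.guard_threshold:.2f} mV"
        )
    return NSIState(V_m=v_new)
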