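"""Graded communication rules from the non-spiking interneuron (NSI).

The NSI never spikes; everything it tells the rest of the network is a
function of the displacement of its membrane potential from rest,
``d = |V_rest - V_m|`` (at most the biologically plausible 15 mV).  Three
rules are defined:

voltage-characteristic manipulation
    An offset ``V_cm = d / 3`` (at most 5 mV, the range known to keep the
    pattern generator stable) applied to the post-synaptic ``V_th``,
    ``V_reset`` or ``V_m``.  The targeted characteristic starts from a
    polarity-specific initial value and the offset moves it *toward* the
    network default (-51 / -46 mV), shrinking ``|V_th - V_reset|`` for
    excitatory drive and growing it for inhibitory drive — which is what
    raises or lowers the burst frequency.

graded current injection
    ``I_injection = w * d`` (nS * mV = pA), signed positive for excitatory
    and negative for inhibitory coupling, added to the post-synaptic bias
    current.

feedback-regulated conductance
    ``w = scaling_factor * (desired - current)`` spikes in the latest rate
    window; inhibitory when the output overshoots the set point,
    excitatory when it undershoots.  This replaces the fixed maximum
    conductance in the closed-loop amplitude-regulation network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "CouplingPolarity",
    "VoltageManipulation",
    "FeedbackConfig",
    "CouplingRangeWarning",
    "voltage_characteristic_offset",
    "injection_current",
    "effective_voltage_characteristic",
    "feedback_weight",
    "V_TH_DEFAULT",
    "V_RESET_DEFAULT",
    "VCM_DIVISOR",
    "VCM_MAX_MV",
    "DISPLACEMENT_RANGE_MV",
]

#: Voltage characteristics of an unmanipulated pattern-generator neuron (mV).
V_TH_DEFAULT = -51.0
V_RESET_DEFAULT = -46.0

#: Divisor mapping the 15 mV NSI fluctuation range onto the 5 mV
#: manipulation range known to be stable.
VCM_DIVISOR = 3.0
DISPLACEMENT_RANGE_MV = 15.0
VCM_MAX_MV = DISPLACEMENT_RANGE_MV / VCM_DIVISOR


class CouplingRangeWarning(UserWarning):
    """NSI displacement outside the biologically plausible range."""


class CouplingPolarity(str, Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"

    @property
    def sign(self) -> float:
        """+1 for excitatory coupling, -1 for inhibitory."""
        return 1.0 if self is CouplingPolarity.EXCITATORY else -1.0


@dataclass(frozen=True)
class VoltageManipulation:
    """Which voltage characteristic is manipulated and from which initial values.

    Excitatory tests start the targeted characteristic displaced 5 mV away
    from the default (V_th at -56, V_reset at -41) so that the full
    manipulation range ends exactly at the default; inhibitory tests start
    at the defaults and are pushed away.
    """

    target: str  # "V_th" | "V_reset" | "V_m"
    V_th_initial: float = V_TH_DEFAULT
    V_reset_initial: float = V_RESET_DEFAULT

    def __post_init__(self) -> None:
        if self.target not in ("V_th", "V_reset", "V_m"):
            raise ValueError(f"unknown manipulation target {self.target!r}")

    @classmethod
    def for_polarity(cls, target: str, polarity: CouplingPolarity) -> "VoltageManipulation":
        """Initial values for an excitatory or inhibitory test of ``target``."""
        if polarity is CouplingPolarity.EXCITATORY:
            return cls(target=target, V_th_initial=-56.0, V_reset_initial=-41.0)
        return cls(target=target, V_th_initial=V_TH_DEFAULT, V_reset_initial=V_RESET_DEFAULT)


@dataclass(frozen=True)
class FeedbackConfig:
    """Configuration of the closed-loop amplitude regulator."""

    desired_spike_number: float
    scaling_factor_excitatory: float = 2.0
    scaling_factor_inhibitory: float = 50.0
    weight_cap: float | None = None  # nS; None = no clamp

    def __post_init__(self) -> None:
        if self.scaling_factor_excitatory <= 0 or self.scaling_factor_inhibitory <= 0:
            raise ValueError("scaling factors must be > 0")
        if self.desired_spike_number < 0:
            raise ValueError("desired_spike_number must be >= 0")


def voltage_characteristic_offset(
    V_rest: float,
    V_m: float,
    polarity: CouplingPolarity,
    strict: bool = False,
) -> float:
    """Offset (mV) applied to a post-synaptic voltage characteristic.

    Magnitude is ``|V_rest - V_m| / 3``, signed by polarity (positive for
    excitatory, negative for inhibitory).  Displacements beyond the 15 mV
    biological range are clamped with a warning, or rejected when
    ``strict`` is set.
    """
    displacement = abs(V_rest - V_m)
    if displacement > DISPLACEMENT_RANGE_MV:
        if strict:
            raise ValueError(
                f"NSI displacement {displacement:.2f} mV outside the "
                f"{DISPLACEMENT_RANGE_MV:.0f} mV biological range"
            )
        warnings.warn(
            f"NSI displacement {displacement:.2f} mV outside the "
            f"{DISPLACEMENT_RANGE_MV:.0f} mV range; offset clamped",
            CouplingRangeWarning,
            stacklevel=2,
        )
        displacement = DISPLACEMENT_RANGE_MV
    return polarity.sign * displacement / VCM_DIVISOR


def injection_current(
    w_syn: float,
    V_rest: float,
    V_m: float,
    polarity: CouplingPolarity,
) -> float:
    """Graded current (pA) injected into a post-synaptic neuron.

    ``I = w * |V_rest - V_m|`` with ``w`` in nS and voltages in mV
    (nS * mV = pA), signed by polarity.  The result is added to the
    post-synaptic neuron's bias current.
    """
    if w_syn < 0:
        raise ValueError("synaptic conductance w_syn must be >= 0")
    return polarity.sign * w_syn * abs(V_rest - V_m)


# Direction in which the manipulation offset moves each characteristic for
# *excitatory* drive: V_th is raised (-56 -> -51), V_reset is lowered
# (-41 -> -46); both shrink |V_th - V_reset| and raise the burst
# frequency.  Inhibitory drive (negative V_cm) is the mirror image.
_CHARACTERISTIC_DIRECTION = {"V_th": +1.0, "V_reset": -1.0, "V_m": +1.0}


def effective_voltage_characteristic(
    manip: VoltageManipulation,
    V_cm: float,
) -> tuple[float, float]:
    """Effective (V_th, V_reset) given a manipulation offset.

    Only the targeted characteristic moves; it is ``initial + direction *
    |V_cm|`` where the direction depends on the characteristic and the
    sign of ``V_cm`` (see module docstring).  The untargeted one keeps the
    network default.  A ``V_m`` target leaves both at the defaults (the
    offset is applied to the membrane potential by the integrator, not
    here).
    """
    if manip.target == "V_m":
        return V_TH_DEFAULT, V_RESET_DEFAULT
    # sign(V_cm) carries the polarity (+ excitatory / - inhibitory)
    polarity_sign = 1.0 if V_cm >= 0 else -1.0
    shift = _CHARACTERISTIC_DIRECTION[manip.target] * polarity_sign * abs(V_cm)
    if manip.target == "V_th":
        return manip.V_th_initial + shift, V_RESET_DEFAULT
    return V_TH_DEFAULT, manip.V_reset_initial + shift


def feedback_weight(
    cfg: FeedbackConfig,
    current_spike_number: float,
) -> tuple[float, CouplingPolarity]:
    """Regulated synaptic conductance (nS) and its polarity.

    The error ``desired - current`` picks the polarity (excitatory when
    the output undershoots the set point) and the magnitude is the error
    times the polarity's scaling factor, optionally clamped.
    """
    if current_spike_number < 0:
        raise ValueError("current_spike_number must be >= 0")
    error = cfg.desired_spike_number - current_spike_number
    if error > 0:
        polarity = CouplingPolarity.EXCITATORY
        w = cfg.scaling_factor_excitatory * error
    else:
        polarity = CouplingPolarity.INHIBITORY
        w = cfg.scaling_factor_inhibitory * (-error)
    if cfg.weight_cap is not None:
        w = min(w, cfg.weight_cap)
    return w, polarity
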