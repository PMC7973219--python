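"""Configuration: published constants, calibrated defaults, YAML round-trip.

Two kinds of numbers live here and are kept deliberately separate:

``PUBLISHED``
    Values fixed by the study conditions: the maximum analog input
    current and its stepping increment, the noise levels, the rate-coding
    window, the rest potential and manipulation divisor, the feedback
    scaling factors and the maximum stable output conductance.  These are
    not free to calibrate.

calibrated topology defaults
    Synaptic weights, delays and bias currents of the network (see
    :class:`nsinet.netsim.NetworkTopology` and ``docs/methods.md``);
    these were fixed once by the calibration procedure and ship as code
    defaults, overridable from a YAML experiment file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from nsinet.neurons import AdExParams, NSIParams
from nsinet.netsim import NetworkTopology, NoiseConfig

__all__ = [
    "PUBLISHED",
    "load_config",
    "dump_config",
    "topology_to_dict",
    "calibration_hash",
]

#: Constants fixed by the study conditions (units in comments).
PUBLISHED = {
    "I_input_max_pA": 148.0,        # maximum analog input to the NSI
    "step_increment_pA": 29.6,      # 148 / 5, six levels over six seconds
    "nsi_noise_std_pA": 25.0,       # comparable to the current steps
    "neuron_noise_std_pA": 50.0,
    "rate_window_ms": 5.0,
    "v_rest_mV": -60.0,
    "vcm_divisor": 3.0,             # 15 mV fluctuation range / 5 mV stable offset
    "vcm_max_mV": 5.0,
    "v_th_default_mV": -51.0,
    "v_reset_default_mV": -46.0,
    "feedback_scaling_excitatory": 2.0,
    "feedback_scaling_inhibitory": 50.0,
    "w_max_nS": 70.0,               # lifting appears one 10 nS increment above
}

_TOPOLOGY_KEYS = {f.name for f in dataclasses.fields(NetworkTopology)} - {"adex", "adex_mnp", "nsi"}
_NOISE_KEYS = {f.name for f in dataclasses.fields(NoiseConfig)}


def topology_to_dict(topology: NetworkTopology, noise: NoiseConfig | None = None) -> dict:
    """Serializable snapshot of a topology (and optionally noise) config."""
    d = {
        "adex": dataclasses.asdict(topology.adex),
        "adex_mnp": dataclasses.asdict(topology.adex_mnp) if topology.adex_mnp else None,
        "nsi": dataclasses.asdict(topology.nsi),
    }
    for k in sorted(_TOPOLOGY_KEYS):
        d[k] = getattr(topology, k)
    if noise is not None:
        d["noise"] = dataclasses.asdict(noise)
    return d


def _build(section: dict | None, cls, label: str):
    if section is None:
        return cls()
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {label} keys: {sorted(unknown)} (valid: {sorted(valid)})")
    return cls(**section)


def load_config(path: str | Path) -> tuple[NetworkTopology, NoiseConfig]:
    """Load a YAML experiment config into (NetworkTopology, NoiseConfig).

    Every key is optional; omitted values use the calibrated defaults.
    Unknown keys raise, naming the valid ones.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - (_TOPOLOGY_KEYS | {"adex", "adex_mnp", "nsi", "noise"})
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: raw[k] for k in _TOPOLOGY_KEYS if k in raw}
    kwargs["adex"] = _build(raw.get("adex"), AdExParams, "adex")
    if "adex_mnp" in raw and raw["adex_mnp"] is None:
        kwargs["adex_mnp"] = None
    else:
        kwargs["adex_mnp"] = (
            _build(raw["adex_mnp"], AdExParams, "adex_mnp")
            if "adex_mnp" in raw
            else NetworkTopology().adex_mnp
        )
    kwargs["nsi"] = _build(raw.get("nsi"), NSIParams, "nsi")
    topology = NetworkTopology(**kwargs)
    noise = _build(raw.get("noise"), NoiseConfig, "noise")
    return topology, noise


def dump_config(topology: NetworkTopology, noise: NoiseConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(topology_to_dict(topology, noise), sort_keys=True))


def calibration_hash(topology: NetworkTopology, noise: NoiseConfig | None = None) -> str:
    """Short content hash of the resolved configuration (for run manifests)."""
    payload = json.dumps(topology_to_dict(topology, noise), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
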