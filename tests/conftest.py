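import warnings

import numpy as np
import pytest

from nsinet.coupling import CouplingPolarity
from nsinet.netsim import ExperimentSpec, InputSchedule, NetworkTopology, simulate

warnings.filterwarnings("ignore", category=RuntimeWarning)


def static_spec(
    w_syn: float,
    polarity: CouplingPolarity = CouplingPolarity.EXCITATORY,
    inject: bool = True,
    duration: float = 6000.0,
    voltage_target: str = "none",
    I_input: float = 148.0,
) -> ExperimentSpec:
    """Constant-input experiment used by the static conductance tests."""
    return ExperimentSpec(
        test_no=1,
        subcategory=0 if polarity is CouplingPolarity.EXCITATORY else 3,
        mnp_injection="constant" if inject else "none",
        scpg_injection="none",
        voltage_target=voltage_target,
        polarity=polarity,
        scpg_targets="both",
        duration=duration,
        w_syn=w_syn,
        input_schedule=InputSchedule(kind="constant", I_max=I_input, step_interval=duration),
    )


@pytest.fixture(scope="session")
def topology() -> NetworkTopology:
    return NetworkTopology()


@pytest.fixture(scope="session")
def baseline_run(topology):
    """One calibrated baseline run (no graded injection), seed 0."""
    return simulate(static_spec(0.0, inject=False), topology=topology, seed=0)


def pooled_gap_frequency(peak_sets, lo: float, hi: float) -> float:
    """Trimmed per-gap frequency pooled over seeds (robust against missed
    or doubled bursts in any single run)."""
    gaps: list[float] = []
    for pk in peak_sets:
        seg = pk.in_segment(lo, hi)
        if len(seg) >= 2:
            gaps.extend(np.diff(seg.times))
    g = np.asarray(gaps)
    if g.size == 0:
        return float("nan")
    med = np.median(g)
    g = g[(g >= 0.45 * med) & (g <= 1.7 * med)]
    return float(np.mean(1000.0 / g))
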