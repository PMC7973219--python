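"""Conversions between analog signals and spikes.

* :func:`rate_code` — sliding-window spike counting, the decoder that
  turns the motor population's spike train into the network's analog
  output (default window 5 ms, stride 1 ms on the recording grid).
* :func:`bsa_encode` / :func:`bsa_decode` — Ben's Spiker Algorithm: an
  FIR-filter based encoder producing a spike train whose filtered
  reconstruction approximates the analog input; used to feed the
  event-driven engine.
* :func:`make_step_signal` — piecewise-constant input generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnalogSignal",
    "RateSignal",
    "rate_code",
    "bsa_encode",
    "bsa_decode",
    "make_step_signal",
    "gaussian_fir",
]

RATE_WINDOW_MS = 5.0
RATE_STRIDE_MS = 1.0


@dataclass(frozen=True)
class AnalogSignal:
    """A sampled analog signal (times in ms, strictly increasing)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples for a grid step")
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class RateSignal:
    """Sliding-window spike counts on the recording grid.

    ``values[k]`` counts all spikes in the half-open window
    ``[times[k], times[k] + window)``.
    """

    times: np.ndarray          # window start times, ms
    values: np.ndarray         # non-negative integer counts
    window: float = RATE_WINDOW_MS
    stride: float = RATE_STRIDE_MS

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values))
        if np.any(self.values < 0):
            raise ValueError("rate-signal counts must be non-negative")


def rate_code(
    spike_times,
    window: float = RATE_WINDOW_MS,
    stride: float = RATE_STRIDE_MS,
    duration: float | None = None,
    t0: float = 0.0,
) -> RateSignal:
    """Rate-code a spike train by sliding-window counting.

    Parameters
    ----------
    spike_times : array-like or SpikeTrain
        Spike times in ms of the whole population (all neurons pooled).
        Objects with an ``all_times()`` method (e.g.
        :class:`nsinet.netsim.SpikeTrain`) are accepted.
    window, stride : float
        Window length and hop in ms (> 0).
    duration : float, optional
        Signal length in ms; defaults to the last spike time.  Window
        starts run from ``t0`` to ``duration - window`` inclusive.
    """
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be > 0")
    if hasattr(spike_times, "all_times"):
        spike_times = spike_times.all_times()
    t = np.sort(np.asarray(spike_times, dtype=float))
    if duration is None:
        duration = float(t[-1]) if t.size else window
    n = int(np.floor((duration - window) / stride)) + 1
    if n < 1:
        raise ValueError("duration shorter than one window")
    starts = t0 + stride * np.arange(n)
    counts = np.searchsorted(t, starts + window, side="left") - np.searchsorted(
        t, starts, side="left"
    )
    return RateSignal(times=starts, values=counts.astype(np.int64), window=window, stride=stride)


def gaussian_fir(n_taps: int = 20, std: float = 3.0) -> np.ndarray:
    """Unit-sum Gaussian FIR filter, the default BSA kernel."""
    x = np.arange(n_taps) - (n_taps - 1) / 2.0
    h = np.exp(-0.5 * (x / std) ** 2)
    return h / h.sum()


def bsa_encode(
    signal: AnalogSignal,
    fir_filter: np.ndarray | None = None,
    threshold: float = 0.95,
):
    """Encode an analog signal to spikes with Ben's Spiker Algorithm.

    At each sample the algorithm compares the error of subtracting the
    FIR filter from the residual signal against the error of leaving it;
    when subtracting is cheaper by at least ``threshold`` (scaled by the
    filter's total mass) a spike is emitted and the filter subtracted.
    Filtering the emitted train with the same FIR approximately
    reconstructs the input.

    Returns
    -------
    np.ndarray
        Spike times (ms) on the signal's sampling grid.
    """
    h = gaussian_fir() if fir_filter is None else np.asarray(fir_filter, dtype=float)
    if np.any(h < 0):
        raise ValueError("FIR coefficients must be non-negative")
    v = np.asarray(signal.values, dtype=float).copy()
    m = h.size
    if m > v.size:
        raise ValueError("FIR filter longer than the signal")
    # thresholds are relative to the filter mass so that encoding is
    # invariant to rescaling the kernel
    thr = threshold * h.sum()
    spike_idx = []
    for i in range(v.size - m + 1):
        seg = v[i : i + m]
        err_sub = np.abs(seg - h).sum()
        err_keep = np.abs(seg).sum()
        if err_sub <= err_keep - thr:
            spike_idx.append(i)
            seg -= h
    return signal.times[np.asarray(spike_idx, dtype=int)]


def bsa_decode(
    spike_times,
    grid: np.ndarray,
    fir_filter: np.ndarray | None = None,
) -> AnalogSignal:
    """Reconstruct an analog signal by FIR-filtering a spike train.

    The round-trip ``bsa_decode(bsa_encode(s), s.times)`` approximates
    ``s``; it is the fidelity check for the encoder.
    """
    h = gaussian_fir() if fir_filter is None else np.asarray(fir_filter, dtype=float)
    grid = np.asarray(grid, dtype=float)
    impulses = np.zeros(grid.size)
    idx = np.searchsorted(grid, np.asarray(spike_times, dtype=float))
    idx = np.clip(idx, 0, grid.size - 1)
    np.add.at(impulses, idx, 1.0)
    rec = np.convolve(impulses, h)[: grid.size]
    return AnalogSignal(times=grid, values=rec)


def make_step_signal(
    levels,
    level_duration: float,
    dt: float = 1.0,
) -> AnalogSignal:
    """Piecewise-constant signal holding each level for ``level_duration`` ms."""
    if level_duration <= 0:
        raise ValueError("level_duration must be > 0")
    levels = np.asarray(levels, dtype=float)
    n_per = int(round(level_duration / dt))
    values = np.repeat(levels, n_per)
    times = dt * np.arange(values.size)
    return AnalogSignal(times=times, values=values)
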