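"""Output measures of the rate-coded motor signal.

The network's analog output is the sliding-window spike count of the
motor population.  Its bursts appear as local maxima of that signal; the
measures defined here are the ones used to compare experimental
conditions:

* peak detection with double-peak rejection,
* average peak amplitude (spikes per window),
* burst frequency from inter-peak intervals (one value per successive
  peak pair),
* phase shift between two peak sets as a circular mean in degrees.

Suppressed outputs legitimately have no peaks; measures that need peaks
raise :class:`UndefinedMeasureError` rather than returning zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.stats import circmean

from nsinet.codecs import RateSignal

__all__ = [
    "PeakSet",
    "FrequencyEstimate",
    "UndefinedMeasureError",
    "detect_peaks",
    "average_peak",
    "estimate_frequency",
    "phase_shift",
]

DEFAULT_MIN_SEPARATION_MS = 50.0
DEFAULT_MIN_PROMINENCE = 2.0


class UndefinedMeasureError(ValueError):
    """A measure is undefined for this signal (e.g. no peaks); distinct from zero."""


@dataclass(frozen=True)
class PeakSet:
    """Detected local maxima of a rate signal, plus rejected double peaks."""

    times: np.ndarray            # ms, strictly increasing
    values: np.ndarray           # spike counts at the peaks
    rejected_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    rejected_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def in_segment(self, t0: float, t1: float) -> "PeakSet":
        m = (self.times >= t0) & (self.times < t1)
        return PeakSet(times=self.times[m], values=self.values[m])


@dataclass(frozen=True)
class FrequencyEstimate:
    """Burst frequency from inter-peak gaps: one value per successive pair."""

    frequencies: np.ndarray  # Hz, per gap
    gaps: np.ndarray         # ms, interval source

    @property
    def mean(self) -> float:
        return float(np.mean(self.frequencies))


def detect_peaks(
    signal: RateSignal,
    min_separation: float = DEFAULT_MIN_SEPARATION_MS,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> PeakSet:
    """Local maxima of the rate signal with double-peak rejection.

    All local maxima with at least ``min_prominence`` are found first;
    within any cluster of maxima closer than ``min_separation`` only the
    largest is kept (ties: the earlier one) and the rest are recorded as
    rejected double peaks.  A constant signal has no peaks.
    """
    values = np.asarray(signal.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty rate signal")
    idx, _ = _sig.find_peaks(values, prominence=min_prominence)
    if idx.size == 0:
        return PeakSet(times=np.empty(0), values=np.empty(0))
    # greedy selection by height, earlier peak wins ties
    order = np.lexsort((idx, -values[idx]))
    kept: list[int] = []
    rejected: list[int] = []
    sep_samples = min_separation / signal.stride
    for j in order:
        i = idx[j]
        if all(abs(i - k) >= sep_samples for k in kept):
            kept.append(i)
        else:
            rejected.append(i)
    kept_arr = np.sort(np.asarray(kept, dtype=int))
    rej_arr = np.sort(np.asarray(rejected, dtype=int))
    return PeakSet(
        times=signal.times[kept_arr],
        values=np.asarray(signal.values)[kept_arr],
        rejected_times=signal.times[rej_arr],
        rejected_values=np.asarray(signal.values)[rej_arr],
    )


def average_peak(peaks: PeakSet) -> float:
    """Arithmetic mean of peak heights (average spikes per window at peaks)."""
    if len(peaks) == 0:
        raise UndefinedMeasureError("average peak undefined: no peaks detected")
    return float(np.mean(peaks.values))


def estimate_frequency(
    peaks: PeakSet,
    segment: tuple[float, float] | None = None,
    outlier_factor: float | None = 1.7,
    double_peak_factor: float = 0.45,
) -> FrequencyEstimate:
    """Mean burst frequency from inter-peak intervals within ``segment``.

    Each successive peak pair contributes one value ``1000 / gap_ms``; the
    estimate is the mean of those per-gap frequencies (not the reciprocal
    of the mean gap).  Gaps far from the median gap are removed as
    outliers before averaging: gaps longer than ``outlier_factor`` times
    the median arise when a weak burst falls below the detection
    threshold (the gap spans two or more true periods), and gaps shorter
    than ``double_peak_factor`` times the median are residual double
    peaks within one burst.  Pass ``outlier_factor=None`` to keep all
    gaps.
    """
    ps = peaks if segment is None else peaks.in_segment(*segment)
    if len(ps) < 2:
        raise UndefinedMeasureError("frequency undefined: fewer than two peaks")
    gaps = np.diff(ps.times)
    if outlier_factor is not None and gaps.size >= 3:
        med = np.median(gaps)
        gaps = gaps[(gaps <= outlier_factor * med) & (gaps >= double_peak_factor * med)]
        if gaps.size == 0:
            raise UndefinedMeasureError("frequency undefined: all gaps rejected")
    return FrequencyEstimate(frequencies=1000.0 / gaps, gaps=gaps)


def phase_shift(a: PeakSet, b: PeakSet, period: float) -> float:
    """Circular mean phase offset of peak set ``b`` relative to ``a``.

    For each peak in ``a`` the nearest peak in ``b`` supplies a time
    offset; offsets are wrapped on the common ``period`` (ms) and averaged
    on the circle.  Returned in degrees in [0, 360).
    """
    if len(a) == 0 or len(b) == 0:
        raise UndefinedMeasureError("phase undefined: empty peak set")
    if period <= 0:
        raise ValueError("period must be > 0")
    ib = np.searchsorted(b.times, a.times)
    ib_lo = np.clip(ib - 1, 0, len(b) - 1)
    ib_hi = np.clip(ib, 0, len(b) - 1)
    d_lo = b.times[ib_lo] - a.times
    d_hi = b.times[ib_hi] - a.times
    offsets = np.where(np.abs(d_lo) <= np.abs(d_hi), d_lo, d_hi)
    angles = 2.0 * np.pi * (offsets / period)
    mean_angle = circmean(angles, high=np.pi, low=-np.pi)
    return float(np.degrees(mean_angle) % 360.0)
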