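"""Waveforms, spike trains, and interval-based temporal codes.

The three substrate types here — :class:`Waveform`, :class:`SpikeTrain`
and :class:`IntervalHistogram` — are shared by every other module.
Times are always seconds, frequencies always Hz.

The temporal-code pipeline is::

    Waveform --encode_phase_locked--> SpikeTrain
             --interspike_intervals--> IntervalHistogram
             --estimate_f0--> Hz

``population_interval_distribution`` pools histograms across a list of
trains by bin-wise summation; no cross-train intervals are ever formed,
so no synchrony across trains is assumed or required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import NoEstimateError, ValidationError

__all__ = [
    "Waveform",
    "SpikeTrain",
    "IntervalHistogram",
    "encode_phase_locked",
    "interspike_intervals",
    "population_interval_distribution",
    "estimate_f0",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_MAX_LAG",
]

#: Default interval-histogram binning: 0.1 ms bins out to 30 ms of lag
#: (resolves fundamentals down to ~33 Hz).
DEFAULT_BIN_WIDTH = 1e-4
DEFAULT_MAX_LAG = 30e-3


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence (arbitrary units), length >= 1.
    sample_rate : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not self.sample_rate > 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (length / sample_rate)."""
        return self.samples.size / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered point events on a finite observation interval.

    ``times`` are strictly increasing and lie in ``[0, duration]``.
    The empty train is valid.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValidationError("times must be 1-D")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValidationError("spike times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] > self.duration + 1e-12):
            raise ValidationError("spike times must lie in [0, duration]")
        if self.duration < 0:
            raise ValidationError("duration must be >= 0")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class IntervalHistogram:
    """Binned interspike-interval counts.

    Bins are half-open ``[k*bin_width, (k+1)*bin_width)`` for
    ``k = 0 .. n_bins-1`` with ``n_bins = ceil(max_lag / bin_width)``.
    ``order`` records whether first-order (consecutive-pair) or
    all-order (every ordered pair) intervals were counted.
    """

    bin_width: float
    max_lag: float
    counts: np.ndarray
    order: str

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValidationError("bin_width must be > 0")
        if not self.max_lag > self.bin_width:
            raise ValidationError("max_lag must exceed bin_width")
        if self.order not in ("first", "all"):
            raise ValidationError(f"order must be 'first' or 'all', got {self.order!r}")
        counts = np.asarray(self.counts, dtype=np.int64)
        n_bins = _n_bins(self.max_lag, self.bin_width)
        if counts.shape != (n_bins,):
            raise ValidationError(
                f"counts length {counts.size} != ceil(max_lag/bin_width) = {n_bins}"
            )
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def lags(self) -> np.ndarray:
        """Left bin edges in seconds."""
        return np.arange(self.n_bins) * self.bin_width

    def total(self) -> int:
        return int(self.counts.sum())


def _n_bins(max_lag: float, bin_width: float) -> int:
    return int(math.ceil(round(max_lag / bin_width, 9)))


def _bin_index(intervals: np.ndarray, bin_width: float) -> np.ndarray:
    # round-then-floor guards against float noise pushing an interval that
    # sits exactly on a bin edge into the lower bin
    return np.floor(np.round(intervals / bin_width, 9)).astype(np.int64)


def encode_phase_locked(
    w: Waveform,
    mode: str = "zero-crossing",
    threshold: float = 0.0,
    refractory: float = 0.0,
) -> SpikeTrain:
    """Encode a waveform as a phase-locked spike train.

    In ``"zero-crossing"`` mode one spike is emitted per positive-going
    crossing of ``threshold``, with the spike time linearly interpolated
    between samples.  In ``"peak"`` mode one spike is emitted per local
    maximum whose amplitude exceeds ``threshold``, at sample resolution.
    A greedy refractory pass then drops any spike closer than
    ``refractory`` seconds to the previously kept spike.

    Raises
    ------
    ValidationError
        If samples are non-finite, the threshold is non-finite, the
        refractory period is negative, or the mode is unknown.
    """
    if not np.all(np.isfinite(w.samples)):
        raise ValidationError("waveform contains non-finite samples")
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if refractory < 0:
        raise ValidationError("refractory must be >= 0")

    s = w.samples
    if mode in ("zero-crossing", "positive-zero-crossing"):
        lo = s[:-1] <= threshold
        hi = s[1:] > threshold
        idx = np.flatnonzero(lo & hi)
        rise = s[idx + 1] - s[idx]
        frac = np.where(rise > 0, (threshold - s[idx]) / np.where(rise > 0, rise, 1.0), 0.0)
        times = w.t0 + (idx + frac) / w.sample_rate
    elif mode == "peak":
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(s)
        peaks = peaks[s[peaks] > threshold]
        times = w.t0 + peaks / w.sample_rate
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    if refractory > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.asarray(kept)

    return SpikeTrain(times=times, duration=w.t0 + w.duration)


def interspike_intervals(
    st: SpikeTrain,
    order: str = "all",
    max_lag: float = DEFAULT_MAX_LAG,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> IntervalHistogram:
    """Histogram the interspike intervals of one train.

    ``order="first"`` counts durations between consecutive spikes;
    ``order="all"`` counts the duration of every ordered spike pair not
    exceeding ``max_lag``.  A train with <= 1 spike yields an all-zero
    histogram.
    """
    if not (max_lag > bin_width > 0):
        raise ValidationError("require max_lag > bin_width > 0")
    if order not in ("first", "all"):
        raise ValidationError(f"order must be 'first' or 'all', got {order!r}")

    n_bins = _n_bins(max_lag, bin_width)
    counts = np.zeros(n_bins, dtype=np.int64)
    times = st.times
    if times.size >= 2:
        if order == "first":
            intervals = np.diff(times)
        else:
            # only pairs within max_lag: bounded forward window per spike
            ends = np.searchsorted(times, times + max_lag, side="right")
            chunks = [times[i + 1 : ends[i]] - times[i] for i in range(times.size - 1)]
            intervals = np.concatenate(chunks) if chunks else np.empty(0)
        if intervals.size:
            idx = _bin_index(intervals, bin_width)
            valid = (idx >= 0) & (idx < n_bins)
            np.add.at(counts, idx[valid], 1)

    return IntervalHistogram(bin_width=bin_width, max_lag=max_lag, counts=counts, order=order)


def population_interval_distribution(
    trains: list[SpikeTrain],
    order: str = "all",
    max_lag: float = DEFAULT_MAX_LAG,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> IntervalHistogram:
    """Pooled interval histogram over a population of trains.

    The result is the bin-wise sum of each train's own histogram.
    Intervals are only ever formed within a train, never across trains.
    """
    if not trains:
        raise ValidationError("train list must be non-empty")
    n_bins = _n_bins(max_lag, bin_width)
    counts = np.zeros(n_bins, dtype=np.int64)
    for st in trains:
        counts += interspike_intervals(st, order, max_lag, bin_width).counts
    return IntervalHistogram(bin_width=bin_width, max_lag=max_lag, counts=counts, order=order)


def estimate_f0(h: IntervalHistogram, f_min: float, f_max: float) -> float:
    """Estimate a fundamental frequency from an interval histogram.

    For each candidate lag ``L = b * bin_width`` with ``1/L`` inside
    ``[f_min, f_max]``, a salience is computed by summing counts at the
    candidate lag and its first two integer multiples (3 subharmonics),
    the k-th multiple weighted ``1/k`` so that a lag supported only via
    a distant multiple cannot outvote the lag it is a subharmonic of.
    The window at multiple ``k`` spans bins ``[k*b, k*b + k)`` to absorb
    bin-quantisation spread of non-divisible periods.  The lag of
    maximal salience wins; ties break toward the shorter lag (larger
    frequency).  Returns ``1 / L*`` in Hz.

    Raises
    ------
    NoEstimateError
        If the histogram is empty (all-zero).
    ValidationError
        If ``[f_min, f_max]`` is not resolvable at this binning.
    """
    if not (0 < f_min < f_max):
        raise ValidationError("require 0 < f_min < f_max")
    if 1.0 / f_min > h.max_lag or 1.0 / f_max < h.bin_width:
        raise ValidationError("[f_min, f_max] outside the histogram's resolvable lag range")
    if h.total() == 0:
        raise NoEstimateError("all-zero interval histogram")

    counts = h.counts
    n_bins = h.n_bins
    b_lo = max(1, int(math.ceil(round(1.0 / (f_max * h.bin_width), 9))))
    b_hi = min(n_bins - 1, int(math.floor(round(1.0 / (f_min * h.bin_width), 9))))
    if b_hi < b_lo:
        raise ValidationError("frequency range narrower than one histogram bin")

    best_b = -1
    best_sal = -1.0
    total = float(h.total())
    for b in range(b_lo, b_hi + 1):
        sal = 0.0
        for k in (1, 2, 3):
            start = k * b
            if start >= n_bins:
                break
            sal += counts[start : min(start + k, n_bins)].sum() / k
        sal /= total
        if sal > best_sal:  # strict: earlier (shorter) lag wins ties
            best_sal = sal
            best_b = b
    if best_sal <= 0:
        raise NoEstimateError("no interval mass in the requested frequency range")
    return 1.0 / (best_b * h.bin_width)
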