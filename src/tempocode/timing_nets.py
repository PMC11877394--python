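"""Delay-line and coincidence-detector networks.

Building blocks: cluster-based coincidence detection across spike
trains, Jeffress-style internal-delay estimation over a tapped delay
line, reverberatory loop strength dynamics, and coincidence-driven
facilitation of delayed paths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_signals import SpikeTrain
from .errors import NoEstimateError, ValidationError

__all__ = [
    "CoincidenceDetector",
    "DelayLine",
    "RecurrentLoop",
    "PathWeights",
    "coincidence_detect",
    "best_internal_delay",
    "reverberate",
    "facilitate_paths",
]

#: Default coincidence window, inside the 1-10 ms synchronous-binding range.
DEFAULT_WINDOW = 5e-3


@dataclass(frozen=True)
class CoincidenceDetector:
    """Emits an event when >= ``min_count`` distinct inputs spike within
    a window of width ``window`` seconds."""

    window: float = DEFAULT_WINDOW
    min_count: int = 2

    def __post_init__(self) -> None:
        if not self.window > 0:
            raise ValidationError("window must be > 0")
        if self.min_count < 2:
            raise ValidationError("min_count must be >= 2")


@dataclass(frozen=True)
class DelayLine:
    """An ordered set of internal delays (taps), in seconds.

    Taps may be negative so that a symmetric line can represent leads as
    well as lags (delay applied to the contralateral side).
    """

    taps: np.ndarray

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        if taps.ndim != 1 or taps.size == 0:
            raise ValidationError("taps must be a non-empty 1-D sequence")
        if np.any(np.diff(taps) <= 0):
            raise ValidationError("taps must be strictly ascending and unique")
        object.__setattr__(self, "taps", taps)

    def __len__(self) -> int:
        return self.taps.size


@dataclass(frozen=True)
class RecurrentLoop:
    """A regenerative delay loop: per-cycle multiplicative ``gain`` with a
    ``saturation`` ceiling on circulating-pattern strength."""

    loop_delay: float
    gain: float
    saturation: float = np.inf

    def __post_init__(self) -> None:
        if not self.loop_delay > 0:
            raise ValidationError("loop_delay must be > 0")
        if self.gain < 0:
            raise ValidationError("gain must be >= 0")
        if not self.saturation > 0:
            raise ValidationError("saturation must be > 0")


@dataclass(frozen=True)
class PathWeights:
    """Per-(tap, input) facilitation weights, bounded in [0, w_max]."""

    weights: np.ndarray
    taps: DelayLine
    learning_rate: float
    w_max: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValidationError("weights must be 2-D (n_taps, n_inputs)")
        if w.shape[0] != len(self.taps):
            raise ValidationError("weights row count must equal number of taps")
        if np.any(w < 0) or np.any(w > self.w_max):
            raise ValidationError("weights must lie in [0, w_max]")
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be > 0")
        object.__setattr__(self, "weights", w)


def coincidence_detect(trains: list[SpikeTrain], det: CoincidenceDetector) -> SpikeTrain:
    """Detect multi-train spike coincidences.

    Scans the pooled, time-sorted events for maximal clusters that fit
    within ``det.window`` and contain spikes from at least
    ``det.min_count`` distinct trains; each such cluster emits one event
    at its mean spike time.  Output events are at least one window
    apart.
    """
    if len(trains) < 2:
        raise ValidationError("need at least 2 trains")
    duration = max(st.duration for st in trains)
    ts = np.concatenate([st.times for st in trains]) if trains else np.empty(0)
    ids = np.concatenate(
        [np.full(len(st), i) for i, st in enumerate(trains)]
    ) if trains else np.empty(0, dtype=int)
    order = np.argsort(ts, kind="stable")
    ts, ids = ts[order], ids[order]

    out: list[float] = []
    last = -np.inf
    i = 0
    n = ts.size
    while i < n:
        j = int(np.searchsorted(ts, ts[i] + det.window, side="right"))
        if np.unique(ids[i:j]).size >= det.min_count:
            m = float(ts[i:j].mean())
            if m - last >= det.window:
                out.append(m)
                last = m
            i = j
        else:
            i += 1
    return SpikeTrain(np.asarray(out), duration)


def best_internal_delay(
    left: SpikeTrain,
    right: SpikeTrain,
    line: DelayLine,
    eps: float = 5e-4,
) -> tuple[float, np.ndarray]:
    """Jeffress-style delay estimation by cross-correlation over a tap set.

    ``correlogram[k]`` counts spike pairs for which a left spike delayed
    by ``taps[k]`` lands within ``eps`` of a right spike.  Returns the
    arg-max tap (ties broken toward the smallest delay) and the full
    correlogram.
    """
    if len(left) == 0 or len(right) == 0:
        raise NoEstimateError("cannot estimate a delay from an empty train")
    if not eps > 0:
        raise ValidationError("eps must be > 0")
    r = right.times
    correlogram = np.empty(len(line), dtype=np.int64)
    for k, tau in enumerate(line.taps):
        shifted = left.times + tau
        hi = np.searchsorted(r, shifted + eps, side="right")
        lo = np.searchsorted(r, shifted - eps, side="left")
        correlogram[k] = int(np.sum(hi - lo))
    best = int(np.argmax(correlogram))  # argmax returns first max: smallest tap
    return float(line.taps[best]), correlogram


def reverberate(st: SpikeTrain, loop: RecurrentLoop, n_cycles: int) -> np.ndarray:
    """Strength trajectory of a pattern circulating in a loop.

    ``strength[k] = min(saturation, gain**k)`` for ``k = 0..n_cycles``
    with unit initial strength.  The circulating spike pattern itself is
    never altered by the loop — only its strength scalar evolves.
    """
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    k = np.arange(n_cycles + 1)
    return np.minimum(loop.saturation, np.power(float(loop.gain), k))


def facilitate_paths(
    pw: PathWeights,
    trains: list[SpikeTrain],
    det: CoincidenceDetector,
) -> PathWeights:
    """Count-proportional facilitation of delayed paths.

    ``trains[0]`` is the reference (target) train; ``trains[1:]`` feed
    the delay line.  For each (tap, input) path, the coincidence count
    is the number of (input spike + tap, reference spike) pairs within
    ``det.window``; each weight grows by ``learning_rate * count`` and
    is clipped to [0, w_max].  Paths with no coincidences are unchanged.
    """
    if len(trains) < 2:
        raise ValidationError("need a reference train plus at least one input train")
    n_inputs = len(trains) - 1
    if pw.weights.shape[1] != n_inputs:
        raise ValidationError(
            f"weights have {pw.weights.shape[1]} input columns but {n_inputs} input trains given"
        )
    ref = trains[0].times
    counts = np.zeros_like(pw.weights)
    for i, st in enumerate(trains[1:]):
        for k, tau in enumerate(pw.taps.taps):
            shifted = st.times + tau
            hi = np.searchsorted(ref, shifted + det.window, side="right")
            lo = np.searchsorted(ref, shifted - det.window, side="left")
            counts[k, i] = np.sum(hi - lo)
    new_w = np.clip(pw.weights + pw.learning_rate * counts, 0.0, pw.w_max)
    return replace(pw, weights=new_w)
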