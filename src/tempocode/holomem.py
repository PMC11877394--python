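"""Time-domain holographic associative memory.

Item pairs are bound by circular convolution and recalled by circular
correlation — the shift / multiply / sum recipe realised on fixed-length
real vectors.  Many bindings superpose additively in a single trace;
recall of any pair degrades gracefully as components of the trace are
lost, and a cleanup dictionary restores noisy reconstructions to their
nearest stored item (content-addressable lookup).

Random unit vectors of dimension ``n`` (default 1024) serve as items;
at that dimension unrelated items correlate at the ~3/sqrt(n) chance
level, so bound-and-recalled partners (correlation ~0.7-0.9) are easily
separated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core_signals import SpikeTrain
from .errors import ValidationError

__all__ = [
    "HoloItem",
    "HoloTrace",
    "CleanupDictionary",
    "CleanupResult",
    "bind",
    "unbind",
    "superpose_traces",
    "cleanup",
    "recall_sequence",
    "degrade",
    "random_item",
    "identity_item",
    "encode_sequence",
    "spike_train_to_item",
    "correlation",
    "DEFAULT_DIMENSION",
    "DEFAULT_ACCEPT_THRESHOLD",
]

DEFAULT_DIMENSION = 1024
#: Below typical chance level for n >= 1024 yet above residual noise.
DEFAULT_ACCEPT_THRESHOLD = 0.15


@dataclass(frozen=True)
class HoloItem:
    """A labelled unit vector of fixed dimension."""

    vector: np.ndarray
    label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValidationError("item vector must be non-empty and 1-D")
        norm = float(np.linalg.norm(v))
        if norm == 0:
            raise ValidationError("item vector must be non-zero")
        object.__setattr__(self, "vector", v / norm)

    @property
    def n(self) -> int:
        return self.vector.size


@dataclass(frozen=True)
class HoloTrace:
    """A distributed memory trace: the superposition of zero or more
    circular-convolution bindings."""

    vector: np.ndarray
    n_bindings: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValidationError("trace vector must be non-empty and 1-D")
        if self.n_bindings < 0:
            raise ValidationError("n_bindings must be >= 0")
        object.__setattr__(self, "vector", v)

    @property
    def n(self) -> int:
        return self.vector.size


@dataclass(frozen=True)
class CleanupDictionary:
    """Content-addressable store of items with an acceptance threshold."""

    items: list[HoloItem]
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD

    def __post_init__(self) -> None:
        labels = [it.label for it in self.items]
        if len(set(labels)) != len(labels):
            raise ValidationError("dictionary labels must be unique")
        if not 0 <= self.accept_threshold <= 1:
            raise ValidationError("accept_threshold must be in [0, 1]")

    def get(self, label: str) -> HoloItem:
        for it in self.items:
            if it.label == label:
                return it
        raise KeyError(label)


class CleanupResult(NamedTuple):
    """Result of a cleanup lookup; ``label is None`` means no match."""

    label: str | None
    score: float


def random_item(n: int, label: str, rng: np.random.Generator) -> HoloItem:
    """A random unitary unit-vector item.

    The spectrum has unit magnitude at every frequency and uniformly
    random phase, so circular correlation with the item is the exact
    inverse of circular convolution by it (up to crosstalk from other
    superposed bindings).  Plain i.i.d. Gaussian vectors would cap the
    bind-then-unbind correlation near 1/sqrt(2).
    """
    half = n // 2 + 1
    spec = np.exp(2j * np.pi * rng.uniform(size=half))
    spec[0] = np.sign(rng.uniform() - 0.5) or 1.0
    if n % 2 == 0:
        spec[-1] = np.sign(rng.uniform() - 0.5) or 1.0
    return HoloItem(np.fft.irfft(spec, n=n), label)


def identity_item(n: int, label: str = "identity") -> HoloItem:
    """The impulse vector e0: the exact identity of circular convolution."""
    v = np.zeros(n)
    v[0] = 1.0
    return HoloItem(v, label)


def spike_train_to_item(
    st: SpikeTrain, n: int, label: str, t_span: float | None = None
) -> HoloItem:
    """Bridge a spike train to a holographic operand.

    The observation span is divided into ``n`` bins; bins containing at
    least one spike map to +1, empty bins to -1, and the result is
    normalized at item creation.
    """
    span = st.duration if t_span is None else t_span
    if not span > 0:
        raise ValidationError("spike train span must be > 0 to vectorize")
    v = -np.ones(n)
    idx = np.minimum((st.times / span * n).astype(int), n - 1)
    v[idx[(st.times >= 0) & (st.times <= span)]] = 1.0
    return HoloItem(v, label)


def _check_dims(a: int, b: int) -> None:
    if a != b:
        raise ValidationError(f"dimension mismatch: {a} != {b}")


def bind(a: HoloItem, b: HoloItem) -> HoloTrace:
    """Bind two items by circular convolution (commutative)."""
    _check_dims(a.n, b.n)
    v = np.fft.irfft(np.fft.rfft(a.vector) * np.fft.rfft(b.vector), n=a.n)
    return HoloTrace(v, n_bindings=1)


def unbind(t: HoloTrace, cue: HoloItem) -> np.ndarray:
    """Approximately invert a binding by circular correlation with a cue.

    ``unbind(bind(a, b), a)`` is a noisy reconstruction of ``b``; the
    exact inverse holds when the cue is the impulse identity.
    """
    _check_dims(t.n, cue.n)
    return np.fft.irfft(np.conj(np.fft.rfft(cue.vector)) * np.fft.rfft(t.vector), n=t.n)


def superpose_traces(traces: list[HoloTrace]) -> HoloTrace:
    """Additive superposition of traces (binding counts accumulate)."""
    if not traces:
        raise ValidationError("trace list must be non-empty")
    n = traces[0].n
    for t in traces:
        _check_dims(t.n, n)
    v = np.sum([t.vector for t in traces], axis=0)
    return HoloTrace(v, n_bindings=sum(t.n_bindings for t in traces))


def correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized correlation (cosine) of two vectors; 0 if either is zero."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def cleanup(v: np.ndarray, dictionary: CleanupDictionary) -> CleanupResult:
    """Return the best-matching dictionary item for a (noisy) vector.

    The item maximizing normalized correlation wins; ties break by
    dictionary order.  Scores below ``accept_threshold`` yield an
    explicit no-match result (``label is None``).
    """
    if not dictionary.items:
        raise ValidationError("cleanup dictionary must be non-empty")
    v = np.asarray(v, dtype=float)
    _check_dims(v.size, dictionary.items[0].n)
    scores = [correlation(v, it.vector) for it in dictionary.items]
    best = int(np.argmax(scores))
    score = scores[best]
    if score < dictionary.accept_threshold:
        return CleanupResult(None, score)
    return CleanupResult(dictionary.items[best].label, score)


def _sequence_permutation(n: int) -> np.ndarray:
    # fixed, dimension-determined component shuffle; breaks the symmetry of
    # commutative binding so "i precedes i+1" is distinguishable from the
    # reverse (a circular shift would NOT do: it commutes with convolution)
    return np.random.default_rng(94781).permutation(n)


def _protect(item: HoloItem) -> HoloItem:
    perm = _sequence_permutation(item.n)
    return HoloItem(item.vector[perm], item.label + "~seq")


def encode_sequence(items: list[HoloItem]) -> HoloTrace:
    """Store a sequence as superposed successive-element bindings.

    Element ``i`` is bound to element ``i+1`` with the cue-side operand
    passed through a fixed component permutation, making the binding
    directional: unbinding with the (permuted) current element retrieves
    its successor, not its predecessor.
    """
    if len(items) < 2:
        raise ValidationError("a sequence needs at least 2 elements")
    return superpose_traces([bind(_protect(a), b) for a, b in zip(items, items[1:])])


def recall_sequence(
    memory: HoloTrace,
    prefix: list[HoloItem],
    dictionary: CleanupDictionary,
    k: int,
) -> list[str]:
    """Complete a stored sequence from a prefix.

    ``memory`` must come from :func:`encode_sequence` (successive
    elements bound pairwise).  Starting from the last prefix element,
    each step unbinds the current element, cleans up the reconstruction,
    appends the recovered label and continues from it.  Stops after
    ``k`` steps or at the first no-match (truncation is flagged with a
    warning).
    """
    if not prefix:
        raise ValidationError("prefix must be non-empty")
    if k < 0:
        raise ValidationError("k must be >= 0")
    labels: list[str] = []
    current = prefix[-1]
    for _ in range(k):
        res = cleanup(unbind(memory, _protect(current)), dictionary)
        if res.label is None:
            warnings.warn(
                f"sequence recall truncated after {len(labels)} of {k} steps "
                f"(best score {res.score:.3f} below threshold)",
                stacklevel=2,
            )
            break
        labels.append(res.label)
        current = dictionary.get(res.label)
    return labels


def degrade(
    t: HoloTrace, keep_fraction: float, rng: np.random.Generator
) -> HoloTrace:
    """Zero all but a random ``ceil(keep_fraction * n)`` components.

    Models losing a piece of the hologram: recall from the surviving
    fragment still works, with resolution falling as the fragment
    shrinks.
    """
    if not 0 < keep_fraction <= 1:
        raise ValidationError("keep_fraction must be in (0, 1]")
    n = t.n
    n_keep = int(np.ceil(keep_fraction * n))
    if n_keep >= n:
        return HoloTrace(t.vector.copy(), t.n_bindings)
    keep = rng.choice(n, size=n_keep, replace=False)
    v = np.zeros(n)
    v[keep] = t.vector[keep]
    return HoloTrace(v, t.n_bindings)
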