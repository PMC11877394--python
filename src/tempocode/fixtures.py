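"""Synthetic fixture generation.

Every input class the toolkit's mechanisms assume can be produced here
deterministically from a :class:`FixtureSpec`: periodic and harmonic
waveforms, AM tones, Poisson and jittered periodic spike trains, and
random bipolar vectors.  A given (spec, seed) pair always yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core_signals import SpikeTrain, Waveform
from .errors import ConfigError

__all__ = ["FixtureSpec", "generate_fixture", "cochlear_channels", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "pure_tone",
    "harmonic_complex",
    "am_tone",
    "poisson_train",
    "jittered_periodic_train",
    "bipolar_vectors",
)

_STOCHASTIC = ("poisson_train", "jittered_periodic_train", "bipolar_vectors")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic input."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    duration: float = 1.0
    sample_rate: float = 8000.0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ConfigError(f"unknown fixture kind {self.kind!r}; valid: {FIXTURE_KINDS}")
        if self.kind in _STOCHASTIC and self.seed is None:
            raise ConfigError(f"field 'seed' is mandatory for stochastic kind {self.kind!r}")
        if not self.duration > 0:
            raise ConfigError("field 'duration' must be > 0")
        if not self.sample_rate > 0:
            raise ConfigError("field 'sample_rate' must be > 0")


def _require(params: dict, name: str, kind: str):
    if name not in params:
        raise ConfigError(f"fixture kind {kind!r} requires parameter {name!r}")
    return params[name]


def generate_fixture(spec: FixtureSpec):
    """Generate the waveform / spike train / vectors a spec describes."""
    p = spec.parameters
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    t = np.arange(int(round(spec.duration * fs))) / fs

    if spec.kind == "pure_tone":
        hz = float(_require(p, "hz", spec.kind))
        if hz <= 0:
            raise ConfigError("parameter 'hz' must be > 0")
        amp = float(p.get("amplitude", 1.0))
        return Waveform(amp * np.sin(2 * np.pi * hz * t), fs)

    if spec.kind == "harmonic_complex":
        freqs = [float(f) for f in _require(p, "freqs", spec.kind)]
        if not freqs or any(f <= 0 for f in freqs):
            raise ConfigError("parameter 'freqs' must be a non-empty list of positive Hz")
        amps = p.get("amplitudes", [1.0] * len(freqs))
        if len(amps) != len(freqs):
            raise ConfigError("parameter 'amplitudes' must match 'freqs' in length")
        s = np.zeros_like(t)
        for f, a in zip(freqs, amps):
            s += a * np.sin(2 * np.pi * f * t)
        return Waveform(s, fs)

    if spec.kind == "am_tone":
        carrier_hz = float(_require(p, "carrier_hz", spec.kind))
        mod_hz = float(_require(p, "mod_hz", spec.kind))
        depth = float(p.get("depth", 1.0))
        if not 0 <= depth <= 1:
            raise ConfigError("parameter 'depth' must be in [0, 1]")
        env = 1.0 + depth * np.sin(2 * np.pi * mod_hz * t)
        return Waveform(env * np.sin(2 * np.pi * carrier_hz * t), fs)

    if spec.kind == "poisson_train":
        rate = float(_require(p, "rate", spec.kind))
        if rate <= 0:
            raise ConfigError("parameter 'rate' must be > 0")
        # draw in blocks of exponential gaps until past duration
        times: list[np.ndarray] = []
        total, last = 0.0, 0.0
        while last < spec.duration:
            gaps = rng.exponential(1.0 / rate, size=max(16, int(rate * spec.duration // 4) + 1))
            block = last + np.cumsum(gaps)
            times.append(block)
            last = block[-1]
        all_times = np.concatenate(times)
        return SpikeTrain(all_times[all_times < spec.duration], spec.duration)

    if spec.kind == "jittered_periodic_train":
        hz = float(_require(p, "hz", spec.kind))
        jitter = float(p.get("jitter", 0.0))
        if hz <= 0:
            raise ConfigError("parameter 'hz' must be > 0")
        if jitter < 0:
            raise ConfigError("parameter 'jitter' must be >= 0")
        base = np.arange(0.0, spec.duration, 1.0 / hz)
        times = np.sort(base + rng.normal(0.0, jitter, size=base.size))
        times = times[(times >= 0) & (times < spec.duration)]
        times = np.unique(times)
        return SpikeTrain(times, spec.duration)

    if spec.kind == "bipolar_vectors":
        n = int(_require(p, "n", spec.kind))
        count = int(_require(p, "count", spec.kind))
        if n < 1 or count < 1:
            raise ConfigError("parameters 'n' and 'count' must be >= 1")
        return rng.choice([-1.0, 1.0], size=(count, n))

    raise ConfigError(f"unknown fixture kind {spec.kind!r}")  # pragma: no cover


def cochlear_channels(
    w: Waveform,
    n_channels: int = 30,
    f_lo: float = 400.0,
    f_hi: float = 1400.0,
    rel_bandwidth: float = 0.25,
) -> list[Waveform]:
    """Minimal band-pass channel bank (log-spaced Butterworth filters).

    Just enough of a front end for missing-fundamental fixtures: each
    channel band-passes the input around a center frequency; channels
    are then phase-lock encoded independently.
    """
    if n_channels < 1 or not 0 < f_lo < f_hi:
        raise ConfigError("need n_channels >= 1 and 0 < f_lo < f_hi")
    centers = np.geomspace(f_lo, f_hi, n_channels)
    out = []
    for fc in centers:
        lo, hi = fc * (1 - rel_bandwidth / 2), fc * (1 + rel_bandwidth / 2)
        sos = butter(4, [lo, hi], btype="bandpass", fs=w.sample_rate, output="sos")
        out.append(Waveform(sosfiltfilt(sos, w.samples), w.sample_rate, w.t0))
    return out
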