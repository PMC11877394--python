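"""Delay-and-sum wave interference in one dimension.

Signals transmitted over pathways with different delays and gains are
superposed pointwise; depending on relative delay the copies reinforce
(constructive) or cancel (destructive).  ``relative_phase`` measures the
phase offset and spectral coherence of two signals at a frequency of
interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import coherence as _scipy_coherence

from .core_signals import Waveform
from .errors import UndefinedPhaseError, ValidationError

__all__ = ["Component", "delay_signal", "superpose", "relative_phase", "steady_state_amplitude"]


@dataclass(frozen=True)
class Component:
    """One pathway: a waveform, its transmission delay, and its gain."""

    wave: Waveform
    delay: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValidationError("delay must be >= 0")
        if not np.isfinite(self.gain):
            raise ValidationError("gain must be finite")


def _shifted_into(out: np.ndarray, s: np.ndarray, shift_samples: float, gain: float) -> None:
    """Add ``gain * s`` delayed by ``shift_samples`` (possibly fractional,
    linearly interpolated) into ``out`` in place."""
    n_int = int(np.floor(shift_samples))
    frac = shift_samples - n_int
    if frac < 1e-9 or frac > 1 - 1e-9:
        n_int = int(round(shift_samples))
        stop = min(out.size, n_int + s.size)
        if stop > n_int >= 0:
            out[n_int:stop] += gain * s[: stop - n_int]
        return
    # out[k] = frac*s[k-n-1] + (1-frac)*s[k-n]
    a = gain * frac
    b = gain * (1.0 - frac)
    stop = min(out.size, n_int + 1 + s.size)
    if stop > n_int + 1:
        out[n_int + 1 : stop] += a * s[: stop - n_int - 1]
    stop = min(out.size, n_int + s.size)
    if stop > n_int:
        out[n_int:stop] += b * s[: stop - n_int]


def delay_signal(w: Waveform, dt: float) -> Waveform:
    """Delay a waveform by ``dt`` seconds.

    The output has the same length and sample rate; sample ``k`` holds
    the input value at time ``t_k - dt`` (linearly interpolated for
    non-sample-aligned delays), and the first ``dt`` seconds are zero.
    A delay at or beyond the waveform's duration returns an all-zero
    signal and emits a warning.
    """
    if dt < 0:
        raise ValidationError("dt must be >= 0")
    if dt >= w.duration:
        warnings.warn(
            f"delay {dt} s is >= waveform duration {w.duration} s; output is all-zero",
            stacklevel=2,
        )
        return Waveform(np.zeros(len(w)), w.sample_rate, w.t0)
    out = np.zeros(len(w))
    _shifted_into(out, w.samples, dt * w.sample_rate, 1.0)
    return Waveform(out, w.sample_rate, w.t0)


def superpose(components: list[Component]) -> Waveform:
    """Pointwise sum of delayed, gain-scaled components.

    All components must share a sample rate.  The output spans the
    longest delayed component; shorter ones are zero-padded.
    """
    if not components:
        raise ValidationError("component list must be non-empty")
    fs = components[0].wave.sample_rate
    for c in components:
        if c.wave.sample_rate != fs:
            raise ValidationError(
                f"mismatched sample rates: {c.wave.sample_rate} != {fs}"
            )
    n_out = max(int(np.ceil(len(c.wave) + c.delay * fs)) for c in components)
    out = np.zeros(n_out)
    for c in components:
        _shifted_into(out, c.wave.samples, c.delay * fs, c.gain)
    return Waveform(out, fs, components[0].wave.t0)


def steady_state_amplitude(w: Waveform, f: float) -> float:
    """Amplitude of the component at ``f`` Hz, excluding one full period
    of onset and offset transient at each end."""
    fs = w.sample_rate
    guard = int(np.ceil(fs / f))
    avail = len(w) - 2 * guard
    # truncate to an integer number of periods so the projection is leak-free
    n_per = int(np.floor(avail / fs * f))
    if n_per < 1:
        raise ValidationError("waveform too short for steady-state analysis at this f")
    m = int(round(n_per * fs / f))
    s = w.samples[guard : guard + m]
    t = np.arange(s.size) / fs
    z = np.sum(s * np.exp(-2j * np.pi * f * t))
    return 2.0 * np.abs(z) / s.size


def relative_phase(w1: Waveform, w2: Waveform, f: float) -> tuple[float, float]:
    """Relative phase (radians, in (-pi, pi]) and magnitude-squared
    coherence of ``w1`` vs ``w2`` at frequency ``f``.

    A positive phase means ``w1`` leads (``w2`` delayed by ``dt``
    yields phase ``+2*pi*f*dt`` mod 2pi).

    Raises
    ------
    UndefinedPhaseError
        If either signal carries negligible power at ``f``.
    ValidationError
        If sample rates differ or ``f`` is not resolvable.
    """
    if w1.sample_rate != w2.sample_rate:
        raise ValidationError("sample rates must match")
    fs = w1.sample_rate
    n = min(len(w1), len(w2))
    if f <= 0 or f >= fs / 2 or n / fs < 2.0 / f:
        raise ValidationError("f not resolvable for these durations")

    guard = int(np.ceil(fs / f))
    sl = slice(guard, n - guard) if n - 2 * guard > 4 else slice(0, n)
    t = np.arange(sl.stop - sl.start) / fs
    e = np.exp(-2j * np.pi * f * t)
    z1 = np.sum(w1.samples[sl] * e)
    z2 = np.sum(w2.samples[sl] * e)
    m = sl.stop - sl.start
    floor1 = 1e-9 * max(1.0, float(np.max(np.abs(w1.samples)))) * m
    floor2 = 1e-9 * max(1.0, float(np.max(np.abs(w2.samples)))) * m
    if np.abs(z1) < floor1 or np.abs(z2) < floor2:
        raise UndefinedPhaseError(f"negligible power at {f} Hz")

    phase = float(np.angle(z1 * np.conj(z2)))

    nperseg = min(n, max(64, n // 16))
    freqs, cxy = _scipy_coherence(w1.samples[:n], w2.samples[:n], fs=fs, nperseg=nperseg)
    coh = float(cxy[np.argmin(np.abs(freqs - f))])
    return phase, min(max(coh, 0.0), 1.0)
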