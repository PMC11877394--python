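"""Single-sideband carrier-suppressed (SSBCS) heterodyne mixing.

Multiplying a carrier at F2 by a local oscillator at F1 produces sum
(F1+F2) and difference (F2-F1) sidebands; a low-pass stage keeps only
the difference band, so the stage output oscillates at an emergent
frequency neither input contained, while the generating frequencies are
suppressed.  Chaining stages — each stage's difference band becoming the
next stage's carrier — yields a strictly descending sequence of
emergent carriers.  Amplitude envelopes ride the sidebands and survive
mixing, so information is transported down the cascade even as the
carriers that carried it are replaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, firwin, kaiserord, periodogram, welch

from .core_signals import Waveform
from .errors import ConfigError, NoEstimateError, ValidationError

__all__ = [
    "MixerStage",
    "StageRecord",
    "CascadeResult",
    "SpectralPeakReport",
    "BAND_HZ",
    "mix",
    "lowpass_fir",
    "ssbcs_select",
    "run_cascade",
    "dominant_frequency",
    "spectral_peaks",
    "transport_envelope",
    "recover_envelope",
    "envelope_correlation",
]

#: Named oscillation-band center frequencies (Hz) used as cascade defaults.
BAND_HZ: dict[str, float] = {
    "very_high_gamma": 180.0,
    "high_gamma": 90.0,
    "gamma": 45.0,
    "beta": 24.0,
    "alpha": 10.0,
    "theta": 6.0,
    "delta": 2.5,
    "low_delta": 1.5,
}

DEFAULT_SAMPLE_RATE = 2000.0
DEFAULT_DURATION = 20.0
DEFAULT_SUPPRESSION_FLOOR = 40.0  # dB


@dataclass(frozen=True)
class MixerStage:
    """One SSBCS stage: carrier F2, local oscillator F1, low-pass cutoff.

    The cutoff must lie strictly between the difference (F2-F1) and sum
    (F2+F1) frequencies so the stage passes the one and rejects the
    other.
    """

    f_carrier: float
    f_lo: float
    lp_cutoff: float
    suppression_floor: float = DEFAULT_SUPPRESSION_FLOOR

    def __post_init__(self) -> None:
        if not self.f_carrier > self.f_lo > 0:
            raise ConfigError(
                f"require f_carrier > f_lo > 0, got F2={self.f_carrier}, F1={self.f_lo}"
            )
        diff, ssum = self.f_carrier - self.f_lo, self.f_carrier + self.f_lo
        if not diff < self.lp_cutoff < ssum:
            raise ConfigError(
                f"lp_cutoff {self.lp_cutoff} must lie strictly between "
                f"difference {diff} and sum {ssum}"
            )
        if not self.suppression_floor > 0:
            raise ConfigError("suppression_floor must be > 0 dB")

    @property
    def f_diff(self) -> float:
        return self.f_carrier - self.f_lo

    @property
    def f_sum(self) -> float:
        return self.f_carrier + self.f_lo


@dataclass(frozen=True)
class StageRecord:
    """Measured outcome of one cascade stage.

    Residual powers are in dB relative to the emergent peak (negative =
    suppressed).  ``separable_f1``/``separable_f2`` flag whether that
    generating frequency is spectrally distinguishable from the emergent
    carrier; when F2 = 2*F1 the difference band lands exactly on F1, so
    no residual there can be attributed to the input.
    """

    f1: float
    f2: float
    emergent_hz: float
    cutoff_hz: float
    residual_f1_db: float
    residual_f2_db: float
    residual_sum_db: float
    separable_f1: bool
    separable_f2: bool

    def to_dict(self) -> dict:
        return {
            "f1": self.f1,
            "f2": self.f2,
            "emergent_hz": self.emergent_hz,
            "cutoff_hz": self.cutoff_hz,
            "residual_db": {"f1": self.residual_f1_db, "f2": self.residual_f2_db},
            "sum_residual_db": self.residual_sum_db,
            "separable": {"f1": self.separable_f1, "f2": self.separable_f2},
        }


@dataclass(frozen=True)
class CascadeResult:
    """All stage records plus per-stage output waveforms."""

    stages: list[StageRecord]
    waveforms: list[Waveform] = field(repr=False, default_factory=list)

    @property
    def final_carrier(self) -> float:
        return self.stages[-1].emergent_hz

    @property
    def emergent_carriers(self) -> list[float]:
        return [s.emergent_hz for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [s.to_dict() for s in self.stages],
            "final_carrier_hz": self.final_carrier,
        }


@dataclass(frozen=True)
class SpectralPeakReport:
    """Spectral peaks sorted by descending power."""

    peaks: list[tuple[float, float]]  # (frequency Hz, power dB)
    resolution: float

    def __post_init__(self) -> None:
        powers = [p for _, p in self.peaks]
        if any(powers[i] < powers[i + 1] for i in range(len(powers) - 1)):
            raise ValidationError("peaks must be sorted by descending power")


def mix(carrier: Waveform, lo: Waveform) -> Waveform:
    """Multiplicative mixing: the pointwise product of two waveforms."""
    if carrier.sample_rate != lo.sample_rate:
        raise ValidationError("sample rates must match")
    if len(carrier) != len(lo):
        raise ValidationError("durations must match")
    return Waveform(carrier.samples * lo.samples, carrier.sample_rate, carrier.t0)


def lowpass_fir(w: Waveform, cutoff: float, transition: float, atten_db: float = 60.0) -> Waveform:
    """Zero-phase linear-phase FIR low-pass (Kaiser windowed-sinc).

    ``cutoff`` is the -6 dB frequency; the transition band spans
    ``cutoff +- transition/2``; stop-band attenuation >= ``atten_db``.
    """
    fs = w.sample_rate
    if not 0 < cutoff < fs / 2:
        raise ConfigError("cutoff must be in (0, Nyquist)")
    if not transition > 0:
        raise ConfigError("transition width must be > 0")
    numtaps, beta = kaiserord(atten_db, transition / (fs / 2))
    numtaps |= 1  # odd length -> exactly linear phase, integer group delay
    numtaps = min(numtaps, 2 * (len(w) // 2) - 1)
    h = firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)
    y = fftconvolve(w.samples, h, mode="same")
    return Waveform(y, fs, w.t0)


def ssbcs_select(product: Waveform, stage: MixerStage) -> Waveform:
    """Keep the difference sideband of a mixer product.

    Low-pass filters the product at the stage cutoff; the transition
    band is sized to pass F2-F1 untouched and reject F2+F1 by at least
    the design attenuation.
    """
    transition = min(stage.lp_cutoff - stage.f_diff, stage.f_sum - stage.lp_cutoff)
    return lowpass_fir(product, stage.lp_cutoff, transition)


def _band_power_db(freqs: np.ndarray, psd: np.ndarray, f: float, half_width: float) -> float:
    mask = np.abs(freqs - f) <= half_width
    if not np.any(mask):
        return -np.inf
    p = float(np.max(psd[mask]))
    return 10.0 * np.log10(max(p, 1e-300))


def dominant_frequency(w: Waveform, f_min: float, f_max: float) -> float:
    """Frequency of the maximal spectral peak in ``[f_min, f_max]``.

    Detection uses a Welch-averaged spectrum (robust noise floor): the
    band maximum must exceed the band median by >= 6 dB or a
    :class:`NoEstimateError` is raised.  The peak is then refined on the
    full-length periodogram with local quadratic interpolation; among
    indistinguishable maxima the lowest frequency wins.  Accuracy is
    ~ max(0.1 Hz, 1/duration).
    """
    if not 0 < f_min < f_max:
        raise ValidationError("require 0 < f_min < f_max")
    if w.duration < 4.0 / f_min:
        raise ValidationError(f"duration {w.duration} s below resolution floor 4/f_min")
    fs = w.sample_rate
    n = len(w)

    nperseg = min(n, max(256, n // 8))
    f_w, p_w = welch(w.samples, fs=fs, nperseg=nperseg)
    band = (f_w >= f_min) & (f_w <= f_max)
    if not np.any(band):
        raise ValidationError("no spectral bins inside [f_min, f_max]")
    p_band = p_w[band]
    peak_p = float(np.max(p_band))
    floor_p = float(np.median(p_band))
    if peak_p <= 0 or (floor_p > 0 and 10 * np.log10(peak_p / floor_p) < 6.0):
        raise NoEstimateError("no spectral peak >= 6 dB above the median floor")
    # full-resolution refinement over the whole band (the Welch pass only
    # gates on the noise floor; the documented lowest-frequency tie-break
    # must see every candidate peak)
    win = np.hanning(n)
    spec = np.abs(np.fft.rfft(w.samples * win))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= f_min) & (freqs <= f_max)
    idx = np.flatnonzero(mask)
    sub = spec[idx]
    m = float(np.max(sub))
    cands = idx[sub >= m * (1 - 1e-9)]
    i = int(cands[0])  # lowest-frequency tie-break

    if 0 < i < freqs.size - 1:
        a, b, c = spec[i - 1], spec[i], spec[i + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    else:
        delta = 0.0
    return float((i + delta) * fs / n)


def spectral_peaks(
    w: Waveform, n_peaks: int = 5, f_min: float = 0.0, f_max: float | None = None
) -> SpectralPeakReport:
    """Top spectral peaks of a waveform as (Hz, dB) pairs."""
    from scipy.signal import find_peaks

    fs = w.sample_rate
    if f_max is None:
        f_max = fs / 2
    freqs, psd = periodogram(w.samples, fs=fs, window="hann")
    band = (freqs >= f_min) & (freqs <= f_max)
    f_b, p_b = freqs[band], psd[band]
    locs, _ = find_peaks(p_b)
    order = locs[np.argsort(p_b[locs])[::-1][:n_peaks]]
    peaks = [(float(f_b[i]), 10.0 * np.log10(max(float(p_b[i]), 1e-300))) for i in order]
    return SpectralPeakReport(peaks=peaks, resolution=float(freqs[1] - freqs[0]))


def run_cascade(
    f_start: float,
    lo_freqs: list[float],
    duration: float = DEFAULT_DURATION,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    suppression_floor: float = DEFAULT_SUPPRESSION_FLOOR,
    keep_waveforms: bool = False,
) -> CascadeResult:
    """Run a chained SSBCS mixing cascade.

    Starts from a unit sinusoid at ``f_start``; each stage mixes the
    running carrier with a unit sinusoid local oscillator, applies an
    SSBCS low-pass with cutoff at the geometric mean of the difference
    and sum frequencies, measures the emergent carrier and residual
    powers, renormalizes the output to unit amplitude, and feeds it
    forward.

    Raises
    ------
    ConfigError
        If any stage has F1 >= F2 (which would produce a zero or
        negative difference carrier).
    """
    if not lo_freqs:
        raise ConfigError("need at least one local oscillator frequency")
    fs = sample_rate
    t = np.arange(int(round(duration * fs))) / fs
    carrier = Waveform(np.sin(2 * np.pi * f_start * t), fs)
    f2 = float(f_start)
    resolution = 1.0 / duration

    stages: list[StageRecord] = []
    waveforms: list[Waveform] = []
    for f1 in lo_freqs:
        f1 = float(f1)
        if f1 >= f2:
            raise ConfigError(
                f"local oscillator {f1} Hz must be below the current carrier {f2:.4g} Hz"
            )
        diff, ssum = f2 - f1, f2 + f1
        cutoff = float(np.sqrt(diff * ssum))
        stage = MixerStage(f2, f1, cutoff, suppression_floor)
        lo_wave = Waveform(np.sin(2 * np.pi * f1 * t), fs)
        out = ssbcs_select(mix(carrier, lo_wave), stage)

        emergent = dominant_frequency(out, max(2.0 / duration, 0.25 * diff), cutoff)

        freqs, psd = periodogram(out.samples, fs=fs, window="hann")
        half = 2.0 * resolution
        p_peak = _band_power_db(freqs, psd, emergent, half)
        rec = StageRecord(
            f1=f1,
            f2=f2,
            emergent_hz=emergent,
            cutoff_hz=cutoff,
            residual_f1_db=_band_power_db(freqs, psd, f1, half) - p_peak,
            residual_f2_db=_band_power_db(freqs, psd, f2, half) - p_peak,
            residual_sum_db=_band_power_db(freqs, psd, ssum, half) - p_peak,
            separable_f1=abs(f1 - emergent) > 5 * resolution,
            separable_f2=abs(f2 - emergent) > 5 * resolution,
        )
        stages.append(rec)

        amp = float(np.sqrt(2.0) * np.std(out.samples[len(out) // 4 : -len(out) // 4]))
        if amp > 0:
            out = Waveform(out.samples / amp, fs)
        if keep_waveforms:
            waveforms.append(out)
        carrier = out
        f2 = emergent

    return CascadeResult(stages=stages, waveforms=waveforms)


def _envelope_bandwidth(w: Waveform, power_fraction: float = 0.99) -> float:
    """Frequency below which ``power_fraction`` of total power lies."""
    freqs, psd = periodogram(w.samples, fs=w.sample_rate)
    cum = np.cumsum(psd)
    if cum[-1] == 0:
        return 0.0
    return float(freqs[np.searchsorted(cum, power_fraction * cum[-1])])


def transport_envelope(envelope: Waveform, f_carrier: float) -> Waveform:
    """Amplitude-modulate an envelope onto a sinusoidal carrier.

    Precondition: envelope bandwidth (99% power) < f_carrier / 2.
    """
    if not f_carrier > 0:
        raise ConfigError("f_carrier must be > 0")
    bw = _envelope_bandwidth(envelope)
    if bw >= f_carrier / 2:
        raise ConfigError(
            f"envelope bandwidth {bw:.3g} Hz must be below f_carrier/2 = {f_carrier / 2:.3g} Hz"
        )
    t = envelope.times()
    return Waveform(envelope.samples * np.cos(2 * np.pi * f_carrier * t), envelope.sample_rate, envelope.t0)


def recover_envelope(modulated: Waveform, f_carrier: float) -> Waveform:
    """Demodulate by rectification plus low-pass at f_carrier / 2.

    The 2/pi rectification loss is compensated so a unit envelope comes
    back near unit amplitude (up to filter ripple).
    """
    if not f_carrier > 0:
        raise ConfigError("f_carrier must be > 0")
    rect = Waveform(np.abs(modulated.samples), modulated.sample_rate, modulated.t0)
    out = lowpass_fir(rect, f_carrier / 2, transition=f_carrier / 4)
    return Waveform(out.samples * (np.pi / 2.0), out.sample_rate, out.t0)


def envelope_correlation(a: Waveform, b: Waveform, edge_fraction: float = 0.1) -> float:
    """Pearson correlation of two envelopes over their common interior
    (a fraction of each edge is excluded to avoid filter transients)."""
    n = min(len(a), len(b))
    lo, hi = int(edge_fraction * n), n - int(edge_fraction * n)
    x, y = a.samples[lo:hi], b.samples[lo:hi]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant envelope: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
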