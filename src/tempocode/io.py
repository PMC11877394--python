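"""File formats: WAV / CSV waveforms, plain-text spike trains, and
CSV + JSON holographic memory serialization.

All formats round-trip exactly (WAV within float32 quantization).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .core_signals import SpikeTrain, Waveform
from .errors import ValidationError
from .holomem import CleanupDictionary, HoloItem, HoloTrace

__all__ = [
    "read_waveform",
    "write_waveform",
    "read_spike_train",
    "write_spike_train",
    "save_memory",
    "load_memory",
]


def write_waveform(path: str | Path, w: Waveform) -> None:
    """Write a waveform as WAV (float32) or two-column CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(w.sample_rate)), w.samples.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        data = np.column_stack([w.times(), w.samples])
        np.savetxt(path, data, delimiter=",", header="time_s,amplitude", comments="")
    else:
        raise ValidationError(f"unsupported waveform extension {path.suffix!r} (use .wav or .csv)")


def read_waveform(path: str | Path) -> Waveform:
    """Read a waveform from WAV (PCM or float) or two-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max)
        return Waveform(data.astype(float), float(fs))
    if path.suffix.lower() == ".csv":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if arr.shape[1] != 2:
            raise ValidationError("waveform CSV must have exactly 2 columns (time_s, amplitude)")
        t, s = arr[:, 0], arr[:, 1]
        if t.size < 2:
            raise ValidationError("waveform CSV needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or np.max(dt) - np.min(dt) > 1e-6 * np.median(dt) + 1e-12:
            raise ValidationError("waveform CSV times must be uniformly increasing")
        return Waveform(s, 1.0 / float(np.median(dt)), t0=float(t[0]))
    raise ValidationError(f"unsupported waveform extension {path.suffix!r} (use .wav or .csv)")


def write_spike_train(path: str | Path, st: SpikeTrain) -> None:
    """One decimal spike time (seconds) per line; duration header first."""
    lines = [f"duration={float(st.duration)!r}"]
    lines += [repr(float(t)) for t in st.times]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_train(path: str | Path) -> SpikeTrain:
    """Parse a spike-time text file (`#` comments, optional duration header)."""
    times: list[float] = []
    duration: float | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("duration="):
            duration = float(line.split("=", 1)[1])
            continue
        try:
            times.append(float(line))
        except ValueError as exc:
            raise ValidationError(f"bad spike-time line {raw!r}") from exc
    arr = np.asarray(times)
    if duration is None:
        duration = float(arr[-1]) if arr.size else 0.0
    return SpikeTrain(arr, duration)


def save_memory(
    basepath: str | Path,
    trace: HoloTrace,
    dictionary: CleanupDictionary,
    seed: int | None = None,
) -> None:
    """Serialize a trace + cleanup dictionary as ``<base>.csv`` (vectors,
    trace first row then one item per row) and ``<base>.json`` (labels,
    dimension, binding count, threshold, seed)."""
    basepath = Path(basepath)
    vectors = np.vstack([trace.vector] + [it.vector for it in dictionary.items])
    np.savetxt(basepath.with_suffix(".csv"), vectors, delimiter=",")
    sidecar = {
        "n": trace.n,
        "n_bindings": trace.n_bindings,
        "labels": [it.label for it in dictionary.items],
        "accept_threshold": dictionary.accept_threshold,
        "seed": seed,
    }
    basepath.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def load_memory(basepath: str | Path) -> tuple[HoloTrace, CleanupDictionary, int | None]:
    """Inverse of :func:`save_memory`."""
    basepath = Path(basepath)
    vectors = np.loadtxt(basepath.with_suffix(".csv"), delimiter=",", ndmin=2)
    sidecar = json.loads(basepath.with_suffix(".json").read_text())
    if vectors.shape[0] != len(sidecar["labels"]) + 1:
        raise ValidationError("memory CSV row count does not match sidecar labels")
    trace = HoloTrace(vectors[0], n_bindings=int(sidecar["n_bindings"]))
    items = [HoloItem(v, lab) for v, lab in zip(vectors[1:], sidecar["labels"])]
    dictionary = CleanupDictionary(items, accept_threshold=float(sidecar["accept_threshold"]))
    return trace, dictionary, sidecar.get("seed")
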