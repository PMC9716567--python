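"""Waveform container, PCM WAV I/O and amplitude rescaling.

All acoustic operations in the package consume and produce :class:`Waveform`
objects holding float samples in [-1, 1].  Files are integer PCM WAV
(16- or 24-bit); 24-bit at 48 kHz is the native stimulus format.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError, FormatError

__all__ = ["Waveform", "load_waveform", "save_waveform", "rescale"]


@dataclass
class Waveform:
    """Mono audio signal.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude values, nominally in [-1, 1].
    rate : int
        Sample rate in Hz.
    bit_depth : int
        PCM bit depth recorded for provenance (does not quantize `samples`).
    """

    samples: np.ndarray
    rate: int = 48000
    bit_depth: int = 24
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate

    def slice(self, start: float, end: float) -> "Waveform":
        """Extract [start, end) seconds as a new waveform."""
        i0 = max(0, int(round(start * self.rate)))
        i1 = min(self.samples.size, int(round(end * self.rate)))
        if i1 <= i0:
            raise ValueError(f"empty slice ({start}, {end})")
        return replace(self, samples=self.samples[i0:i1].copy())

    def peak_normalized(self) -> "Waveform":
        return replace(self, samples=rescale(self.samples, mode="peak"))


def rescale(values, mode: str = "peak") -> np.ndarray:
    """Rescale amplitudes.

    ``peak``  : divide by max absolute value so max(|out|) == 1.
    ``minmax``: map linearly onto [0, 1].

    Raises
    ------
    DegenerateInputError
        All-zero input (peak) or constant input (minmax).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty input")
    if mode == "peak":
        peak = np.max(np.abs(x))
        if peak == 0:
            raise DegenerateInputError("all-zero input has no peak")
        return x / peak
    if mode == "minmax":
        lo, hi = np.min(x), np.max(x)
        if hi == lo:
            raise DegenerateInputError("constant input: min-max undefined")
        return (x - lo) / (hi - lo)
    raise ValueError(f"unknown mode {mode!r}")


def load_waveform(path) -> Waveform:
    """Read an integer PCM WAV file into a float waveform in [-1, 1].

    Multichannel files are averaged to mono.
    """
    try:
        with wave.open(str(path), "rb") as fh:
            n_channels = fh.getnchannels()
            sampwidth = fh.getsampwidth()
            rate = fh.getframerate()
            n_frames = fh.getnframes()
            raw = fh.readframes(n_frames)
    except (wave.Error, EOFError) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if sampwidth not in (2, 3):
        raise FormatError(f"unsupported sample width {sampwidth * 8} bits")
    if sampwidth == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    else:  # 24-bit: widen each triple to int32 then shift for sign
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        data = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        data = (data << 8) >> 8  # sign-extend
    if n_channels > 1:
        data = data.reshape(-1, n_channels).mean(axis=1)
    scale = float(1 << (8 * sampwidth - 1))
    return Waveform(data / scale, rate=rate, bit_depth=8 * sampwidth, source=str(path))


def save_waveform(w: Waveform, path) -> None:
    """Write a waveform as integer PCM WAV at its recorded bit depth."""
    if w.bit_depth not in (16, 24):
        raise FormatError(f"unsupported bit depth {w.bit_depth}")
    sampwidth = w.bit_depth // 8
    full = 1 << (w.bit_depth - 1)
    clipped = np.clip(w.samples, -1.0, 1.0 - 1.0 / full)
    ints = np.round(clipped * full).astype(np.int32)
    if sampwidth == 2:
        raw = ints.astype("<i2").tobytes()
    else:
        u = ints.astype(np.int32).view(np.uint32)
        b = np.empty((ints.size, 3), dtype=np.uint8)
        b[:, 0] = u & 0xFF
        b[:, 1] = (u >> 8) & 0xFF
        b[:, 2] = (u >> 16) & 0xFF
        raw = b.tobytes()
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(sampwidth)
        fh.setframerate(w.rate)
        fh.writeframes(raw)
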