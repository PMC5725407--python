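"""Triangle-wave rendering of a tone set and audio analysis utilities.

Each lobe's frequency drives an ideal triangular-wave oscillator; the
three oscillators are mixed at equal amplitude and written as 16-bit PCM
mono WAV.  The analysis helpers (spectral peak picking, Hilbert envelope,
modulation depth) are what the test suite and acceptance checks use to
verify that a render actually carries the intended tones and beat rates.

The triangle is the naive (non-band-limited) waveform
``tri(x) = (2/pi) * arcsin(sin(x))``: at fundamentals of a few hundred Hz
rendered at 44.1 kHz the aliasing of its 1/k^2 harmonics is inaudible,
and the closed form makes the waveform exactly testable.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import find_peaks, hilbert

from .errors import AliasingError, ParameterError
from .sonify import ToneSet

DEFAULT_SAMPLE_RATE = 44100
DEFAULT_DURATION_S = 30.0
_PCM_FULL_SCALE = 32767


@dataclass(frozen=True)
class AudioBuffer:
    """Mono float audio in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


def triangle_wave(
    freq: float,
    duration_s: float = DEFAULT_DURATION_S,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    amplitude: float = 1.0,
    phase: float = 0.0,
) -> AudioBuffer:
    """Ideal triangle oscillator.

    Zero-crossing convention: at t = 0 with zero phase the sample is 0 and
    rising.  One period spans ``sample_rate / freq`` samples.
    """
    if freq <= 0:
        raise ParameterError(f"frequency must be positive, got {freq}")
    if freq >= sample_rate / 2:
        raise AliasingError(
            f"frequency {freq} Hz at or above Nyquist ({sample_rate / 2} Hz)"
        )
    if not (0.0 < amplitude <= 1.0):
        raise ParameterError(f"amplitude must be in (0, 1], got {amplitude}")
    n = round(sample_rate * duration_s)
    t = np.arange(n) / sample_rate
    x = 2.0 * np.pi * freq * t + phase
    samples = amplitude * (2.0 / np.pi) * np.arcsin(np.sin(x))
    return AudioBuffer(samples=samples, sample_rate=sample_rate)


def render_tts(
    tones: ToneSet,
    duration_s: float = DEFAULT_DURATION_S,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioBuffer:
    """Equal-amplitude mix of the three triangle oscillators.

    Each oscillator contributes amplitude 1/3 at zero initial phase; the
    mix is peak-normalized so no sample exceeds 1 in magnitude.  Bitwise
    deterministic for fixed inputs.
    """
    mix = np.zeros(round(sample_rate * duration_s))
    for f in tones.frequencies:
        mix += triangle_wave(
            f, duration_s, sample_rate, amplitude=1.0 / 3.0
        ).samples
    peak = np.abs(mix).max()
    if peak > 1.0:
        mix = mix / peak
    return AudioBuffer(samples=mix, sample_rate=sample_rate)


def write_wav(buffer: AudioBuffer, path: str | Path) -> None:
    """Write 16-bit PCM mono WAV: samples scaled by 32767 and rounded
    half-away-from-zero."""
    x = np.asarray(buffer.samples, dtype=float)
    if x.size and np.abs(x).max() > 1.0:
        raise ParameterError("buffer samples exceed [-1, 1]; normalize first")
    scaled = x * _PCM_FULL_SCALE
    pcm = (np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)).astype(np.int16)
    with wave.open(str(path), "wb") as wav:
        wav.setnchannels(1)
        wav.setsampwidth(2)
        wav.setframerate(buffer.sample_rate)
        wav.writeframes(pcm.tobytes())


def read_wav(path: str | Path) -> AudioBuffer:
    """Read a 16-bit PCM mono WAV back into float samples in [-1, 1]."""
    with wave.open(str(path), "rb") as wav:
        if wav.getnchannels() != 1 or wav.getsampwidth() != 2:
            raise ParameterError("expected 16-bit PCM mono WAV")
        rate = wav.getframerate()
        pcm = np.frombuffer(wav.readframes(wav.getnframes()), dtype=np.int16)
    return AudioBuffer(samples=pcm / _PCM_FULL_SCALE, sample_rate=rate)


def _windowed_spectrum(samples: np.ndarray, sample_rate: int):
    window = np.hanning(len(samples))
    mag = np.abs(rfft(samples * window))
    freqs = rfftfreq(len(samples), d=1.0 / sample_rate)
    return freqs, mag


def spectral_peaks(buffer: AudioBuffer, n_peaks: int) -> list[float]:
    """Frequencies of the ``n_peaks`` largest local maxima of the magnitude
    spectrum, descending by magnitude.

    Uses a Hann window; a peak frequency is accurate to within one FFT bin
    (``sample_rate / len(samples)`` Hz).  Returns fewer peaks (possibly
    none, e.g. for silence) when fewer are resolvable.
    """
    if len(buffer.samples) < 16:
        raise ParameterError("buffer too short for spectral analysis")
    freqs, mag = _windowed_spectrum(buffer.samples, buffer.sample_rate)
    floor = mag.max() * 1e-3  # ignore window-leakage sidelobes
    if floor == 0.0:
        return []
    idx, _ = find_peaks(mag, height=floor, distance=3)
    top = idx[np.argsort(mag[idx])[::-1][:n_peaks]]
    return [float(freqs[i]) for i in top]


def amplitude_envelope(buffer: AudioBuffer, smooth_s: float = 0.0) -> np.ndarray:
    """Hilbert-transform amplitude envelope, optionally smoothed by a
    moving average of ``smooth_s`` seconds (suppresses waveform-harmonic
    ripple while passing beat-rate modulation)."""
    env = np.abs(hilbert(buffer.samples))
    if smooth_s > 0:
        width = max(1, round(smooth_s * buffer.sample_rate))
        env = np.convolve(env, np.ones(width) / width, mode="same")
    return env


def envelope_peaks(
    buffer: AudioBuffer, n_peaks: int, fmax: float = 100.0
) -> list[float]:
    """Dominant amplitude-modulation rates (Hz) below ``fmax``.

    The mean-removed Hilbert envelope is Hann-windowed and transformed;
    the ``n_peaks`` largest local maxima below ``fmax`` are returned,
    descending by magnitude.  For a mixture of close tones these are the
    beat rates (pairwise frequency differences).
    """
    env = amplitude_envelope(buffer)
    env = env - env.mean()
    freqs, mag = _windowed_spectrum(env, buffer.sample_rate)
    keep = (freqs > 0.0) & (freqs <= fmax)
    if not keep.any() or mag[keep].max() == 0.0:
        return []
    mag_kept = np.where(keep, mag, 0.0)
    idx, _ = find_peaks(mag_kept, height=mag[keep].max() * 1e-4, distance=3)
    top = idx[np.argsort(mag_kept[idx])[::-1][:n_peaks]]
    return [float(freqs[i]) for i in top]


def modulation_depth(buffer: AudioBuffer, smooth_s: float = 0.010) -> float:
    """Amplitude-modulation depth (max-min)/(max+min) of the smoothed
    envelope, with 5% trimmed from each end to discard transform edge
    effects.  Near 0 for a steady tone; large when tones beat."""
    env = amplitude_envelope(buffer, smooth_s=smooth_s)
    trim = len(env) // 20
    env = env[trim : len(env) - trim]
    hi, lo = env.max(), env.min()
    if hi + lo == 0.0:
        return 0.0
    return float((hi - lo) / (hi + lo))
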