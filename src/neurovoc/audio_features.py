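"""Log-mel spectrogram extraction from the audio track.

The audio is downsampled to 16 kHz, short-time Fourier transformed in
50 ms windows with a 10 ms frameshift (800 / 160 samples at 16 kHz,
periodic Hann, 1024-point FFT) and compressed through 23 triangular
filters spaced on the HTK mel scale between 0 and 8 kHz. Energies are
power (squared magnitude) pooled, floored at 1e-10 and natural-log
compressed; the same conventions are inverted exactly by the synthesis
module, so they must not drift apart.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import firwin, resample_poly

from .errors import DimensionError, InvalidRateError, TooShortError
from .framing import HOP_S, WINDOW_S, FrameGrid
from . import stft as _stft

__all__ = [
    "TARGET_RATE",
    "N_MELS",
    "LOG_FLOOR",
    "MelFilterbank",
    "LogMelSpectrogram",
    "resample_to_16k",
    "stft_magnitude",
    "hz_to_mel",
    "mel_to_hz",
    "build_mel_filterbank",
    "apply_log_mel",
    "compute_log_mel",
]

logger = logging.getLogger(__name__)

TARGET_RATE = 16000
N_MELS = 23
F_MIN = 0.0
F_MAX = 8000.0
WIN_SAMPLES = int(round(WINDOW_S * TARGET_RATE))  # 800
HOP_SAMPLES = int(round(HOP_S * TARGET_RATE))  # 160
N_FFT = 1024  # next power of two above the 800-sample window
LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class MelFilterbank:
    """Triangular mel filterbank on one-sided FFT bins."""

    weights: np.ndarray  # (n_filters, n_fft_bins)
    center_frequencies: np.ndarray  # (n_filters,), Hz
    rate: float = TARGET_RATE
    n_fft: int = N_FFT
    f_min: float = F_MIN
    f_max: float = F_MAX

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


@dataclass
class LogMelSpectrogram:
    """Frames x mel-band natural-log power energies on the shared grid."""

    values: np.ndarray  # (n_frames, n_mels)
    grid: FrameGrid
    n_filters: int = N_MELS
    f_min: float = F_MIN
    f_max: float = F_MAX
    target_rate: float = TARGET_RATE

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def hz_to_mel(f):
    """HTK mel scale: 2595 * log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def resample_to_16k(audio: np.ndarray, audio_rate: float) -> np.ndarray:
    """Anti-aliased polyphase resampling down to 16 kHz."""
    audio = np.asarray(audio, dtype=float).ravel()
    r = int(round(audio_rate))
    if abs(audio_rate - r) > 1e-6:
        raise InvalidRateError(f"audio rate must be an integer number of Hz, got {audio_rate}")
    if r < TARGET_RATE:
        raise InvalidRateError(f"cannot upsample {r} Hz audio to {TARGET_RATE} Hz")
    if r == TARGET_RATE:
        return audio.copy()
    frac = Fraction(TARGET_RATE, r)
    up, down = frac.numerator, frac.denominator
    # sharp anti-alias FIR at the upsampled rate; the resample_poly default
    # (2*10*max(up,down)+1 taps) leaves aliases only ~26 dB down
    max_rate = max(up, down)
    ntaps = min(2 * 160 * max_rate + 1, 8001)
    h = firwin(ntaps, 0.995 * TARGET_RATE / 2, window=("kaiser", 8.0), fs=r * up)
    return resample_poly(audio, up, down, window=h * up)


def stft_magnitude(audio16: np.ndarray) -> tuple[np.ndarray, FrameGrid]:
    """Magnitude spectrogram of 16 kHz audio on the shared frame grid."""
    audio16 = np.asarray(audio16, dtype=float).ravel()
    if audio16.size < WIN_SAMPLES:
        raise TooShortError(
            f"audio of {audio16.size} samples is shorter than one {WIN_SAMPLES}-sample window"
        )
    mag = _stft.stft_magnitude_frames(audio16, WIN_SAMPLES, HOP_SAMPLES, N_FFT)
    grid = FrameGrid(window=WINDOW_S, hop=HOP_S, n_frames=mag.shape[0])
    return mag, grid


def build_mel_filterbank(
    n_filters: int = N_MELS,
    rate: float = TARGET_RATE,
    n_fft: int = N_FFT,
    f_min: float = F_MIN,
    f_max: float = F_MAX,
) -> MelFilterbank:
    """Triangular filters with peaks at n_filters mel-equidistant centers."""
    if not (0 <= f_min < f_max <= rate / 2):
        raise ValueError("need 0 <= f_min < f_max <= Nyquist")
    edges_mel = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_filters + 2)
    edges_hz = mel_to_hz(edges_mel)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    weights = np.zeros((n_filters, fft_freqs.size))
    for j in range(n_filters):
        lo, mid, hi = edges_hz[j], edges_hz[j + 1], edges_hz[j + 2]
        up = (fft_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - mid, 1e-12)
        weights[j] = np.clip(np.minimum(up, down), 0.0, None)
    return MelFilterbank(
        weights=weights,
        center_frequencies=edges_hz[1:-1],
        rate=rate,
        n_fft=n_fft,
        f_min=f_min,
        f_max=f_max,
    )


def apply_log_mel(mag: np.ndarray, fb: MelFilterbank, grid: FrameGrid | None = None) -> LogMelSpectrogram:
    """Pool squared magnitudes through the filterbank and log-compress.

    Power convention: mel energy = fb @ |X|^2, then log(max(e, 1e-10)).
    """
    mag = np.asarray(mag, dtype=float)
    if mag.ndim != 2 or mag.shape[1] != fb.weights.shape[1]:
        raise DimensionError(
            f"magnitude has {mag.shape[-1] if mag.ndim == 2 else '?'} bins, "
            f"filterbank expects {fb.weights.shape[1]}"
        )
    energy = (mag**2) @ fb.weights.T
    values = np.log(np.maximum(energy, LOG_FLOOR))
    if grid is None:
        grid = FrameGrid(n_frames=values.shape[0])
    return LogMelSpectrogram(
        values=values,
        grid=grid,
        n_filters=fb.n_filters,
        f_min=fb.f_min,
        f_max=fb.f_max,
        target_rate=fb.rate,
    )


def compute_log_mel(audio: np.ndarray, audio_rate: float, fb: MelFilterbank | None = None) -> LogMelSpectrogram:
    """Resample -> STFT -> 23-band log-mel, the full audio feature chain."""
    audio16 = resample_to_16k(audio, audio_rate)
    mag, grid = stft_magnitude(audio16)
    if fb is None:
        fb = build_mel_filterbank()
    return apply_log_mel(mag, fb, grid)
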