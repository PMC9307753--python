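"""Minimal STFT / inverse-STFT pair with fixed conventions.

Frames start at sample k*hop (no centering, no padding at the edges), are
windowed with a periodic Hann window and zero-padded to ``n_fft`` before a
one-sided FFT. The inverse is the least-squares overlap-add inverse
(window-weighted OLA divided by the summed squared window), which is the
orthogonal projection onto the range of the STFT — the property the
Griffin-Lim iteration needs for its error to be non-increasing.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .errors import TooShortError

__all__ = ["stft", "stft_magnitude_frames", "istft", "n_stft_frames"]


def n_stft_frames(n_samples: int, win_length: int, hop_length: int) -> int:
    if n_samples < win_length:
        return 0
    return (n_samples - win_length) // hop_length + 1


def _frames(x: np.ndarray, win_length: int, hop_length: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < win_length:
        raise TooShortError(
            f"signal of {x.size} samples is shorter than one {win_length}-sample window"
        )
    return sliding_window_view(x, win_length)[::hop_length]


def stft(x: np.ndarray, win_length: int, hop_length: int, n_fft: int | None = None) -> np.ndarray:
    """Complex one-sided STFT, shape (n_frames, n_fft//2 + 1)."""
    n_fft = n_fft or win_length
    win = get_window("hann", win_length, fftbins=True)
    return np.fft.rfft(_frames(x, win_length, hop_length) * win, n=n_fft, axis=1)


def stft_magnitude_frames(x: np.ndarray, win_length: int, hop_length: int, n_fft: int | None = None) -> np.ndarray:
    return np.abs(stft(x, win_length, hop_length, n_fft))


def istft(spec: np.ndarray, win_length: int, hop_length: int, n_fft: int | None = None,
          n_samples: int | None = None) -> np.ndarray:
    """Least-squares inverse of :func:`stft`.

    ``spec`` is (n_frames, n_fft//2+1) complex. Output length defaults to
    the smallest signal covering all frames.
    """
    spec = np.asarray(spec)
    n_fft = n_fft or 2 * (spec.shape[1] - 1)
    n_frames = spec.shape[0]
    if n_samples is None:
        n_samples = (n_frames - 1) * hop_length + win_length
    win = get_window("hann", win_length, fftbins=True)
    frames = np.fft.irfft(spec, n=n_fft, axis=1)[:, :win_length]
    num = np.zeros(n_samples)
    den = np.zeros(n_samples)
    wsq = win * win
    for k in range(n_frames):
        s = k * hop_length
        e = min(s + win_length, n_samples)
        num[s:e] += frames[k, : e - s] * win[: e - s]
        den[s:e] += wsq[: e - s]
    out = np.zeros(n_samples)
    nz = den > 1e-12
    out[nz] = num[nz] / den[nz]
    return out
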