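"""Waveform resynthesis from log-mel spectrograms.

The log-mel representation discards phase, so a waveform cannot be
recovered directly. Mel energies are mapped back to a linear-frequency
magnitude spectrogram through the non-negative pseudo-inverse of the
filterbank (power convention, matching audio_features), and the phase is
recovered with the Griffin-Lim iteration: initialize with noise, then
alternately project onto signals consistent with some STFT and onto
spectra with the target magnitude. With the least-squares inverse STFT
the spectral-convergence error is non-increasing over iterations.
"""

from __future__ import annotations

import numpy as np

from . import stft as _stft
from .audio_features import (
    HOP_SAMPLES,
    LOG_FLOOR,
    N_FFT,
    WIN_SAMPLES,
    LogMelSpectrogram,
    MelFilterbank,
    build_mel_filterbank,
)
from .errors import DimensionError

__all__ = ["mel_to_linear", "griffin_lim", "synthesize_from_logmel", "spectral_convergence"]

N_ITER_DEFAULT = 32


def mel_to_linear(logmel: LogMelSpectrogram | np.ndarray,
                  fb: MelFilterbank | None = None) -> np.ndarray:
    """Invert the log-mel pooling to a magnitude spectrogram.

    Exponentiate to mel power, apply the pseudo-inverse of the filterbank,
    clamp negatives to zero and take the square root back to magnitude.
    """
    if fb is None:
        fb = build_mel_filterbank()
    values = np.asarray(getattr(logmel, "values", logmel), dtype=float)
    if values.ndim != 2 or values.shape[1] != fb.n_filters:
        raise DimensionError(
            f"log-mel has {values.shape[-1] if values.ndim == 2 else '?'} bands, "
            f"filterbank has {fb.n_filters}"
        )
    power = np.exp(values)
    power = np.where(power <= LOG_FLOOR * 1.0000001, 0.0, power)  # silence stays silent
    pinv = np.linalg.pinv(fb.weights)
    lin_power = np.clip(power @ pinv.T, 0.0, None)
    return np.sqrt(lin_power)


def spectral_convergence(mag_est: np.ndarray, mag_target: np.ndarray) -> float:
    denom = np.linalg.norm(mag_target)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(mag_est - mag_target) / denom)


def griffin_lim(
    magnitude: np.ndarray,
    n_iter: int = N_ITER_DEFAULT,
    seed: int | None = None,
    return_errors: bool = False,
):
    """Recover a waveform whose STFT magnitude approximates ``magnitude``.

    Phase is initialized uniformly in (-pi, pi] from the seeded generator
    and refined for ``n_iter`` iterations. The output is peak-normalized
    to at most 1; an all-zero magnitude gives an all-zero waveform.
    Returns the waveform, or ``(waveform, errors)`` with the
    spectral-convergence error after each iteration when requested.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if np.any(magnitude < 0):
        raise ValueError("magnitude must be non-negative")
    n_samples = (magnitude.shape[0] - 1) * HOP_SAMPLES + WIN_SAMPLES
    if not np.any(magnitude > 0):
        wave = np.zeros(n_samples)
        return (wave, []) if return_errors else wave

    rng = np.random.default_rng(seed)
    phase = np.exp(1j * rng.uniform(-np.pi, np.pi, size=magnitude.shape))
    errors = []
    for _ in range(n_iter):
        x = _stft.istft(magnitude * phase, WIN_SAMPLES, HOP_SAMPLES, N_FFT,
                        n_samples=n_samples)
        spec = _stft.stft(x, WIN_SAMPLES, HOP_SAMPLES, N_FFT)
        est = np.abs(spec)
        errors.append(spectral_convergence(est, magnitude))
        phase = spec / np.maximum(est, 1e-16)
    wave = _stft.istft(magnitude * phase, WIN_SAMPLES, HOP_SAMPLES, N_FFT,
                       n_samples=n_samples)
    peak = np.max(np.abs(wave))
    if peak > 1.0:
        wave = wave / peak
    return (wave, errors) if return_errors else wave


def synthesize_from_logmel(
    logmel: LogMelSpectrogram | np.ndarray,
    fb: MelFilterbank | None = None,
    n_iter: int = N_ITER_DEFAULT,
    seed: int | None = None,
) -> np.ndarray:
    """Full resynthesis chain: mel inversion + Griffin-Lim, 16 kHz output."""
    return griffin_lim(mel_to_linear(logmel, fb), n_iter=n_iter, seed=seed)
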