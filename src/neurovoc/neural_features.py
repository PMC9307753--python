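"""Broadband high-gamma envelope features from raw neural traces.

Each channel is band-passed to 70-170 Hz (Butterworth order 4, applied
forward and backward so no phase shift is introduced), the first two
line-noise harmonics at 100 and 150 Hz are removed with order-4 band-stop
filters, and the Hilbert envelope is averaged in 50 ms windows advanced
by 10 ms. Nine non-overlapping 50 ms context windows (up to 200 ms into
the past and future, i.e. offsets -200..+200 ms in 50 ms steps) are
stacked per channel; frames lacking full context are dropped. Features
are z-scored with training-set statistics only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .errors import DimensionError, InvalidRateError, TooShortError
from .framing import HOP_S, WINDOW_S, FrameGrid

__all__ = [
    "HG_BAND",
    "CONTEXT_OFFSETS_S",
    "NeuralFeatureMatrix",
    "Normalizer",
    "bandpass_high_gamma",
    "notch_line_harmonics",
    "hilbert_envelope",
    "frame_average",
    "stack_context",
    "extract_features",
]

logger = logging.getLogger(__name__)

HG_BAND = (70.0, 170.0)
NOTCH_BANDS = ((98.0, 102.0), (148.0, 152.0))
FILTER_ORDER = 4
# 9 context windows: 4 non-overlapping 50 ms windows per side plus the center,
# taken at 5-hop (50 ms) strides on the 10 ms frame grid
CONTEXT_OFFSETS_S = (-0.200, -0.150, -0.100, -0.050, 0.0, 0.050, 0.100, 0.150, 0.200)
CONTEXT_OFFSET_HOPS = tuple(int(round(o / HOP_S)) for o in CONTEXT_OFFSETS_S)
STD_FLOOR = 1e-8


@dataclass
class NeuralFeatureMatrix:
    """Stacked envelope features: (n_valid_frames, n_channels * 9)."""

    values: np.ndarray
    grid: FrameGrid
    context_offsets: tuple[float, ...] = CONTEXT_OFFSETS_S
    channel_names: list[str] = field(default_factory=list)
    first_valid_frame: int = 20

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1] // len(self.context_offsets)


def _check_rate(rate: float) -> None:
    if rate <= 2 * HG_BAND[1]:
        raise InvalidRateError(
            f"sampling rate {rate} Hz too low: need > {2 * HG_BAND[1]} Hz "
            f"to resolve the {HG_BAND[0]:.0f}-{HG_BAND[1]:.0f} Hz band"
        )


def bandpass_high_gamma(signal: np.ndarray, rate: float) -> np.ndarray:
    """Zero-phase order-4 Butterworth band-pass to 70-170 Hz."""
    _check_rate(rate)
    signal = np.asarray(signal, dtype=float)
    sos = butter(FILTER_ORDER, HG_BAND, btype="bandpass", fs=rate, output="sos")
    return sosfiltfilt(sos, signal, axis=-1)


def notch_line_harmonics(signal: np.ndarray, rate: float) -> np.ndarray:
    """Zero-phase order-4 band-stops at the 100 and 150 Hz line harmonics."""
    _check_rate(rate)
    out = np.asarray(signal, dtype=float)
    for band in NOTCH_BANDS:
        sos = butter(FILTER_ORDER, band, btype="bandstop", fs=rate, output="sos")
        out = sosfiltfilt(sos, out, axis=-1)
    return out


def hilbert_envelope(signal: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (instantaneous amplitude)."""
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    return np.abs(hilbert(signal, axis=-1))


def frame_average(
    envelope: np.ndarray,
    rate: float,
    window: float = WINDOW_S,
    hop: float = HOP_S,
) -> tuple[np.ndarray, FrameGrid]:
    """Mean of the envelope in [k*hop, k*hop + window) per frame k.

    Accepts a vector or a (n_channels, n_samples) matrix; returns frames
    with shape (n_frames,) or (n_frames, n_channels).
    """
    envelope = np.asarray(envelope, dtype=float)
    vec = envelope.ndim == 1
    env = np.atleast_2d(envelope)
    n = env.shape[1]
    grid = FrameGrid.from_duration(n / rate, window=window, hop=hop)
    if grid.n_frames == 0:
        raise TooShortError(f"signal of {n / rate:.4f} s is shorter than one {window} s window")
    starts, stops = grid.sample_bounds(rate)
    stops = np.minimum(stops, n)
    csum = np.concatenate([np.zeros((env.shape[0], 1)), np.cumsum(env, axis=1)], axis=1)
    frames = (csum[:, stops] - csum[:, starts]) / (stops - starts)
    frames = frames.T  # (n_frames, n_channels)
    return (frames[:, 0] if vec else frames), grid


def stack_context(frames: np.ndarray, grid: FrameGrid | None = None,
                  channel_names: list[str] | None = None) -> NeuralFeatureMatrix:
    """Stack 9 context windows per channel; drop frames lacking context.

    Output row t (for valid t) is the concatenation over offsets
    delta in (-20, -15, ..., +20) hops of the channel vector at frame
    t + delta; width = 9 * n_channels, rows = n_frames - 40.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 1:
        frames = frames[:, None]
    n_frames, n_channels = frames.shape
    max_off = max(abs(o) for o in CONTEXT_OFFSET_HOPS)
    if n_frames <= 2 * max_off:
        raise TooShortError(
            f"{n_frames} frames is too few to stack +/-{max_off}-hop context"
        )
    n_valid = n_frames - 2 * max_off
    blocks = [frames[max_off + off : max_off + off + n_valid] for off in CONTEXT_OFFSET_HOPS]
    values = np.concatenate(blocks, axis=1)
    if grid is None:
        grid = FrameGrid(n_frames=n_frames)
    names = channel_names or [f"ch{i + 1:02d}" for i in range(n_channels)]
    return NeuralFeatureMatrix(
        values=values, grid=grid, channel_names=names, first_valid_frame=max_off
    )


@dataclass
class Normalizer:
    """Per-feature z-scoring with statistics of the training fold only."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    fitted_on: str | None = None

    def fit(self, train: np.ndarray, fold: str | None = None) -> "Normalizer":
        train = np.asarray(train, dtype=float)
        if train.ndim != 2 or train.shape[0] < 2:
            raise ValueError("need a 2-D training matrix with >= 2 rows")
        self.mean = train.mean(axis=0)
        std = train.std(axis=0)
        n_flat = int(np.sum(std < STD_FLOOR))
        if n_flat:
            logger.warning("%d zero-variance feature(s); std floored at %g", n_flat, STD_FLOOR)
            warnings.warn(f"{n_flat} zero-variance feature(s) floored", RuntimeWarning, stacklevel=2)
        self.std = np.maximum(std, STD_FLOOR)
        self.fitted_on = fold
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("normalizer not fitted")
        data = np.asarray(data, dtype=float)
        if data.shape[-1] != self.mean.shape[0]:
            raise DimensionError(
                f"data has {data.shape[-1]} features, normalizer fitted on {self.mean.shape[0]}"
            )
        return (data - self.mean) / self.std

    def fit_transform(self, train: np.ndarray, fold: str | None = None) -> np.ndarray:
        return self.fit(train, fold).transform(train)


def extract_features(
    neural: np.ndarray,
    rate: float,
    channel_names: list[str] | None = None,
) -> NeuralFeatureMatrix:
    """Full unnormalized chain: band-pass -> notches -> envelope -> frames -> stack.

    Filters and the envelope run on the full continuous recording, not
    per trial. Normalization is deliberately left to the decoder, which
    must fit it per cross-validation fold.
    """
    neural = np.atleast_2d(np.asarray(neural, dtype=float))
    x = bandpass_high_gamma(neural, rate)
    x = notch_line_harmonics(x, rate)
    env = hilbert_envelope(x)
    frames, grid = frame_average(env, rate)
    return stack_context(frames, grid, channel_names)
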