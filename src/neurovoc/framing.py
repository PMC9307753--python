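"""Shared analysis frame grid.

Both the neural envelope features and the audio spectrogram are computed
in 50 ms windows advanced by 10 ms, so frames of the two streams
correspond one-to-one for equal-duration signals regardless of their
sampling rates. Frame k covers the half-open interval
[k*hop, k*hop + window) in seconds from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

__all__ = ["FrameGrid", "WINDOW_S", "HOP_S"]

WINDOW_S = 0.050
HOP_S = 0.010

# slack absorbing float rounding in (duration - window) / hop; one part in
# a million of a hop, far below any real duration mismatch
_EPS = 1e-6


@dataclass(frozen=True)
class FrameGrid:
    """Uniform frame grid: frame k covers [k*hop, k*hop + window)."""

    window: float = WINDOW_S
    hop: float = HOP_S
    n_frames: int = 0

    @classmethod
    def from_duration(cls, duration: float, window: float = WINDOW_S, hop: float = HOP_S) -> "FrameGrid":
        if duration < window:
            n = 0
        else:
            n = int(math.floor((duration - window) / hop + _EPS)) + 1
        return cls(window=window, hop=hop, n_frames=n)

    def frame_times(self, center: bool = True):
        import numpy as np

        t = np.arange(self.n_frames) * self.hop
        return t + self.window / 2 if center else t

    def sample_bounds(self, rate: float):
        """Per-frame [start, stop) sample indices at a given rate."""
        import numpy as np

        k = np.arange(self.n_frames)
        starts = np.ceil(k * self.hop * rate - 1e-9).astype(int)
        stops = np.ceil((k * self.hop + self.window) * rate - 1e-9).astype(int)
        return starts, stops
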