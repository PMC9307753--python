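"""Core session containers.

A recording session pairs a multichannel neural array (nominally 1024 Hz
sEEG) with a mono audio track (nominally 48 kHz) and the stimulus schedule
of a prompted single-word reading task: each trial shows one word for
2 s followed by a 1 s fixation cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["StimulusSchedule", "PlantedMapping", "RecordingSession"]


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered word-presentation events of one session.

    Each event is ``(onset_s, duration_s, label)``. Events are
    non-overlapping and time-ordered; with the standard task timing each
    word is shown for 2.0 s and followed by a 1.0 s fixation gap, so a
    100-word session lasts 300 s.
    """

    events: tuple[tuple[float, float, str], ...]
    session_duration: float

    def __post_init__(self):
        last_end = 0.0
        for onset, duration, _ in self.events:
            if duration <= 0:
                raise ValueError("event durations must be positive")
            if onset < last_end - 1e-9:
                raise ValueError("events must be time-ordered and non-overlapping")
            last_end = onset + duration
        if self.events and last_end > self.session_duration + 1e-9:
            raise ValueError("events extend past session_duration")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e[0] for e in self.events], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([e[1] for e in self.events], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [e[2] for e in self.events]


@dataclass(frozen=True)
class PlantedMapping:
    """Ground-truth linear coupling from speech mel energy to channel gain.

    ``weights`` has one row per neural channel and one column per mel band;
    row c, applied to the smoothed log-mel trajectory of the audio, gives
    the modulation signal of channel c's high-gamma amplitude. This stands
    in for the unknown true neural encoding so that recovery by the decoder
    can be tested against a known answer.
    """

    weights: np.ndarray  # (n_channels, n_mel)
    modulation_depth: float = 1.0
    noise_sigma: float = 0.1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-D (n_channels x n_mel) matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if self.modulation_depth < 0 or self.noise_sigma < 0:
            raise ValueError("modulation_depth and noise_sigma must be >= 0")
        if self.modulation_depth > 0 and not np.any(np.abs(w).sum(axis=1) > 0):
            raise ValueError("at least one nonzero weight row required when modulation_depth > 0")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


@dataclass
class RecordingSession:
    """Paired neural + audio recording with its stimulus schedule.

    Invariants: ``neural.shape == (n_channels, round(duration * neural_rate))``
    and ``len(audio) == round(duration * audio_rate)``; all samples finite.
    """

    neural: np.ndarray  # (n_channels, n_samples)
    audio: np.ndarray  # (n_audio_samples,)
    schedule: StimulusSchedule
    neural_rate: float = 1024.0
    audio_rate: float = 48000.0
    channel_names: list[str] = field(default_factory=list)
    planted: PlantedMapping | None = None
    seed: int | None = None

    def __post_init__(self):
        self.neural = np.atleast_2d(np.asarray(self.neural, dtype=float))
        self.audio = np.asarray(self.audio, dtype=float).ravel()
        dur = self.schedule.session_duration
        n_exp = int(round(dur * self.neural_rate))
        if self.neural.shape[1] != n_exp:
            raise ValueError(
                f"neural has {self.neural.shape[1]} samples, expected {n_exp} "
                f"for {dur} s at {self.neural_rate} Hz"
            )
        a_exp = int(round(dur * self.audio_rate))
        if self.audio.size != a_exp:
            raise ValueError(
                f"audio has {self.audio.size} samples, expected {a_exp} "
                f"for {dur} s at {self.audio_rate} Hz"
            )
        if not np.all(np.isfinite(self.neural)) or not np.all(np.isfinite(self.audio)):
            raise ValueError("session contains non-finite samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.neural.shape[0]

    @property
    def duration(self) -> float:
        return self.schedule.session_duration

    def copy(self) -> "RecordingSession":
        return replace(
            self,
            neural=self.neural.copy(),
            audio=self.audio.copy(),
            channel_names=list(self.channel_names),
        )
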