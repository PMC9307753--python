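"""Seeded synthetic sessions with a planted neural-speech coupling.

The generator emulates the statistical structure the downstream analysis
assumes: a prompted-word session (100 trials of 2 s word + 1 s fixation by
default), a 48 kHz audio track alternating voiced bursts and silence, and
1024 Hz neural channels whose 70-170 Hz band amplitude is linearly coupled
to the speech log-mel trajectory through a known weight matrix. Nuisances
are 1/f background, 50/100/150 Hz line components and white noise. An
optional additive leak of the audio into the neural channels provides
positive controls for the contamination audit.

The planted linear mapping is a test harness with a known answer, not a
claim about speech physiology.
"""

from __future__ import annotations

import numpy as np
from fractions import Fraction
from scipy.signal import resample_poly

from . import audio_features
from .errors import DimensionError
from .neural_features import bandpass_high_gamma
from .session import PlantedMapping, RecordingSession, StimulusSchedule

__all__ = [
    "DEFAULT_VOCABULARY",
    "make_schedule",
    "synth_audio",
    "synth_neural",
    "make_planted_mapping",
    "synth_session",
    "inject_contamination",
]

# placeholder vocabulary; the real task used Dutch corpus words plus the
# numbers one to ten, but labels are carried, never used numerically
DEFAULT_VOCABULARY = (
    "appel", "boom", "drie", "acht", "water", "licht", "steen", "vogel",
    "twee", "zeven", "huis", "groen", "vijf", "tien", "klein", "rood",
)

WORD_DURATION_S = 2.0
FIXATION_DURATION_S = 1.0
NOISE_FLOOR = 1e-4  # -80 dB re the voiced peak, comfortably below the -60 dB contract
LINE_FREQS = (50.0, 100.0, 150.0)


def make_schedule(
    n_words: int = 100,
    word_duration: float = WORD_DURATION_S,
    fixation_duration: float = FIXATION_DURATION_S,
    vocabulary=DEFAULT_VOCABULARY,
    seed: int | None = None,
) -> StimulusSchedule:
    """Word-presentation schedule: word k starts at k*(word+fixation)."""
    if n_words < 0:
        raise ValueError("n_words must be >= 0")
    if word_duration <= 0 or fixation_duration <= 0:
        raise ValueError("durations must be positive")
    if n_words > 0 and not vocabulary:
        raise ValueError("vocabulary must be non-empty when n_words > 0")
    rng = np.random.default_rng(seed)
    trial = word_duration + fixation_duration
    labels = rng.choice(list(vocabulary), size=n_words, replace=True) if n_words else []
    events = tuple(
        (k * trial, word_duration, str(labels[k])) for k in range(n_words)
    )
    return StimulusSchedule(events=events, session_duration=n_words * trial)


def synth_audio(schedule: StimulusSchedule, audio_rate: float = 48000.0,
                seed: int | None = None) -> np.ndarray:
    """Voiced harmonic bursts during word events, near-silence elsewhere.

    Each word gets a randomized fundamental in 100-250 Hz with the full
    harmonic stack up to min(8 kHz, Nyquist) under a 1/h spectral tilt —
    voiced speech carries harmonic energy across the whole mel analysis
    range, not just near the fundamental — plus a weak broadband
    aspiration-noise component, a raised-cosine utterance envelope
    covering ~70% of the 2 s window and a 3-7 Hz syllabic amplitude
    modulation. Peak is normalized to 0.95; the fixation noise floor sits
    80 dB below it.
    """
    if audio_rate <= 0:
        raise ValueError("audio_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.session_duration * audio_rate))
    if n == 0:
        return np.zeros(0)
    out = np.zeros(n)
    f_top = min(8000.0, 0.45 * audio_rate)
    for onset, duration, _ in schedule.events:
        f0 = rng.uniform(100.0, 250.0)
        utter_len = 0.7 * duration
        t0 = onset + rng.uniform(0.05, 0.25) * duration
        i0 = int(round(t0 * audio_rate))
        i1 = min(int(round((t0 + utter_len) * audio_rate)), n)
        if i1 <= i0:
            continue
        t = np.arange(i1 - i0) / audio_rate
        env = np.sin(np.pi * t / (t[-1] if t[-1] > 0 else 1.0)) ** 2
        syl = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(3.0, 7.0) * t + rng.uniform(0, 2 * np.pi))
        burst = np.zeros_like(t)
        for h in range(1, int(f_top / f0) + 1):
            burst += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
        # aspiration: broadband noise ~26 dB below the harmonic stack
        burst += 0.05 * np.sum(1.0 / np.arange(1, int(f_top / f0) + 1)) * rng.standard_normal(t.size)
        out[i0:i1] += env * syl * burst
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 0.95 / peak
    out += NOISE_FLOOR * 0.95 * rng.standard_normal(n)
    np.clip(out, -1.0, 1.0, out=out)
    return out


def make_planted_mapping(
    n_channels: int,
    n_mel: int = audio_features.N_MELS,
    modulation_depth: float = 1.0,
    noise_sigma: float = 0.1,
    seed: int | None = None,
) -> PlantedMapping:
    """Random Gaussian coupling gains, one row per channel."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n_channels, n_mel))
    return PlantedMapping(weights=w, modulation_depth=modulation_depth, noise_sigma=noise_sigma)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise: white noise shaped by 1/sqrt(f) in amplitude."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _mel_modulation(
    audio: np.ndarray,
    audio_rate: float,
    weights: np.ndarray,
    n_samples: int,
    neural_rate: float,
) -> np.ndarray:
    """Per-channel modulation: weights applied to the smoothed log-mel trajectory.

    The trajectory is computed with the same audio_features chain the
    analysis uses, interpolated to the neural rate, smoothed with a 100 ms
    moving average and scaled per channel to max |m| = 1 so that
    (1 + depth * m) stays non-negative at depth <= 1.
    """
    logmel = audio_features.compute_log_mel(audio, audio_rate)
    centered = logmel.values - logmel.values.mean(axis=0)
    m_frames = centered @ weights.T  # (n_frames, n_channels)
    t_frames = logmel.grid.frame_times(center=True)
    t_samples = np.arange(n_samples) / neural_rate
    m = np.empty((weights.shape[0], n_samples))
    for c in range(weights.shape[0]):
        m[c] = np.interp(t_samples, t_frames, m_frames[:, c])
    k = max(int(round(0.100 * neural_rate)), 1)
    kernel = np.ones(k) / k
    for c in range(m.shape[0]):
        m[c] = np.convolve(m[c], kernel, mode="same")
    scale = np.max(np.abs(m), axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return m / scale


def synth_neural(
    audio: np.ndarray,
    audio_rate: float,
    schedule: StimulusSchedule,
    n_channels: int,
    neural_rate: float = 1024.0,
    mapping: PlantedMapping | None = None,
    line_noise_amp: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, PlantedMapping]:
    """Neural traces whose high-gamma amplitude encodes the mel trajectory.

    Channel c = pink background + line sinusoids + band-limited 70-170 Hz
    carrier * (1 + depth * m_c(t)) + white noise, with m_c the channel's
    planted projection of the smoothed speech log-mel trajectory.
    """
    rng = np.random.default_rng(seed)
    if mapping is None:
        mapping = make_planted_mapping(
            n_channels, seed=int(rng.integers(0, 2**31 - 1))
        )
    if mapping.weights.shape[0] != n_channels:
        raise DimensionError(
            f"mapping has {mapping.weights.shape[0]} weight rows, expected {n_channels}"
        )
    n = int(round(schedule.session_duration * neural_rate))
    t = np.arange(n) / neural_rate

    if mapping.modulation_depth > 0:
        m = _mel_modulation(audio, audio_rate, mapping.weights, n, neural_rate)
        gain = 1.0 + mapping.modulation_depth * m
    else:
        gain = np.ones((n_channels, n))

    neural = np.empty((n_channels, n))
    for c in range(n_channels):
        carrier = rng.standard_normal(n)
        carrier = bandpass_high_gamma(carrier, neural_rate)
        sd = carrier.std()
        if sd > 0:
            carrier /= sd
        chan = carrier * gain[c]
        chan += _pink_noise(n, rng)
        for f in LINE_FREQS:
            chan += line_noise_amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if mapping.noise_sigma > 0:
            chan += mapping.noise_sigma * rng.standard_normal(n)
        neural[c] = chan
    return neural, mapping


def synth_session(
    n_words: int = 100,
    n_channels: int = 20,
    neural_rate: float = 1024.0,
    audio_rate: float = 48000.0,
    modulation_depth: float = 1.0,
    noise_sigma: float = 0.1,
    line_noise_amp: float = 1.0,
    vocabulary=DEFAULT_VOCABULARY,
    seed: int = 0,
) -> RecordingSession:
    """One-call generator: schedule + audio + coupled neural traces.

    Sub-seeds for the schedule, audio, mapping and neural noise are drawn
    from a single generator seeded with ``seed``, so equal seeds give
    bitwise-identical sessions.
    """
    root = np.random.default_rng(seed)
    s_sched, s_audio, s_map, s_neural = root.integers(0, 2**31 - 1, size=4)
    schedule = make_schedule(n_words, vocabulary=vocabulary, seed=int(s_sched))
    audio = synth_audio(schedule, audio_rate, seed=int(s_audio))
    mapping = make_planted_mapping(
        n_channels, modulation_depth=modulation_depth,
        noise_sigma=noise_sigma, seed=int(s_map),
    )
    neural, mapping = synth_neural(
        audio, audio_rate, schedule, n_channels, neural_rate,
        mapping=mapping, line_noise_amp=line_noise_amp, seed=int(s_neural),
    )
    return RecordingSession(
        neural=neural, audio=audio, schedule=schedule,
        neural_rate=neural_rate, audio_rate=audio_rate,
        planted=mapping, seed=seed,
    )


def inject_contamination(session: RecordingSession, gain: float) -> RecordingSession:
    """Add the (anti-alias resampled) audio to every neural channel.

    ``gain`` multiplies the resampled audio amplitude; gain=0 returns an
    identical copy. Positive-control construction for the contamination
    audit — applied last, so a clean/contaminated pair differs only by
    this leak term.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    out = session.copy()
    if gain == 0:
        return out
    frac = Fraction(int(round(session.neural_rate)), int(round(session.audio_rate)))
    leak = resample_poly(session.audio, frac.numerator, frac.denominator)
    n = session.neural.shape[1]
    if leak.size < n:
        leak = np.pad(leak, (0, n - leak.size))
    out.neural = out.neural + gain * leak[:n]
    return out
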