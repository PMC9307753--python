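"""Session persistence: HDF5 container + WAV + BIDS-dialect TSV sidecars.

A session directory contains:

- ``recording.h5`` — datasets ``/neural`` (channels x samples) and
  ``/audio``, root attributes ``neural_rate``, ``audio_rate``,
  ``session_duration``; optional ``/planted`` group with the ground-truth
  mapping of a synthetic session. This mirrors the deposit's layout of
  raw data streams in one hierarchical file without requiring the NWB
  schema.
- ``audio.wav`` — 16-bit PCM render of the audio track (for listening;
  the float audio in the container is authoritative on read).
- ``events.tsv`` — BIDS events dialect: onset / duration / trial_type,
  decimal seconds.
- ``channels.tsv`` — name / type / sampling_rate / status / description.
- ``manifest.json`` — list of written files.

Datasets are written with ``track_times=False`` so a rewrite of identical
content is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import ConsistencyError, MissingComponentError
from .session import PlantedMapping, RecordingSession, StimulusSchedule

__all__ = ["write_session", "read_session", "write_wav", "read_wav", "SESSION_FILES"]

SESSION_FILES = {
    "recording": "recording.h5",
    "audio": "audio.wav",
    "events": "events.tsv",
    "channels": "channels.tsv",
    "manifest": "manifest.json",
}


def write_wav(path, audio: np.ndarray, rate: float) -> None:
    """16-bit PCM WAV; input clipped to [-1, 1] full scale."""
    pcm = np.clip(np.asarray(audio, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(round(rate)),
                  np.round(pcm * 32767.0).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, float]:
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    else:
        data = data.astype(float)
    return data, float(rate)


def write_session(session: RecordingSession, path) -> dict:
    """Write all session components; returns a manifest of written files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    h5_path = path / SESSION_FILES["recording"]
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("neural", data=session.neural, track_times=False)
        f.create_dataset("audio", data=session.audio, track_times=False)
        f.attrs["neural_rate"] = float(session.neural_rate)
        f.attrs["audio_rate"] = float(session.audio_rate)
        f.attrs["session_duration"] = float(session.schedule.session_duration)
        if session.seed is not None:
            f.attrs["seed"] = int(session.seed)
        if session.planted is not None:
            g = f.create_group("planted")
            g.create_dataset("weights", data=session.planted.weights, track_times=False)
            g.attrs["modulation_depth"] = float(session.planted.modulation_depth)
            g.attrs["noise_sigma"] = float(session.planted.noise_sigma)

    write_wav(path / SESSION_FILES["audio"], session.audio, session.audio_rate)

    events = pd.DataFrame(
        {
            "onset": [f"{e[0]:.9f}" for e in session.schedule.events],
            "duration": [f"{e[1]:.9f}" for e in session.schedule.events],
            "trial_type": [e[2] for e in session.schedule.events],
        }
    )
    events.to_csv(path / SESSION_FILES["events"], sep="\t", index=False, lineterminator="\n")

    channels = pd.DataFrame(
        {
            "name": session.channel_names,
            "type": ["SEEG"] * session.n_channels,
            "sampling_rate": [repr(float(session.neural_rate))] * session.n_channels,
            "status": ["good"] * session.n_channels,
            "description": ["synthetic"] * session.n_channels,
        }
    )
    channels.to_csv(path / SESSION_FILES["channels"], sep="\t", index=False, lineterminator="\n")

    manifest = {"files": sorted(v for k, v in SESSION_FILES.items() if k != "manifest")}
    with open(path / SESSION_FILES["manifest"], "w", encoding="utf-8") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
        f.write("\n")
    return manifest


def read_session(path) -> RecordingSession:
    """Read a session directory written by :func:`write_session`.

    Neural samples round-trip exactly (float64 in the container); the
    authoritative audio is also the container's float array, so the WAV's
    16-bit quantization never enters.
    """
    path = Path(path)
    for key in ("recording", "events", "channels"):
        if not (path / SESSION_FILES[key]).exists():
            raise MissingComponentError(
                f"session directory {path} is missing its {key} file "
                f"({SESSION_FILES[key]})"
            )

    with h5py.File(path / SESSION_FILES["recording"], "r") as f:
        neural = f["neural"][()]
        audio = f["audio"][()]
        neural_rate = float(f.attrs["neural_rate"])
        audio_rate = float(f.attrs["audio_rate"])
        duration = float(f.attrs["session_duration"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        planted = None
        if "planted" in f:
            g = f["planted"]
            planted = PlantedMapping(
                weights=g["weights"][()],
                modulation_depth=float(g.attrs["modulation_depth"]),
                noise_sigma=float(g.attrs["noise_sigma"]),
            )

    events = pd.read_csv(path / SESSION_FILES["events"], sep="\t",
                         dtype={"trial_type": str}, keep_default_na=False)
    schedule = StimulusSchedule(
        events=tuple(
            (float(r.onset), float(r.duration), str(r.trial_type))
            for r in events.itertuples()
        ),
        session_duration=duration,
    )

    channels = pd.read_csv(path / SESSION_FILES["channels"], sep="\t")
    tsv_rates = channels["sampling_rate"].astype(float).to_numpy()
    if not np.allclose(tsv_rates, neural_rate):
        raise ConsistencyError(
            f"channels.tsv sampling_rate disagrees with container rate {neural_rate}"
        )
    if len(channels) != neural.shape[0]:
        raise ConsistencyError(
            f"channels.tsv has {len(channels)} rows for {neural.shape[0]} neural channels"
        )

    return RecordingSession(
        neural=neural,
        audio=audio,
        schedule=schedule,
        neural_rate=neural_rate,
        audio_rate=audio_rate,
        channel_names=[str(n) for n in channels["name"]],
        planted=planted,
        seed=seed,
    )
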