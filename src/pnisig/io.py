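"""Session container reader/writer.

A recording session lives in a directory:

* ``signal.f32``  — little-endian float32 voltage samples, sample-major
  interleave (frame = one sample for every channel); layout is documented
  in the sidecar so the file is self-describing.
* ``meta.json``   — fs, channel count/labels, units ("uV"), t0, day index.
* ``events.csv``  — acute sessions: one stimulation event per row
  (``time_s, current_uA, polarity``).
* ``motifs.csv``  — chronic sessions: one song-motif rendition per row
  (``start_s, stop_s, duration_unwarped_s``).
* ``audio.wav``   — optional simultaneous audio (written via scipy).

Round-tripping a float32 session through write/read is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .sigproc import Channel, Recording

SIGNAL_FILE = "signal.f32"
META_FILE = "meta.json"
EVENTS_FILE = "events.csv"
MOTIFS_FILE = "motifs.csv"
AUDIO_FILE = "audio.wav"


def write_session(
    path: str | Path,
    rec: Recording,
    events: pd.DataFrame | None = None,
    motifs: pd.DataFrame | None = None,
    audio: tuple[int, np.ndarray] | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write a session directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = rec.samples.astype("<f4")
    data.tofile(path / SIGNAL_FILE)
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "units": "uV",
        "dtype": "float32",
        "byte_order": "little",
        "interleave": "sample",  # frame-major: index = sample * n_channels + channel
        "t0": rec.t0,
        "channels": [{"id": c.id, "layer": c.layer} for c in rec.channels],
    }
    if extra_meta:
        meta.update(extra_meta)
    (path / META_FILE).write_text(json.dumps(meta, indent=1))
    if events is not None:
        events.to_csv(path / EVENTS_FILE, index=False)
    if motifs is not None:
        motifs.to_csv(path / MOTIFS_FILE, index=False)
    if audio is not None:
        audio_fs, audio_x = audio
        wavfile.write(path / AUDIO_FILE, int(audio_fs), audio_x)
    return path


def read_session(path: str | Path) -> dict:
    """Read a session directory.

    Returns a dict with keys ``recording`` (Recording), ``meta`` (dict) and,
    when present, ``events`` / ``motifs`` (DataFrame) and ``audio``
    ((fs, samples) tuple).
    """
    path = Path(path)
    meta = json.loads((path / META_FILE).read_text())
    raw = np.fromfile(path / SIGNAL_FILE, dtype="<f4")
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch:
        raise ValueError(f"signal file size {raw.size} not divisible by {n_ch} channels")
    samples = raw.reshape(-1, n_ch)
    channels = [Channel(id=c["id"], layer=c.get("layer", "L1")) for c in meta["channels"]]
    rec = Recording(
        samples=samples, fs=float(meta["fs"]), channels=channels, t0=float(meta.get("t0", 0.0))
    )
    out: dict = {"recording": rec, "meta": meta}
    if (path / EVENTS_FILE).exists():
        out["events"] = pd.read_csv(path / EVENTS_FILE)
    if (path / MOTIFS_FILE).exists():
        out["motifs"] = pd.read_csv(path / MOTIFS_FILE)
    if (path / AUDIO_FILE).exists():
        audio_fs, audio_x = wavfile.read(path / AUDIO_FILE)
        out["audio"] = (audio_fs, audio_x)
    return out
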