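"""File I/O: envelope WAV/CSV, recordings (raw binary + JSON header, EDF
reading), channel tables and result CSVs.

Recordings are written as a documented pair of files: ``<stem>.dat`` holds
float32 channel-major samples and ``<stem>.json`` the header (sample rate,
channel table, trial onsets, seed). EDF files (the real-data entry point)
are read through MNE together with a CSV channel table supplying the
geometry the EDF header cannot carry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth_seeg import ContinuousRecording

TABLE_COLUMNS = ["name", "x", "y", "z", "roi", "shaft", "contact_index"]


def write_envelope_wav(path, envelope, fs: float = 250.0) -> None:
    """Write an envelope as a mono float32 WAV stream at the control rate."""
    wavfile.write(str(path), int(round(fs)), np.asarray(envelope, dtype=np.float32))


def read_envelope_wav(path) -> tuple[np.ndarray, float]:
    fs, data = wavfile.read(str(path))
    return np.asarray(data, dtype=float), float(fs)


def write_trial_csv(path, trial) -> None:
    """Per-trial CSV: time, vp_envelope, participant_envelope."""
    n = len(trial.vp_envelope)
    pd.DataFrame(
        {
            "time": np.arange(n) / trial.fs,
            "vp_envelope": trial.vp_envelope,
            "participant_envelope": trial.participant_envelope,
        }
    ).to_csv(path, index=False)


def write_session(session, outdir) -> None:
    """Write a simulated session: per-trial envelope CSVs + the condition log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    session.log.to_csv(outdir / "condition_log.csv", index=False)
    for trial in session.trials:
        write_trial_csv(outdir / f"trial_{trial.trial_index:03d}.csv", trial)


def save_recording(recording: ContinuousRecording, stem) -> None:
    """Write a recording as float32 raw binary + JSON header.

    ``<stem>.dat``: channel-major float32 little-endian samples.
    ``<stem>.json``: {fs, kind, seed, n_channels, n_samples, trial_onsets,
    channel_table (records)}.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data32 = np.ascontiguousarray(recording.data, dtype="<f4")
    data32.tofile(stem.with_suffix(".dat"))
    header = {
        "fs": recording.fs,
        "kind": recording.kind,
        "seed": recording.seed,
        "n_channels": int(recording.data.shape[0]),
        "n_samples": int(recording.data.shape[1]),
        "trial_onsets": np.asarray(recording.trial_onsets, dtype=float).tolist(),
        "channel_table": recording.channel_table.to_dict(orient="records"),
    }
    stem.with_suffix(".json").write_text(json.dumps(header))


def load_recording(stem) -> ContinuousRecording:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".dat"), dtype="<f4").astype(float)
    data = data.reshape(header["n_channels"], header["n_samples"])
    return ContinuousRecording(
        data=data,
        channel_table=pd.DataFrame(header["channel_table"]),
        trial_onsets=np.asarray(header["trial_onsets"], dtype=float),
        fs=header["fs"],
        kind=header["kind"],
        seed=header["seed"],
    )


def read_edf_recording(edf_path, channel_table_csv, trial_onsets=None) -> ContinuousRecording:
    """Real-data entry point: EDF recording + CSV channel table.

    The CSV must provide the columns name, x, y, z, roi, shaft,
    contact_index; rows are matched to EDF channels by name and order follows
    the table.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    table = pd.read_csv(channel_table_csv)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"channel table missing columns: {missing}")
    picks = [raw.ch_names.index(n) for n in table["name"]]
    data = raw.get_data(picks=picks)
    return ContinuousRecording(
        data=data,
        channel_table=table.reset_index(drop=True),
        trial_onsets=np.asarray(trial_onsets if trial_onsets is not None else [], dtype=float),
        fs=float(raw.info["sfreq"]),
        kind="task",
    )
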