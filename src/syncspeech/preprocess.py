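"""sEEG preprocessing: bipolar montage, filtering, artifact rejection, epoching.

All filters are zero-phase (forward-backward), which is mandatory upstream of
any phase-sensitive analysis. The preprocessing order mirrors the analysis
chain: bipolar re-referencing of adjacent within-shaft contacts (virtual
channels at pair midpoints), notch at 50 Hz and harmonics up to 300 Hz plus a
0.5-300 Hz band-pass, robust variance-based channel rejection on the raw task
recording, then task epoching (-0.2 to 14 s, baseline -0.1 to 0 s, first
0.5 s excluded from analysis) and rest epoching (seventeen 14 s epochs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, iirnotch, sosfiltfilt, tf2sos

from .synth_seeg import ContinuousRecording

TASK_WINDOW = (-0.2, 14.0)  # s relative to trial onset
BASELINE_WINDOW = (-0.1, 0.0)
ANALYSIS_START = 0.5  # s; activity before this is excluded from analysis
REST_EPOCH_LEN = 14.0
N_REST_EPOCHS = 17


@dataclass
class EpochSet:
    """Epoched data (trials x channels x samples) with its time axis."""

    data: np.ndarray
    times: np.ndarray  # s relative to onset
    sample_rate: float
    kind: str  # task | rest
    channel_table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis does not match epoch length")

    @property
    def analysis_mask(self) -> np.ndarray:
        """Samples entering analysis: t >= 0.5 s (task) or everything (rest)."""
        if self.kind == "task":
            return self.times >= ANALYSIS_START
        return np.ones_like(self.times, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def bipolar_rereference(recording: ContinuousRecording) -> ContinuousRecording:
    """Bipolar montage: difference adjacent within-shaft contacts.

    Each virtual channel is contact_i - contact_{i+1}, located at the
    midpoint of the pair; a shaft with c contacts yields c - 1 virtual
    channels. Single-contact shafts are skipped with a warning. Common-mode
    signal shared by a shaft's contacts cancels exactly.
    """
    table = recording.channel_table
    if "shaft" not in table.columns or "contact_index" not in table.columns:
        raise ValueError("channel table must provide shaft and contact_index columns")
    rows = []
    pair_pos: list[tuple[int, int]] = []
    for shaft, grp in table.groupby("shaft", sort=True):
        grp = grp.sort_values("contact_index")
        if len(grp) < 2:
            warnings.warn(f"shaft {shaft!r} has a single contact; skipped")
            continue
        idx = grp.index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            ra, rb = table.loc[a], table.loc[b]
            pair_pos.append((table.index.get_loc(a), table.index.get_loc(b)))
            rows.append(
                {
                    "name": f"{ra['name']}-{rb['name']}",
                    "x": (ra["x"] + rb["x"]) / 2.0,
                    "y": (ra["y"] + rb["y"]) / 2.0,
                    "z": (ra["z"] + rb["z"]) / 2.0,
                    "roi": ra["roi"],
                    "shaft": shaft,
                    "contact_index": int(ra["contact_index"]),
                }
            )
    data = np.empty((len(pair_pos), recording.data.shape[1]), dtype=recording.data.dtype)
    for vi, (pa, pb) in enumerate(pair_pos):
        np.subtract(recording.data[pa], recording.data[pb], out=data[vi])
    return ContinuousRecording(
        data=data,
        channel_table=pd.DataFrame(rows),
        trial_onsets=recording.trial_onsets,
        fs=recording.fs,
        kind=recording.kind,
        seed=recording.seed,
        specs=recording.specs,
        meta=dict(recording.meta),
    )


def filter_continuous(
    recording: ContinuousRecording,
    band: tuple[float, float] = (0.5, 300.0),
    notch_base: float = 50.0,
    notch_max: float = 300.0,
    notch_q: float = 30.0,
) -> ContinuousRecording:
    """Zero-phase notch (50 Hz + harmonics) and band-pass (0.5-300 Hz).

    Notch frequencies run at multiples of ``notch_base`` up to
    min(notch_max, Nyquist - 5); the band-pass upper edge is clipped below
    Nyquist. Requires a sample rate of at least ~600 Hz so the fundamental
    harmonics sit below Nyquist.
    """
    fs = recording.fs
    nyq = fs / 2.0
    if fs < 2.2 * notch_base:
        raise ValueError("sample rate too low for the notch cascade")
    # one zero-phase pass over the whole cascade (notches + band-pass); for
    # zero-phase filtering the cascade of filtfilts equals filtfilt of the
    # cascade, so this is exact and much cheaper than sequential passes
    sections = []
    f = notch_base
    while f <= min(notch_max, nyq - 5.0):
        b, a = iirnotch(f, notch_q, fs=fs)
        sections.append(tf2sos(b, a))
        f += notch_base
    hi = min(band[1], 0.95 * nyq)
    sections.append(butter(4, (band[0], hi), btype="bandpass", fs=fs, output="sos"))
    x = sosfiltfilt(np.vstack(sections), recording.data, axis=-1)
    return replace(recording, data=x)


@dataclass
class ArtifactReport:
    keep: np.ndarray  # boolean mask over channels
    variance: np.ndarray
    threshold: float
    center: str


def reject_artifact_channels(
    recording: ContinuousRecording, n_iqr: float = 2.0, center: str = "median"
) -> ArtifactReport:
    """Robust variance fence for artifact channels.

    Channels whose broadband variance exceeds ``center + n_iqr * IQR``
    (computed across channels on the task recording) are rejected. The
    reference point of the fence is configurable (``median``, ``q3`` or
    ``zero``) since the rule's centre is a convention.
    """
    if recording.data.shape[0] < 8:
        raise ValueError("need at least 8 channels for a meaningful variance fence")
    var = recording.data.var(axis=1)
    q1, q2, q3 = np.percentile(var, [25, 50, 75])
    iqr = q3 - q1
    ref = {"median": q2, "q3": q3, "zero": 0.0}[center]
    threshold = ref + n_iqr * iqr
    keep = var <= threshold
    return ArtifactReport(keep=keep, variance=var, threshold=float(threshold), center=center)


def apply_channel_mask(recording: ContinuousRecording, keep: np.ndarray) -> ContinuousRecording:
    table = recording.channel_table.loc[np.asarray(keep)].reset_index(drop=True)
    return replace(recording, data=recording.data[np.asarray(keep)], channel_table=table)


def epoch_task(
    recording: ContinuousRecording, trial_onsets: np.ndarray | None = None
) -> EpochSet:
    """Epoch the task recording from -0.2 to 14 s around each trial onset.

    A baseline correction subtracts the per-epoch mean over [-0.1, 0] s.
    Epochs that would run past the recording edges are dropped with a warning.
    The first 0.5 s remain in the array but are excluded by `analysis_mask`.
    """
    if trial_onsets is None:
        trial_onsets = recording.trial_onsets
    fs = recording.fs
    n = recording.data.shape[1]
    i0 = int(round(TASK_WINDOW[0] * fs))
    i1 = int(round(TASK_WINDOW[1] * fs))
    times = np.arange(i0, i1) / fs
    b0 = int(round(BASELINE_WINDOW[0] * fs)) - i0
    b1 = int(round(BASELINE_WINDOW[1] * fs)) - i0
    epochs = []
    for onset in np.asarray(trial_onsets, dtype=float):
        s = int(round(onset * fs))
        if s + i0 < 0 or s + i1 > n:
            warnings.warn(f"trial at {onset:.2f}s too close to the recording edge; dropped")
            continue
        ep = recording.data[:, s + i0 : s + i1].astype(float)
        ep = ep - ep[:, b0:b1].mean(axis=1, keepdims=True)
        epochs.append(ep)
    if not epochs:
        raise ValueError("no usable task epochs")
    return EpochSet(np.asarray(epochs), times, fs, "task", recording.channel_table)


def epoch_rest(recording: ContinuousRecording, n_epochs: int = N_REST_EPOCHS) -> EpochSet:
    """Cut the rest recording into consecutive non-overlapping 14 s epochs.

    Defaults to seventeen epochs (the 5 min rest period); if the recording is
    shorter, as many full epochs as fit are returned with a warning.
    """
    fs = recording.fs
    ep_len = int(round(REST_EPOCH_LEN * fs))
    n_fit = recording.data.shape[1] // ep_len
    if n_fit == 0:
        raise ValueError("rest recording shorter than one 14 s epoch")
    if n_fit < n_epochs:
        warnings.warn(f"rest supports only {n_fit} of {n_epochs} requested epochs")
    n_use = min(n_epochs, n_fit)
    eps = np.stack(
        [recording.data[:, i * ep_len : (i + 1) * ep_len] for i in range(n_use)]
    )
    times = np.arange(ep_len) / fs
    return EpochSet(eps, times, fs, "rest", recording.channel_table)


def preprocess_pair(
    task: ContinuousRecording,
    rest: ContinuousRecording,
    n_iqr: float = 2.0,
    center: str = "median",
) -> tuple[EpochSet, EpochSet, ArtifactReport]:
    """Full preprocessing of a task/rest pair.

    Bipolar montage on both recordings, channel rejection from the raw
    (unfiltered) bipolar task recording, zero-phase filtering, then task and
    rest epoching with the common surviving channel set.
    """
    task_bp = bipolar_rereference(task)
    rest_bp = bipolar_rereference(rest)
    report = reject_artifact_channels(task_bp, n_iqr=n_iqr, center=center)
    task_bp = apply_channel_mask(task_bp, report.keep)
    rest_bp = apply_channel_mask(rest_bp, report.keep)
    task_f = filter_continuous(task_bp)
    rest_f = filter_continuous(rest_bp)
    return epoch_task(task_f), epoch_rest(rest_f), report
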