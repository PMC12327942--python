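"""Synthetic stereotactic-EEG generator with known ground truth.

Generates continuous multichannel recordings at 1 kHz (a task session and a
resting baseline) in which every effect the analysis chain targets is
injected explicitly and recorded in a ground-truth table:

* band-specific power changes vs rest (percent power change per canonical
  band, realised by scaling band-limited noise components inside trial
  windows);
* across-trial correlation between high-frequency (70-125 Hz, HFa) power and
  the verbal coordination index (a monotone, rank-matched per-trial amplitude
  multiplier with calibrated noise);
* phase-amplitude coupling between a behavioural phase (VP speech phase or
  VP-participant phase difference) and HFa amplitude;
* 50 Hz line noise plus harmonics (strong on the common mode, weak residual
  per channel);
* occasional 20x-amplitude artifact segments on dedicated artifact channels.

Signals are constructed at the level of *virtual* (bipolar) channels — the
carriers of the injected effects — and then integrated into contact-level
potentials along each electrode shaft together with a strong per-shaft
common-mode signal, so that the bipolar re-referencing stage has realistic
geometry to consume and recovers the virtual channels exactly.

The spectrum is partitioned into contiguous band-limited components with a
1/f power profile; the six canonical analysis bands are a subset of the
partition, so a task/rest gain applied to one component is exactly the band
effect the spectral stage should measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr

from ._utils import wrap_phase

FS = 1000.0  # Hz

#: contiguous spectral partition used for synthesis (Hz); the named analysis
#: bands are members, so per-band gains map one-to-one onto components.
GEN_BANDS: list[tuple[float, float]] = [
    (0.5, 1.0),
    (1.0, 4.0),     # delta
    (4.0, 8.0),     # theta
    (8.0, 13.0),    # alpha
    (13.0, 30.0),   # beta
    (30.0, 50.0),   # low gamma
    (50.0, 70.0),   # gap band (no named analysis band)
    (70.0, 125.0),  # HFa
    (125.0, 300.0),
]

NAMED_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 50.0),
    "hfa": (70.0, 125.0),
}

ROIS = ("STG_BA41_42", "STG_BA22", "IPL_BA40", "IFG_BA44", "NULL_REGION")

#: approximate left-hemisphere centres (mm, MNI-like frame); separations are
#: generous so the five regional channel clouds form clean spatial clusters.
ROI_CENTERS = {
    "STG_BA41_42": (-45.0, -20.0, 5.0),
    "STG_BA22": (-58.0, -55.0, 10.0),
    "IPL_BA40": (-50.0, -60.0, 50.0),
    "IFG_BA44": (-50.0, 20.0, 15.0),
    "NULL_REGION": (-25.0, -75.0, -25.0),
}

#: per-ROI injected effects: percent power change vs rest by band, target
#: Spearman rho of HFa power vs VCI, and the PAC phase source/depth.
ROI_EFFECTS = {
    "STG_BA41_42": {
        "gains": {"delta": 20.0, "theta": -30.0, "alpha": -35.0, "beta": -30.0,
                  "low_gamma": 40.0, "hfa": 100.0},
        "behaviour_rho": 0.0,
        "pac_mode": "vp_speech",
        "pac_depth": 0.5,
    },
    "STG_BA22": {
        "gains": {"theta": -25.0, "alpha": -30.0, "beta": -25.0,
                  "low_gamma": 25.0, "hfa": 60.0},
        "behaviour_rho": -0.6,
        "pac_mode": "vp_speech",
        "pac_depth": 0.5,
    },
    "IPL_BA40": {
        "gains": {"alpha": -25.0, "beta": -20.0, "hfa": 30.0},
        "behaviour_rho": -0.3,
        "pac_mode": "none",
        "pac_depth": 0.0,
    },
    "IFG_BA44": {
        "gains": {"beta": -20.0, "hfa": 50.0},
        "behaviour_rho": -0.6,
        "pac_mode": "phase_difference",
        "pac_depth": 0.5,
    },
    "NULL_REGION": {"gains": {}, "behaviour_rho": 0.0, "pac_mode": "none", "pac_depth": 0.0},
}

CONTACT_SPACING_MM = 3.5  # centre-to-centre along the shaft


@dataclass
class ChannelSpec:
    """Ground-truth description of one virtual (bipolar) channel."""

    name: str
    xyz: tuple[float, float, float]
    roi: str
    shaft: str
    effect_gains: dict = field(default_factory=dict)  # band -> percent power change
    behaviour_rho: float = 0.0
    pac_mode: str = "none"  # none | vp_speech | phase_difference
    pac_depth: float = 0.0
    artifact: bool = False

    def __post_init__(self) -> None:
        if self.roi not in ROIS:
            raise ValueError(f"unknown ROI {self.roi!r}")
        if not (0.0 <= self.pac_depth < 1.0):
            raise ValueError("pac_depth must be in [0, 1)")
        if self.pac_mode not in ("none", "vp_speech", "phase_difference"):
            raise ValueError(f"unknown pac_mode {self.pac_mode!r}")
        unknown = set(self.effect_gains) - set(NAMED_BANDS)
        if unknown:
            raise ValueError(f"unknown bands in effect profile: {sorted(unknown)}")


@dataclass
class ContinuousRecording:
    """Contact-level multichannel recording at 1 kHz with its channel table."""

    data: np.ndarray  # (n_channels, n_samples)
    channel_table: pd.DataFrame  # name, x, y, z, roi, shaft, contact_index
    trial_onsets: np.ndarray  # seconds
    fs: float = FS
    kind: str = "task"
    seed: int = 0
    specs: list[ChannelSpec] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.trial_onsets, dtype=float)
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        self.trial_onsets = onsets

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


def default_layout(
    channels_per_roi: int = 6, n_artifact: int = 4
) -> list[ChannelSpec]:
    """The default electrode layout: 5 ROI shafts + one artifact shaft.

    Each ROI shaft carries ``channels_per_roi`` virtual channels (one more
    contact than channels), oriented laterally with the standard contact
    spacing; a separate shaft of ``n_artifact`` virtual channels is flagged
    as artifact-carrying. Default: 5 x 6 + 4 = 34 virtual channels.
    """
    specs: list[ChannelSpec] = []
    for si, roi in enumerate(ROIS):
        shaft = chr(ord("A") + si)
        cx, cy, cz = ROI_CENTERS[roi]
        eff = ROI_EFFECTS[roi]
        for ci in range(channels_per_roi):
            # virtual channel sits at the midpoint of contacts ci, ci+1
            x = cx + (ci + 0.5 - channels_per_roi / 2.0) * CONTACT_SPACING_MM
            specs.append(
                ChannelSpec(
                    name=f"{shaft}{ci + 1}-{shaft}{ci + 2}",
                    xyz=(x, cy, cz),
                    roi=roi,
                    shaft=shaft,
                    effect_gains=dict(eff["gains"]),
                    behaviour_rho=eff["behaviour_rho"],
                    pac_mode=eff["pac_mode"],
                    pac_depth=eff["pac_depth"],
                )
            )
    cx, cy, cz = (-30.0, -40.0, -30.0)
    for ci in range(n_artifact):
        x = cx + (ci + 0.5 - n_artifact / 2.0) * CONTACT_SPACING_MM
        specs.append(
            ChannelSpec(
                name=f"X{ci + 1}-X{ci + 2}",
                xyz=(x, cy, cz),
                roi="NULL_REGION",
                shaft="X",
                artifact=True,
            )
        )
    return specs


def tiny_layout() -> list[ChannelSpec]:
    """Reduced layout (2 channels per ROI, 2 artifact channels) for fast tests."""
    return default_layout(channels_per_roi=2, n_artifact=2)


def _band_noise(rng: np.random.Generator, n: int, fs: float, bands) -> np.ndarray:
    """Gaussian noise limited to one or more [lo, hi) bands, 1/f power profile.

    Synthesised in the frequency domain on a fast-FFT-length grid and
    truncated, with variance independent of length.
    """
    from scipy.fft import irfft, next_fast_len

    if np.isscalar(bands[0]):
        bands = [bands]
    nf = next_fast_len(n)
    freqs = np.fft.rfftfreq(nf, d=1.0 / fs)
    shape = np.zeros(len(freqs))
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs < hi)
        shape[mask] = freqs[mask] ** -0.5  # amplitude ~ f^-1/2 -> power ~ 1/f
    nz = np.flatnonzero(shape)
    spec = np.zeros(len(freqs), dtype=complex)
    spec[nz] = (rng.standard_normal(len(nz)) + 1j * rng.standard_normal(len(nz))) * shape[nz]
    x = irfft(spec, n=nf)[:n]
    return x * np.sqrt(nf)


def _line_noise(rng: np.random.Generator, n: int, fs: float, amp: float) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    for h, a in ((50.0, amp), (100.0, 0.4 * amp), (150.0, 0.25 * amp)):
        out += a * np.sin(2 * np.pi * h * t + rng.uniform(0, 2 * np.pi))
    return out


def _gain_index(band_name: str) -> int:
    return GEN_BANDS.index(NAMED_BANDS[band_name])


def _rho_multipliers(
    vci: np.ndarray, rho: float, rng: np.random.Generator, spread: float = 0.35
) -> tuple[np.ndarray, float]:
    """Per-trial HFa amplitude multipliers with target Spearman rho vs VCI.

    Normal scores of the VCI ranks are mixed with Gaussian noise at the
    Pearson equivalent of the target Spearman correlation (r = 2 sin(pi
    rho / 6)), then mapped through a monotone lognormal multiplier normalised
    to unit mean *power* so the across-trial mean band power is untouched.
    Returns the multipliers and the attained sample Spearman rho.
    """
    n = len(vci)
    z = norm.ppf((rankdata(vci) - 0.5) / n)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    y = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    mult = np.exp(spread * y - spread * spread)
    attained = float(spearmanr(mult, vci).statistic) if np.std(mult) > 0 else 0.0
    return mult, attained


def _contact_assembly(
    specs: list[ChannelSpec],
    virtual: np.ndarray,
    rng: np.random.Generator,
    common_amp: float = 3.0,
    line_amp: float = 5.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Integrate virtual-channel signals into contact potentials per shaft.

    contact[0] carries the shaft's common mode; contact[i+1] = contact[i] -
    virtual[i], so that adjacent differencing (the bipolar montage) recovers
    each virtual channel exactly and cancels the common mode.
    """
    n = virtual.shape[1]
    virtual = np.asarray(virtual, dtype=np.float32)
    shafts: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        shafts.setdefault(s.shaft, []).append(i)
    rows = []
    contacts = []
    for shaft in sorted(shafts):
        idx = shafts[shaft]
        first = specs[idx[0]]
        common = (
            common_amp * _band_noise(rng, n, FS, (0.5, 300.0)) + _line_noise(rng, n, FS, line_amp)
        ).astype(np.float32)
        c = common.copy()
        x0, y0, z0 = first.xyz
        x_positions = [s.xyz[0] for s in (specs[i] for i in idx)]
        # contact j sits half a spacing outside/between the virtual midpoints
        xs = [x_positions[0] - CONTACT_SPACING_MM / 2.0] + [
            xp + CONTACT_SPACING_MM / 2.0 for xp in x_positions
        ]
        contacts.append(c)
        rows.append(
            {"name": f"{shaft}1", "x": xs[0], "y": y0, "z": z0, "roi": first.roi,
             "shaft": shaft, "contact_index": 1}
        )
        for j, vi in enumerate(idx):
            c = c - virtual[vi]
            contacts.append(c)
            rows.append(
                {"name": f"{shaft}{j + 2}", "x": xs[j + 1], "y": y0, "z": z0,
                 "roi": specs[vi].roi, "shaft": shaft, "contact_index": j + 2}
            )
    return np.asarray(contacts), pd.DataFrame(rows)


def generate_rest(
    specs: list[ChannelSpec],
    duration: float = 300.0,
    seed: int = 0,
    line_residual: float = 0.15,
) -> ContinuousRecording:
    """Resting-state recording: 1/f background per band + line noise.

    ``duration`` defaults to the 5 min resting period; shorter durations are
    allowed for reduced test fixtures.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * FS))
    virtual = np.empty((len(specs), n), dtype=np.float32)
    for i, _spec in enumerate(specs):
        x = _band_noise(rng, n, FS, GEN_BANDS)
        x += _line_noise(rng, n, FS, line_residual)
        virtual[i] = x
    contacts, table = _contact_assembly(specs, virtual, rng, line_amp=0.0 if line_residual == 0 else 5.0)
    return ContinuousRecording(
        data=contacts, channel_table=table, trial_onsets=np.empty(0), fs=FS,
        kind="rest", seed=seed, specs=list(specs),
    )


def _trial_phase_1khz(trial, mode: str, n_trial: int) -> np.ndarray:
    """Behavioural phase of one trial resampled from 250 Hz to 1 kHz."""
    if mode == "vp_speech":
        ph = trial.vp_phase
        u = np.unwrap(ph)
    else:  # phase_difference
        u = np.unwrap(trial.vp_phase) - np.unwrap(trial.participant_phase)
    t250 = np.arange(len(u)) / trial.fs
    t1k = np.arange(n_trial) / FS
    return wrap_phase(np.interp(t1k, t250, u))


def generate_task(
    specs: list[ChannelSpec],
    trials,
    vci,
    seed: int = 0,
    lead_in: float = 2.0,
    trial_gap: float = 1.5,
    line_residual: float = 0.15,
    artifact_factor: float = 20.0,
) -> ContinuousRecording:
    """Task recording realising the injected effects against the behaviour.

    Within each trial window, each named band's component is scaled by
    sqrt(1 + gain/100) (power gain as printed in the ground truth); the HFa
    component is additionally scaled by a per-trial multiplier rank-matched to
    the trial VCI (targeting ``behaviour_rho``) and, for PAC channels,
    modulated within the trial by (1 + depth * cos(phase)) / sqrt(1 + depth^2/2)
    where the phase is the VP speech phase or the VP-participant phase
    difference. Artifact channels receive ``artifact_factor``-amplitude
    segments covering about a third of the task.
    """
    vci = np.asarray(vci, dtype=float)
    if len(trials) != len(vci):
        raise ValueError(f"behaviour mismatch: {len(trials)} trials vs {len(vci)} VCI values")
    rng = np.random.default_rng(seed)
    n_trials = len(trials)
    trial_dur = len(trials[0].vp_phase) / trials[0].fs
    n_trial = int(round(trial_dur * FS))
    onsets = lead_in + np.arange(n_trials) * (trial_dur + trial_gap)
    duration = lead_in + n_trials * (trial_dur + trial_gap) + 2.0
    n = int(round(duration * FS))
    onset_idx = np.round(onsets * FS).astype(int)

    hfa_i = _gain_index("hfa")
    # per-trial PAC modulators, shared across channels with the same source
    pac_mod: dict[str, np.ndarray] = {}
    for mode in ("vp_speech", "phase_difference"):
        if any(s.pac_mode == mode for s in specs):
            m = np.ones(n)
            for ti, tr in enumerate(trials):
                ph = _trial_phase_1khz(tr, mode, n_trial)
                m[onset_idx[ti] : onset_idx[ti] + n_trial] = np.cos(ph)
            pac_mod[mode] = m

    attained_rho: dict[str, float] = {}
    virtual = np.empty((len(specs), n), dtype=np.float32)
    trial_mask = np.zeros(n, dtype=bool)
    for oi in onset_idx:
        trial_mask[oi : oi + n_trial] = True

    for ci, spec in enumerate(specs):
        rho_mult = None
        if spec.behaviour_rho != 0.0:
            rho_mult, attained = _rho_multipliers(vci, spec.behaviour_rho, rng)
            attained_rho[spec.name] = attained
        gains = np.zeros(len(GEN_BANDS))
        for band_name, g in spec.effect_gains.items():
            gains[_gain_index(band_name)] = g
        modulated = [
            bi
            for bi in range(len(GEN_BANDS))
            if gains[bi] != 0.0
            or (bi == hfa_i and (rho_mult is not None or spec.pac_mode != "none"))
        ]
        static = [bi for bi in range(len(GEN_BANDS)) if bi not in modulated]
        # unmodulated bands share one synthesis pass; modulated bands get their
        # own component so the trial-window multiplier applies to them alone
        x = _band_noise(rng, n, FS, [GEN_BANDS[bi] for bi in static]) if static else np.zeros(n)
        for bi in modulated:
            comp = _band_noise(rng, n, FS, GEN_BANDS[bi])
            mult = np.ones(n)
            mult[trial_mask] = np.sqrt(1.0 + gains[bi] / 100.0)
            if bi == hfa_i:
                if rho_mult is not None:
                    for ti in range(n_trials):
                        sl = slice(onset_idx[ti], onset_idx[ti] + n_trial)
                        mult[sl] = mult[sl] * rho_mult[ti]
                if spec.pac_mode != "none":
                    depth = spec.pac_depth
                    mod = (1.0 + depth * pac_mod[spec.pac_mode]) / np.sqrt(1.0 + depth**2 / 2.0)
                    mult = mult * np.where(trial_mask, mod, 1.0)
            x += comp * mult
        x += _line_noise(rng, n, FS, line_residual)
        if spec.artifact:
            seg_mask = np.zeros(n, dtype=bool)
            covered = 0
            while covered < 0.30 * n:
                start = rng.integers(0, n)
                length = int(rng.uniform(5.0, 20.0) * FS)
                seg_mask[start : start + length] = True
                covered = int(seg_mask.sum())
            x = np.where(seg_mask, artifact_factor * x, x)
        virtual[ci] = x

    contacts, table = _contact_assembly(specs, virtual, rng)
    return ContinuousRecording(
        data=contacts, channel_table=table, trial_onsets=onsets, fs=FS,
        kind="task", seed=seed, specs=list(specs),
        meta={"attained_rho": attained_rho, "trial_duration": trial_dur},
    )


def ground_truth(specs: list[ChannelSpec], attained_rho: dict | None = None) -> pd.DataFrame:
    """The injected per-channel effects as a flat table (one row per channel)."""
    rows = []
    for s in specs:
        row = {
            "channel": s.name,
            "roi": s.roi,
            "shaft": s.shaft,
            "x": s.xyz[0],
            "y": s.xyz[1],
            "z": s.xyz[2],
            "behaviour_rho": s.behaviour_rho,
            "pac_mode": s.pac_mode,
            "pac_depth": s.pac_depth,
            "artifact": s.artifact,
        }
        for band in NAMED_BANDS:
            row[f"gain_{band}"] = float(s.effect_gains.get(band, 0.0))
        if attained_rho is not None:
            row["attained_rho"] = attained_rho.get(s.name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
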