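"""End-to-end orchestration of the synthetic study.

A ``RunConfig`` carries every stage parameter (defaulting to the task's
printed values: 24 trials of 14 s in coupling thirds, 500 surrogates, 1000
permutations, the six-band scheme, cluster range 2-10) plus a master seed
from which each stage derives its own seed, so stages are independently
re-runnable and a full run is bit-reproducible from the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import stage_seed
from . import coordination as coord
from .clustering import kmeans_silhouette
from .dyad import DyadConfig, count_syllable_onsets, simulate_session
from .pac import compare_pac_types, hfa_amplitude, pac_table
from .preprocess import preprocess_pair
from .spectral import (
    BAND_NAMES,
    band_power,
    brain_behaviour_correlation,
    compute_psd,
    global_effect,
    roi_statistics,
    spectral_summary,
)
from .synth_seeg import default_layout, generate_rest, generate_task, ground_truth, tiny_layout


@dataclass
class RunConfig:
    """Master configuration of a synthetic study run."""

    master_seed: int = 0
    n_trials: int = 24
    rest_duration: float = 300.0
    n_surrogates: int = 500
    n_perm: int = 1000
    channels_per_roi: int = 6
    n_artifact: int = 4
    alpha: float = 0.05
    cluster_k_min: int = 2
    cluster_k_max: int = 10
    phase_noise_sd: float = 2.25
    k_participant: float = 0.15
    outdir: str = "results"

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def tiny_run_config(master_seed: int = 0) -> RunConfig:
    """Reduced configuration (12 trials, 2 channels/ROI, 100 surrogates) for
    fast integration tests; 12 trials is the smallest session that still
    supports the across-trial correlation stage."""
    return RunConfig(
        master_seed=master_seed,
        n_trials=12,
        rest_duration=140.0,
        n_surrogates=100,
        n_perm=200,
        channels_per_roi=2,
        n_artifact=2,
    )


@dataclass
class RunResult:
    """Bundle of every stage's outputs plus the run manifest."""

    behaviour: pd.DataFrame
    coordination: pd.DataFrame
    ground_truth: pd.DataFrame
    artifact_report: object
    spectral: pd.DataFrame
    roi_stats: pd.DataFrame
    pac: pd.DataFrame
    pac_roi: pd.DataFrame
    cluster: object
    summary: pd.DataFrame
    manifest: dict


def run_all(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full synthetic study: simulate -> coordination ->
    synthetic sEEG -> preprocess -> spectral -> PAC -> clustering.

    Writes per-stage CSVs, the manifest and a summary comparing recovered
    effects to the injected ground truth under ``config.outdir`` (unless
    ``write`` is False).
    """
    dyad_cfg = DyadConfig(
        n_trials=config.n_trials,
        phase_noise_sd=config.phase_noise_sd,
        k_participant=config.k_participant,
        seed=config.seed_for("simulate"),
    )
    session = simulate_session(dyad_cfg)
    results = coord.analyse_session(
        session, n_surrogates=config.n_surrogates, seed=config.seed_for("coordination")
    )
    vci = np.array([r.vci for r in results])
    delays = np.array([r.delay_s for r in results])
    coordination_df = pd.DataFrame(
        {
            "trial": [r.trial_index for r in results],
            "condition": [r.condition for r in results],
            "vci": vci,
            "p": [r.p_value for r in results],
            "delay_s": delays,
        }
    )

    specs = default_layout(config.channels_per_roi, config.n_artifact)
    task = generate_task(specs, session.trials, vci, seed=config.seed_for("synth-task"))
    rest = generate_rest(specs, duration=config.rest_duration, seed=config.seed_for("synth-rest"))
    gt = ground_truth(specs, task.meta.get("attained_rho"))

    task_ep, rest_ep, report = preprocess_pair(task, rest)

    task_bp = band_power(compute_psd(task_ep), kind="task")
    rest_bp = band_power(compute_psd(rest_ep), kind="rest")
    glob = global_effect(task_bp, rest_bp, n_perm=config.n_perm, seed=config.seed_for("spectral"))
    corr = brain_behaviour_correlation(task_bp, vci, n_perm=config.n_perm,
                                       seed=config.seed_for("correlation"))
    spec_df = spectral_summary(glob, corr)
    hfa_i = BAND_NAMES.index("hfa")
    rois = task_ep.channel_table["roi"].to_numpy()
    roi_df = roi_statistics(corr.rho[:, hfa_i], rois, alpha=config.alpha)

    pac_df = pac_table(session.trials, task_ep, n_surrogates=config.n_surrogates,
                       seed=config.seed_for("pac"))
    pac_roi = compare_pac_types(pac_df)

    coords = task_ep.channel_table[["x", "y", "z"]].to_numpy()
    k_max = min(config.cluster_k_max, len(coords) - 1)
    cluster = kmeans_silhouette(
        coords, range(config.cluster_k_min, k_max + 1), seed=config.seed_for("cluster")
    )

    summary = _recovery_summary(gt, spec_df, pac_df, task_ep.channel_table)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {
            s: config.seed_for(s)
            for s in ("simulate", "coordination", "synth-task", "synth-rest",
                      "spectral", "correlation", "pac", "cluster")
        },
        "n_syllables": count_syllable_onsets(session),
        "n_channels_kept": int(report.keep.sum()),
        "n_channels_rejected": int((~report.keep).sum()),
        "best_k": cluster.best_k,
    }

    out = RunResult(
        behaviour=session.log,
        coordination=coordination_df,
        ground_truth=gt,
        artifact_report=report,
        spectral=spec_df,
        roi_stats=roi_df,
        pac=pac_df,
        pac_roi=pac_roi,
        cluster=cluster,
        summary=summary,
        manifest=manifest,
    )
    if write:
        _write_results(out, Path(config.outdir))
    return out


def _recovery_summary(gt, spec_df, pac_df, channel_table) -> pd.DataFrame:
    """Injected vs recovered effects, joined per surviving channel."""
    hfa_spec = spec_df[spec_df["band"] == "hfa"].set_index("channel")
    pac_vp = pac_df[pac_df["phase_source"] == "vp_speech"].set_index("channel")
    pac_pd = pac_df[pac_df["phase_source"] == "phase_difference"].set_index("channel")
    rows = []
    for _, g in gt.iterrows():
        ch = g["channel"]
        if ch not in hfa_spec.index:
            continue  # rejected channel
        rows.append(
            {
                "channel": ch,
                "roi": g["roi"],
                "injected_hfa_gain": g["gain_hfa"],
                "recovered_hfa_pct": hfa_spec.loc[ch, "percent_change"],
                "injected_rho": g.get("attained_rho", g["behaviour_rho"]),
                "recovered_rho": hfa_spec.loc[ch, "rho"],
                "pac_mode": g["pac_mode"],
                "pac_vp_pct": pac_vp.loc[ch, "pct_increase"] if ch in pac_vp.index else np.nan,
                "pac_diff_pct": pac_pd.loc[ch, "pct_increase"] if ch in pac_pd.index else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _write_results(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.behaviour.to_csv(outdir / "behaviour_log.csv", index=False)
    result.coordination.to_csv(outdir / "coordination.csv", index=False)
    result.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    result.spectral.to_csv(outdir / "spectral.csv", index=False)
    result.roi_stats.to_csv(outdir / "roi_stats.csv", index=False)
    result.pac.to_csv(outdir / "pac.csv", index=False)
    result.pac_roi.to_csv(outdir / "pac_roi.csv", index=False)
    result.summary.to_csv(outdir / "recovery_summary.csv", index=False)
    pd.DataFrame(
        {"k": result.cluster.k_range, "silhouette": result.cluster.silhouette}
    ).to_csv(outdir / "cluster_silhouette.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def make_fixtures(size: str = "tiny", outdir="fixtures", master_seed: int = 0):
    """Generate a fixture directory (simulated session + recordings).

    ``tiny``: 6 trials, 2 channels per ROI, 100 surrogates — a full-pipeline
    fixture that runs in well under a minute. ``default``: the task's session
    geometry (24 trials, thirds schedule, 34 channels).
    """
    from .io import save_recording, write_session

    if size == "tiny":
        cfg = tiny_run_config(master_seed)
        cfg.n_trials = 6  # fixtures skip the correlation stage, so 6 is enough
        specs = tiny_layout()
    elif size == "default":
        cfg = RunConfig(master_seed=master_seed)
        specs = default_layout()
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dyad_cfg = DyadConfig(n_trials=cfg.n_trials, seed=cfg.seed_for("simulate"))
    session = simulate_session(dyad_cfg)
    write_session(session, outdir / "session")
    results = coord.analyse_session(session, n_surrogates=cfg.n_surrogates,
                                    seed=cfg.seed_for("coordination"))
    vci = np.array([r.vci for r in results])
    task = generate_task(specs, session.trials, vci, seed=cfg.seed_for("synth-task"))
    rest = generate_rest(specs, duration=cfg.rest_duration, seed=cfg.seed_for("synth-rest"))
    save_recording(task, outdir / "task")
    save_recording(rest, outdir / "rest")
    ground_truth(specs, task.meta.get("attained_rho")).to_csv(
        outdir / "ground_truth.csv", index=False
    )
    cfg.to_yaml(outdir / "config.yaml")
    return outdir
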