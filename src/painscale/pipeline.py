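"""End-to-end study composition: simulate -> GLM -> decode -> inference.

`run_full_study` strings the stages together in the order the decoding
analysis defines them: trial-wise GLM on (optionally smoothed) volumes,
whole-brain and per-region condition-split decoding with group permutation
p-values, cumulative region combinations and the tripling voxel-count
curve, and classifier weight-map inference.  Every stage writes its outputs
under the run directory and is skipped on re-run if they already exist, so
a study is resumable from intermediates.  All randomness derives from the
seeds in the configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .decoding import DecodingConfig, FeatureSpec, decode_subject, group_accuracy
from .glm import BetaSeries, build_trialwise_design, fit_glm, smooth_gaussian
from .multiscale import (
    cumulative_roi_combinations,
    roi_group_results,
    roi_rank_order,
    scale_curve,
)
from .perminfer import (
    fwe_threshold,
    group_accuracy_null,
    perm_pvalue,
    weight_null,
    weight_tscores,
)
from .decoding import train_linear_margin
from .features import feature_matrix, l2_normalize_trials, standardize_voxels
from .synthdata import SyntheticDataset, generate_group

__all__ = ["StudyConfig", "run_full_study", "beta_series_for_dataset"]


@dataclass
class StudyConfig:
    """Study constants; defaults mirror the target experimental design."""

    n_subjects: int = 16
    n_sessions: int = 4
    trials_per_session: int = 30
    TR_s: float = 3.0
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_regions: int = 26
    n_control_regions: int = 2
    effect_size_mean: float = 0.5
    effect_size_sd: float = 0.25
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    label_balance: float = 0.5
    smooth_fwhm_mm: float = 5.0
    voxel_size_mm: float = 3.0
    highpass_cutoff_s: float = 128.0
    C_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
    phases: tuple[str, ...] = ("anticipation", "stimulation")
    scaling: str = "fold"
    alpha: float = 0.05
    N_perm: int = 1000
    N_perm_roi: int = 2600
    N_perm_weights: int = 2000
    weight_map_C: float = 1.0
    n_cumulative_regions: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        for k in ("grid_shape", "C_grid", "phases"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)

    def __post_init__(self):
        self.grid_shape = tuple(self.grid_shape)
        self.C_grid = tuple(self.C_grid)
        self.phases = tuple(self.phases)


def beta_series_for_dataset(
    ds: SyntheticDataset,
    smooth_fwhm_mm: float = 0.0,
    voxel_size_mm: float = 3.0,
    highpass_s: float | None = 128.0,
    whiten: bool = True,
) -> BetaSeries:
    """Trial-wise GLM for one subject, restricted to in-brain voxels."""
    vols = ds.volumes
    if smooth_fwhm_mm > 0:
        vols = smooth_gaussian(vols, smooth_fwhm_mm, voxel_size_mm)
    design = build_trialwise_design(ds.events, ds.session_n_volumes, ds.TR)
    return fit_glm(vols, design, mask=ds.atlas.brain_mask(), highpass_s=highpass_s, whiten=whiten)


def _decoding_config(cfg: StudyConfig, phase: str, spec: FeatureSpec) -> DecodingConfig:
    return DecodingConfig(
        C_grid=cfg.C_grid, phase=phase, scaling=cfg.scaling, feature_spec=spec, seed=cfg.seed
    )


def _stage_done(path: Path) -> bool:
    return path.exists()


def run_full_study(config: StudyConfig, out_dir: str | Path, resume: bool = True) -> Path:
    """Run the complete analysis; returns the run directory.

    Outputs: per-subject data and beta series, `whole_brain.tsv`,
    `roi_ranking_<phase>.tsv`, `combinations_<phase>.tsv`,
    `voxel_curve_<phase>.tsv`, weight t-maps, a summary figure, and a
    manifest capturing configuration and seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- simulate ---------------------------------------------------------
    data_dir = out / "data"
    datasets: list[SyntheticDataset]
    if resume and _stage_done(data_dir / "sub-00" / "dataset.json"):
        datasets = [
            psio.load_dataset(d) for d in sorted(data_dir.glob("sub-*")) if d.is_dir()
        ]
    else:
        datasets = generate_group(
            config.n_subjects,
            S=config.n_sessions,
            trials_per_session=config.trials_per_session,
            label_balance=config.label_balance,
            grid_shape=config.grid_shape,
            n_regions=config.n_regions,
            n_control=config.n_control_regions,
            TR=config.TR_s,
            master_seed=config.seed,
            effect_size_mean=config.effect_size_mean,
            effect_size_sd_between_subjects=config.effect_size_sd,
            noise_sd=config.noise_sd,
            ar1_rho=config.ar1_rho,
            drift_amplitude=config.drift_amplitude,
        )
        for i, ds in enumerate(datasets):
            psio.save_dataset(ds, data_dir / f"sub-{i:02d}")
    atlas = datasets[0].atlas

    # --- trial-wise GLM ---------------------------------------------------
    beta_dir = out / "betas"
    betas: list[BetaSeries] = []
    for i, ds in enumerate(datasets):
        sub = beta_dir / f"sub-{i:02d}"
        if resume and _stage_done(sub / "beta.json"):
            betas.append(psio.load_beta_series(sub))
        else:
            b = beta_series_for_dataset(
                ds,
                smooth_fwhm_mm=config.smooth_fwhm_mm,
                voxel_size_mm=config.voxel_size_mm,
                highpass_s=config.highpass_cutoff_s,
            )
            psio.save_beta_series(b, sub)
            betas.append(b)

    # --- whole-brain decoding --------------------------------------------
    wb_path = out / "whole_brain.tsv"
    if not (resume and _stage_done(wb_path)):
        rows = []
        for phase in config.phases:
            cfg = _decoding_config(config, phase, FeatureSpec.whole_brain())
            res = group_accuracy([decode_subject(b, cfg, atlas=atlas)[0] for b in betas])
            null = group_accuracy_null(betas, cfg, config.N_perm, seed=config.seed, atlas=atlas)
            rows.append(
                {
                    "phase": phase,
                    "mean_accuracy": res.mean_accuracy,
                    "sem": res.sem,
                    "p": perm_pvalue(res.mean_accuracy, null),
                    "N_perm": config.N_perm,
                }
            )
        pd.DataFrame(rows).to_csv(wb_path, sep="\t", index=False)

    # --- ROI ranking, combinations, voxel curve (per phase) ---------------
    for phase in config.phases:
        rank_path = out / f"roi_ranking_{phase}.tsv"
        comb_path = out / f"combinations_{phase}.tsv"
        curve_path = out / f"voxel_curve_{phase}.tsv"
        if resume and all(map(_stage_done, (rank_path, comb_path, curve_path))):
            continue
        base = _decoding_config(config, phase, FeatureSpec.whole_brain())
        results = roi_group_results(
            betas, atlas, base, N_perm=config.N_perm_roi, perm_seed=config.seed
        )
        ranking = roi_rank_order(results, alpha=config.alpha)
        ranking.table.to_csv(rank_path, sep="\t", index=False)

        ks = range(1, min(config.n_cumulative_regions, len(ranking.ordered_regions)) + 1)
        specs = cumulative_roi_combinations(ranking, ks, atlas=atlas)
        comb = scale_curve(
            betas, atlas, base, specs=specs, N_perm=config.N_perm, perm_seed=config.seed
        )
        comb.table.to_csv(comb_path, sep="\t", index=False)

        curve = scale_curve(
            betas, atlas, base, specs=None, N_perm=config.N_perm, perm_seed=config.seed
        )
        curve.table.to_csv(curve_path, sep="\t", index=False)

    # --- weight-map inference --------------------------------------------
    wmap_dir = out / "weight_maps"
    if not (resume and _stage_done(wmap_dir / "summary.tsv")):
        wmap_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        mean_t: dict[str, np.ndarray] = {}
        for phase in config.phases:
            t_stack = []
            for i, b in enumerate(betas):
                X = feature_matrix(b, phase).values
                Xs, _, _, _ = standardize_voxels(X)
                Xn = l2_normalize_trials(Xs)
                y = (b.meta["label"] == "pain").to_numpy()
                sess = b.meta["session"].to_numpy()

                def train(Xm, labels):
                    w, _, _ = train_linear_margin(Xm, labels, C=config.weight_map_C)
                    return w

                w_obs = train(Xn, y)
                null = weight_null(
                    train, Xn, y, sess, N=config.N_perm_weights, seed=config.seed + i
                )
                tmap = weight_tscores(w_obs, null)
                t_crit, pos, neg = fwe_threshold(tmap, alpha=config.alpha)
                t_stack.append(tmap.t)
                rows.append(
                    {
                        "phase": phase,
                        "subject": i,
                        "t_crit": t_crit,
                        "n_pos": int(pos.sum()),
                        "n_neg": int(neg.sum()),
                        "n_flagged": tmap.n_flagged,
                    }
                )
                vol = np.full(b.grid_shape, np.nan)
                x, yy, z = b.voxel_coords.T
                vol[x, yy, z] = tmap.t
                psio.write_nifti(vol, wmap_dir / f"tmap_{phase}_sub-{i:02d}.nii.gz")
            # simple across-subject mean map (interpretation aid, not a group test)
            mean_map = np.nanmean(np.stack(t_stack), axis=0)
            vol = np.full(betas[0].grid_shape, np.nan)
            x, yy, z = betas[0].voxel_coords.T
            vol[x, yy, z] = mean_map
            psio.write_nifti(vol, wmap_dir / f"tmap_{phase}_groupmean.nii.gz")
        pd.DataFrame(rows).to_csv(wmap_dir / "summary.tsv", sep="\t", index=False)

    # --- report -----------------------------------------------------------
    report_path = out / "report.png"
    if not (resume and _stage_done(report_path)):
        render_report(out, config)

    psio.write_manifest(out, asdict(config) | {"grid_shape": list(config.grid_shape)}, {"seed": config.seed})
    return out


def render_report(run_dir: str | Path, config: StudyConfig) -> Path:
    """Accuracy-vs-scale figure (chance line at 50%) from saved tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    phases = list(config.phases)
    fig, axes = plt.subplots(1, len(phases), figsize=(6 * len(phases), 4), squeeze=False)
    for ax, phase in zip(axes[0], phases):
        curve = pd.read_csv(run_dir / f"voxel_curve_{phase}.tsv", sep="\t")
        ax.errorbar(
            curve["n_voxels"], 100 * curve["mean_accuracy"], yerr=100 * curve["sem"],
            marker="o", label="t-contrast voxel selection",
        )
        comb_file = run_dir / f"combinations_{phase}.tsv"
        if comb_file.exists():
            comb = pd.read_csv(comb_file, sep="\t")
            ax.errorbar(
                comb["n_voxels"], 100 * comb["mean_accuracy"], yerr=100 * comb["sem"],
                marker="s", linestyle="--", label="region combinations",
            )
        ax.axhline(50, color="gray", lw=3, alpha=0.4)
        ax.set_xscale("log")
        ax.set_xlabel("number of voxels")
        ax.set_ylabel("accuracy (%)")
        ax.set_title(phase)
        ax.legend(fontsize=8)
    fig.tight_layout()
    out = run_dir / "report.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
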