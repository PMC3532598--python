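"""On-disk formats: NIfTI-1 volumes, TSV event/result tables, JSON manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .glm import BetaSeries
from .synthdata import Atlas, SignalSpec, SyntheticDataset, TrialEvent

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_events",
    "read_events",
    "save_dataset",
    "load_dataset",
    "save_beta_series",
    "load_beta_series",
    "write_manifest",
]

EVENT_COLUMNS = [
    "session_index",
    "trial_index",
    "anticipation_onset",
    "anticipation_duration",
    "stimulation_onset",
    "stimulation_duration",
    "label",
    "threat",
]


def write_nifti(data: np.ndarray, path: str | Path, voxel_size_mm: float = 3.0) -> Path:
    """Write a 3D/4D array as NIfTI-1 with an isotropic diagonal affine."""
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError("expected a 3D or 4D array")
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    path = Path(path)
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a NIfTI-1 file; returns (data, voxel size in mm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    if any(z <= 0 for z in zooms[:3]):
        raise ValueError(f"malformed NIfTI header in {path}: non-positive voxel size")
    return np.asarray(img.get_fdata()), float(zooms[0])


def write_events(events: list[TrialEvent], path: str | Path) -> Path:
    df = pd.DataFrame([asdict(e) for e in events])[EVENT_COLUMNS]
    # %.17g round-trips doubles exactly through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return Path(path)


def read_events(path: str | Path) -> list[TrialEvent]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [TrialEvent(**{k: row[k] for k in EVENT_COLUMNS}) for _, row in df.iterrows()]


def _atlas_sidecar(atlas: Atlas) -> dict:
    return {
        "regions": {str(i + 1): n for i, n in enumerate(atlas.region_names)},
        "control_regions": list(atlas.control_regions),
    }


def save_dataset(ds: SyntheticDataset, out_dir: str | Path) -> Path:
    """Persist one subject: 4D volumes, events, atlas + sidecar, ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(ds.volumes, out / "bold.nii.gz")
    write_events(ds.events, out / "events.tsv")
    write_nifti(ds.atlas.labels.astype(np.int16), out / "atlas.nii.gz")
    (out / "atlas_regions.json").write_text(json.dumps(_atlas_sidecar(ds.atlas), indent=2))
    write_nifti(ds.truth.informative_voxel_mask.astype(np.int16), out / "truth_mask.nii.gz")
    info = {
        "TR": ds.TR,
        "subject_id": ds.subject_id,
        "seed": ds.seed,
        "session_n_volumes": {str(k): v for k, v in ds.session_n_volumes.items()},
        "effect_size": ds.effect_size,
        "signal": {
            "effect_size_mean": ds.truth.effect_size_mean,
            "effect_size_sd_between_subjects": ds.truth.effect_size_sd_between_subjects,
            "phase": ds.truth.phase,
            "noise_sd": ds.truth.noise_sd,
            "ar1_rho": ds.truth.ar1_rho,
            "drift_amplitude": ds.truth.drift_amplitude,
            "base_amplitude": ds.truth.base_amplitude,
        },
    }
    (out / "dataset.json").write_text(json.dumps(info, indent=2))
    return out


def load_dataset(in_dir: str | Path) -> SyntheticDataset:
    p = Path(in_dir)
    volumes, _ = read_nifti(p / "bold.nii.gz")
    events = read_events(p / "events.tsv")
    labels, _ = read_nifti(p / "atlas.nii.gz")
    sidecar = json.loads((p / "atlas_regions.json").read_text())
    names = [sidecar["regions"][str(i)] for i in range(1, len(sidecar["regions"]) + 1)]
    atlas = Atlas(labels=labels.astype(int), region_names=names, control_regions=sidecar["control_regions"])
    truth_mask, _ = read_nifti(p / "truth_mask.nii.gz")
    info = json.loads((p / "dataset.json").read_text())
    truth = SignalSpec(informative_voxel_mask=truth_mask.astype(bool), **info["signal"])
    return SyntheticDataset(
        volumes=volumes,
        TR=info["TR"],
        events=events,
        atlas=atlas,
        truth=truth,
        subject_id=info["subject_id"],
        seed=info["seed"],
        session_n_volumes={int(k): v for k, v in info["session_n_volumes"].items()},
        effect_size=info["effect_size"],
    )


def save_beta_series(beta: BetaSeries, out_dir: str | Path) -> Path:
    """One 4D NIfTI per phase (trials along the 4th axis) + metadata table.

    Voxels outside the analysis mask are NaN in the images.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for phase, pat in beta.patterns.items():
        vol = np.full(beta.grid_shape + (pat.shape[0],), np.nan)
        x, y, z = beta.voxel_coords.T
        vol[x, y, z, :] = pat.T
        write_nifti(vol, out / f"beta_{phase}.nii.gz")
    beta.meta.to_csv(out / "trials.tsv", sep="\t", index=False)
    mask = np.zeros(beta.grid_shape, dtype=np.int16)
    x, y, z = beta.voxel_coords.T
    mask[x, y, z] = 1
    write_nifti(mask, out / "mask.nii.gz")
    extra = {"ar1_rho": beta.ar1_rho}
    (out / "beta.json").write_text(json.dumps(extra, indent=2))
    return out


def load_beta_series(in_dir: str | Path) -> BetaSeries:
    p = Path(in_dir)
    mask, _ = read_nifti(p / "mask.nii.gz")
    coords = np.argwhere(mask > 0)
    patterns = {}
    for f in sorted(p.glob("beta_*.nii.gz")):
        phase = f.name[len("beta_") : -len(".nii.gz")]
        vol, _ = read_nifti(f)
        x, y, z = coords.T
        patterns[phase] = vol[x, y, z, :].T
    meta = pd.read_csv(p / "trials.tsv", sep="\t")
    extra = json.loads((p / "beta.json").read_text())
    return BetaSeries(
        patterns=patterns,
        meta=meta,
        voxel_coords=coords,
        grid_shape=tuple(mask.shape),
        ar1_rho=extra.get("ar1_rho"),
    )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: dict,
    seeds: dict,
    input_paths: list[str | Path] | None = None,
) -> Path:
    """Record everything needed to reproduce a run (config, seeds, versions)."""
    import sklearn
    import scipy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seeds": seeds,
        "versions": {
            "painscale": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "pandas": pd.__version__,
        },
        "input_hashes": {str(p): _hash_file(Path(p)) for p in (input_paths or [])},
        "timestamp": pd.Timestamp.now().isoformat(),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
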