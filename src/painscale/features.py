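"""Feature construction: scaling, ROI masking, and discriminability ranking.

Two scaling steps precede classification, in this order: per-voxel
standardization (mean 0, population sd 1, estimated on the fitting rows and
applied to all rows) and per-trial l2 scaling (each trial pattern to unit
Euclidean norm).  Voxel selection ranks voxels by the absolute two-sample
pooled-variance t statistic between classes, computed on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .glm import BetaSeries
from .synthdata import Atlas

__all__ = [
    "FeatureMatrix",
    "feature_matrix",
    "standardize_voxels",
    "l2_normalize_trials",
    "apply_roi_mask",
    "rank_voxels_tcontrast",
    "select_top_voxels",
    "scale_schedule",
]


@dataclass
class FeatureMatrix:
    """Trials x features matrix with provenance and scaling-state flags."""

    values: np.ndarray
    voxel_coords: np.ndarray  # (p, 3) int coordinates into the grid
    provenance: str = "whole_brain"
    standardized: bool = False
    l2_normalized: bool = False
    flagged: np.ndarray | None = None  # zero-variance / degenerate features

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def feature_matrix(beta: BetaSeries, phase: str) -> FeatureMatrix:
    """Whole-brain feature matrix for one phase of a beta series."""
    if phase not in beta.patterns:
        raise KeyError(f"phase {phase!r} not in beta series")
    return FeatureMatrix(
        values=np.asarray(beta.patterns[phase], dtype=float),
        voxel_coords=beta.voxel_coords,
        provenance="whole_brain",
    )


def standardize_voxels(
    matrix: np.ndarray, fit_rows: Sequence[int] | np.ndarray | None = None
):
    """Standardize each column using mean/sd estimated on `fit_rows`.

    Returns (standardized matrix, means, sds, zero-variance flags).  The
    population (divide-by-n) convention makes the fitting-set sd exactly 1.
    Zero-variance columns get sd 1 and are flagged: they carry no
    information and standardize to all zeros on the fitting rows.
    """
    X = np.asarray(matrix, dtype=float)
    rows = np.arange(X.shape[0]) if fit_rows is None else np.asarray(fit_rows)
    if rows.dtype == bool:
        rows = np.flatnonzero(rows)
    if rows.size < 2:
        raise ValueError("need >= 2 fitting rows to standardize")
    mu = X[rows].mean(axis=0)
    sd = X[rows].std(axis=0)  # ddof=0
    flags = sd == 0
    sd = np.where(flags, 1.0, sd)
    return (X - mu) / sd, mu, sd, flags


def l2_normalize_trials(matrix: np.ndarray) -> np.ndarray:
    """Scale each row (trial pattern) to unit Euclidean norm."""
    X = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"cannot l2-normalize all-zero trial rows: {zero.tolist()}")
    return X / norms[:, None]


def apply_roi_mask(
    obj: BetaSeries | FeatureMatrix,
    atlas: Atlas,
    region_names: Sequence[str],
    phase: str | None = None,
) -> FeatureMatrix:
    """Restrict features to voxels in the union of the named regions."""
    if isinstance(obj, BetaSeries):
        if phase is None:
            raise ValueError("phase required when masking a BetaSeries")
        fm = feature_matrix(obj, phase)
    else:
        fm = obj
    mask = atlas.union_mask(list(region_names))
    flat_mask = mask.ravel()
    lin = np.ravel_multi_index(fm.voxel_coords.T, atlas.grid_shape)
    keep = flat_mask[lin]
    if not np.any(keep):
        raise ValueError(f"ROI union {list(region_names)} contains no features")
    prov = f"roi:{region_names[0]}" if len(region_names) == 1 else "roi_union:" + "+".join(region_names)
    return FeatureMatrix(
        values=fm.values[:, keep],
        voxel_coords=fm.voxel_coords[keep],
        provenance=prov,
        standardized=fm.standardized,
        l2_normalized=fm.l2_normalized,
        flagged=None if fm.flagged is None else fm.flagged[keep],
    )


def rank_voxels_tcontrast(matrix: np.ndarray, labels: np.ndarray):
    """Rank voxels by |t| of a two-sample pooled-variance t-contrast.

    `labels` is boolean (True = pain) or a string array containing both
    classes.  Returns (order, t): `order` indexes voxels by descending |t|;
    ties break by ascending voxel index (stable), and infinite |t| (zero
    pooled variance with distinct class means) sorts above all finite values.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y == "pain"
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to rank voxels")
    m1 = X[y].mean(axis=0)
    m0 = X[~y].mean(axis=0)
    v1 = X[y].var(axis=0, ddof=1) if n1 > 1 else np.zeros(X.shape[1])
    v0 = X[~y].var(axis=0, ddof=1) if n0 > 1 else np.zeros(X.shape[1])
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df if df > 0 else np.zeros(X.shape[1])
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / denom
    t = np.where((denom == 0) & (m1 == m0), 0.0, t)  # 0/0 -> no evidence
    order = np.argsort(-np.abs(t), kind="stable")  # -inf sorts last, -|inf| first
    return order, t


def select_top_voxels(fm: FeatureMatrix, order: np.ndarray, k: int) -> FeatureMatrix:
    """Keep the top-min(k, V) voxels of a ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = order[: min(k, fm.n_features)]
    return FeatureMatrix(
        values=fm.values[:, keep],
        voxel_coords=fm.voxel_coords[keep],
        provenance=f"top_voxels:{min(k, fm.n_features)}",
        standardized=fm.standardized,
        l2_normalized=fm.l2_normalized,
        flagged=None if fm.flagged is None else fm.flagged[keep],
    )


def scale_schedule(n_voxels: int) -> list[int]:
    """Voxel-count schedule 3^0, 3^1, ... capped by and ending at V."""
    if n_voxels < 1:
        raise ValueError("need at least one voxel")
    ks: list[int] = []
    k = 1
    while k < n_voxels:
        ks.append(k)
        k *= 3
    ks.append(n_voxels)
    return ks
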