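"""Spatial-scale analysis: ROI ranking, cumulative combinations, voxel curve.

Accuracy is studied as a function of the feature space: single most
discriminative voxel, 3^k voxels, single anatomical regions, cumulative
unions of the most significant regions, the full set of pain-related
regions ("pain matrix"), and whole brain.  Region significance comes from
the group permutation test; rankings sort by p-value, not accuracy, so
between-subject variability is taken into account.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .decoding import DecodingConfig, FeatureSpec, GroupResult, decode_subject, group_accuracy
from .features import scale_schedule
from .glm import BetaSeries
from .perminfer import group_accuracy_null, paired_accuracy_comparison, perm_pvalue
from .synthdata import Atlas

__all__ = [
    "RoiRanking",
    "ScaleCurve",
    "roi_rank_order",
    "cumulative_roi_combinations",
    "decode_group",
    "roi_group_results",
    "scale_curve",
    "split_half_combination_curve",
    "compare_scales",
]


@dataclass
class RoiRanking:
    """Regions ordered by the significance of their group accuracies."""

    table: pd.DataFrame  # region, mean_accuracy, sem, p, significant
    alpha: float
    n_tests: int

    @property
    def ordered_regions(self) -> list[str]:
        return self.table["region"].tolist()


@dataclass
class ScaleCurve:
    """Accuracy across feature-space definitions, one row per scale point."""

    table: pd.DataFrame  # spec, kind, n_voxels, mean_accuracy, sem, p
    per_subject: dict[str, np.ndarray]  # provenance -> per-subject accuracies
    config: DecodingConfig


def decode_group(
    betas: Sequence[BetaSeries],
    config: DecodingConfig,
    atlas: Atlas | None = None,
) -> GroupResult:
    """Decode every subject with a shared configuration and aggregate."""
    accs = [decode_subject(b, config, atlas=atlas)[0] for b in betas]
    return group_accuracy(accs)


def roi_group_results(
    betas: Sequence[BetaSeries],
    atlas: Atlas,
    config: DecodingConfig,
    regions: Sequence[str] | None = None,
    N_perm: int = 1000,
    perm_seed: int = 0,
) -> dict[str, GroupResult]:
    """Per-region group decoding with permutation p-values."""
    regions = list(atlas.region_names) if regions is None else list(regions)
    out: dict[str, GroupResult] = {}
    for i, name in enumerate(regions):
        cfg = replace(config, feature_spec=FeatureSpec.roi(name))
        res = decode_group(betas, cfg, atlas=atlas)
        null = group_accuracy_null(list(betas), cfg, N_perm, seed=perm_seed + i, atlas=atlas)
        res.null_accuracies = null
        res.p_value = perm_pvalue(res.mean_accuracy, null)
        out[name] = res
    return out


def roi_rank_order(
    results: dict[str, GroupResult], alpha: float = 0.05
) -> RoiRanking:
    """Sort regions by p ascending; ties by higher accuracy, then name.

    Bonferroni significance flags use alpha divided by the number of
    regions tested (controls included).
    """
    if len(results) < 1:
        raise ValueError("need at least one region result")
    n = len(results)
    ns = {len(r.subject_accuracies) for r in results.values()}
    if len(ns) != 1:
        raise ValueError("all regions must be decoded on the same subjects")
    rows = [
        {
            "region": name,
            "mean_accuracy": r.mean_accuracy,
            "sem": r.sem,
            "p": r.p_value if r.p_value is not None else np.nan,
        }
        for name, r in results.items()
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["p", "mean_accuracy", "region"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    df["significant"] = df["p"] <= alpha / n
    return RoiRanking(table=df, alpha=alpha, n_tests=n)


def cumulative_roi_combinations(
    ranking: RoiRanking,
    ks: Sequence[int],
    atlas: Atlas | None = None,
    include_presets: bool = True,
) -> list[FeatureSpec]:
    """Feature specs for unions of the top-k ranked regions.

    Optionally appends the `pain_matrix` preset (union of all non-control
    regions; requires the atlas) and the whole-brain spec.
    """
    order = ranking.ordered_regions
    specs: list[FeatureSpec] = []
    for k in ks:
        if not (1 <= k <= len(order)):
            raise ValueError(f"k={k} outside 1..{len(order)}")
        specs.append(FeatureSpec.roi(*order[:k]))
    if include_presets:
        if atlas is not None:
            specs.append(FeatureSpec.roi(*atlas.noncontrol_regions))
        specs.append(FeatureSpec.whole_brain())
    return specs


def _spec_n_voxels(spec: FeatureSpec, betas: Sequence[BetaSeries], atlas: Atlas | None) -> float:
    if spec.kind == "top_voxels":
        return float(spec.k)
    if spec.kind == "whole_brain":
        return float(np.mean([b.n_voxels for b in betas]))
    mask = atlas.union_mask(list(spec.region_names))
    return float(mask.sum())


def scale_curve(
    betas: Sequence[BetaSeries],
    atlas: Atlas,
    config: DecodingConfig,
    specs: Sequence[FeatureSpec] | None = None,
    N_perm: int = 1000,
    perm_seed: int = 0,
) -> ScaleCurve:
    """Group accuracy per feature-space definition, with permutation p.

    Default specs follow the tripling voxel-count schedule 3^0, 3^1, ...
    up to whole brain, with the whole-brain point appended explicitly.
    Voxel rankings for top-k points are recomputed inside each training
    fold.  Each ROI point is also placed on the voxel-count axis by its
    mask size, so anatomical and t-contrast feature selection can be read
    off a common axis.
    """
    if specs is None:
        V = betas[0].n_voxels
        specs = [FeatureSpec.top_voxels(k) for k in scale_schedule(V)[:-1]]
        specs.append(FeatureSpec.whole_brain())
    rows = []
    per_subject: dict[str, np.ndarray] = {}
    for i, spec in enumerate(specs):
        cfg = replace(config, feature_spec=spec)
        res = decode_group(betas, cfg, atlas=atlas)
        null = group_accuracy_null(list(betas), cfg, N_perm, seed=perm_seed + i, atlas=atlas)
        p = perm_pvalue(res.mean_accuracy, null)
        per_subject[spec.provenance] = res.per_subject
        rows.append(
            {
                "spec": spec.provenance,
                "kind": spec.kind,
                "n_voxels": _spec_n_voxels(spec, betas, atlas),
                "mean_accuracy": res.mean_accuracy,
                "sem": res.sem,
                "p": p,
            }
        )
    return ScaleCurve(table=pd.DataFrame(rows), per_subject=per_subject, config=config)


def split_half_combination_curve(
    betas: Sequence[BetaSeries],
    atlas: Atlas,
    config: DecodingConfig,
    ks: Sequence[int],
    N_perm: int = 1000,
    perm_seed: int = 0,
    rank_subjects: Sequence[int] | None = None,
    roi_N_perm: int | None = None,
) -> tuple[RoiRanking, ScaleCurve]:
    """Rank regions on one half of the subjects, evaluate unions on the rest.

    The default combination analysis ranks and evaluates on the same group,
    which is mildly circular at the group level; this variant removes that
    circularity at the cost of halving the sample.  `rank_subjects` gives
    the indices used for ranking (default: the first half); the remaining
    subjects are decoded on the cumulative unions.
    """
    n = len(betas)
    if n < 4:
        raise ValueError("split-half needs at least 4 subjects")
    idx = set(range(n // 2) if rank_subjects is None else map(int, rank_subjects))
    if not idx or idx == set(range(n)):
        raise ValueError("both halves must be nonempty")
    rank_half = [b for i, b in enumerate(betas) if i in idx]
    eval_half = [b for i, b in enumerate(betas) if i not in idx]
    results = roi_group_results(
        rank_half, atlas, config, N_perm=roi_N_perm or N_perm, perm_seed=perm_seed
    )
    ranking = roi_rank_order(results)
    specs = cumulative_roi_combinations(ranking, ks, atlas=atlas)
    curve = scale_curve(
        eval_half, atlas, config, specs=specs, N_perm=N_perm, perm_seed=perm_seed + 1
    )
    return ranking, curve


def compare_scales(
    curve: ScaleCurve, spec_a: str, spec_b: str, N: int = 1000, seed: int = 0
) -> float:
    """Paired sign-flip permutation test between two scale points."""
    for s in (spec_a, spec_b):
        if s not in curve.per_subject:
            raise KeyError(f"scale point {s!r} not in curve")
    a, b = curve.per_subject[spec_a], curve.per_subject[spec_b]
    if a.shape != b.shape:
        raise ValueError("scale points computed on different subjects")
    return paired_accuracy_comparison(a, b, N=N, seed=seed)
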