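"""Linear maximum-margin decoding with leave-one-session-out cross-validation.

The decoder is a soft-margin linear SVM.  Outer folds leave one scanning
session out; within each training fold, scaling parameters, the voxel
ranking (when a top-k feature spec is used) and the regularization
hyperparameter C (nested leave-one-trial-out selection) are computed on
training trials only, so test data never influence training.  Decoding runs
separately within each threat stratum and a subject's score is the mean of
the two stratum accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .features import (
    FeatureMatrix,
    apply_roi_mask,
    feature_matrix,
    l2_normalize_trials,
    rank_voxels_tcontrast,
    select_top_voxels,
    standardize_voxels,
)
from .glm import BetaSeries
from .synthdata import Atlas

__all__ = [
    "FeatureSpec",
    "DecodingConfig",
    "FoldResult",
    "SubjectAccuracy",
    "GroupResult",
    "loso_folds",
    "train_linear_margin",
    "nested_select_C",
    "decode_subject",
    "group_accuracy",
]

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


@dataclass(frozen=True)
class FeatureSpec:
    """What enters the classifier: whole brain, ROI(s), or top-k voxels."""

    kind: str = "whole_brain"  # whole_brain | roi | roi_union | top_voxels
    region_names: tuple[str, ...] = ()
    k: int = 0

    def __post_init__(self):
        if self.kind not in ("whole_brain", "roi", "roi_union", "top_voxels"):
            raise ValueError(f"unknown feature spec kind {self.kind!r}")
        if self.kind in ("roi", "roi_union") and not self.region_names:
            raise ValueError("ROI feature spec needs region names")
        if self.kind == "top_voxels" and self.k < 1:
            raise ValueError("top_voxels spec needs k >= 1")

    @property
    def provenance(self) -> str:
        if self.kind == "whole_brain":
            return "whole_brain"
        if self.kind == "roi":
            return f"roi:{self.region_names[0]}"
        if self.kind == "roi_union":
            return "roi_union:" + "+".join(self.region_names)
        return f"top_voxels:{self.k}"

    @staticmethod
    def whole_brain() -> "FeatureSpec":
        return FeatureSpec("whole_brain")

    @staticmethod
    def roi(*names: str) -> "FeatureSpec":
        return FeatureSpec("roi" if len(names) == 1 else "roi_union", tuple(names))

    @staticmethod
    def top_voxels(k: int) -> "FeatureSpec":
        return FeatureSpec("top_voxels", k=k)


@dataclass
class DecodingConfig:
    """Everything a decoding run depends on, for reproducibility."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    phase: str = "stimulation"
    scaling: str = "fold"  # 'fold' (non-circular, default) or 'global'
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec.whole_brain)
    seed: int = 0
    tol: float = 1e-6

    def __post_init__(self):
        if len(self.C_grid) == 0 or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid must be nonempty and strictly positive")
        if self.scaling not in ("fold", "global"):
            raise ValueError("scaling must be 'fold' or 'global'")


@dataclass
class FoldResult:
    threat: str
    test_session: int
    chosen_C: float
    weights: np.ndarray
    intercept: float
    scaler_mean: np.ndarray | None
    scaler_sd: np.ndarray | None
    selected_voxels: np.ndarray | None  # column indices into the masked matrix
    predicted: np.ndarray  # bool, True = pain
    true: np.ndarray
    train_class_counts: tuple[int, int]  # (pain, no_pain) in training fold

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predicted == self.true))


@dataclass
class SubjectAccuracy:
    accuracy_high_threat: float
    accuracy_low_threat: float
    n_trials_high: int
    n_trials_low: int
    mean_fold_accuracy: float = float("nan")

    @property
    def mean_accuracy(self) -> float:
        return 0.5 * (self.accuracy_high_threat + self.accuracy_low_threat)


@dataclass
class GroupResult:
    subject_accuracies: list[SubjectAccuracy]
    p_value: float | None = None
    null_accuracies: np.ndarray | None = None

    @property
    def per_subject(self) -> np.ndarray:
        return np.array([s.mean_accuracy for s in self.subject_accuracies])

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_subject.mean())

    @property
    def sem(self) -> float:
        a = self.per_subject
        return float(a.std(ddof=1) / np.sqrt(len(a)))


def loso_folds(sessions: Sequence[int]) -> list[tuple[tuple[int, ...], int]]:
    """Leave-one-session-out folds: (train sessions, test session) per session."""
    uniq = sorted(set(int(s) for s in sessions))
    if len(uniq) < 2:
        raise ValueError("leave-one-session-out needs >= 2 sessions")
    return [(tuple(s for s in uniq if s != t), t) for t in uniq]


def train_linear_margin(features: np.ndarray, labels: np.ndarray, C: float, tol: float = 1e-6):
    """Fit a soft-margin linear SVM; returns (weights, intercept, classifier).

    Positive decision values predict the positive (pain) class.
    """
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y == "pain"
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    if C <= 0:
        raise ValueError("C must be positive")
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(np.asarray(features, dtype=float), y)
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    return w, b, clf


def nested_select_C(
    features: np.ndarray, labels: np.ndarray, C_grid: Sequence[float], tol: float = 1e-6
) -> float:
    """Choose C by inner leave-one-trial-out accuracy; ties -> smallest C.

    Inner folds whose training set would lose a class entirely (the left-out
    trial is the last of its class) are skipped; if no inner fold is
    evaluable the smallest C is returned.
    """
    grid = sorted(C_grid)
    if len(grid) == 0:
        raise ValueError("empty C grid")
    if len(grid) == 1:
        return float(grid[0])
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y == "pain"
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("nested selection needs both classes in the training data")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    evaluable = [
        i for i in range(n) if (n_pos - int(y[i]) >= 1 and n_neg - int(not y[i]) >= 1)
    ]
    if not evaluable:
        return float(grid[0])
    best_C, best_acc = None, -1.0
    for C in grid:
        correct = 0
        for i in evaluable:
            tr = np.arange(n) != i
            clf = SVC(kernel="linear", C=C, tol=tol)
            clf.fit(X[tr], y[tr])
            correct += int(clf.predict(X[i : i + 1])[0] == y[i])
        acc = correct / len(evaluable)
        if acc > best_acc:  # strict: ties keep the smaller C seen first
            best_acc, best_C = acc, float(C)
    return best_C


def _resolve_static_columns(beta: BetaSeries, spec: FeatureSpec, atlas: Atlas | None) -> np.ndarray | None:
    """Column indices for ROI specs (fold-independent); None = all columns."""
    if spec.kind in ("roi", "roi_union"):
        if atlas is None:
            raise ValueError("atlas required for ROI feature specs")
        mask_flat = atlas.union_mask(list(spec.region_names)).ravel()
        lin = np.ravel_multi_index(beta.voxel_coords.T, atlas.grid_shape)
        cols = np.flatnonzero(mask_flat[lin])
        if cols.size == 0:
            raise ValueError(f"feature spec {spec.provenance} selects no voxels")
        return cols
    return None


def decode_subject(
    beta: BetaSeries,
    config: DecodingConfig,
    atlas: Atlas | None = None,
    labels: Sequence[str] | None = None,
) -> tuple[SubjectAccuracy, list[FoldResult]]:
    """Condition-split, leave-one-session-out decoding of one subject.

    Runs one analysis per threat stratum; within each outer fold the
    scaling fit, the t-contrast ranking (for top-k specs) and the nested
    C selection see training trials only.  Stratum accuracy pools correctly
    predicted test trials across folds; the subject value is the mean of the
    two stratum accuracies.  `labels` overrides the perception labels (used
    by permutation schemes) without copying the patterns.
    """
    X_all = np.asarray(beta.patterns[config.phase], dtype=float)
    meta = beta.meta
    y_all = np.asarray(meta["label"] if labels is None else list(labels))
    y_all = y_all == "pain"
    sessions_all = meta["session"].to_numpy()
    threat_all = meta["threat"].to_numpy()

    static_cols = _resolve_static_columns(beta, config.feature_spec, atlas)
    if static_cols is not None:
        X_all = X_all[:, static_cols]

    fold_results: list[FoldResult] = []
    stratum_acc: dict[str, float] = {}
    stratum_n: dict[str, int] = {}
    fold_accs: list[float] = []

    for threat in ("high", "low"):
        rows = np.flatnonzero(threat_all == threat)
        X = X_all[rows]
        y = y_all[rows]
        sess = sessions_all[rows]

        if config.scaling == "global":
            # replicates pre-CV global standardization (mildly circular)
            X, g_mu, g_sd, _ = standardize_voxels(X)

        n_correct = 0
        n_tested = 0
        for train_sessions, test_session in loso_folds(sess):
            tr = np.isin(sess, train_sessions)
            te = sess == test_session
            y_tr, y_te = y[tr], y[te]
            if len(np.unique(y_tr)) < 2:
                warnings.warn(
                    f"threat={threat}: training fold for test session {test_session} "
                    "has one class; fold skipped"
                )
                continue

            if config.scaling == "fold":
                Xs, mu, sd, _ = standardize_voxels(X, fit_rows=np.flatnonzero(tr))
            else:
                Xs, mu, sd = X, None, None
            Xn = l2_normalize_trials(Xs)

            sel = None
            X_tr, X_te = Xn[tr], Xn[te]
            if config.feature_spec.kind == "top_voxels":
                order, _t = rank_voxels_tcontrast(X_tr, y_tr)
                sel = order[: min(config.feature_spec.k, Xn.shape[1])]
                X_tr, X_te = X_tr[:, sel], X_te[:, sel]

            if len(config.C_grid) == 1:
                C = float(config.C_grid[0])
            else:
                C = nested_select_C(X_tr, y_tr, config.C_grid, tol=config.tol)
            w, b, clf = train_linear_margin(X_tr, y_tr, C, tol=config.tol)
            pred = clf.predict(X_te)

            n_correct += int(np.sum(pred == y_te))
            n_tested += int(te.sum())
            fr = FoldResult(
                threat=threat,
                test_session=int(test_session),
                chosen_C=C,
                weights=w,
                intercept=b,
                scaler_mean=mu,
                scaler_sd=sd,
                selected_voxels=sel,
                predicted=pred.astype(bool),
                true=y_te,
                train_class_counts=(int(y_tr.sum()), int((~y_tr).sum())),
            )
            fold_results.append(fr)
            fold_accs.append(fr.accuracy)

        if n_tested == 0:
            raise ValueError(f"threat stratum {threat!r} undecodable: every fold skipped")
        stratum_acc[threat] = n_correct / n_tested
        stratum_n[threat] = n_tested

    acc = SubjectAccuracy(
        accuracy_high_threat=stratum_acc["high"],
        accuracy_low_threat=stratum_acc["low"],
        n_trials_high=stratum_n["high"],
        n_trials_low=stratum_n["low"],
        mean_fold_accuracy=float(np.mean(fold_accs)) if fold_accs else float("nan"),
    )
    return acc, fold_results


def group_accuracy(subject_accuracies: Sequence[SubjectAccuracy]) -> GroupResult:
    """Aggregate subjects: arithmetic mean of per-subject mean accuracies."""
    if len(subject_accuracies) < 2:
        raise ValueError("group statistics need >= 2 subjects")
    return GroupResult(subject_accuracies=list(subject_accuracies))
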