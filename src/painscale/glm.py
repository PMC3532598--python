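"""First-level GLM for trial-wise (beta-series) estimation.

The model follows the standard mass-univariate fMRI convention: each trial
contributes one boxcar regressor for the anticipation phase (trial-specific
duration) and one for the 1 s stimulation phase, both convolved with the
canonical double-gamma hemodynamic response function.  Low-frequency drift is
removed with a discrete-cosine high-pass filter (cut-off 128 s) and serial
autocorrelation is handled by a pooled first-order autoregressive model, both
applied consistently to data and design before the final least-squares fit.
The per-trial parameter estimates form the patterns used by the decoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import ndimage
from scipy.stats import gamma as _gamma_dist

if TYPE_CHECKING:  # pragma: no cover
    from .synthdata import TrialEvent

__all__ = [
    "DesignMatrix",
    "BetaSeries",
    "hrf_kernel",
    "build_trialwise_design",
    "highpass_dct",
    "dct_basis",
    "ar1_fit_whiten",
    "estimate_ar1",
    "ar1_whitening_matrix",
    "fit_glm",
    "smooth_gaussian",
]

# Canonical double-gamma parameterization: response gamma with shape 6 (peak
# delay 6 s at unit dispersion), undershoot gamma with shape 16, undershoot
# ratio 1/6, kernel support 32 s.
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_DISPERSION = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0
_HRF_LENGTH = 32.0
_MICROTIME_DT = 0.1


def _double_gamma(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, _PEAK_DELAY / _DISPERSION, scale=_DISPERSION)
    h = h - _UNDERSHOOT_RATIO * _gamma_dist.pdf(
        t, _UNDERSHOOT_DELAY / _DISPERSION, scale=_DISPERSION
    )
    return h


def _hrf_peak() -> float:
    # dense evaluation; cached after first call
    global _HRF_PEAK_CACHE
    try:
        return _HRF_PEAK_CACHE
    except NameError:
        tt = np.arange(0.0, _HRF_LENGTH, 0.001)
        _HRF_PEAK_CACHE = float(_double_gamma(tt).max())
        return _HRF_PEAK_CACHE


def hrf_kernel(TR: float, duration: float = _HRF_LENGTH) -> np.ndarray:
    """Canonical double-gamma HRF sampled every `TR` seconds on [0, duration].

    The kernel is scaled to unit peak amplitude (peak measured on a dense
    grid), so GLM parameter estimates are in units of peak response height.
    """
    if TR <= 0:
        raise ValueError("TR must be positive")
    n = int(np.floor(duration / TR + 1e-12)) + 1
    t = np.arange(n) * TR
    return _double_gamma(t) / _hrf_peak()


@dataclass
class DesignMatrix:
    """Time x regressor design with per-column bookkeeping.

    `kinds` holds one of {'trial_anticipation', 'trial_stimulation',
    'confound', 'constant'} per column; `row_sessions` maps each scan volume
    to its session so filtering and whitening can respect session boundaries.
    """

    matrix: np.ndarray
    names: list[str]
    kinds: np.ndarray  # dtype object/str, one per column
    TR: float
    row_sessions: np.ndarray  # session index per row (volume)
    session_n_volumes: dict[int, int]
    trial_meta: pd.DataFrame  # session, trial_index, label, threat per trial

    @property
    def n_trials(self) -> int:
        return int(np.sum(self.kinds == "trial_anticipation"))

    def columns_of_kind(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.kinds == kind)


def _as_session_n_volumes(
    events: Sequence["TrialEvent"], n_volumes: int | Sequence[int] | dict[int, int], TR: float
) -> dict[int, int]:
    sessions = sorted({e.session_index for e in events})
    if isinstance(n_volumes, dict):
        missing = set(sessions) - set(n_volumes)
        if missing:
            raise ValueError(f"n_volumes missing sessions {sorted(missing)}")
        return {int(s): int(v) for s, v in sorted(n_volumes.items())}
    if np.isscalar(n_volumes):
        return {s: int(n_volumes) for s in sessions}
    seq = list(n_volumes)
    if len(seq) != len(sessions):
        raise ValueError("n_volumes sequence length must match number of sessions")
    return dict(zip(sessions, (int(v) for v in seq)))


def build_trialwise_design(
    events: Sequence["TrialEvent"],
    n_volumes: int | Sequence[int] | dict[int, int],
    TR: float,
) -> DesignMatrix:
    """Build the trial-wise design: 2 HRF-convolved boxcars per trial.

    Onsets in `events` are relative to the start of their session; sessions
    are concatenated along the time axis in ascending session order, each
    padded to the volume count given by `n_volumes` (an int applied to every
    session, or one count per session).  Boxcars are built on a 0.1 s
    microtime grid, convolved with the canonical HRF, and sampled at volume
    onsets (slice-time 0).  One constant column is added per session.
    """
    events = list(events)
    sess_nvol = _as_session_n_volumes(events, n_volumes, TR)
    sessions = sorted(sess_nvol)
    total_T = sum(sess_nvol.values())

    n_trials = len(events)
    # column layout: all anticipation regressors (trial order), then all
    # stimulation regressors, then per-session constants
    n_cols = 2 * n_trials + len(sessions)
    X = np.zeros((total_T, n_cols))
    names: list[str] = [""] * n_cols
    kinds = np.empty(n_cols, dtype=object)

    row_sessions = np.concatenate(
        [np.full(sess_nvol[s], s, dtype=int) for s in sessions]
    )
    row_offset = {s: int(np.flatnonzero(row_sessions == s)[0]) for s in sessions}

    dt = _MICROTIME_DT
    h = _double_gamma(np.arange(0.0, _HRF_LENGTH + dt / 2, dt)) / _hrf_peak()

    # per-session convolved regressors
    for s in sessions:
        T_s = sess_nvol[s]
        scan_len = T_s * TR
        n_micro = int(round(scan_len / dt))
        vol_idx = (np.arange(T_s) * TR / dt).round().astype(int)
        sess_events = [(i, e) for i, e in enumerate(events) if e.session_index == s]
        for i, e in sess_events:
            for phase, onset, dur, col in (
                ("trial_anticipation", e.anticipation_onset, e.anticipation_duration, i),
                ("trial_stimulation", e.stimulation_onset, e.stimulation_duration, n_trials + i),
            ):
                if onset + dur > scan_len + 1e-9:
                    raise ValueError(
                        f"event (session {s}, trial {e.trial_index}) extends past "
                        f"scan end ({onset + dur:.1f} s > {scan_len:.1f} s)"
                    )
                box = np.zeros(n_micro)
                a = int(round(onset / dt))
                b = int(round((onset + dur) / dt))
                box[a:b] = 1.0
                reg = np.convolve(box, h)[:n_micro] * dt
                rows = slice(row_offset[s], row_offset[s] + T_s)
                X[rows, col] = reg[vol_idx]
                names[col] = f"{'ant' if phase == 'trial_anticipation' else 'stim'}_s{s}_t{e.trial_index}"
                kinds[col] = phase

    for j, s in enumerate(sessions):
        col = 2 * n_trials + j
        rows = row_sessions == s
        X[rows, col] = 1.0
        names[col] = f"const_s{s}"
        kinds[col] = "constant"

    # fill names/kinds of trial columns for sessions handled above
    trial_meta = pd.DataFrame(
        {
            "session": [e.session_index for e in events],
            "trial_index": [e.trial_index for e in events],
            "label": [e.label for e in events],
            "threat": [e.threat for e in events],
        }
    )
    return DesignMatrix(
        matrix=X,
        names=names,
        kinds=kinds,
        TR=TR,
        row_sessions=row_sessions,
        session_n_volumes=sess_nvol,
        trial_meta=trial_meta,
    )


def dct_basis(n: int, TR: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis (constant included) up to 1/cutoff Hz."""
    if n < 2:
        raise ValueError("need at least 2 time points")
    if cutoff_s <= 2 * TR:
        raise ValueError("cutoff must exceed 2*TR")
    k = int(np.floor(2.0 * n * TR / cutoff_s)) + 1  # includes k=0 constant
    k = max(k, 1)
    t = np.arange(n)
    D = np.cos(np.pi * np.outer(2 * t + 1, np.arange(k)) / (2.0 * n))
    # orthonormalize for a numerically clean projector
    D, _ = np.linalg.qr(D)
    return D


def highpass_dct(series: np.ndarray, TR: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Residualize a (time x anything) array against the DCT drift basis."""
    Y = np.atleast_2d(np.asarray(series, dtype=float))
    squeeze = np.asarray(series).ndim == 1
    if squeeze:
        Y = Y.T
    D = dct_basis(Y.shape[0], TR, cutoff_s)
    out = Y - D @ (D.T @ Y)
    return out[:, 0] if squeeze else out


def estimate_ar1(resid: np.ndarray, row_sessions: np.ndarray | None = None) -> float:
    """Pooled lag-1 autocorrelation of residuals, respecting session breaks."""
    R = np.atleast_2d(np.asarray(resid, dtype=float))
    if np.asarray(resid).ndim == 1:
        R = R.T
    if R.shape[0] < 10:
        raise ValueError("need at least 10 time points to estimate AR(1)")
    if row_sessions is None:
        row_sessions = np.zeros(R.shape[0], dtype=int)
    num = 0.0
    den = 0.0
    for s in np.unique(row_sessions):
        Rs = R[row_sessions == s]
        num += float(np.sum(Rs[1:] * Rs[:-1]))
        den += float(np.sum(Rs**2))
    rho = num / den if den > 0 else 0.0
    if abs(rho) >= 1.0:
        warnings.warn(f"AR(1) estimate {rho:.3f} outside (-1, 1); clipping to +/-0.95")
        rho = float(np.clip(rho, -0.95, 0.95))
    return float(rho)


def ar1_whitening_matrix(n: int, rho: float) -> np.ndarray:
    """Exact whitening transform for stationary AR(1) noise of length n."""
    W = np.eye(n)
    if n > 0:
        W[0, 0] = np.sqrt(1.0 - rho**2)
        for t in range(1, n):
            W[t, t - 1] = -rho
    return W


def ar1_fit_whiten(resid: np.ndarray, row_sessions: np.ndarray | None = None):
    """Estimate pooled AR(1) rho and return (rho, whitening matrix).

    For multi-session residuals the returned matrix is block-diagonal with
    one whitening block per session.
    """
    rho = estimate_ar1(resid, row_sessions)
    R = np.atleast_2d(np.asarray(resid, dtype=float))
    n = R.shape[0] if np.asarray(resid).ndim > 1 else len(np.asarray(resid))
    if row_sessions is None:
        return rho, ar1_whitening_matrix(n, rho)
    blocks = [
        ar1_whitening_matrix(int(np.sum(row_sessions == s)), rho)
        for s in np.unique(row_sessions)
    ]
    return rho, scipy.linalg.block_diag(*blocks)


@dataclass
class BetaSeries:
    """Per-trial activity patterns for each modeled phase.

    `patterns[phase]` is a (trials x voxels) matrix aligned row-wise with
    `meta` (session, trial_index, label, threat).  `voxel_coords` maps
    columns back into the 3D grid.
    """

    patterns: dict[str, np.ndarray]
    meta: pd.DataFrame
    voxel_coords: np.ndarray  # (V, 3) int
    grid_shape: tuple[int, int, int]
    ar1_rho: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.meta)

    @property
    def n_voxels(self) -> int:
        return self.voxel_coords.shape[0]

    def with_labels(self, labels: Sequence[str]) -> "BetaSeries":
        """Shallow copy with replaced perception labels (patterns shared)."""
        meta = self.meta.copy()
        meta["label"] = list(labels)
        return BetaSeries(
            patterns=self.patterns,
            meta=meta,
            voxel_coords=self.voxel_coords,
            grid_shape=self.grid_shape,
            ar1_rho=self.ar1_rho,
            extras=self.extras,
        )


def _collinear_column_names(X: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d[0] * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int(np.sum(d > tol))
    return [names[j] for j in sorted(piv[rank:])]


def fit_glm(
    volumes: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    highpass_s: float | None = 128.0,
    whiten: bool = True,
) -> BetaSeries:
    """Fit the trial-wise GLM and extract per-phase beta series.

    `volumes` is either a 4D (x, y, z, time) array or an already-flattened
    (time x voxels) matrix.  High-pass filtering and AR(1) whitening are
    applied identically to data and design, per session; session-constant
    columns are dropped when filtering is on (they lie in the drift span).
    """
    if volumes.ndim == 4:
        grid_shape = volumes.shape[:3]
        if mask is None:
            mask = np.ones(grid_shape, dtype=bool)
        coords = np.argwhere(mask)
        Y = volumes[mask].T.astype(float)  # time x voxels
    elif volumes.ndim == 2:
        Y = np.asarray(volumes, dtype=float)
        grid_shape = (Y.shape[1], 1, 1)
        coords = np.column_stack(
            [np.arange(Y.shape[1]), np.zeros(Y.shape[1], int), np.zeros(Y.shape[1], int)]
        )
    else:
        raise ValueError("volumes must be 4D (x,y,z,t) or 2D (t,voxels)")

    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"time dimension mismatch: data has {Y.shape[0]} volumes, design {X.shape[0]}"
        )

    keep = np.ones(X.shape[1], dtype=bool)
    if highpass_s is not None:
        keep = design.kinds != "constant"
    Xf = X[:, keep].astype(float).copy()
    names = [design.names[j] for j in np.flatnonzero(keep)]
    kinds = design.kinds[keep]
    Yf = Y.copy()

    if highpass_s is not None:
        for s in np.unique(design.row_sessions):
            rows = design.row_sessions == s
            Yf[rows] = highpass_dct(Yf[rows], design.TR, highpass_s)
            Xf[rows] = highpass_dct(Xf[rows], design.TR, highpass_s)

    d = np.abs(np.diag(scipy.linalg.qr(Xf, mode="economic", pivoting=True)[1]))
    tol = d[0] * max(Xf.shape) * np.finfo(float).eps if d.size else 0.0
    if d.size and np.sum(d > tol) < Xf.shape[1]:
        bad = _collinear_column_names(Xf, names)
        raise np.linalg.LinAlgError(
            f"design is rank-deficient after filtering; collinear columns: {bad}"
        )

    beta, *_ = np.linalg.lstsq(Xf, Yf, rcond=None)
    rho = None
    if whiten:
        resid = Yf - Xf @ beta
        rho, W = ar1_fit_whiten(resid, design.row_sessions)
        if abs(rho) > 1e-12:
            Yw = W @ Yf
            Xw = W @ Xf
            beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)

    ant_cols = [i for i, k in enumerate(kinds) if k == "trial_anticipation"]
    stim_cols = [i for i, k in enumerate(kinds) if k == "trial_stimulation"]
    patterns = {
        "anticipation": beta[ant_cols, :],
        "stimulation": beta[stim_cols, :],
    }
    return BetaSeries(
        patterns=patterns,
        meta=design.trial_meta.copy(),
        voxel_coords=coords,
        grid_shape=tuple(grid_shape),
        ar1_rho=rho,
    )


def smooth_gaussian(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 3.0
) -> np.ndarray:
    """Separable Gaussian smoothing over the first three (spatial) axes."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.array(volume, dtype=float, copy=True)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    vol = np.asarray(volume, dtype=float)
    sigmas = [sigma_vox] * 3 + [0.0] * (vol.ndim - 3)
    return ndimage.gaussian_filter(vol, sigma=sigmas)
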