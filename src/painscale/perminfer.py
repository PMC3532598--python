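"""Permutation inference for accuracies and classifier weight maps.

Labels are shuffled within scanning sessions, which preserves the
exchangeability structure that leave-one-session-out cross-validation
relies on (serial autocorrelation makes trials exchangeable only within a
session).  Accuracy p-values are the fraction of null accuracies at or above
the observed one, floored at 1/N.  Weight-map inference summarizes each
voxel's permutation null as a Gaussian (mean mu_v, sd sigma_v over N refits)
and refers t_v = (w_v - mu_v) / sigma_v to Student's t on N-1 degrees of
freedom; a Kolmogorov-Smirnov-type audit checks the Gaussian summary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .decoding import DecodingConfig, GroupResult, decode_subject, group_accuracy
from .glm import BetaSeries
from .synthdata import Atlas

__all__ = [
    "PermutationScheme",
    "WeightNull",
    "WeightTMap",
    "permute_within_sessions",
    "subject_accuracy_null",
    "group_accuracy_null",
    "accuracy_null",
    "perm_pvalue",
    "required_N",
    "weight_null",
    "weight_tscores",
    "normality_fraction",
    "fwe_threshold",
    "paired_accuracy_comparison",
]


@dataclass(frozen=True)
class PermutationScheme:
    N: int = 1000
    unit: str = "within_session"
    seed: int = 0
    level: str = "group"  # 'subject' or 'group'

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.unit != "within_session":
            raise ValueError("only within-session permutation is supported")
        if self.level not in ("subject", "group"):
            raise ValueError("level must be 'subject' or 'group'")


def permute_within_sessions(
    labels: Sequence,
    sessions: Sequence[int],
    rng: np.random.Generator,
    strata: Sequence | None = None,
) -> np.ndarray:
    """Shuffle labels independently within each session (counts preserved).

    When `strata` is given (the threat condition), shuffling happens within
    each session x stratum cell instead: the condition-split decoding
    analyses each see only one stratum's trials, so within those analyses
    trials are exchangeable only within a session and stratum.  Per-cell
    label counts are preserved either way.
    """
    labels = np.asarray(labels)
    sessions = np.asarray(sessions)
    if labels.shape != sessions.shape:
        raise ValueError("labels and sessions must be aligned")
    if strata is None:
        units = sessions
    else:
        strata = np.asarray(strata)
        if strata.shape != sessions.shape:
            raise ValueError("strata and sessions must be aligned")
        # encode (session, stratum) pairs as single unit ids
        _, units = np.unique(
            np.stack([sessions.astype(str), strata.astype(str)]), axis=1, return_inverse=True
        )
    out = labels.copy()
    for s in np.unique(units):
        idx = np.flatnonzero(units == s)
        out[idx] = labels[idx[rng.permutation(idx.size)]]
    return out


def subject_accuracy_null(
    beta: BetaSeries,
    config: DecodingConfig,
    N: int,
    seed: int = 0,
    atlas: Atlas | None = None,
) -> np.ndarray:
    """N permuted mean accuracies for one subject (full pipeline per draw)."""
    rng = np.random.default_rng(seed)
    sessions = beta.meta["session"].to_numpy()
    labels = beta.meta["label"].to_numpy()
    threat = beta.meta["threat"].to_numpy()
    out = np.empty(N)
    for i in range(N):
        perm = permute_within_sessions(labels, sessions, rng, strata=threat)
        acc, _ = decode_subject(beta, config, atlas=atlas, labels=perm)
        out[i] = acc.mean_accuracy
    return out


def group_accuracy_null(
    betas: Sequence[BetaSeries],
    config: DecodingConfig,
    N: int,
    seed: int = 0,
    atlas: Atlas | None = None,
) -> np.ndarray:
    """N permuted group-mean accuracies; each subject permuted independently."""
    rng = np.random.default_rng(seed)
    metas = [
        (
            b.meta["label"].to_numpy(),
            b.meta["session"].to_numpy(),
            b.meta["threat"].to_numpy(),
        )
        for b in betas
    ]
    out = np.empty(N)
    for i in range(N):
        accs = []
        for b, (labels, sessions, threat) in zip(betas, metas):
            perm = permute_within_sessions(labels, sessions, rng, strata=threat)
            acc, _ = decode_subject(b, config, atlas=atlas, labels=perm)
            accs.append(acc.mean_accuracy)
        out[i] = float(np.mean(accs))
    return out


def accuracy_null(
    betas: BetaSeries | Sequence[BetaSeries],
    config: DecodingConfig,
    scheme: PermutationScheme,
    atlas: Atlas | None = None,
) -> np.ndarray:
    """Dispatch to the subject- or group-level permutation null."""
    if scheme.level == "subject":
        if isinstance(betas, (list, tuple)):
            raise ValueError("subject-level scheme expects a single BetaSeries")
        return subject_accuracy_null(betas, config, scheme.N, scheme.seed, atlas)
    if not isinstance(betas, (list, tuple)):
        raise ValueError("group-level scheme expects a list of BetaSeries")
    return group_accuracy_null(list(betas), config, scheme.N, scheme.seed, atlas)


def perm_pvalue(observed: float, null: Sequence[float]) -> float:
    """p = (#null >= observed) / N, floored at 1/N; ties count against us."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    count = int(np.sum(null >= observed))
    return max(count, 1) / null.size


def required_N(alpha: float, n_tests: int = 1) -> int:
    """Smallest permutation count N with 1/N <= alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return int(np.ceil(n_tests / alpha))


@dataclass
class WeightNull:
    """Per-voxel Gaussian summary of the weight permutation null."""

    mean: np.ndarray
    sd: np.ndarray  # sample sd over permutations (ddof=1)
    N: int
    flagged: np.ndarray  # sd == 0: t undefined there
    draws: np.ndarray | None = None  # (N, V), kept only on request


def _within_session_arrangements(labels: np.ndarray, sessions: np.ndarray):
    """All distinct label arrangements obtainable by within-session shuffles."""
    per_session = []
    sess_order = []
    for s in np.unique(sessions):
        idx = np.flatnonzero(sessions == s)
        sess_order.append(idx)
        uniq = sorted(set(map(tuple, (p for p in itertools.permutations(labels[idx])))))
        per_session.append(uniq)
    for combo in itertools.product(*per_session):
        out = np.empty(len(labels), dtype=labels.dtype)
        for idx, arr in zip(sess_order, combo):
            out[idx] = arr
        yield out


def weight_null(
    train_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    features: np.ndarray,
    labels: Sequence,
    sessions: Sequence[int],
    N: int = 2000,
    seed: int = 0,
    keep_draws: bool = False,
    exhaustive: bool = False,
) -> WeightNull:
    """Null distribution of classifier weights under within-session shuffles.

    `train_fn(X, y) -> weight vector` is refit on each permuted label vector;
    the per-voxel mean and sd (ddof=1) summarize the null.  With
    `exhaustive`, every distinct within-session arrangement is used exactly
    once instead of N random draws (feasible only for small designs).
    Unless the draws are needed (normality audit), the summary is
    accumulated streaming to bound memory.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    sessions = np.asarray(sessions)

    if exhaustive:
        draws = np.array([train_fn(X, perm) for perm in _within_session_arrangements(labels, sessions)])
        N_eff = draws.shape[0]
    elif keep_draws:
        rng = np.random.default_rng(seed)
        draws = np.array(
            [train_fn(X, permute_within_sessions(labels, sessions, rng)) for _ in range(N)]
        )
        N_eff = N
    else:
        rng = np.random.default_rng(seed)
        s1 = None
        s2 = None
        for _ in range(N):
            w = train_fn(X, permute_within_sessions(labels, sessions, rng))
            if s1 is None:
                s1 = np.zeros_like(w)
                s2 = np.zeros_like(w)
            s1 += w
            s2 += w**2
        mean = s1 / N
        var = (s2 - N * mean**2) / (N - 1) if N > 1 else np.zeros_like(mean)
        sd = np.sqrt(np.maximum(var, 0.0))
        flagged = sd == 0
        return WeightNull(mean=mean, sd=sd, N=N, flagged=flagged, draws=None)

    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1) if N_eff > 1 else np.zeros_like(mean)
    flagged = sd == 0
    return WeightNull(mean=mean, sd=sd, N=N_eff, flagged=flagged, draws=draws)


@dataclass
class WeightTMap:
    """Observed weights scored against their permutation nulls."""

    weights: np.ndarray
    t: np.ndarray  # NaN at flagged voxels
    p: np.ndarray  # two-sided, Student t on N-1 df; NaN at flagged voxels
    df: int
    flagged: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def weight_tscores(weights: np.ndarray, null: WeightNull) -> WeightTMap:
    """t_v = (w_v - mu_v) / sigma_v, referred to t on N-1 df (two-sided)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != null.mean.shape:
        raise ValueError("weight vector does not match null dimensions")
    df = null.N - 1
    t = np.full_like(w, np.nan)
    ok = ~null.flagged
    t[ok] = (w[ok] - null.mean[ok]) / null.sd[ok]
    p = np.full_like(w, np.nan)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    return WeightTMap(weights=w, t=t, p=p, df=df, flagged=null.flagged.copy())


def normality_fraction(draws: np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of voxel nulls rejected by a KS-type test of Gaussianity.

    Each voxel's permutation draws are tested against a Gaussian with that
    voxel's estimated mean and sd; because the parameters are estimated from
    the same draws, the Lilliefors null distribution of the KS statistic is
    used so the test attains its nominal size `alpha`.  Degenerate
    (zero-variance) nulls count as rejected.
    """
    D = np.asarray(draws, dtype=float)
    if D.ndim != 2:
        raise ValueError("draws must be (N permutations, V voxels)")
    rejected = 0
    for v in range(D.shape[1]):
        x = D[:, v]
        if np.std(x) == 0:
            rejected += 1
            continue
        _, p = lilliefors(x, dist="norm", pvalmethod="table")
        if p <= alpha:
            rejected += 1
    return rejected / D.shape[1]


def _rft_t_threshold(df: int, alpha: float, resels: float) -> float:
    """Expected-Euler-characteristic threshold for a 3D t-field."""

    def expected_ec(t: float) -> float:
        # 3D EC density for a t field (unit-variance, resel counts)
        u2 = 1.0 + t**2 / df
        rho3 = (
            (4 * np.log(2.0)) ** 1.5
            / (2 * np.pi) ** 2
            * u2 ** (-(df - 1) / 2.0)
            * ((df - 1) / df * t**2 - 1.0)
        )
        return resels * rho3 + stats.t.sf(t, df)  # + EC0 term for bounded search region

    from scipy.optimize import brentq

    lo, hi = 1.0, 100.0
    target = alpha / 2.0  # two-sided: alpha split over signs
    while expected_ec(hi) > target:  # pragma: no cover
        hi *= 2
    return float(brentq(lambda t: expected_ec(t) - target, lo, hi))


def _estimate_resels(resid_maps: np.ndarray) -> float:
    """Resel count from residual-map gradients (isotropic smoothness)."""
    R = np.asarray(resid_maps, dtype=float)  # (n_maps, x, y, z)
    R = R / (R.std(axis=0, keepdims=True) + 1e-12)
    var_grad = []
    for ax in (1, 2, 3):
        g = np.diff(R, axis=ax)
        var_grad.append(np.mean(g**2))
    # FWHM per axis from gradient variance of unit-variance field
    fwhm = [np.sqrt(4 * np.log(2.0) / max(v, 1e-12)) for v in var_grad]
    n_vox = np.prod(R.shape[1:])
    return float(n_vox / np.prod(fwhm))


def fwe_threshold(
    tmap: WeightTMap,
    alpha: float = 0.05,
    method: str = "bonferroni",
    grid_shape: tuple[int, int, int] | None = None,
    resid_maps: np.ndarray | None = None,
):
    """Family-wise-error threshold and signed significance masks.

    Bonferroni (default) tests each voxel at alpha/V on the two-sided
    t_{N-1} p-value; the random-field-theory option derives the threshold
    from the expected Euler characteristic of a smooth t-field, with
    smoothness estimated from residual maps.  Returns
    (t threshold, positive mask, negative mask); positive-significant voxels
    are those with higher activity on subjectively painful trials.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    ok = ~tmap.flagged
    V = int(ok.sum())
    if V == 0:
        raise ValueError("no scorable voxels")
    if method == "bonferroni":
        t_crit = float(stats.t.isf(alpha / V / 2.0, tmap.df))
    elif method == "rft":
        if grid_shape is None or len(grid_shape) != 3:
            raise ValueError("rft correction needs a 3D grid_shape")
        if resid_maps is None:
            raise ValueError("rft correction needs residual maps for smoothness estimation")
        resels = _estimate_resels(resid_maps)
        t_crit = _rft_t_threshold(tmap.df, alpha, resels)
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    sig = ok & (np.abs(tmap.t) >= t_crit)
    pos = sig & (tmap.t > 0)
    neg = sig & (tmap.t < 0)
    return t_crit, pos, neg


def paired_accuracy_comparison(
    accuracies_a: Sequence[float],
    accuracies_b: Sequence[float],
    N: int = 1000,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> float:
    """Two-sided sign-flip permutation test on per-subject differences.

    The statistic is the mean paired difference; the null flips each
    subject's difference sign at random (exhaustively over all 2^n flips
    when n is small or `exhaustive` is requested).  Counting uses the same
    >=-ties-against-the-observation rule as `perm_pvalue`.
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison needs the same subjects in both lists")
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 subjects")
    d = a - b
    obs = abs(d.mean())
    if exhaustive is None:
        exhaustive = n <= 12
    if exhaustive:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        null = np.abs(flips @ d) / n
        count = int(np.sum(null >= obs - 1e-15))
        return max(count, 1) / len(null)
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(N, n))
    null = np.abs(signs @ d) / n
    count = int(np.sum(null >= obs - 1e-15))
    return max(count, 1) / N


def attach_group_pvalue(
    result: GroupResult,
    betas: Sequence[BetaSeries],
    config: DecodingConfig,
    scheme: PermutationScheme,
    atlas: Atlas | None = None,
) -> GroupResult:
    """Fill a GroupResult's permutation p-value from a fresh group null."""
    null = group_accuracy_null(list(betas), config, scheme.N, scheme.seed, atlas)
    result.null_accuracies = null
    result.p_value = perm_pvalue(result.mean_accuracy, null)
    return result
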