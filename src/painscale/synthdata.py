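"""Synthetic multi-subject BOLD datasets for near-threshold pain decoding.

The generator emulates the statistical structure the decoding analysis
assumes: S sessions of n trials per subject (default 4 x 30), anticipation
periods of 4-8 s followed by a 1 s stimulus, a crossed two-level threat
factor balanced within sessions, near-threshold perception labels that vary
trial-to-trial, and a weak distributed class signal confined to a subset of
atlas regions.  Noise is stationary AR(1) per voxel with low-frequency
drift; between-subject effect-size variability induces the random-effects
structure the group permutation test assumes.  Everything is a deterministic
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .glm import build_trialwise_design

__all__ = [
    "TrialEvent",
    "Atlas",
    "SignalSpec",
    "SyntheticDataset",
    "generate_events",
    "generate_atlas",
    "make_signal_spec",
    "simulate_subject",
    "generate_group",
    "session_n_volumes",
    "PAIN_REGION_NAMES",
    "CONTROL_REGION_NAMES",
]

# Default region naming mirrors the standard pain-processing nomenclature
# (somatosensory, insular, cingulate, prefrontal, thalamic, midbrain and
# amygdala masks, left/right), plus auditory-cortex controls.
PAIN_REGION_NAMES = [
    "SI.L", "SI.R", "SII.L", "SII.R",
    "AI.L", "AI.R", "MI.L", "MI.R", "PI.L", "PI.R",
    "dACC.L", "dACC.R", "rACC.L", "rACC.R",
    "DLPFC.L", "DLPFC.R", "VLPFC.L", "VLPFC.R",
    "OFC.L", "OFC.R", "THA.L", "THA.R",
    "AMYG.L", "AMYG.R", "PAG.L", "PAG.R",
]
CONTROL_REGION_NAMES = ["HG.L", "HG.R"]


@dataclass(frozen=True)
class TrialEvent:
    """A single trial: anticipation cue followed by a brief stimulus.

    Onsets are in seconds relative to the start of the trial's session.
    """

    session_index: int
    trial_index: int
    anticipation_onset: float
    anticipation_duration: float
    stimulation_onset: float
    stimulation_duration: float = 1.0
    label: str = "no_pain"  # perceived: 'pain' or 'no_pain'
    threat: str = "low"  # 'high' or 'low'

    def __post_init__(self):
        if not (4.0 - 1e-9 <= self.anticipation_duration <= 8.0 + 1e-9):
            raise ValueError("anticipation_duration must lie in [4, 8] s")
        if abs(self.stimulation_onset - (self.anticipation_onset + self.anticipation_duration)) > 1e-9:
            raise ValueError("stimulation must start at anticipation offset")
        if self.label not in ("pain", "no_pain"):
            raise ValueError("label must be 'pain' or 'no_pain'")
        if self.threat not in ("high", "low"):
            raise ValueError("threat must be 'high' or 'low'")


@dataclass
class Atlas:
    """Integer-labeled region atlas on a 3D grid (0 = background)."""

    labels: np.ndarray
    region_names: list[str]
    control_regions: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels)) - {0}
        if present != set(range(1, len(self.region_names) + 1)):
            raise ValueError("labels must cover 1..n_regions exactly; every region needs >= 1 voxel")
        unknown = set(self.control_regions) - set(self.region_names)
        if unknown:
            raise ValueError(f"control regions not in atlas: {sorted(unknown)}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def region_label(self, name: str) -> int:
        return self.region_names.index(name) + 1

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.region_label(name)

    def union_mask(self, names: Sequence[str]) -> np.ndarray:
        if len(names) == 0:
            raise ValueError("empty region union")
        ids = [self.region_label(n) for n in names]
        return np.isin(self.labels, ids)

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def noncontrol_regions(self) -> list[str]:
        return [n for n in self.region_names if n not in self.control_regions]

    def voxel_counts(self) -> dict[str, int]:
        return {n: int(np.sum(self.labels == i + 1)) for i, n in enumerate(self.region_names)}


@dataclass
class SignalSpec:
    """Ground truth for the planted class signal and the noise model.

    `informative_voxel_mask` marks voxels whose stimulus-response amplitude
    differs between perceived-pain and no-pain trials (difference
    `effect_size`, drawn per subject from a normal truncated at zero).
    `phase` says which trial phase carries the difference. Amplitude units
    are arbitrary; the decoding pipeline is scale-invariant after
    standardization and l2 scaling.
    """

    informative_voxel_mask: np.ndarray
    effect_size_mean: float = 0.5
    effect_size_sd_between_subjects: float = 0.25
    phase: str = "both"  # 'anticipation' | 'stimulation' | 'both'
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    base_amplitude: float = 1.0

    def __post_init__(self):
        self.informative_voxel_mask = np.asarray(self.informative_voxel_mask, dtype=bool)
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (-1 < self.ar1_rho < 1):
            raise ValueError("ar1_rho must lie in (-1, 1)")
        if self.phase not in ("anticipation", "stimulation", "both"):
            raise ValueError("phase must be anticipation/stimulation/both")


@dataclass
class SyntheticDataset:
    """One subject's simulated 4D scan plus everything needed to analyze it."""

    volumes: np.ndarray  # (x, y, z, time) across concatenated sessions
    TR: float
    events: list[TrialEvent]
    atlas: Atlas
    truth: SignalSpec
    subject_id: int
    seed: int
    session_n_volumes: dict[int, int]
    effect_size: float = 0.0  # realized per-subject effect

    @property
    def n_sessions(self) -> int:
        return len(self.session_n_volumes)


def generate_events(
    S: int,
    n: int,
    label_balance: float = 0.5,
    rng_seed: int | np.random.Generator = 0,
    *,
    initial_rest_s: float = 10.0,
    iti_range_s: tuple[float, float] = (6.0, 10.0),
    ensure_both_labels: bool = True,
) -> list[TrialEvent]:
    """Draw the trial schedule and labels for one subject.

    Anticipation durations are uniform on [4, 8] s, stimuli last 1 s, and
    inter-trial rests are uniform on `iti_range_s`.  Threat assignment is
    balanced within each session (n//2 high); perception labels are
    Bernoulli(label_balance).  With `ensure_both_labels` (default), a
    session's labels are redrawn until every threat stratum contains both
    classes, so leave-one-session-out decoding is defined; the constraint is
    label-exchangeable within sessions and leaves chance accuracy at 0.5.
    """
    if S < 2:
        raise ValueError("need >= 2 sessions for leave-one-session-out analysis")
    if n < 2:
        raise ValueError("need >= 2 trials per session")
    if not (0.0 < label_balance < 1.0) and label_balance not in (0.0, 1.0):
        raise ValueError("label_balance must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    events: list[TrialEvent] = []
    degenerate = label_balance in (0.0, 1.0)
    for s in range(1, S + 1):
        threat = np.array(["high"] * (n // 2) + ["low"] * (n - n // 2))
        rng.shuffle(threat)
        for _attempt in range(1000):
            labels = np.where(rng.random(n) < label_balance, "pain", "no_pain")
            if degenerate or not ensure_both_labels:
                break
            ok = all(
                len(set(labels[threat == t])) == 2
                for t in ("high", "low")
                if np.sum(threat == t) >= 2
            )
            if ok:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw labels with both classes per stratum")

        cursor = initial_rest_s
        for i in range(n):
            dur = rng.uniform(4.0, 8.0)
            ev = TrialEvent(
                session_index=s,
                trial_index=i,
                anticipation_onset=cursor,
                anticipation_duration=dur,
                stimulation_onset=cursor + dur,
                stimulation_duration=1.0,
                label=str(labels[i]),
                threat=str(threat[i]),
            )
            events.append(ev)
            cursor = ev.stimulation_onset + ev.stimulation_duration + rng.uniform(*iti_range_s)
    return events


def session_n_volumes(
    events: Sequence[TrialEvent], TR: float = 3.0, tail_s: float = 16.0
) -> dict[int, int]:
    """Volumes per session: events padded by `tail_s` for the HRF to resolve,
    rounded up to whole volumes."""
    out: dict[int, int] = {}
    for e in events:
        end = e.stimulation_onset + e.stimulation_duration + tail_s
        s = e.session_index
        out[s] = max(out.get(s, 0), int(np.ceil(end / TR)))
    return dict(sorted(out.items()))


def generate_atlas(
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    n_regions: int = 26,
    n_control: int = 2,
    rng_seed: int | np.random.Generator = 0,
) -> Atlas:
    """Pack disjoint rectangular region blocks into the grid.

    The grid is divided into a lattice of cells; each region occupies a
    random sub-block of its own cell, guaranteeing disjointness.  Region
    geometry is deliberately simple -- it is irrelevant to the statistics
    under test.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    total = n_regions + n_control
    if total < 1:
        raise ValueError("need at least one region")

    # choose cells-per-axis so the lattice holds all regions
    grid_shape = tuple(int(g) for g in grid_shape)
    cells_per_axis = int(np.ceil(total ** (1.0 / 3.0)))
    while np.prod([min(c, g) for c, g in zip([cells_per_axis] * 3, grid_shape)]) < total:
        cells_per_axis += 1
        if cells_per_axis > max(grid_shape):
            raise ValueError(f"cannot pack {total} regions into grid {grid_shape}")
    cell_sizes = [g // min(cells_per_axis, g) for g in grid_shape]
    if any(c < 1 for c in cell_sizes):
        raise ValueError(f"cannot pack {total} regions into grid {grid_shape}")
    n_cells_axis = [g // c for g, c in zip(grid_shape, cell_sizes)]
    if int(np.prod(n_cells_axis)) < total:
        raise ValueError(f"cannot pack {total} regions into grid {grid_shape}")

    cell_ids = np.array(
        [(i, j, k) for i in range(n_cells_axis[0]) for j in range(n_cells_axis[1]) for k in range(n_cells_axis[2])]
    )
    chosen = cell_ids[rng.choice(len(cell_ids), size=total, replace=False)]

    labels = np.zeros(grid_shape, dtype=int)
    for r, cell in enumerate(chosen, start=1):
        lo = [int(c * sz) for c, sz in zip(cell, cell_sizes)]
        ext = [int(rng.integers(1, max(sz, 2))) for sz in cell_sizes]
        off = [int(rng.integers(0, sz - e + 1)) for sz, e in zip(cell_sizes, ext)]
        sl = tuple(slice(l + o, l + o + e) for l, o, e in zip(lo, off, ext))
        labels[sl] = r

    if n_regions == 26 and n_control == 2:
        names = PAIN_REGION_NAMES + CONTROL_REGION_NAMES
        controls = list(CONTROL_REGION_NAMES)
    else:
        names = [f"R{i:02d}" for i in range(1, n_regions + 1)] + [
            f"CTRL{i:02d}" for i in range(1, n_control + 1)
        ]
        controls = names[n_regions:]
    return Atlas(labels=labels, region_names=names, control_regions=controls)


def make_signal_spec(
    atlas: Atlas,
    informative_regions: Sequence[str] | None = None,
    n_informative_regions: int = 5,
    rng_seed: int | np.random.Generator = 0,
    **kwargs,
) -> SignalSpec:
    """Signal confined to a subset of non-control regions (default: 5 drawn
    at random), the weak-distributed-signal regime of near-threshold pain."""
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if informative_regions is None:
        pool = atlas.noncontrol_regions
        idx = rng.choice(len(pool), size=min(n_informative_regions, len(pool)), replace=False)
        informative_regions = [pool[i] for i in sorted(idx)]
    bad = set(informative_regions) & set(atlas.control_regions)
    if bad:
        raise ValueError(f"control regions cannot carry signal: {sorted(bad)}")
    mask = atlas.union_mask(list(informative_regions))
    spec = SignalSpec(informative_voxel_mask=mask, **kwargs)
    return spec


def _draw_effect_size(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return float(max(mean, 0.0))
    a = (0.0 - mean) / sd  # truncate at zero
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def simulate_subject(
    events: Sequence[TrialEvent],
    atlas: Atlas,
    signal: SignalSpec,
    TR: float = 3.0,
    rng_seed: int = 0,
    subject_id: int = 0,
    effect_size: float | None = None,
) -> SyntheticDataset:
    """Simulate one subject's 4D scan.

    Each voxel's time course is the sum of HRF-convolved trial responses,
    session-wise low-frequency drift, and stationary AR(1) noise.  In-brain
    voxels respond to every trial with `base_amplitude`; informative voxels
    additionally gain +effect/2 on perceived-pain and -effect/2 on no-pain
    trials in the phase(s) named by the signal spec.  Control regions and
    background carry no label effect by construction.
    """
    rng = np.random.default_rng(rng_seed)
    if not np.all(atlas.brain_mask()[signal.informative_voxel_mask]):
        raise ValueError("informative voxels must lie inside atlas regions")
    control_mask = (
        atlas.union_mask(atlas.control_regions) if atlas.control_regions else np.zeros(atlas.grid_shape, bool)
    )
    if np.any(signal.informative_voxel_mask & control_mask):
        raise ValueError("informative voxels must avoid control regions")

    events = list(events)
    sess_nvol = session_n_volumes(events, TR)
    design = build_trialwise_design(events, sess_nvol, TR)
    n_trials = len(events)
    T = design.matrix.shape[0]

    if effect_size is None:
        effect_size = _draw_effect_size(
            signal.effect_size_mean, signal.effect_size_sd_between_subjects, rng
        )

    brain = atlas.brain_mask()
    grid = atlas.grid_shape
    n_vox = int(np.prod(grid))
    brain_flat = np.flatnonzero(brain.ravel())
    info_flat_local = np.flatnonzero(signal.informative_voxel_mask.ravel()[brain_flat])

    labels = np.array([1.0 if e.label == "pain" else -1.0 for e in events])
    # trial x brain-voxel amplitudes per phase
    amp = {ph: np.full((n_trials, brain_flat.size), signal.base_amplitude) for ph in ("anticipation", "stimulation")}
    phases = ("anticipation", "stimulation") if signal.phase == "both" else (signal.phase,)
    for ph in phases:
        amp[ph][:, info_flat_local] += np.outer(labels * effect_size / 2.0, np.ones(info_flat_local.size))

    Xa = design.matrix[:, design.columns_of_kind("trial_anticipation")]
    Xs = design.matrix[:, design.columns_of_kind("trial_stimulation")]
    signal_ts = Xa @ amp["anticipation"] + Xs @ amp["stimulation"]  # T x brain voxels

    data = np.zeros((T, n_vox))
    data[:, brain_flat] += signal_ts

    rho, sd = signal.ar1_rho, signal.noise_sd
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    row_sessions = design.row_sessions
    for s in np.unique(row_sessions):
        rows = np.flatnonzero(row_sessions == s)
        Ts = rows.size
        # AR(1) noise, stationary initialization
        z = rng.standard_normal((Ts, n_vox))
        e = np.empty_like(z)
        e[0] = sd * z[0]
        for t in range(1, Ts):
            e[t] = rho * e[t - 1] + innov_sd * z[t]
        # session-wise drift: linear trend + slow cosine, random per voxel
        tt = np.arange(Ts) * TR
        c_lin = rng.standard_normal(n_vox)
        c_cos = rng.standard_normal(n_vox)
        phase0 = rng.uniform(0, 2 * np.pi, n_vox)
        drift = signal.drift_amplitude * (
            np.outer(tt / max(tt[-1], 1.0), c_lin)
            + np.cos(np.outer(2 * np.pi * tt / 300.0, np.ones(n_vox)) + phase0) * c_cos
        )
        data[rows] += e + drift

    volumes = data.T.reshape(grid + (T,))
    return SyntheticDataset(
        volumes=volumes,
        TR=TR,
        events=events,
        atlas=atlas,
        truth=signal,
        subject_id=subject_id,
        seed=int(rng_seed) if np.isscalar(rng_seed) else -1,
        session_n_volumes=sess_nvol,
        effect_size=float(effect_size),
    )


def generate_group(
    n_subjects: int = 16,
    *,
    S: int = 4,
    trials_per_session: int = 30,
    label_balance: float = 0.5,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    n_regions: int = 26,
    n_control: int = 2,
    atlas: Atlas | None = None,
    signal: SignalSpec | None = None,
    TR: float = 3.0,
    master_seed: int = 0,
    **signal_kwargs,
) -> list[SyntheticDataset]:
    """Simulate a group sharing one atlas and one signal specification.

    Subjects get independent child seeds (events, noise, effect size) derived
    from `master_seed`; the per-subject effect size is drawn from the
    truncated-normal between-subject distribution in the signal spec.
    """
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects for group inference")
    rng = np.random.default_rng(master_seed)
    if atlas is None:
        atlas = generate_atlas(grid_shape, n_regions, n_control, rng_seed=rng)
    if signal is None:
        signal = make_signal_spec(atlas, rng_seed=rng, **signal_kwargs)

    datasets = []
    for subj in range(n_subjects):
        child_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(child_seed)
        events = generate_events(S, trials_per_session, label_balance, rng_seed=sub_rng)
        ds = simulate_subject(
            events, atlas, signal, TR=TR, rng_seed=child_seed + 1, subject_id=subj
        )
        ds.seed = child_seed
        datasets.append(ds)
    return datasets
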