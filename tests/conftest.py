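import numpy as np
import pandas as pd
import pytest

from painscale import Atlas, BetaSeries, generate_atlas


def make_beta(
    n_sessions: int = 2,
    per_session: int = 10,
    n_vox: int = 30,
    effect: float = 0.0,
    n_informative: int = 5,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> BetaSeries:
    """Directly construct a beta series (bypassing the GLM) for decoder tests.

    Labels and threat are balanced within every session x stratum cell so
    leave-one-session-out condition-split decoding is always defined.  The
    first `n_informative` voxels carry a mean shift of +/- effect/2 by label.
    """
    rng = np.random.default_rng(seed)
    sessions, labels, threats = [], [], []
    for s in range(1, n_sessions + 1):
        for threat in ("high", "low"):
            c = per_session // 2
            lab = ["pain"] * (c // 2) + ["no_pain"] * (c - c // 2)
            rng.shuffle(lab)
            labels += lab
            threats += [threat] * c
            sessions += [s] * c
    n = len(sessions)
    y_pm = np.where(np.array(labels) == "pain", 1.0, -1.0)
    X = rng.normal(scale=noise_sd, size=(n, n_vox))
    X[:, :n_informative] += (effect / 2.0) * y_pm[:, None]
    meta = pd.DataFrame(
        {
            "session": sessions,
            "trial_index": np.arange(n),
            "label": labels,
            "threat": threats,
        }
    )
    coords = np.column_stack([np.arange(n_vox), np.zeros(n_vox, int), np.zeros(n_vox, int)])
    return BetaSeries(
        patterns={"anticipation": X.copy(), "stimulation": X},
        meta=meta,
        voxel_coords=coords,
        grid_shape=(n_vox, 1, 1),
    )


@pytest.fixture(scope="session")
def tiny_atlas() -> Atlas:
    return generate_atlas((6, 6, 6), n_regions=4, n_control=1, rng_seed=11)


@pytest.fixture()
def beta_factory():
    return make_beta
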