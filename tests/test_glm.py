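import numpy as np
import pandas as pd
import pytest

from painscale import (
    ar1_fit_whiten,
    build_trialwise_design,
    fit_glm,
    generate_events,
    highpass_dct,
    hrf_kernel,
    smooth_gaussian,
)
from painscale.glm import DesignMatrix, estimate_ar1, _double_gamma
from painscale.synthdata import session_n_volumes


class TestHrf:
    def test_zero_at_origin(self):
        assert hrf_kernel(3.0)[0] == 0.0

    def test_sample_count_at_tr3(self):
        # 32 s support sampled every 3 s -> 0, 3, ..., 30
        assert len(hrf_kernel(3.0)) == 11

    def test_peak_near_five_seconds(self):
        t = np.arange(0.0, 32.0, 0.01)
        h = _double_gamma(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.2)
        assert h.max() > 0


def _random_design(rng, T, n_trials, n_conf=0):
    """A DesignMatrix with random columns, for solver-level tests."""
    n_cols = 2 * n_trials + n_conf
    kinds = np.array(
        ["trial_anticipation"] * n_trials
        + ["trial_stimulation"] * n_trials
        + ["confound"] * n_conf,
        dtype=object,
    )
    meta = pd.DataFrame(
        {
            "session": np.ones(n_trials, int),
            "trial_index": np.arange(n_trials),
            "label": ["pain"] * n_trials,
            "threat": ["high"] * n_trials,
        }
    )
    return DesignMatrix(
        matrix=rng.normal(size=(T, n_cols)),
        names=[f"c{i}" for i in range(n_cols)],
        kinds=kinds,
        TR=3.0,
        row_sessions=np.zeros(T, int),
        session_n_volumes={1: T},
        trial_meta=meta,
    )


class TestDesign:
    def test_column_count_matches_trials(self):
        events = generate_events(4, 30, rng_seed=0)
        design = build_trialwise_design(events, session_n_volumes(events), 3.0)
        assert int(np.sum(design.kinds == "trial_anticipation")) == 120
        assert int(np.sum(design.kinds == "trial_stimulation")) == 120
        assert int(np.sum(design.kinds == "constant")) == 4
        assert design.matrix.shape[1] == 244

    def test_no_trials_constant_only(self):
        design = build_trialwise_design([], {1: 20}, 3.0)
        assert design.matrix.shape == (20, 1)
        assert list(design.kinds) == ["constant"]

    def test_event_past_scan_end_rejected(self):
        events = generate_events(2, 3, rng_seed=0)
        with pytest.raises(ValueError, match="scan end"):
            build_trialwise_design(events, 5, 3.0)

    def test_single_trial_amplitude_recovered(self):
        from painscale import TrialEvent

        events = [
            TrialEvent(s, 0, 10.0, 5.0, 15.0, 1.0, "pain", "high") for s in (1, 2)
        ]
        nv = session_n_volumes(events)
        design = build_trialwise_design(events, nv, 3.0)
        ant0 = design.columns_of_kind("trial_anticipation")[0]
        stim0 = design.columns_of_kind("trial_stimulation")[0]
        y = 2.5 * design.matrix[:, ant0] - 1.25 * design.matrix[:, stim0]
        assert design.matrix.shape[1] == 6  # 2x2 trial regressors + 2 constants
        beta = fit_glm(y[:, None], design, highpass_s=None, whiten=False)
        assert beta.patterns["anticipation"][0, 0] == pytest.approx(2.5, abs=1e-10)
        assert beta.patterns["stimulation"][0, 0] == pytest.approx(-1.25, abs=1e-10)


class TestHighpass:
    def test_constant_series_zeroed(self):
        out = highpass_dct(np.full(100, 3.7), TR=3.0)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_slow_cosine_removed(self):
        t = np.arange(120) * 3.0
        slow = np.cos(2 * np.pi * t / 256.0)  # period beyond the cutoff
        out = highpass_dct(slow, TR=3.0, cutoff_s=128.0)
        assert np.var(out) < 0.01 * np.var(slow)

    def test_projection_contracts_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        out = highpass_dct(x, TR=3.0)
        assert np.var(out) <= np.var(x)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            highpass_dct(np.array([1.0]), TR=3.0)


class TestAr1:
    def _ar1(self, rho, n, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = z[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + z[t]
        return x

    def test_white_noise_near_zero(self):
        rho = estimate_ar1(self._ar1(0.0, 10_000, 1))
        assert abs(rho) < 0.05

    def test_recovers_simulated_rho(self):
        rho = estimate_ar1(self._ar1(0.3, 10_000, 2))
        assert rho == pytest.approx(0.3, abs=0.05)

    def test_zero_rho_whitening_is_identity(self):
        x = np.zeros(50)
        x[0] = 1.0  # rho estimate 0
        rho, W = ar1_fit_whiten(x)
        assert rho == 0.0
        np.testing.assert_allclose(W, np.eye(50))

    def test_whitening_decorrelates(self):
        x = self._ar1(0.5, 5000, 3)
        rho, W = ar1_fit_whiten(x)
        xw = W @ x
        assert abs(estimate_ar1(xw)) < 0.05


class TestFitGlm:
    def test_noiseless_recovery_with_filter_and_whitening(self):
        # identical projections on data and design keep recovery exact
        events = generate_events(2, 5, rng_seed=4)
        nv = session_n_volumes(events)
        design = build_trialwise_design(events, nv, 3.0)
        rng = np.random.default_rng(0)
        trial_cols = np.flatnonzero(design.kinds != "constant")
        b_true = rng.normal(size=trial_cols.size)
        y = design.matrix[:, trial_cols] @ b_true
        # add per-session mean + slow drift inside each session's DCT span
        drift = np.concatenate(
            [5.0 + 0.5 * np.cos(np.pi * (2 * np.arange(n) + 1) / (2 * n)) for n in nv.values()]
        )
        y = y + drift
        beta = fit_glm(y[:, None], design, highpass_s=128.0, whiten=True)
        got = np.concatenate(
            [beta.patterns["anticipation"][:, 0], beta.patterns["stimulation"][:, 0]]
        )
        np.testing.assert_allclose(got, b_true, atol=1e-7)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        design = _random_design(rng, T=40, n_trials=4)
        Y = rng.normal(size=(40, 3))
        beta = fit_glm(Y, design, highpass_s=None, whiten=False)
        X = design.matrix
        oracle = np.linalg.pinv(X.T @ X) @ X.T @ Y
        np.testing.assert_allclose(beta.patterns["anticipation"], oracle[:4], atol=1e-9)
        np.testing.assert_allclose(beta.patterns["stimulation"], oracle[4:8], atol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(6)
        design = _random_design(rng, T=30, n_trials=3)
        design.matrix[:, 1] = design.matrix[:, 0]  # duplicate a regressor
        with pytest.raises(np.linalg.LinAlgError, match="c1|c0"):
            fit_glm(rng.normal(size=(30, 2)), design, highpass_s=None, whiten=False)

    def test_beta_series_shape_for_full_subject(self):
        events = generate_events(2, 6, rng_seed=7)
        design = build_trialwise_design(events, session_n_volumes(events), 3.0)
        T = design.matrix.shape[0]
        rng = np.random.default_rng(8)
        beta = fit_glm(rng.normal(size=(T, 5)), design)
        assert beta.patterns["anticipation"].shape == (12, 5)
        assert beta.patterns["stimulation"].shape == (12, 5)
        assert list(beta.meta["session"]) == [e.session_index for e in events]


class TestSmoothing:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8, 8), 2.0)
        np.testing.assert_allclose(smooth_gaussian(img, 8.0), img)

    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(6, 6, 6))
        np.testing.assert_array_equal(smooth_gaussian(img, 0.0), img)

    def test_impulse_width_matches_fwhm(self):
        img = np.zeros((41, 41, 41))
        img[20, 20, 20] = 1.0
        out = smooth_gaussian(img, fwhm_mm=9.0, voxel_size_mm=3.0)
        profile = out[:, 20, 20]
        half = profile.max() / 2.0
        width = np.sum(profile >= half)  # voxels above half maximum
        assert width == pytest.approx(9.0 / 3.0, abs=1.0)

    def test_4d_smoothing_is_spatial_only(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(6, 6, 6, 4))
        out = smooth_gaussian(vol, 5.0)
        # each time point smoothed independently
        np.testing.assert_allclose(out[..., 2], smooth_gaussian(vol[..., 2], 5.0))


class TestUnbiasedness:
    def test_mean_beta_error_near_zero_under_noise(self):
        # repeated noisy refits: trial-regressor estimates are unbiased
        events = generate_events(2, 3, rng_seed=10)
        nv = session_n_volumes(events)
        design = build_trialwise_design(events, nv, 3.0)
        rng = np.random.default_rng(11)
        trial_cols = np.flatnonzero(design.kinds != "constant")
        b_true = rng.normal(size=trial_cols.size)
        signal = design.matrix[:, trial_cols] @ b_true
        errs = []
        for _ in range(100):
            y = signal + rng.normal(scale=1.0, size=signal.shape)
            beta = fit_glm(y[:, None], design)
            got = np.concatenate(
                [beta.patterns["anticipation"][:, 0], beta.patterns["stimulation"][:, 0]]
            )
            errs.append(got - b_true)
        mean_err = np.mean(errs, axis=0)
        se = np.std(errs, axis=0, ddof=1) / np.sqrt(len(errs))
        assert np.all(np.abs(mean_err) < 4 * se + 0.02)
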