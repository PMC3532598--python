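import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.svm import SVC

from painscale import (
    DecodingConfig,
    paired_accuracy_comparison,
    perm_pvalue,
    permute_within_sessions,
    required_N,
    subject_accuracy_null,
    weight_null,
    weight_tscores,
)
from painscale.perminfer import fwe_threshold, normality_fraction
from conftest import make_beta


class TestPermuteWithinSessions:
    def test_counts_preserved_per_session(self):
        rng = np.random.default_rng(0)
        labels = np.array(["pain", "pain", "no_pain", "no_pain", "pain", "no_pain"])
        sessions = np.array([1, 1, 1, 2, 2, 2])
        perm = permute_within_sessions(labels, sessions, rng)
        for s in (1, 2):
            assert sorted(perm[sessions == s]) == sorted(labels[sessions == s])

    def test_identical_labels_unchanged(self):
        rng = np.random.default_rng(1)
        labels = np.array(["pain"] * 4)
        perm = permute_within_sessions(labels, np.array([1, 1, 2, 2]), rng)
        np.testing.assert_array_equal(perm, labels)

    def test_stratified_shuffle_preserves_cell_counts(self):
        rng = np.random.default_rng(2)
        labels = np.array(["pain", "no_pain"] * 6)
        sessions = np.repeat([1, 2], 6)
        threat = np.tile(["high", "high", "high", "low", "low", "low"], 2)
        perm = permute_within_sessions(labels, sessions, rng, strata=threat)
        for s in (1, 2):
            for t in ("high", "low"):
                cell = (sessions == s) & (threat == t)
                assert sorted(perm[cell]) == sorted(labels[cell])

    def test_uniform_over_arrangements(self):
        # 2 sessions x 2 mixed trials: 4 equally likely outcomes
        rng = np.random.default_rng(3)
        labels = np.array(["pain", "no_pain", "pain", "no_pain"])
        sessions = np.array([1, 1, 2, 2])
        counts = {}
        n = 4000
        for _ in range(n):
            perm = tuple(permute_within_sessions(labels, sessions, rng))
            counts[perm] = counts.get(perm, 0) + 1
        assert len(counts) == 4
        chi2 = sum((c - n / 4) ** 2 / (n / 4) for c in counts.values())
        assert chi2 < stats.chi2.isf(0.001, df=3)


class TestPermPvalue:
    def test_observed_beats_all(self):
        null = np.linspace(0.3, 0.6, 1000)
        assert perm_pvalue(0.99, null) == 0.001

    def test_observed_below_all(self):
        assert perm_pvalue(0.1, np.array([0.4, 0.5, 0.6])) == 1.0

    def test_tie_counts_against_observation(self):
        assert perm_pvalue(0.55, np.array([0.4, 0.5, 0.6])) == pytest.approx(1 / 3)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_in_observed_and_matches_count(self, seed):
        rng = np.random.default_rng(seed)
        null = rng.random(rng.integers(1, 50))
        obs = np.sort(rng.random(5))
        ps = [perm_pvalue(o, null) for o in obs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        for o, p in zip(obs, ps):
            brute = sum(1 for v in null if v >= o)
            assert p == max(brute, 1) / len(null)


class TestRequiredN:
    def test_known_values(self):
        assert required_N(0.05, 1) == 20
        assert required_N(0.001, 1) == 1000
        assert required_N(0.05, 26) == 520


class TestWeightNull:
    @staticmethod
    def _train(X, y):
        y = np.asarray(y)
        if y.dtype != bool:
            y = y == "pain"
        return SVC(kernel="linear", C=1.0, tol=1e-6).fit(X, y).coef_[0]

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        labels = np.array(["pain", "pain", "no_pain", "no_pain", "pain", "no_pain"])
        sessions = np.array([1, 1, 1, 2, 2, 2])
        null = weight_null(self._train, X, labels, sessions, exhaustive=True)
        # oracle: brute-force product of per-session multiset permutations
        per_sess = []
        for s in (1, 2):
            idx = np.flatnonzero(sessions == s)
            per_sess.append(sorted(set(itertools.permutations(labels[idx]))))
        draws = []
        for a, b in itertools.product(*per_sess):
            lab = np.array(a + b)
            draws.append(self._train(X, lab))
        draws = np.array(draws)
        assert null.N == len(draws) == 9
        np.testing.assert_allclose(null.mean, draws.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(null.sd, draws.std(axis=0, ddof=1), atol=1e-12)

    def test_streaming_equals_retained_draws(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        labels = np.array(["pain", "no_pain"] * 4)
        sessions = np.repeat([1, 2], 4)
        a = weight_null(self._train, X, labels, sessions, N=20, seed=9)
        b = weight_null(self._train, X, labels, sessions, N=20, seed=9, keep_draws=True)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-10)
        np.testing.assert_allclose(a.sd, b.sd, atol=1e-10)
        assert a.draws is None and b.draws.shape == (20, 4)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 3))
        labels = np.array(["pain", "no_pain"] * 4)
        sessions = np.repeat([1, 2], 4)
        a = weight_null(self._train, X, labels, sessions, N=15, seed=3)
        b = weight_null(self._train, X, labels, sessions, N=15, seed=3)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_degenerate_null_flagged(self):
        X = np.ones((4, 2))
        labels = np.array(["pain"] * 4)  # only one arrangement
        null = weight_null(
            lambda Xm, lab: np.zeros(2), X, labels, np.array([1, 1, 2, 2]), N=5, seed=0
        )
        assert null.flagged.all()


class TestWeightTscores:
    def _null(self):
        from painscale import WeightNull

        return WeightNull(
            mean=np.array([0.0, 1.0, 2.0]),
            sd=np.array([1.0, 0.5, 2.0]),
            N=100,
            flagged=np.array([False, False, False]),
        )

    def test_weight_at_null_mean(self):
        tm = weight_tscores(np.array([0.0, 1.0, 2.0]), self._null())
        np.testing.assert_allclose(tm.t, 0.0)
        np.testing.assert_allclose(tm.p, 1.0)

    def test_two_sigma_weight(self):
        tm = weight_tscores(np.array([2.0, 1.0, 2.0]), self._null())
        assert tm.t[0] == pytest.approx(2.0)

    def test_pvalues_match_t_cdf_oracle(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=3)
        tm = weight_tscores(w, self._null())
        for tv, pv in zip(tm.t, tm.p):
            assert pv == pytest.approx(2 * (1 - stats.t.cdf(abs(tv), 99)), abs=1e-10)


class TestNormalityAudit:
    def test_gaussian_nulls_reject_at_test_size(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(size=(200, 300))
        frac = normality_fraction(draws, alpha=0.05)
        assert frac == pytest.approx(0.05, abs=0.035)

    def test_degenerate_draws_rejected(self):
        draws = np.ones((50, 3))
        assert normality_fraction(draws) == 1.0

    def test_heavy_tails_rejected_far_above_alpha(self):
        rng = np.random.default_rng(9)
        scale = np.where(rng.random((500, 100)) < 0.1, 6.0, 1.0)
        draws = rng.normal(size=(500, 100)) * scale
        assert normality_fraction(draws, alpha=0.05) > 0.5


class TestFwe:
    def _tmap(self, t, df=99):
        from painscale import WeightNull

        V = len(t)
        null = WeightNull(np.zeros(V), np.ones(V), df + 1, np.zeros(V, bool))
        return weight_tscores(np.asarray(t, float), null)

    def test_bonferroni_per_voxel_level(self):
        tm = self._tmap(np.zeros(10))
        t_crit, pos, neg = fwe_threshold(tm, alpha=0.05)
        assert t_crit == pytest.approx(stats.t.isf(0.005 / 2, 99))
        assert not pos.any() and not neg.any()

    def test_single_voxel_uncorrected(self):
        tm = self._tmap([3.0])
        t_crit, pos, _ = fwe_threshold(tm, alpha=0.05)
        assert t_crit == pytest.approx(stats.t.isf(0.025, 99))
        assert pos[0]

    def test_sign_split(self):
        tm = self._tmap([8.0, -8.0, 0.0])
        _, pos, neg = fwe_threshold(tm, alpha=0.05)
        assert pos.tolist() == [True, False, False]
        assert neg.tolist() == [False, True, False]

    def test_rft_requires_grid_and_residuals(self):
        tm = self._tmap(np.zeros(8))
        with pytest.raises(ValueError, match="grid"):
            fwe_threshold(tm, method="rft")

    def test_rft_threshold_above_uncorrected(self):
        rng = np.random.default_rng(10)
        tm = self._tmap(np.zeros(6 * 6 * 6))
        resid = rng.normal(size=(20, 6, 6, 6))
        t_crit, _, _ = fwe_threshold(
            tm, alpha=0.05, method="rft", grid_shape=(6, 6, 6), resid_maps=resid
        )
        assert t_crit > stats.t.isf(0.025, tm.df)


class TestPairedComparison:
    def test_identical_accuracies_give_p_one(self):
        a = np.array([0.5, 0.6, 0.7, 0.55])
        assert paired_accuracy_comparison(a, a) == 1.0

    def test_exhaustive_matches_manual_enumeration(self):
        a = np.array([0.62, 0.55, 0.71, 0.58])
        b = np.array([0.50, 0.52, 0.60, 0.54])
        d = a - b
        obs = abs(d.mean())
        null = [
            abs(np.dot(s, d)) / 4
            for s in itertools.product((1, -1), repeat=4)
        ]
        expected = max(sum(1 for v in null if v >= obs - 1e-15), 1) / 16
        assert paired_accuracy_comparison(a, b, exhaustive=True) == pytest.approx(expected)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(11)
        b = 0.5 + rng.normal(scale=0.01, size=16)
        a = b + 0.2
        assert paired_accuracy_comparison(a, b, N=1000, seed=0) <= 0.001

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            paired_accuracy_comparison([0.5, 0.6], [0.5, 0.6, 0.7])


class TestAccuracyNull:
    def test_subject_null_centered_near_chance(self):
        beta = make_beta(n_sessions=2, per_session=10, n_vox=10, effect=0.0, seed=12)
        cfg = DecodingConfig(C_grid=(1.0,))
        null = subject_accuracy_null(beta, cfg, N=40, seed=1)
        assert null.shape == (40,)
        assert abs(null.mean() - 0.5) < 0.08

    def test_fixed_seed_reproducible(self):
        beta = make_beta(n_sessions=2, per_session=8, n_vox=6, seed=13)
        cfg = DecodingConfig(C_grid=(1.0,))
        a = subject_accuracy_null(beta, cfg, N=5, seed=2)
        b = subject_accuracy_null(beta, cfg, N=5, seed=2)
        np.testing.assert_array_equal(a, b)
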