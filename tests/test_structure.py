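import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sedapop.errors import AnalysisError, ValidationError
from sedapop.io_core import AlleleFrequencyMatrix, SedimentSample
from sedapop.structure import (
    multilocus_fst,
    pca_allelic,
    per_locus_fst,
    permanova,
    windowed_fst,
)


def _bruteforce_fst(p1, p2):
    """Independent per-locus summation oracle for variance FST."""
    num = den = 0.0
    for a, b in zip(p1, p2):
        if np.isnan(a) or np.isnan(b):
            continue
        pbar = (a + b) / 2
        d = pbar * (1 - pbar)
        if d == 0:
            continue
        num += (a - b) ** 2 / 4
        den += d
    return num / den if den > 0 else None


class TestPerLocusFst:
    def test_identical_populations(self):
        num, den = per_locus_fst(0.3, 0.3)
        assert num == 0.0 and den > 0

    def test_fixed_difference_is_one(self):
        num, den = per_locus_fst(0.0, 1.0)
        assert num / den == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        num, den = per_locus_fst(0.2, 0.8)
        assert num == pytest.approx(0.09)
        assert den == pytest.approx(0.25)

    def test_monomorphic_skipped(self):
        assert per_locus_fst(0.0, 0.0) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            per_locus_fst(-0.1, 0.5)


class TestMultilocusFst:
    def test_identical_sites_zero(self):
        p = np.random.default_rng(0).random(50)
        assert multilocus_fst(p, p) == 0.0

    def test_ratio_of_sums(self):
        assert multilocus_fst([0.0, 0.5], [1.0, 0.5]) == pytest.approx(0.5)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p1 = rng.random(50)
            p2 = np.clip(p1 + rng.normal(0, 0.1, 50), 0, 1)
            assert multilocus_fst(p1, p2) == pytest.approx(
                _bruteforce_fst(p1, p2), abs=1e-12
            )

    def test_all_monomorphic_is_missing(self):
        assert multilocus_fst([0.0, 1.0], [0.0, 1.0]) is None

    @given(
        arrays(float, 20, elements=st.floats(0, 1)),
        arrays(float, 20, elements=st.floats(0, 1)),
    )
    @settings(derandomize=True, max_examples=100)
    def test_bounds_and_symmetry(self, p1, p2):
        f = multilocus_fst(p1, p2)
        if f is not None:
            assert 0.0 <= f <= 1.0
            assert f == pytest.approx(multilocus_fst(p2, p1), abs=1e-12)


def _meta(sid, site, age):
    return SedimentSample(
        sample_id=sid, site=site, depth_cm=1.0, age_calBP=age, toc=1.0,
        coverage={"chloroplast": 100.0, "mitochondrion": 20.0},
    )


def _afm(freq, sample_ids):
    loci = [("chloroplast", i + 1, "A", "C") for i in range(freq.shape[0])]
    return AlleleFrequencyMatrix(loci=loci, samples=sample_ids, freq=freq)


class TestWindowedFst:
    def test_identical_samples_give_zero(self):
        freq = np.tile(np.random.default_rng(2).random(30)[:, None], (1, 4))
        m = _afm(freq, ["A1", "A2", "B1", "B2"])
        samples = [_meta("A1", "EGB", 900), _meta("A2", "EGB", 400),
                   _meta("B1", "GOF", 800), _meta("B2", "GOF", 300)]
        windows = windowed_fst(m, samples, window_years=1000, step_years=500)
        assert any(w.fst is not None for w in windows)
        for w in windows:
            if w.fst is not None:
                assert w.fst == pytest.approx(0.0, abs=1e-15)

    def test_single_site_window_is_missing(self):
        freq = np.random.default_rng(3).random((10, 3))
        m = _afm(freq, ["A1", "A2", "B1"])
        samples = [_meta("A1", "EGB", 5000), _meta("A2", "EGB", 4800),
                   _meta("B1", "GOF", 100)]
        windows = windowed_fst(m, samples, window_years=500, step_years=500)
        # only EGB layers fall in the old windows: missing FST, counts (k, 0)
        old_windows = [w for w in windows if w.window_start_age >= 4500]
        assert all(w.fst is None for w in old_windows)
        assert sum(w.n_samples_per_site[0] for w in old_windows) == 2
        assert all(w.n_samples_per_site[1] == 0 for w in old_windows)

    def test_windows_run_oldest_to_youngest(self):
        freq = np.random.default_rng(4).random((10, 4))
        m = _afm(freq, ["A1", "A2", "B1", "B2"])
        samples = [_meta("A1", "EGB", 3000), _meta("A2", "EGB", 100),
                   _meta("B1", "GOF", 2500), _meta("B2", "GOF", 50)]
        windows = windowed_fst(m, samples, window_years=1000, step_years=250)
        mids = [w.mid_age for w in windows]
        assert mids == sorted(mids, reverse=True)
        assert windows[0].window_start_age == 3000

    def test_bad_window_width_rejected(self):
        with pytest.raises(ValidationError):
            windowed_fst(_afm(np.zeros((2, 2)), ["a", "b"]),
                         [_meta("a", "EGB", 1), _meta("b", "GOF", 0)],
                         window_years=0)


class TestPca:
    def test_rank_one_matrix(self):
        t = np.linspace(0, 1, 6)
        freq = np.outer(np.array([0.2, 0.4, 0.8]), t) + 0.1
        res = pca_allelic(_afm(freq, [f"S{i}" for i in range(6)]))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(5)
        freq = rng.random((8, 3))
        freq = np.column_stack([freq, freq[:, 0]])  # S3 duplicates S0
        res = pca_allelic(_afm(freq, ["S0", "S1", "S2", "S3"]))
        np.testing.assert_allclose(res.scores[0], res.scores[3], atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        """4x3 toy: scores agree with an independent eigendecomposition."""
        freq = np.array(
            [[0.1, 0.9, 0.5, 0.3],
             [0.8, 0.2, 0.4, 0.6],
             [0.3, 0.3, 0.9, 0.1]]
        )  # 3 loci x 4 samples
        res = pca_allelic(_afm(freq, list("ABCD")))
        X = freq.T - freq.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        oracle_scores = X @ evecs
        for k in range(3):
            got = res.scores[:, k]
            want = oracle_scores[:, k]
            if np.dot(got, want) < 0:
                want = -want
            np.testing.assert_allclose(got, want, atol=1e-10)
        np.testing.assert_allclose(
            res.explained_variance_ratio, np.maximum(evals, 0) / evals.sum(),
            atol=1e-10,
        )

    def test_matches_sklearn_pca(self):
        """Cross-check scores and variance ratios against scikit-learn."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(21)
        freq = rng.random((25, 7))
        res = pca_allelic(_afm(freq, [f"S{i}" for i in range(7)]))
        sk = PCA().fit(freq.T)
        sk_scores = sk.transform(freq.T)
        for k in range(sk_scores.shape[1] - 1):  # last component is null space
            want = sk_scores[:, k]
            if np.dot(res.scores[:, k], want) < 0:
                want = -want
            np.testing.assert_allclose(res.scores[:, k], want, atol=1e-10)
        np.testing.assert_allclose(
            res.explained_variance_ratio[: sk_scores.shape[1] - 1],
            sk.explained_variance_ratio_[:-1],
            atol=1e-10,
        )

    def test_ratios_sum_to_one_and_variance_preserved(self):
        rng = np.random.default_rng(6)
        freq = rng.random((40, 9))
        res = pca_allelic(_afm(freq, [f"S{i}" for i in range(9)]))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        X = freq.T - freq.T.mean(axis=0)
        assert np.sum(res.scores**2) == pytest.approx(np.sum(X**2), rel=1e-10)

    def test_missing_cells_imputed_with_locus_mean(self):
        rng = np.random.default_rng(7)
        freq = rng.random((10, 5))
        freq[3, 2] = np.nan
        res = pca_allelic(_afm(freq, [f"S{i}" for i in range(5)]))
        assert res.imputed_loci == [3]

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        freq = rng.random((20, 6))
        m = _afm(freq, [f"S{i}" for i in range(6)])
        a, b = pca_allelic(m), pca_allelic(m)
        np.testing.assert_array_equal(a.scores, b.scores)
        for k in range(a.loadings.shape[1]):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, k])), k] > 0


def _oracle_permanova_r2(coords, x):
    """Independent route: multivariate OLS explained-SS over total-SS."""
    X = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(X, coords, rcond=None)
    fitted = X @ beta
    centered = coords - coords.mean(axis=0)
    explained = fitted - coords.mean(axis=0)
    return np.sum(explained**2) / np.sum(centered**2)


class TestPermanova:
    def test_perfect_predictor_r2_one(self):
        rng = np.random.default_rng(9)
        pc1 = rng.normal(size=12)
        res = permanova(pc1[:, None], pc1, n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_toy_matches_trace_oracle(self):
        coords = np.array(
            [[0.0, 0.0], [1.0, 0.2], [2.0, -0.3], [3.0, 0.1], [4.0, 0.4], [5.0, -0.2]]
        )
        x = np.array([0.1, 0.9, 1.7, 3.2, 4.1, 4.8])
        res = permanova(coords, x, n_permutations=999, seed=1)
        # direct trace arithmetic on the Gower-centered matrix
        n = 6
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ d2 @ j
        X = np.column_stack([np.ones(n), x])
        h = X @ np.linalg.inv(X.T @ X) @ X.T
        ss_model = np.trace(h @ g @ h)
        assert res.r_squared == pytest.approx(ss_model / np.trace(g), abs=1e-12)
        # and against the independent multivariate-regression route
        assert res.r_squared == pytest.approx(
            _oracle_permanova_r2(coords, x), abs=1e-10
        )

    def test_p_reproducible_given_seed(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(15, 2))
        x = rng.normal(size=15)
        a = permanova(coords, x, n_permutations=199, seed=42)
        b = permanova(coords, x, n_permutations=199, seed=42)
        assert a.p_value == b.p_value

    def test_r2_invariant_under_affine_covariate_rescaling(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(15, 2))
        x = rng.normal(size=15)
        a = permanova(coords, x, n_permutations=99, seed=0)
        b = permanova(coords, 7.0 * x - 3.0, n_permutations=99, seed=0)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(AnalysisError):
            permanova(np.random.default_rng(0).normal(size=(8, 2)),
                      np.ones(8), n_permutations=99)


class TestEventClustering:
    def test_event_layers_separate_in_pc_space(self):
        """Layers inside a shift event sit apart from background layers."""
        from sedapop.simulate import (
            SimulationConfig, observed_frequency_matrix, simulate_trajectories,
        )

        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, n_loci=200, site_divergence_sd=0.0,
                event_windows=[(3000.0, 2200.0, 0.3, 0.4)], accel_factor=1.0,
            )
            latent, _ = simulate_trajectories(cfg)
            matrix, samples = observed_frequency_matrix(latent, cfg)
            res = pca_allelic(matrix)
            coords = res.scores[:, :2]
            age = np.array([
                next(s.age_calBP for s in samples if s.sample_id == sid)
                for sid in res.sample_ids
            ])
            in_event = (age >= 2200.0) & (age <= 3000.0)
            if in_event.sum() < 1 or (~in_event).sum() < 2:
                continue
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            between = d[np.ix_(in_event, ~in_event)].mean()
            within = d[np.ix_(~in_event, ~in_event)]
            within = within[np.triu_indices_from(within, 1)].mean()
            if between > within:
                hits += 1
        assert hits >= 18
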