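import numpy as np
import pytest

from sedapop.errors import AnalysisError
from sedapop.io_core import AlleleFrequencyMatrix, SedimentSample
from sedapop.turnover import (
    GamFit,
    TurnoverConfig,
    TurnoverInterval,
    era_contrast,
    fit_gam,
    turnover_series,
)


def _meta(sid, age, site="EGB"):
    return SedimentSample(
        sample_id=sid, site=site, depth_cm=1.0, age_calBP=age, toc=1.0,
        coverage={"chloroplast": 100.0, "mitochondrion": 20.0},
    )


def _afm(freq, sample_ids):
    freq = np.asarray(freq, dtype=float)
    loci = [("chloroplast", i + 1, "A", "C") for i in range(freq.shape[0])]
    return AlleleFrequencyMatrix(loci=loci, samples=sample_ids, freq=freq)


def _intervals(ages, values):
    out = []
    for j in range(len(ages) - 1):
        out.append(TurnoverInterval(
            age_older=ages[j], age_younger=ages[j + 1],
            mid_age=(ages[j] + ages[j + 1]) / 2, n_changes=0,
            n_loci_compared=1, generations=ages[j] - ages[j + 1],
            turnover=values[j],
        ))
    return out


class TestTurnoverSeries:
    def test_worked_example(self):
        """Two loci, |dp| = 0.02 and 0.005, dt = 100 y: one change, 0.01/gen."""
        m = _afm([[0.50, 0.52], [0.50, 0.505]], ["old", "young"])
        samples = [_meta("old", 100.0), _meta("young", 0.0)]
        cfg = TurnoverConfig(per_locus_normalized=False)
        (iv,) = turnover_series(m, samples, cfg)
        assert iv.n_changes == 1
        assert iv.generations == 100.0
        assert iv.turnover == pytest.approx(0.01)

    def test_threshold_is_strict(self):
        """A frequency change of exactly 1% is not counted."""
        m = _afm([[0.50, 0.51]], ["old", "young"])
        samples = [_meta("old", 100.0), _meta("young", 0.0)]
        (iv,) = turnover_series(m, samples, TurnoverConfig())
        assert iv.n_changes == 0
        assert iv.turnover == 0.0

    def test_identical_samples_zero(self):
        m = _afm([[0.3, 0.3], [0.7, 0.7]], ["old", "young"])
        samples = [_meta("old", 500.0), _meta("young", 0.0)]
        (iv,) = turnover_series(m, samples, TurnoverConfig())
        assert iv.turnover == 0.0

    def test_missing_loci_excluded_from_comparison(self):
        m = _afm([[0.5, np.nan], [0.1, 0.9]], ["old", "young"])
        samples = [_meta("old", 100.0), _meta("young", 0.0)]
        (iv,) = turnover_series(m, samples, TurnoverConfig())
        assert iv.n_loci_compared == 1
        assert iv.n_changes == 1

    def test_tied_ages_merged(self):
        m = _afm([[0.5, 0.6, 0.8]], ["a", "b", "young"])
        samples = [_meta("a", 100.0), _meta("b", 100.0, site="GOF"),
                   _meta("young", 0.0)]
        with pytest.warns(UserWarning, match="pseudo-sample"):
            (iv,) = turnover_series(m, samples, TurnoverConfig())
        assert iv.n_loci_compared == 1  # merged 0.55 vs 0.8
        assert iv.n_changes == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        freq = rng.random((50, 6))
        samples = [_meta(f"s{i}", 1000.0 - 200 * i) for i in range(6)]
        m = _afm(freq, [s.sample_id for s in samples])
        counts = []
        for thr in (0.005, 0.01, 0.05, 0.2, 0.5):
            ivs = turnover_series(m, samples, TurnoverConfig(change_threshold=thr))
            counts.append(sum(iv.n_changes for iv in ivs))
        assert counts == sorted(counts, reverse=True)

    def test_gens_per_year_scaling(self):
        """Doubling generations per year halves the turnover rate exactly."""
        rng = np.random.default_rng(1)
        freq = rng.random((30, 4))
        samples = [_meta(f"s{i}", 900.0 - 300 * i) for i in range(4)]
        m = _afm(freq, [s.sample_id for s in samples])
        t1 = turnover_series(m, samples, TurnoverConfig(gens_per_year=1.0))
        t2 = turnover_series(m, samples, TurnoverConfig(gens_per_year=2.0))
        for a, b in zip(t1, t2):
            assert b.turnover == pytest.approx(a.turnover / 2.0, rel=1e-12)

    def test_fewer_than_two_samples_rejected(self):
        m = _afm([[0.5]], ["only"])
        with pytest.raises(AnalysisError):
            turnover_series(m, [_meta("only", 0.0)], TurnoverConfig())


class TestGam:
    def test_infinite_lambda_is_ols_line(self):
        rng = np.random.default_rng(2)
        ages = np.linspace(5000, 0, 15)
        y = 0.002 + rng.normal(0, 5e-4, 15)
        ivs = _intervals(list(ages) + [-100.0], list(y))
        fit = fit_gam(ivs, basis_dim=8, lam=np.inf)
        x = np.array([iv.mid_age for iv in ivs])
        slope, intercept = np.polyfit(x, y, 1)
        expected = slope * fit.ages_grid + intercept
        np.testing.assert_allclose(fit.fitted, expected, atol=1e-6)
        assert fit.edf == pytest.approx(2.0)

    def test_noiseless_line_recovered_with_auto_lambda(self):
        ages = np.linspace(6000, 0, 20)
        ivs = _intervals(list(ages) + [-50.0], [0.0] * 20)
        for iv in ivs:
            iv.turnover = 1e-3 + 2e-7 * iv.mid_age  # exactly linear in age
        fit = fit_gam(ivs, basis_dim=10, lam="auto")
        expected = 1e-3 + 2e-7 * fit.ages_grid
        np.testing.assert_allclose(fit.fitted, expected, atol=1e-6)
        assert fit.edf <= 2.5

    def test_determinism_given_lambda(self):
        rng = np.random.default_rng(3)
        ivs = _intervals(list(np.linspace(4000, 0, 12)) + [-10.0],
                         list(rng.random(12) * 1e-3))
        a = fit_gam(ivs, basis_dim=8, lam=10.0)
        b = fit_gam(ivs, basis_dim=8, lam=10.0)
        np.testing.assert_array_equal(a.fitted, b.fitted)

    def test_oversized_basis_rejected(self):
        ivs = _intervals([300.0, 200.0, 100.0, 0.0, -50.0], [1, 2, 3, 4])
        with pytest.raises(AnalysisError, match="smaller basis"):
            fit_gam(ivs, basis_dim=12)

    def test_too_few_intervals_rejected(self):
        ivs = _intervals([200.0, 100.0, 0.0], [1, 2])
        with pytest.raises(AnalysisError):
            fit_gam(ivs)


class TestEraContrast:
    def test_flat_fit_ratio_one(self):
        fit = GamFit(
            ages_grid=np.linspace(4000, 0, 50), fitted=np.full(50, 3e-3),
            lam=1.0, edf=2.0, basis_dim=8, gcv=0.0,
            knots=np.arange(12.0), coefficients=np.zeros(8),
        )
        recent, ancient, ratio = era_contrast(fit, 1500.0)
        assert ratio == pytest.approx(1.0)
        assert recent == pytest.approx(ancient)

    def test_step_up_ratio_above_one(self):
        grid = np.linspace(4000, 0, 50)
        fitted = np.where(grid < 1500.0, 2e-3, 1e-3)
        fit = GamFit(grid, fitted, 1.0, 2.0, 8, 0.0, np.arange(12.0), np.zeros(8))
        _, _, ratio = era_contrast(fit, 1500.0)
        assert ratio == pytest.approx(2.0)

    def test_one_sided_grid_rejected(self):
        fit = GamFit(np.linspace(4000, 2000, 10), np.ones(10), 1.0, 2.0, 8, 0.0,
                     np.arange(12.0), np.zeros(8))
        with pytest.raises(AnalysisError):
            era_contrast(fit, 1500.0)

    def test_ratio_monotone_in_acceleration(self):
        """Stronger recent drift acceleration gives larger era ratios."""
        from sedapop.simulate import (
            SimulationConfig, observed_frequency_matrix, simulate_trajectories,
        )

        mean_ratio = {}
        for kappa in (1.0, 2.0, 5.0):
            ratios = []
            for seed in range(10):
                cfg = SimulationConfig(
                    seed=seed, n_loci=200, accel_factor=kappa,
                    site_divergence_sd=0.0, event_windows=[],
                )
                latent, _ = simulate_trajectories(cfg)
                matrix, samples = observed_frequency_matrix(latent, cfg)
                ivs = turnover_series(matrix, samples, TurnoverConfig())
                fit = fit_gam(ivs, basis_dim=8)
                ratios.append(era_contrast(fit, 1500.0)[2])
            mean_ratio[kappa] = np.mean(ratios)
        assert mean_ratio[1.0] < mean_ratio[2.0] < mean_ratio[5.0]
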