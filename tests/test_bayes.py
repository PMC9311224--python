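"""Posterior samplers and propagation to angles/norms."""

import numpy as np
import pytest
import statsmodels.api as sm

import aridclines as ac
from aridclines.bayes import PosteriorDraws, split_rhat


def _linear_data(seed=0, n=500, p=3, sigma=0.8):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    beta = np.linspace(1.0, -0.5, p)
    y = X @ beta + rng.standard_normal(n) * sigma
    return X, y


class TestConjugateLinearSampler:
    def test_posterior_means_match_ols(self):
        X, y = _linear_data()
        d = ac.sample_posterior_linear(y, X, n_draws=10_000, seed=1)
        ols = sm.OLS(y, X).fit()
        mc_se = d.draws[:, :3].std(axis=0) / np.sqrt(d.n_draws)
        err = np.abs(d.draws[:, :3].mean(axis=0) - ols.params)
        assert (err < 2.0 * mc_se + 1e-12).all()

    def test_same_seed_reproduces_draws(self):
        X, y = _linear_data()
        d1 = ac.sample_posterior_linear(y, X, n_draws=2000, seed=9)
        d2 = ac.sample_posterior_linear(y, X, n_draws=2000, seed=9)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_sampled_moments_match_closed_form(self):
        X, y = _linear_data(seed=3)
        est = ac.BayesianLinearRegression(n_draws=20_000, seed=4).fit(X, y)
        draws = est.sample()
        mean, cov = est.closed_form_moments()
        np.testing.assert_allclose(draws[:, :3].mean(axis=0), mean, atol=0.02)
        np.testing.assert_allclose(np.cov(draws[:, :3].T), cov,
                                   atol=0.1 * np.abs(cov).max())

    def test_posterior_sd_shrinks_with_root_n(self):
        sds = []
        for n in (100, 400, 1600):
            X, y = _linear_data(seed=5, n=n)
            d = ac.sample_posterior_linear(y, X, n_draws=5000, seed=6)
            sds.append(d.draws[:, 1].std())
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.15)
        assert sds[1] / sds[2] == pytest.approx(2.0, rel=0.15)

    def test_rank_deficiency_rejected(self):
        X, y = _linear_data()
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank deficient"):
            ac.sample_posterior_linear(y, X, n_draws=1000, seed=0)

    def test_invalid_prior_rejected(self):
        X, y = _linear_data()
        with pytest.raises(ValueError):
            ac.sample_posterior_linear(
                y, X, n_draws=1000, prior=ac.PriorSpec(ig_shape=-1.0), seed=0)


class TestMixedGibbs:
    def test_reduces_to_linear_sampler_without_random_variance(self):
        rng = np.random.default_rng(7)
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(n) * 0.5
        groups = rng.integers(0, 10, n)      # grouping with no true effect
        dm = ac.sample_posterior_mixed(y, X, {"g": groups}, n_draws=6000,
                                       burn_in=1000, seed=8, labels=["a", "b"])
        dl = ac.sample_posterior_linear(y, X, n_draws=6000, seed=9,
                                        labels=["a", "b"])
        for lab in ("a", "b"):
            se = max(dm.column(lab).std(), dl.column(lab).std()) / np.sqrt(6000)
            # Gibbs draws are autocorrelated; allow a small ESS haircut
            assert abs(dm.column(lab).mean() - dl.column(lab).mean()) < 6 * se

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(10)
        est_g, est_e = [], []
        for rep in range(5):
            groups = np.repeat(np.arange(50), 10)
            u = rng.standard_normal(50)
            y = 2.0 + u[groups] + rng.standard_normal(500) * 0.5
            d = ac.sample_posterior_mixed(
                y, np.ones((500, 1)), {"g": groups}, n_draws=2000,
                burn_in=500, seed=11 + rep, labels=["mu"])
            est_g.append(d.column("s2_g").mean())
            est_e.append(d.column("s2_resid").mean())
        assert np.median(est_g) == pytest.approx(1.0, rel=0.25)
        assert np.median(est_e) == pytest.approx(0.25, rel=0.25)

    def test_same_seed_reproduces_draws(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(60)
        g = np.tile(np.arange(6), 10)
        args = dict(n_draws=1500, burn_in=200, seed=13, labels=["mu"])
        d1 = ac.sample_posterior_mixed(y, np.ones((60, 1)), {"g": g}, **args)
        d2 = ac.sample_posterior_mixed(y, np.ones((60, 1)), {"g": g}, **args)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_single_level_grouping_rejected(self):
        with pytest.raises(ValueError, match=">= 2 levels"):
            ac.sample_posterior_mixed(np.zeros(10), np.ones((10, 1)),
                                      {"g": np.zeros(10)}, n_draws=1000, seed=0)


class TestPropagation:
    @staticmethod
    def _draws(matrix, labels, seed=0):
        return PosteriorDraws(labels, matrix, seed)

    def test_degenerate_draws_equal_point_estimate(self):
        pops = [f"P{i}" for i in range(6)]
        aridity = {p: float(i + 1) for i, p in enumerate(pops)}
        means = np.array([0.2 * aridity[p] + 1.0 for p in pops])
        draws = {"biomass": self._draws(np.tile(means, (2000, 1)), pops)}
        out = ac.propagate_cline_draws(draws, aridity)
        np.testing.assert_allclose(out.draws, 0.2, atol=1e-12)

    def test_known_generating_slope_recovered(self):
        rng = np.random.default_rng(14)
        pops = [f"P{i}" for i in range(8)]
        aridity = {p: a for p, a in zip(pops, np.linspace(0.5, 4.0, 8))}
        base = np.array([0.4 * aridity[p] for p in pops])
        draws = {"sla": self._draws(
            base + rng.standard_normal((10_000, 8)) * 0.05, pops)}
        out = ac.propagate_cline_draws(draws, aridity)
        mc_se = out.draws[:, 0].std() / 100.0
        assert out.draws[:, 0].mean() == pytest.approx(0.4, abs=2 * mc_se + 1e-4)

    def test_aridity_scaling_halves_slopes(self):
        rng = np.random.default_rng(15)
        pops = [f"P{i}" for i in range(5)]
        mat = rng.standard_normal((1500, 5))
        aridity1 = {p: float(i + 1) for i, p in enumerate(pops)}
        aridity2 = {p: 2.0 * v for p, v in aridity1.items()}
        d = {"biomass": self._draws(mat, pops)}
        s1 = ac.propagate_cline_draws(d, aridity1).draws
        s2 = ac.propagate_cline_draws(d, aridity2).draws
        np.testing.assert_allclose(s1, 2.0 * s2, atol=1e-12)

    def test_label_misalignment_rejected(self):
        d = {"biomass": self._draws(np.zeros((1000, 3)), ["P1", "P2", "PX"])}
        with pytest.raises(ValueError, match="PX"):
            ac.propagate_cline_draws(d, {"P1": 1.0, "P2": 2.0, "P3": 3.0})


class TestVectorComparison:
    def test_constant_orthogonal_draws(self):
        e1 = np.zeros((2000, 3)); e1[:, 0] = 1.0
        e2 = np.zeros((2000, 3)); e2[:, 1] = 1.0
        labels = ("a", "b", "c")
        comp = ac.compare_vectors_posterior(
            PosteriorDraws(labels, e1, 0), PosteriorDraws(labels, e2, 0))
        s = comp.angle_summary
        assert s.mean == pytest.approx(90.0, abs=1e-10)
        assert s.upper95 - s.lower95 == pytest.approx(0.0, abs=1e-10)
        assert comp.alignment_verdict == "orthogonal_indistinguishable"

    def test_identical_draw_matrices_align_exactly(self):
        rng = np.random.default_rng(16)
        m = rng.standard_normal((2000, 4)) + 1.0
        labels = tuple("abcd")
        comp = ac.compare_vectors_posterior(
            PosteriorDraws(labels, m, 0), PosteriorDraws(labels, m.copy(), 0))
        assert comp.angle_summary.mean == pytest.approx(0.0, abs=1e-9)
        assert comp.alignment_verdict == "less_than_orthogonal"

    def test_relabeling_consistently_preserves_angle(self):
        rng = np.random.default_rng(17)
        U = rng.standard_normal((3000, 5))
        V = rng.standard_normal((3000, 5)) + 0.5
        labels = tuple("abcde")
        perm = [3, 1, 4, 0, 2]
        c1 = ac.compare_vectors_posterior(
            PosteriorDraws(labels, U, 0), PosteriorDraws(labels, V, 0))
        plabels = tuple(labels[i] for i in perm)
        c2 = ac.compare_vectors_posterior(
            PosteriorDraws(plabels, U[:, perm], 0),
            PosteriorDraws(plabels, V[:, perm], 0))
        assert c1.angle_summary.mean == pytest.approx(c2.angle_summary.mean,
                                                      abs=1e-10)

    def test_zero_norm_draws_dropped_with_budget(self):
        U = np.ones((2000, 3))
        U[:5] = 0.0                       # 0.25% zero-norm draws: tolerated
        V = np.ones((2000, 3))
        labels = ("a", "b", "c")
        comp = ac.compare_vectors_posterior(
            PosteriorDraws(labels, U, 0), PosteriorDraws(labels, V, 0))
        assert comp.n_draws_dropped == 5
        U[:100] = 0.0                     # 5%: too many
        with pytest.raises(ValueError, match="zero norm"):
            ac.compare_vectors_posterior(
                PosteriorDraws(labels, U, 0), PosteriorDraws(labels, V, 0))

    def test_mismatched_labels_rejected(self):
        U = np.ones((1000, 2))
        with pytest.raises(ValueError, match="orderings differ"):
            ac.compare_vectors_posterior(
                PosteriorDraws(("a", "b"), U, 0), PosteriorDraws(("b", "a"), U, 0))


class TestScalarSummaries:
    def test_constant_draws(self):
        s = ac.summarize_scalar_draws(np.full(2000, 3.5))
        assert (s.mean, s.lower95, s.upper95) == (3.5, 3.5, 3.5)

    def test_standard_normal_quantiles(self):
        x = np.random.default_rng(18).standard_normal(10_000)
        s = ac.summarize_scalar_draws(x)
        assert s.lower95 == pytest.approx(-1.96, abs=0.07)
        assert s.upper95 == pytest.approx(1.96, abs=0.07)

    def test_uniform_mean(self):
        x = np.random.default_rng(19).random(10_000)
        assert ac.summarize_scalar_draws(x).mean == pytest.approx(0.5, abs=0.01)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match=">= 1000"):
            ac.summarize_scalar_draws(np.ones(10))

    def test_non_finite_rejected(self):
        x = np.ones(2000)
        x[5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ac.summarize_scalar_draws(x)


def test_split_rhat_flags_trending_chain():
    rng = np.random.default_rng(20)
    stationary = rng.standard_normal(4000)
    trending = np.linspace(0, 5, 4000) + rng.standard_normal(4000) * 0.1
    assert split_rhat(stationary) < 1.01
    assert split_rhat(trending) > 1.5
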