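"""Bayesian intensity model: oracle cross-checks, recovery, and posterior summaries."""

import numpy as np
import pytest

from armdyn import intensity, synthetic
from armdyn.io_maps import OUTSIDE, ArmdynError, count_shared
from armdyn.intensity import (IntensityModelSpec, IntensityPosterior,
                              connectivity_ratio, fit_intensity_model,
                              hot_probability)


def fit_scenario(scenario, **spec_kw):
    m1, m2, r1, r2, h = synthetic.gen_shared_markers(scenario)
    table = count_shared(m1, m2, r1, r2, h)
    return table, fit_intensity_model(table, IntensityModelSpec(**spec_kw))


def make_posterior(gamma):
    """Posterior object with given (chains, draws, n1, n2) gamma samples."""
    gamma = np.asarray(gamma, dtype=float)
    C, S, n1, n2 = gamma.shape
    return IntensityPosterior(
        region_ids1=[f"r{i}" for i in range(n1 - 1)] + [OUTSIDE],
        region_ids2=[f"s{j}" for j in range(n2 - 1)] + [OUTSIDE],
        lam1=np.ones((C, S, n1)), lam2=np.ones((C, S, n2)),
        gamma=gamma, mu_hot=np.ones((C, S)), mu_cold=-np.ones((C, S)))


def grid_posterior_mean_gamma(O, f1, f2, N, lo=0.02, hi=6.0, n_grid=100):
    """Numeric-integration oracle for the 2x2 product model (no random effects).

    Free parameters a = lam1_out, b = lam2_inv, c = lam2_out (lam1_inv
    anchored at 1); gamma = [[b, c], [a b, a c]]. The posterior over (a, b, c)
    — binomial likelihood times the Jeffreys term per cell — is integrated on
    a log-spaced grid, giving posterior means of all four gamma cells without
    any MCMC.
    """
    g = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
    a = g[:, None, None]; b = g[None, :, None]; c = g[None, None, :]
    F = np.outer(f1, f2)
    cells = [(0, 0, b), (0, 1, c), (1, 0, a * b), (1, 1, a * c)]
    logp = np.zeros((n_grid, n_grid, n_grid))
    valid = np.ones_like(logp, dtype=bool)
    for i, j, gam in cells:
        pi = F[i, j] * gam
        ok = (pi > 0) & (pi < 1)
        pi = np.where(ok, pi, 0.5)
        logp = logp + (O[i, j] - 0.5) * np.log(pi) + (N - O[i, j] - 0.5) * np.log1p(-pi)
        valid &= np.broadcast_to(ok, valid.shape)
    logp = logp + np.log(a) + np.log(b) + np.log(c)   # log-spaced grid measure
    w = np.where(valid, np.exp(logp - logp[valid].max()), 0.0)
    w /= w.sum()
    out = np.empty((2, 2))
    for i, j, gam in cells:
        out[i, j] = (w * gam).sum()
    return out


class TestProductModelOracle:
    def test_mcmc_matches_grid_integration(self):
        sc = synthetic.SharingScenario(n_homologs=150, seed=13,
                                       inversions1=[("A", 8, 22)],
                                       inversions2=[("B", 30, 46)])
        m1, m2, r1, r2, h = synthetic.gen_shared_markers(sc)
        table = count_shared(m1, m2, r1, r2, h)
        spec = IntensityModelSpec(p0=1.0, p_hot=0.0, p_cold=0.0,
                                  burnin=10_000, samples=15_000, chains=4, seed=5)
        post = fit_intensity_model(table, spec)
        oracle = grid_posterior_mean_gamma(table.O.astype(float), table.f1, table.f2,
                                           table.n_homologs)
        assert np.allclose(post.posterior_mean_gamma(), oracle, rtol=0.06)

    def test_reduces_to_exact_product_without_mixture(self):
        sc = synthetic.SharingScenario(n_homologs=200, seed=3,
                                       inversions1=[("A", 5, 20)],
                                       inversions2=[("B", 10, 30)])
        _, post = fit_scenario(sc, p0=1.0, p_hot=0.0, p_cold=0.0,
                               burnin=2000, samples=2000, chains=2, seed=1)
        product = post.lam1[..., :, None] * post.lam2[..., None, :]
        assert np.array_equal(post.gamma, product)

    def test_anchored_marginal_is_one_in_every_sample(self):
        sc = synthetic.SharingScenario(n_homologs=150, seed=8,
                                       inversions1=[("A", 5, 20)],
                                       inversions2=[("B", 10, 30)])
        _, post = fit_scenario(sc, burnin=2000, samples=2000, chains=2, seed=2)
        assert (post.lam1[..., 0] == 1.0).all()
        assert (post.lam1 > 0).all() and (post.lam2 > 0).all()

    def test_fixed_seed_bit_identical(self):
        sc = synthetic.SharingScenario(n_homologs=120, seed=4,
                                       inversions1=[("A", 5, 20)],
                                       inversions2=[("B", 10, 30)])
        _, a = fit_scenario(sc, burnin=1500, samples=1500, chains=2, seed=11)
        _, b = fit_scenario(sc, burnin=1500, samples=1500, chains=2, seed=11)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.mu_hot, b.mu_hot)


class TestRecovery:
    def test_null_posterior_means_near_one(self):
        """gamma* = 1: every posterior mean gamma stays in [0.7, 1.4]."""
        for seed in (11, 23, 37):
            sc = synthetic.SharingScenario(
                n_homologs=500, seed=seed,
                inversions1=[("A1", 5, 20), ("A2", 25, 40)],
                inversions2=[("B1", 10, 28), ("B2", 35, 50)])
            _, post = fit_scenario(sc, burnin=4000, samples=4000, chains=2, seed=seed)
            g = post.posterior_mean_gamma()
            assert (g > 0.7).all() and (g < 1.4).all()

    def test_null_hot_probabilities_calibrated_on_average(self):
        """Under the null Pr(gamma > 1) is centred: its replicate average is ~0.5.

        Any calibrated posterior spreads Pr(gamma > 1) roughly uniformly over
        replicates, so single cells can be extreme; the average over
        replicates and inversion pairs must not be.
        """
        probs = []
        for seed in range(8):
            sc = synthetic.SharingScenario(
                n_homologs=500, seed=100 + seed,
                inversions1=[("A1", 5, 20), ("A2", 25, 40)],
                inversions2=[("B1", 10, 28), ("B2", 35, 50)])
            _, post = fit_scenario(sc, burnin=3000, samples=3000, chains=2, seed=seed)
            for i in range(2):
                for j in range(2):
                    probs.append(hot_probability(post, i, j))
        assert 0.25 < np.mean(probs) < 0.75

    def test_planted_hotspot_recovered(self):
        sc = synthetic.SharingScenario(
            n_homologs=230, seed=21,
            inversions1=[("A1", 5, 15), ("A2", 25, 40)],
            inversions2=[("B1", 10, 22), ("B2", 35, 50)],
            gamma={("A1", "B1"): 6.0})
        _, post = fit_scenario(sc, burnin=8000, samples=8000, chains=4, seed=7)
        mean = float(post.gamma_samples("A1", "B1").mean())
        assert 4.0 <= mean <= 9.0
        assert hot_probability(post, "A1", "B1") > 0.95

    def test_planted_rank_order_recovered(self):
        """Posterior means of gamma rank identically to planted {0.2, 1, 3, 6}."""
        planted = {("A1", "B1"): 0.2, ("A1", "B2"): 1.0, ("A2", "B1"): 3.0, ("A2", "B2"): 6.0}
        for seed in (1, 2):
            sc = synthetic.SharingScenario(
                n_homologs=600, seed=seed,
                inversions1=[("A1", 5, 15), ("A2", 25, 38)],
                inversions2=[("B1", 10, 22), ("B2", 35, 48)],
                gamma=planted)
            _, post = fit_scenario(sc, burnin=5000, samples=5000, chains=2, seed=seed)
            means = {pair: float(post.gamma_samples(*pair).mean()) for pair in planted}
            order = sorted(planted, key=planted.get)
            assert order == sorted(means, key=means.get)


class TestSummaries:
    def test_hot_probability_degenerate_and_symmetric(self):
        post = make_posterior(np.full((1, 100, 2, 2), 2.0))
        assert hot_probability(post, 0, 0) == 1.0
        sym = make_posterior(1.0 + np.linspace(-0.5, 0.5, 200).reshape(1, 200, 1, 1)
                             * np.ones((1, 1, 2, 2)))
        assert hot_probability(sym, 0, 0) == pytest.approx(0.5, abs=0.01)

    def test_hot_probability_equals_sample_recount(self):
        rng = np.random.default_rng(0)
        post = make_posterior(rng.lognormal(0, 0.5, size=(2, 300, 2, 2)))
        samples = post.gamma_samples(0, 1)
        assert hot_probability(post, 0, 1) == (samples > 1).sum() / samples.size

    def test_unknown_pair_errors(self):
        post = make_posterior(np.ones((1, 10, 2, 2)))
        with pytest.raises(ArmdynError, match="unknown region pair"):
            hot_probability(post, "nope", 0)

    def test_connectivity_ratio_homogeneous_is_one(self):
        post = make_posterior(np.full((2, 50, 3, 3), 1.7))
        ratio = connectivity_ratio(post)
        assert ratio.mean == pytest.approx(1.0)
        assert ratio.ci_low == pytest.approx(1.0) and ratio.ci_high == pytest.approx(1.0)

    def test_connectivity_ratio_planted_inside_hotspots(self):
        """Inversion pairs planted at gamma* = 3: outside/inside ratio < 1."""
        sc = synthetic.SharingScenario(
            n_homologs=400, seed=6,
            inversions1=[("A1", 5, 20), ("A2", 25, 40)],
            inversions2=[("B1", 10, 28), ("B2", 35, 50)],
            gamma={(a, b): 3.0 for a in ("A1", "A2") for b in ("B1", "B2")})
        _, post = fit_scenario(sc, burnin=5000, samples=5000, chains=2, seed=3)
        ratio = connectivity_ratio(post)
        assert ratio.mean < 1.0
        assert ratio.ci_high < 1.0

    def test_requires_outside_region(self):
        post = make_posterior(np.ones((1, 10, 2, 2)))
        post.region_ids1 = ["a", "b"]
        with pytest.raises(ArmdynError, match="outside"):
            connectivity_ratio(post)


def test_spec_validation():
    with pytest.raises(ArmdynError, match="sum to 1"):
        IntensityModelSpec(p0=0.9, p_hot=0.0, p_cold=0.0)
    with pytest.raises(ArmdynError):
        IntensityModelSpec(burnin=0)
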