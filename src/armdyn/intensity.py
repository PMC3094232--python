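"""Bayesian sharing-intensity model for region pairs of one arm pair.

The observed count for region pair (i, j) is modelled as
``O_ij ~ Binomial(N, pi_ij)`` with ``pi_ij = f_i f_j gamma_ij`` and
``gamma_ij = lambda_i^(1) lambda_j^(2) + mu_ij``: a multiplicative product of
per-region marginal intensities plus a sparse random effect that captures
additionally hot (mu > 0) or cold (mu < 0) pairs. The random effect has a
three-component mixture prior — a point mass at zero (weight p0 = 0.99) and
positive/negative truncated normal components (weight 0.005 each) around the
hot and cold means mu_H > 0 and mu_C < 0 — so only large deviations from the
product model are declared hot or cold. The first species-1 region's marginal
is anchored at 1 for identifiability; marginals are interpreted only through
ratios. Inference is Metropolis-within-Gibbs over multiple dispersed chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .io_maps import OUTSIDE, ArmdynError, SharedCountTable

logger = logging.getLogger("armdyn")

_NEUTRAL, _HOT, _COLD = 0, 1, 2


@dataclass
class IntensityModelSpec:
    """Model constants, priors and MCMC settings.

    Mixture weights are fixed (p0 + pH + pC = 1); the random-effect spread
    sigma is a fixed constant; mu_H and mu_C have flat priors on bounded
    ranges (0, mu_bound] and [-mu_bound, 0) so their conditionals stay proper
    even when no pair occupies the hot or cold component. Defaults for the
    chain sizes are desk-scale; the study-scale run used 1,000,000 burn-in
    iterations and 100,000 retained samples.
    """

    p0: float = 0.99
    p_hot: float = 0.005
    p_cold: float = 0.005
    prior: str = "jeffreys"       # marginal reference prior on pi; or "flat"
    sigma: float = 1.0
    mu_bound: float = 50.0
    burnin: int = 20_000
    samples: int = 20_000
    thin: int = 1
    chains: int = 4
    seed: int = 0
    init_spread: float = 0.5      # log-scale dispersion of chain starts
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if abs(self.p0 + self.p_hot + self.p_cold - 1.0) > 1e-12:
            raise ArmdynError("mixture weights must sum to 1")
        if self.burnin <= 0 or self.samples <= 0 or self.chains < 1:
            raise ArmdynError("burn-in, samples and chains must be positive")
        if self.sigma <= 0:
            raise ArmdynError("sigma must be positive")
        if self.prior not in ("jeffreys", "flat"):
            raise ArmdynError(f"unknown prior {self.prior!r}")


@dataclass
class IntensityPosterior:
    """Retained post-burn-in samples, kept per chain for diagnostics."""

    region_ids1: list[str]
    region_ids2: list[str]
    lam1: np.ndarray      # (chains, draws, n1) marginal intensities, anchor at index 0
    lam2: np.ndarray      # (chains, draws, n2)
    gamma: np.ndarray     # (chains, draws, n1, n2)
    mu_hot: np.ndarray    # (chains, draws)
    mu_cold: np.ndarray   # (chains, draws)
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    spec: IntensityModelSpec | None = None

    @property
    def mu(self) -> np.ndarray:
        return self.gamma - self.lam1[..., :, None] * self.lam2[..., None, :]

    def _pair_index(self, i, j) -> tuple[int, int]:
        ii = self.region_ids1.index(i) if isinstance(i, str) else int(i)
        jj = self.region_ids2.index(j) if isinstance(j, str) else int(j)
        return ii, jj

    def gamma_samples(self, i, j) -> np.ndarray:
        """Pooled gamma_ij samples across chains."""
        try:
            ii, jj = self._pair_index(i, j)
        except ValueError as exc:
            raise ArmdynError(f"unknown region pair ({i!r}, {j!r})") from exc
        return self.gamma[:, :, ii, jj].reshape(-1)

    def posterior_mean_gamma(self) -> np.ndarray:
        return self.gamma.mean(axis=(0, 1))


def _cell_logp(gamma: np.ndarray, F: np.ndarray, O: np.ndarray, N: int,
               jeffreys: bool = True) -> np.ndarray:
    """Binomial log-likelihood + per-cell prior on pi; -inf where inadmissible.

    The reference prior is the binomial Jeffreys density pi^-1/2 (1-pi)^-1/2
    applied to pi = f_i f_j gamma (``jeffreys=False`` substitutes a flat prior
    on pi). Admissibility: gamma > 0 and pi in (0, 1); proposals outside are
    rejected so the binomial stays well-defined.
    """
    pi = F * gamma
    valid = (gamma > 0) & (pi > 0) & (pi < 1)
    safe = np.where(valid, pi, 0.5)
    half = 0.5 if jeffreys else 0.0
    lp = (O - half) * np.log(safe) + (N - O - half) * np.log1p(-safe)
    return np.where(valid, lp, -np.inf)


def _logpdf_trunc(mu: np.ndarray, mean: np.ndarray, sigma: float, positive: bool) -> np.ndarray:
    """Log density of a normal truncated to (0, inf) or (-inf, 0)."""
    z = np.asarray(mean) / sigma
    norm = ndtr(z) if positive else ndtr(-z)
    # out-of-range proposals are rejected by the caller; keep the log finite here
    return -0.5 * ((np.asarray(mu) - mean) / sigma) ** 2 - np.log(np.maximum(norm, 1e-300))


def _sample_trunc(rng, mean: np.ndarray, sigma: float, positive: bool) -> np.ndarray:
    """Inverse-CDF draw from a one-sided truncated normal (vectorized)."""
    u = rng.uniform(size=np.shape(mean))
    if positive:
        lo = ndtr(-np.asarray(mean) / sigma)       # P(X < 0)
        return mean + sigma * ndtri(lo + u * (1.0 - lo))
    hi = ndtr(-np.asarray(mean) / sigma)           # P(X < 0)
    return mean + sigma * ndtri(u * hi)


def fit_intensity_model(table: SharedCountTable, spec: IntensityModelSpec | None = None,
                        ) -> IntensityPosterior:
    """Fit the product-intensity + mixture-random-effect model by MCMC.

    Requires the outside region on both arms (it enters the model and the
    connectivity ratio even though the frequentist test scopes to inversion
    pairs). Region pairs with f_i f_j = 0 are excluded with a warning. Chains
    start from dispersed points; split-chain R-hat on the marginals flags
    non-convergence (the result is flagged, never suppressed). Fixed seed and
    chain count give bit-identical output.
    """
    spec = spec or IntensityModelSpec()
    if OUTSIDE not in table.region_ids1 or OUTSIDE not in table.region_ids2:
        raise ArmdynError("intensity model requires the outside region on both arms")
    if table.n_homologs <= 0:
        raise ArmdynError("N must be positive")

    keep1 = table.f1 > 0
    keep2 = table.f2 > 0
    if not keep1.all() or not keep2.all():
        logger.warning("excluding %d region(s) with zero length fraction",
                       int((~keep1).sum() + (~keep2).sum()))
    ids1 = [r for r, k in zip(table.region_ids1, keep1) if k]
    ids2 = [r for r, k in zip(table.region_ids2, keep2) if k]
    O = table.O[np.ix_(keep1, keep2)].astype(float)
    f1, f2 = table.f1[keep1], table.f2[keep2]
    F = np.outer(f1, f2)
    N = table.n_homologs
    n1, n2 = O.shape
    C = spec.chains
    use_mixture = spec.p_hot + spec.p_cold > 0

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(70,)))

    # dispersed initial states (admissible by shrinking toward 1)
    lam1 = np.exp(rng.normal(0.0, spec.init_spread, size=(C, n1)))
    lam1[:, 0] = 1.0
    lam2 = np.exp(rng.normal(0.0, spec.init_spread, size=(C, n2)))
    for _ in range(200):
        bad = (F[None] * (lam1[:, :, None] * lam2[:, None, :]) >= 1.0).any(axis=(1, 2))
        if not bad.any():
            break
        lam1[bad] = np.sqrt(lam1[bad]); lam2[bad] = np.sqrt(lam2[bad])
        lam1[:, 0] = 1.0
    mu = np.zeros((C, n1, n2))
    z = np.zeros((C, n1, n2), dtype=np.int8)
    mu_hot = 1.0 + rng.uniform(0, 2, size=C)
    mu_cold = -1.0 - rng.uniform(0, 2, size=C)

    jef = spec.prior == "jeffreys"
    gamma = lam1[:, :, None] * lam2[:, None, :] + mu
    cell = _cell_logp(gamma, F[None], O[None], N, jef)   # (C, n1, n2)

    # adaptive random-walk scales (adapted during burn-in only)
    sc1 = np.full(n1, 0.3); sc2 = np.full(n2, 0.3)
    sc_h = 0.5; sc_c = 0.5
    acc1 = np.zeros(n1); acc2 = np.zeros(n2); acc_h = 0.0; acc_c = 0.0
    mix_p = np.array([spec.p0, spec.p_hot, spec.p_cold])

    n_iter = spec.burnin + spec.samples * spec.thin
    S = spec.samples
    keep_lam1 = np.empty((C, S, n1)); keep_lam2 = np.empty((C, S, n2))
    keep_gamma = np.empty((C, S, n1, n2))
    keep_h = np.empty((C, S)); keep_c = np.empty((C, S))
    s_idx = 0

    for t in range(n_iter):
        # --- marginal intensities, species 1 (rows factorize given the rest)
        prop = lam1 * np.exp(rng.normal(0, 1, size=(C, n1)) * sc1)
        prop[:, 0] = 1.0
        g_new = prop[:, :, None] * lam2[:, None, :] + mu
        c_new = _cell_logp(g_new, F[None], O[None], N, jef)
        delta = c_new.sum(axis=2) - cell.sum(axis=2) + np.log(prop) - np.log(lam1)
        accept = np.log(rng.uniform(size=(C, n1))) < delta
        accept[:, 0] = False
        lam1 = np.where(accept, prop, lam1)
        upd = accept[:, :, None]
        gamma = np.where(upd, g_new, gamma); cell = np.where(upd, c_new, cell)
        acc1 += accept.mean(axis=0)

        # --- marginal intensities, species 2 (columns factorize)
        prop = lam2 * np.exp(rng.normal(0, 1, size=(C, n2)) * sc2)
        g_new = lam1[:, :, None] * prop[:, None, :] + mu
        c_new = _cell_logp(g_new, F[None], O[None], N, jef)
        delta = c_new.sum(axis=1) - cell.sum(axis=1) + np.log(prop) - np.log(lam2)
        accept = np.log(rng.uniform(size=(C, n2))) < delta
        lam2 = np.where(accept, prop, lam2)
        upd = accept[:, None, :]
        gamma = np.where(upd, g_new, gamma); cell = np.where(upd, c_new, cell)
        acc2 += accept.mean(axis=0)

        # --- random effects: Metropolized draw of (component, value) from the
        # conditional mixture prior; prior and proposal cancel, leaving the
        # likelihood (+ Jeffreys) ratio per cell. Cells are conditionally
        # independent given the marginals, so all update at once.
        if use_mixture:
            z_new = rng.choice(3, p=mix_p, size=(C, n1, n2)).astype(np.int8)
            mu_new = np.zeros_like(mu)
            hot_mask = z_new == _HOT
            cold_mask = z_new == _COLD
            if hot_mask.any():
                means = np.broadcast_to(mu_hot[:, None, None], mu.shape)[hot_mask]
                mu_new[hot_mask] = _sample_trunc(rng, means, spec.sigma, positive=True)
            if cold_mask.any():
                means = np.broadcast_to(mu_cold[:, None, None], mu.shape)[cold_mask]
                mu_new[cold_mask] = _sample_trunc(rng, means, spec.sigma, positive=False)
            g_new = lam1[:, :, None] * lam2[:, None, :] + mu_new
            c_new = _cell_logp(g_new, F[None], O[None], N, jef)
            accept = np.log(rng.uniform(size=mu.shape)) < (c_new - cell)
            mu = np.where(accept, mu_new, mu)
            z = np.where(accept, z_new, z)
            gamma = np.where(accept, g_new, gamma)
            cell = np.where(accept, c_new, cell)

            # --- hot / cold component means (flat prior on bounded range)
            prop_h = mu_hot + rng.normal(0, sc_h, size=C)
            in_range = (prop_h > 0) & (prop_h <= spec.mu_bound)
            hot_cells = z == _HOT
            lp_new = np.where(hot_cells, _logpdf_trunc(mu, prop_h[:, None, None], spec.sigma, True), 0.0).sum(axis=(1, 2))
            lp_old = np.where(hot_cells, _logpdf_trunc(mu, mu_hot[:, None, None], spec.sigma, True), 0.0).sum(axis=(1, 2))
            accept = in_range & (np.log(rng.uniform(size=C)) < lp_new - lp_old)
            mu_hot = np.where(accept, prop_h, mu_hot)
            acc_h += accept.mean()

            prop_c = mu_cold + rng.normal(0, sc_c, size=C)
            in_range = (prop_c < 0) & (prop_c >= -spec.mu_bound)
            cold_cells = z == _COLD
            lp_new = np.where(cold_cells, _logpdf_trunc(mu, prop_c[:, None, None], spec.sigma, False), 0.0).sum(axis=(1, 2))
            lp_old = np.where(cold_cells, _logpdf_trunc(mu, mu_cold[:, None, None], spec.sigma, False), 0.0).sum(axis=(1, 2))
            accept = in_range & (np.log(rng.uniform(size=C)) < lp_new - lp_old)
            mu_cold = np.where(accept, prop_c, mu_cold)
            acc_c += accept.mean()

        # --- scale adaptation (burn-in only; frozen afterwards)
        if t < spec.burnin and (t + 1) % 100 == 0:
            rate1, rate2 = acc1 / 100, acc2 / 100
            sc1 *= np.where(rate1 > 0.35, 1.15, np.where(rate1 < 0.15, 1 / 1.15, 1.0))
            sc2 *= np.where(rate2 > 0.35, 1.15, np.where(rate2 < 0.15, 1 / 1.15, 1.0))
            if use_mixture:
                sc_h *= 1.15 if acc_h / 100 > 0.35 else (1 / 1.15 if acc_h / 100 < 0.15 else 1.0)
                sc_c *= 1.15 if acc_c / 100 > 0.35 else (1 / 1.15 if acc_c / 100 < 0.15 else 1.0)
            acc1[:] = 0; acc2[:] = 0; acc_h = 0.0; acc_c = 0.0

        if t >= spec.burnin and (t - spec.burnin) % spec.thin == 0:
            keep_lam1[:, s_idx] = lam1; keep_lam2[:, s_idx] = lam2
            keep_gamma[:, s_idx] = gamma
            keep_h[:, s_idx] = mu_hot; keep_c[:, s_idx] = mu_cold
            s_idx += 1

    rhat = {}
    diag = {"lam1": keep_lam1[:, :, 1:] if n1 > 1 else None,
            "lam2": keep_lam2, "gamma": keep_gamma}
    for name, arr in diag.items():
        if arr is None or arr.size == 0:
            continue
        flat = arr.reshape(C, S, -1)
        rhat[name] = float(np.nanmax([_split_rhat(flat[:, :, k]) for k in range(flat.shape[2])]))
    converged = all(v < spec.rhat_threshold for v in rhat.values() if np.isfinite(v))
    if not converged:
        logger.warning("intensity model chains may not have converged: rhat=%s", rhat)

    return IntensityPosterior(
        region_ids1=ids1, region_ids2=ids2,
        lam1=keep_lam1, lam2=keep_lam2, gamma=keep_gamma,
        mu_hot=keep_h, mu_cold=keep_c,
        rhat=rhat, converged=converged, spec=spec,
    )


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter."""
    C, S = x.shape
    half = S // 2
    if half < 2:
        return float("nan")
    chains = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def hot_probability(posterior: IntensityPosterior, i, j) -> float:
    """Pr(gamma_ij > 1 | data): fraction of retained samples above 1."""
    return float((posterior.gamma_samples(i, j) > 1.0).mean())


@dataclass
class ConnectivityRatio:
    mean: float
    ci_low: float
    ci_high: float
    samples: np.ndarray


def connectivity_ratio(posterior: IntensityPosterior) -> ConnectivityRatio:
    """Posterior of R_out / R_in: outside vs inside average sharing intensity.

    Per retained sample, R_out averages the intensities of the pairs touching
    an outside region — (sum_i gamma_{i,out} + sum_j gamma_{out,j} +
    gamma_{out,out}) / (N1 + N2 + 1) with i, j over inversions — and R_in
    averages the inversion-pair intensities. Ratios below 1 mean the outside
    regions share fewer homologs than the inversions, relative to chance.
    """
    if OUTSIDE not in posterior.region_ids1 or OUTSIDE not in posterior.region_ids2:
        raise ArmdynError("posterior lacks outside regions")
    o1 = posterior.region_ids1.index(OUTSIDE)
    o2 = posterior.region_ids2.index(OUTSIDE)
    inv1 = [k for k in range(len(posterior.region_ids1)) if k != o1]
    inv2 = [k for k in range(len(posterior.region_ids2)) if k != o2]
    if not inv1 or not inv2:
        raise ArmdynError("no inversion regions on one of the arms")
    g = posterior.gamma.reshape(-1, *posterior.gamma.shape[2:])   # (samples, n1, n2)
    r_out = (g[:, inv1, o2].sum(axis=1) + g[:, o1, inv2].sum(axis=1) + g[:, o1, o2]) \
        / (len(inv1) + len(inv2) + 1)
    r_in = g[:, inv1][:, :, inv2].sum(axis=(1, 2)) / (len(inv1) * len(inv2))
    ratio = r_out / r_in
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return ConnectivityRatio(float(ratio.mean()), float(lo), float(hi), ratio)
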