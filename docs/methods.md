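# Methods

This note records the models implemented in `armdyn`, the defaults and the
reasoning behind the choices that were genuinely open, in the spirit of a
statistical software methods appendix.

## Coordinates and data model

All coordinates are megabases, 0-based, half-open `[start, end)` per
chromosome arm. Cytological band coordinates must be converted to Mb by the
user before input. Overlapping inversions (common on 2R: 2Rb/2Rc/2Rd/2Ru-type
arrangements) are kept as distinct regions — no flattening — so a marker
inside two inversions counts in each, and region fractions need not sum
to one. Each arm carries a single aggregate *outside* region: the complement
of the union of its inversions, represented by its total length only (it is
generally not an interval). Markers are single-copy per species (one marker
per homolog group); markers with no homolog in the partner species carry no
sharing information and are dropped from pairwise tables. Marker orientation
is not stored; colinearity is assessed unsigned.

## Sharing test

With N shared homologs and fractional region lengths f_i, f_j, the null of
uniform, independent placement gives E_ij = N f_i f_j, and the statistic
T = Σ (O_ij − E_ij)²/E_ij over **inversion×inversion pairs only** (the
outside region enters only the Bayesian model; the reported tests concern
inversion pairs). Design choices:

- **Degrees of freedom.** T is asymptotically chi-squared; df is taken as
  the number of included inversion pairs — no parameters are estimated and
  overlap removes any sum constraint. Since this convention is not canonical,
  the CLI exposes `--df` to substitute another value. The simulated p-value
  needs no df.
- **Monte-Carlo null.** Each draw repositions every homolog pair uniformly
  and independently on its two arms, recounts the matrix, and recomputes T
  against the *original* E (E depends only on N and the region fractions,
  which repositioning leaves unchanged). p is the plain proportion of draws
  with T̃ ≥ T_obs; ties count as exceedances, and p = 0 is displayed as
  `< 1/n_draws`. Default 10,000 draws.
- Pairs with f = 0 are excluded (T would divide by zero) with a warning.
- No multiple-testing correction is applied across arm-pair tests.

## Bayesian sharing intensities

O_ij ~ Binomial(N, π_ij), π_ij = f_i f_j γ_ij, γ_ij = λ_i^(1) λ_j^(2) + μ_ij,
over all region pairs including the outside regions.

- **Product factorization.** The marginal structure λ_i^(1)·λ_j^(2) is the
  multiplicative model under which anchoring one marginal (the first
  species-1 region, fixed at 1) identifies the rest, and under which
  marginals are interpretable purely through ratios λ_i^(k)/λ_j^(k′).
- **Random effects.** μ_ij has a three-part mixture prior: point mass at 0
  with weight p0 = 0.99, and truncated normals N(μ_H, σ) on (0, ∞) and
  N(μ_C, σ) on (−∞, 0) with weight 0.005 each, so only large deviations from
  the product model are declared hot or cold. The mixture weights are fixed
  constants. μ_H and μ_C get flat priors; to keep their conditionals proper
  when no pair occupies a component, the flat priors are bounded to
  (0, 50] and [−50, 0) — 50 is far above any plausible intensity, so the
  bound is inert in practice. σ is a fixed constant (default 1); it sets the
  within-component spread of hot/cold effects and is exposed on the spec.
- **Reference prior.** Each cell contributes a binomial Jeffreys factor
  π^(−1/2)(1−π)^(−1/2) evaluated at π_ij, chosen for its frequency-coverage
  behavior; `prior="flat"` substitutes a flat prior on π for sensitivity
  checks.
- **Admissibility.** Proposals with γ_ij ≤ 0 or π_ij outside (0, 1) get
  log-posterior −∞ (rejected), keeping the binomial well-defined.
- **Sampler.** Metropolis-within-Gibbs, vectorized across chains:
  (1) log-scale random walks on the free species-1 marginals — rows of the
  count matrix are conditionally independent given the rest, so all rows
  update in parallel with per-row acceptance; (2) the same for species-2
  marginals by columns; (3) a Metropolized independence proposal per cell
  drawing (component, μ) from the conditional mixture prior, so the
  acceptance ratio reduces to the likelihood(+Jeffreys) ratio; (4) bounded
  random walks on μ_H and μ_C. Random-walk scales adapt toward a 0.15–0.35
  acceptance window during burn-in only and are frozen afterwards, so
  retained samples come from a fixed kernel.
- **Runs.** Default 4 chains from dispersed log-normal starts. Study-scale
  settings are 1,000,000 burn-in / 100,000 retained; the package defaults to
  20,000/20,000, which matches study-scale posterior summaries to well
  within Monte-Carlo error on the data sizes here (N ≈ 90–230, ≤ ~6 regions
  per arm) and keeps a fit in seconds. Split-chain R-hat is computed for the
  marginals and every γ cell; fits exceeding 1.05 are flagged
  `converged=False`, never suppressed.
- **Summaries.** Hotspot probability is the fraction of retained samples
  with γ_ij > 1. The connectivity ratio is, per sample, the unweighted mean
  intensity of pairs touching an outside region divided by the unweighted
  mean over inversion pairs — (Σ_i γ_i,out + Σ_j γ_out,j + γ_out,out)/(N1 +
  N2 + 1) over (Σ_ij γ_ij)/(N1·N2) — reported as posterior mean and central
  95% credible interval. Region-length weighting of these averages would be
  an alternative; unweighted means are used.

**Known limitation.** When many pairs deviate from the null at once, the
decomposition of γ into marginals versus random effects is only weakly
identified: chains can settle in different but γ-equivalent allocations, and
the marginal R-hat flags it. γ itself (and every reported summary, which is
a function of γ) is data-identified and stable across such modes. Treat the
flag as a caution for interpreting marginals, not γ summaries.

## Conserved blocks

Shared homologs are ordered by the first species' positions. Adjacent shared
markers join a block when they are consecutive among shared markers in both
species, their rank step in the partner is ±1 with a constant sign along the
run (forward/reversed orientation), and their physical gaps agree within a
relative tolerance: |g_A − g_B| ≤ rel_tol·max(g_A, g_B).

- **rel_tol = 0.5 default.** Cross-species physical distances never match
  exactly; a 50% relative band reflects the precision of physical mapping at
  ~1 Mb resolution. `rel_tol = inf` disables the distance criterion.
- Reversed runs count as conserved; two-marker blocks are allowed.
- **Three-species classification.** An adjacent pair is *fully conserved*
  when it lies inside a block of all three pairwise comparisons; maximal
  chains of such pairs (re-maximalized, ≥ 2 markers) are the fully conserved
  blocks. Each pairwise block then contributes its remainder — maximal
  sub-runs not covered by fully conserved adjacencies, ≥ 2 markers — as
  partially conserved blocks labelled with the surviving pair. A block
  nesting a shorter fully conserved run therefore yields the fully conserved
  core plus partial boundary remainders; the boundary marker is shared,
  which is the price of emitting both classes explicitly.
- Block lengths for rate fitting are spans on the designated reference
  species.
- The implementation is verified against a brute-force oracle that
  enumerates all contiguous shared runs and keeps the maximal conserved
  ones, across randomized instances.

## Disruption rates

Per arm: N(L) ~ Poisson(λL); scaled lengths b/L i.i.d. Exponential(γ). The
exponential is the unique length law consistent with the closed form
E[R] = N(L)·L/γ for the total conserved length. With Gamma(a0, b0) priors,
λ | data ~ Gamma(a0+N, b0+L) and γ | data ~ Gamma(a0+N, b0+Σb/L).

- **Priors** default to Gamma(0.001, 0.001): effectively flat, posterior
  means within a fraction of a percent of the maximum-likelihood values N/L
  and N/(Σb/L) whenever N ≥ 1. Zero-block arms stay proper
  (prior-dominated) and are flagged low-information.
- **Differences.** λ^(diff) = λ^(c) − λ^(c+d) and (γ^(−1))^(diff) =
  (γ^(c))^(−1) − (γ^(c+d))^(−1) from independently paired posterior draws;
  the sign convention is stored in the outputs so either reading is
  available. Since the fully conserved set is a subset of c+d, the two
  posteriors are not truly independent; differencing them independently is
  a deliberate approximation. Summaries report mean, central 95% interval,
  and the probability mass on the dominant sign (0.5 for a difference
  symmetric about zero — the signature of an arm with no disrupted blocks).
- **Ranking.** z = λ^(diff) γ^(diff)/L per arm; joint independent draws give
  each arm's probability of attaining the maximal |z|, and (because the
  conditioning of a printed rank probability can be read either way) also
  the probability of maximal |λ^(diff)|.

## Synthetic data

The generators produce data satisfying exactly the assumptions above:

- **Shared markers.** Arms are atomized at inversion boundaries; a homolog
  pair picks an atom pair with probability ∝ |a||b|·γ*, where γ* is the
  planted intensity of the covering region pair (overlap conflicts take the
  maximum, preserving hotspot strength), then uniform positions within the
  atoms. With γ* ≡ 1 the marginal law is exactly uniform per arm — the
  verified property of the real marker maps. Planting γ* > 1 on one pair
  necessarily *dilutes* all other pairs slightly (the categorical weights
  renormalize); recovered intensities are relative, matching the model's
  ratio-based interpretation. Defaults: N = 100 homologs per arm pair
  (study range ≈ 87–230), 61.5 Mb arms.
- **Rearranged orders.** Three lineages independently apply segment
  reversals to a common identity order with unit spacing; segment default is
  uniform over all contiguous segments of length ≥ 2 (no empirical reversal-
  length law is assumed; a truncated-geometric alternative is provided).
  Gene content is conserved — no gain, loss, translocation or pericentric
  events, mirroring the observed rearrangement spectrum of these genomes.
- **Block lengths.** Direct draws from the compound Poisson law, for
  coverage and recovery checks of the fitting code.
- All generators draw from named substreams of a single seed (CRC-keyed
  `SeedSequence`), so identical scenarios reproduce bit-identically across
  processes.

What the generators do **not** emulate: mapping error in marker positions,
marker density varying along an arm, lineage-correlated reversal locations
(breakpoint reuse), or inversions moving blocks relative to planted
hotspots. Passing recovery tests on this synthetic data therefore
demonstrates correctness of the inferential machinery under the stated
assumptions, not robustness to their violation on real maps.

## Test and acceptance problem sizes

The statistical checks run at the simulated study conditions: null
calibration over 500 datasets × 1,000 draws (N = 200, 4×4 inversions, type-I
error within [0.03, 0.07]); hotspot power over 100 replicates of a planted
γ* = 6 pair at N = 230; one 50,000/50,000 four-chain fit for Bayesian
hotspot recovery; 1,000 randomized block-finder instances against the
enumeration oracle; 200 simulated arms for credible-interval coverage. These
sizes give Monte-Carlo error comfortably below every asserted margin while
keeping the default suite to a couple of minutes.
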