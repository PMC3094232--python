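# armdyn

Chromosome-arm dynamics of anopheline inversions and gene order: statistical
machinery for asking two questions about malaria-mosquito genomes
(*Anopheles gambiae*, *An. funestus*, *An. stephensi* — or any trio of taxa
with ordered, homologous marker maps):

1. **Do polymorphic inversions of distant species capture the same genes more
   often than chance predicts?** If natural selection favors particular gene
   combinations under shared environmental pressures, homologous markers
   should co-locate in inversion pairs of independent origin.
2. **Do chromosome arms differ in how fast conserved gene order is
   disrupted?** Arms differ strikingly in inversion density; comparing
   conserved-block counts and lengths across arms quantifies each arm's
   tolerance to breakage.

The package is aimed at comparative cytogenetics / molecular evolution work
with physically or *in silico* mapped markers: ordered marker maps per
(species, arm) and inversion coordinate tables are the only inputs. A
synthetic-data module generates inputs with the exact statistical structure
the analyses assume, so the full pipeline is testable without mapping data.

## Models

**Sharing test.** For an arm pair sharing N single-copy homologs, a region
pair (i, j) — inversion i on arm 1, inversion j on arm 2, with fractional
lengths f_i, f_j — expects E_ij = N f_i f_j co-located homologs when markers
are uniform and independent on both arms. The statistic

    T = sum_ij (O_ij - E_ij)^2 / E_ij

is chi-squared asymptotically; because N is small in practice, the null is
also simulated by repositioning every homolog pair uniformly on its two arms
(default 10,000 draws) and reporting the fraction of draws with a statistic
at least as large as the observed one.

**Sharing intensities.** O_ij ~ Binomial(N, f_i f_j gamma_ij) with
gamma_ij = lambda_i^(1) lambda_j^(2) + mu_ij: a product of per-region
marginal intensities (one anchored at 1 for identifiability) plus a sparse
random effect with a point-mass/truncated-normal mixture prior
(p0 = 0.99, pH = pC = 0.005) that declares only large deviations hot
(mu > 0) or cold (mu < 0). Fitted by Metropolis-within-Gibbs over several
dispersed chains. Posterior summaries: per-pair mean gamma, hotspot
probability Pr(gamma_ij > 1 | data), and the outside/inside connectivity
ratio — the average intensity of pairs touching the non-inverted remainder
of each arm relative to the average over inversion pairs.

**Conserved blocks.** A block is a maximal run of >= 2 homologs consecutive
among shared markers in both species, colinear (identical or fully reversed
order) and distance-conserved (|g_A - g_B| <= rel_tol * max(g_A, g_B) per
adjacent gap; default rel_tol = 0.5). Blocks found in all three species are
*fully conserved* (c); runs surviving in exactly one species pair are
*partially conserved* (disrupted in the third lineage; c+d = all blocks).

**Disruption rates.** Per arm j of length L_j, block counts follow
N(L_j) ~ Poisson(lambda_j L_j) and arm-scaled block lengths b/L_j are
exponential with rate gamma_j (so E[R_j] = N(L_j) L_j / gamma_j). Gamma
conjugate priors give closed-form posteriors. Differencing the c and c+d
fits — lambda^(diff) = lambda^(c) - lambda^(c+d), and likewise for 1/gamma —
isolates the disrupted blocks, and z_j = lambda_j^(diff) gamma_j^(diff) / L_j
(blocks per region length per total length) ranks arms by disruption rate.

## Worked example

Plant a single hotspot (gamma* = 6 between inversions 2Rj and 2Rf) among 230
shared homologs and run both analyses:

```python
import armdyn as ad

scenario = ad.SharingScenario(
    n_homologs=230, seed=21,
    inversions1=[("2Rj", 5, 15), ("2Rb", 25, 40)],
    inversions2=[("2Rf", 10, 22), ("2Re", 35, 50)],
    gamma={("2Rj", "2Rf"): 6.0})
m1, m2, r1, r2, homologs = ad.gen_shared_markers(scenario)

res = ad.monte_carlo_pvalue(m1, m2, r1, r2, homologs, n_draws=10_000, seed=1)
print("T =", round(res.statistic, 2), "df =", res.df)
print("asymptotic p =", f"{res.p_asymptotic:.3g}", "| simulated p =", res.format_p_simulated())

table = ad.count_shared(m1, m2, r1, r2, homologs)
post = ad.fit_intensity_model(table, ad.IntensityModelSpec(
    burnin=50_000, samples=50_000, chains=4, seed=7))
print("posterior mean gamma(2Rj, 2Rf) =",
      round(float(post.gamma_samples("2Rj", "2Rf").mean()), 2))
print("Pr(gamma > 1 | data) =", ad.hot_probability(post, "2Rj", "2Rf"))
ratio = ad.connectivity_ratio(post)
print("outside/inside connectivity ratio = %.2f (%.2f, %.2f)"
      % (ratio.mean, ratio.ci_low, ratio.ci_high))
```

prints

```
T = 167.69 df = 4
asymptotic p = 3.27e-35 | simulated p = < 0.0001
posterior mean gamma(2Rj, 2Rf) = 5.82
Pr(gamma > 1 | data) = 1.0
outside/inside connectivity ratio = 0.40 (0.32, 0.52)
```

The test rejects uniform placement decisively (no null draw reached the
observed statistic); the intensity model recovers the planted six-fold excess
(5.82, hotspot probability 1), and the outside regions share fewer homologs
than the inversions (ratio well below 1) — the planted hotspot inflates the
inversion-pair average.

The same stages are available as a shell tool:

```sh
armdyn simulate --n-homologs 200 --seed 3 --out-dir data/
armdyn share-test --markers data/markers.tsv --regions data/regions.tsv \
    --draws 10000 --seed 1 --out result.json
armdyn fixtures --out-dir fixture/        # small standard dataset + config
armdyn report --config fixture/config.yaml
```

`armdyn report` runs count → share-test → fit-intensity → find-blocks →
fit-blocks from a YAML config and writes a JSON report (plus heat-map and
density figures) with every seed recorded.

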