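"""Synthetic inputs with the statistical structure the analyses assume.

Three generators:

* shared-marker maps for an arm pair, with uniform placement under the null
  (planted sharing intensity ``gamma* = 1`` everywhere) or categorical
  hotspot/coldspot placement with weights proportional to ``f_i f_j gamma*_{i,j}``;
* three-lineage gene orders produced by independent random segment reversals
  of a common ancestral order;
* compound-Poisson block counts and lengths (count ~ Poisson(lambda*L),
  scaled length b/L ~ Exponential(gamma)).

All randomness flows from a single seed through named
:class:`numpy.random.SeedSequence` substreams, so identical scenarios give
identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .blocks import OrderedArmMap
from .io_maps import (OUTSIDE, ArmdynError, ArmRegionSet, HomologTable, Marker,
                      MarkerMap)


def _rng(seed: int, *path: str) -> np.random.Generator:
    """Generator for a named substream of the global seed (process-independent)."""
    key = tuple(zlib.crc32(p.encode()) for p in path)
    child = np.random.SeedSequence(seed, spawn_key=key)
    return np.random.default_rng(child)


# ---------------------------------------------------------------------------
# Shared-marker scenario
# ---------------------------------------------------------------------------

@dataclass
class SharingScenario:
    """Arm pair with planted sharing intensities for each region pair.

    ``gamma`` maps region-id pairs (including ``outside``) to planted
    intensities gamma* >= 0; unlisted pairs default to 1 (the null). With
    gamma* = 1 everywhere, marker positions are uniform and independent on
    both arms — the configuration whose uniformity the analyses assume.
    """

    species1: str = "speciesA"
    species2: str = "speciesB"
    arm: str = "2R"
    arm_length1: float = 61.5
    arm_length2: float = 61.5
    inversions1: Sequence[tuple[str, float, float]] = ()
    inversions2: Sequence[tuple[str, float, float]] = ()
    n_homologs: int = 100
    gamma: Mapping[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def region_sets(self) -> tuple[ArmRegionSet, ArmRegionSet]:
        r1 = ArmRegionSet.from_intervals(self.species1, self.arm, self.arm_length1, self.inversions1)
        r2 = ArmRegionSet.from_intervals(self.species2, self.arm, self.arm_length2, self.inversions2)
        return r1, r2


def _atomize(region_set: ArmRegionSet) -> tuple[np.ndarray, np.ndarray, list[list[str]]]:
    """Split an arm into disjoint atoms at every inversion boundary.

    Returns atom starts, ends, and the region ids covering each atom (the
    aggregate outside region covers atoms under no inversion).
    """
    cuts = {0.0, region_set.arm_length}
    for r in region_set.inversions:
        cuts.update((r.start, r.end))
    edges = np.array(sorted(cuts))
    starts, ends = edges[:-1], edges[1:]
    covers: list[list[str]] = []
    for s, e in zip(starts, ends):
        mid = 0.5 * (s + e)
        ids = [r.region_id for r in region_set.inversions if r.start <= mid < r.end]
        covers.append(ids if ids else [OUTSIDE])
    return starts, ends, covers


def gen_shared_markers(scenario: SharingScenario,
                       ) -> tuple[MarkerMap, MarkerMap, ArmRegionSet, ArmRegionSet, HomologTable]:
    """Sample N homolog pairs from the categorical region-pair law.

    Each arm is atomized into disjoint sub-intervals; an atom pair (a, b) gets
    weight ``|a| |b| * gamma*`` where gamma* is the maximum planted intensity
    over the region pairs covering (a, b) (overlap conflicts keep the hotspot
    strength). Positions are then uniform within the chosen atoms, so
    gamma* = 1 gives the uniform marginal law on each arm.
    """
    if scenario.n_homologs < 0:
        raise ArmdynError("n_homologs must be >= 0")
    r1, r2 = scenario.region_sets()
    s1, e1, cov1 = _atomize(r1)
    s2, e2, cov2 = _atomize(r2)

    def planted(ids1: list[str], ids2: list[str]) -> float:
        vals = [float(scenario.gamma.get((i, j), 1.0)) for i in ids1 for j in ids2]
        if any(v < 0 for v in vals):
            raise ArmdynError("planted gamma* must be >= 0")
        return max(vals)

    len1, len2 = e1 - s1, e2 - s2
    weight = np.array([[la * lb * planted(ca, cb) for lb, cb in zip(len2, cov2)]
                       for la, ca in zip(len1, cov1)])
    total = weight.sum()
    if scenario.n_homologs > 0 and total <= 0:
        raise ArmdynError("all placement weights are zero")

    markers1: list[Marker] = []
    markers2: list[Marker] = []
    if scenario.n_homologs > 0:
        rng = _rng(scenario.seed, "shared_markers")
        flat = weight.ravel() / total
        pick = rng.choice(flat.size, size=scenario.n_homologs, p=flat)
        a_idx, b_idx = np.unravel_index(pick, weight.shape)
        p1 = rng.uniform(s1[a_idx], e1[a_idx])
        p2 = rng.uniform(s2[b_idx], e2[b_idx])
        for k in range(scenario.n_homologs):
            group = f"hg{k:04d}"
            markers1.append(Marker(f"{scenario.species1}_m{k:04d}", group, float(p1[k])))
            markers2.append(Marker(f"{scenario.species2}_m{k:04d}", group, float(p2[k])))

    m1 = MarkerMap(scenario.species1, scenario.arm, scenario.arm_length1, markers1)
    m2 = MarkerMap(scenario.species2, scenario.arm, scenario.arm_length2, markers2)
    return m1, m2, r1, r2, HomologTable.from_maps(m1, m2)


# ---------------------------------------------------------------------------
# Rearranged gene orders
# ---------------------------------------------------------------------------

@dataclass
class RearrangementScenario:
    """Three lineages diverging from one ancestor by random segment reversals."""

    n_genes: int = 60
    reversals: tuple[int, int, int] = (5, 5, 5)
    length_distribution: str = "uniform"     # uniform | truncated-geometric
    geometric_p: float = 0.2
    unit_spacing: float = 1.0
    species: tuple[str, str, str] = ("speciesA", "speciesB", "speciesC")
    arm: str = "2R"
    seed: int = 0


def apply_reversal(order: np.ndarray, i: int, j: int) -> np.ndarray:
    """Reverse the contiguous index range [i, j] (inclusive)."""
    out = order.copy()
    out[i:j + 1] = out[i:j + 1][::-1]
    return out


def _sample_segment(rng: np.random.Generator, n: int, scenario: RearrangementScenario) -> tuple[int, int]:
    if scenario.length_distribution == "uniform":
        # uniform over all contiguous segments of length >= 2
        i, j = sorted(rng.choice(n, size=2, replace=False))
        return int(i), int(j)
    if scenario.length_distribution == "truncated-geometric":
        length = 2 + rng.geometric(scenario.geometric_p)
        length = min(int(length), n)
        i = int(rng.integers(0, n - length + 1))
        return i, i + length - 1
    raise ArmdynError(f"unknown length_distribution {scenario.length_distribution!r}")


def gen_rearranged_orders(scenario: RearrangementScenario) -> list[OrderedArmMap]:
    """Apply each lineage's reversal count independently to the identity order.

    The ancestral arm is the identity permutation of ``n_genes`` homologs with
    equal unit spacing; positions after rearrangement are the permuted index
    times the unit spacing (gene content is conserved — no gain or loss).
    """
    if any(r < 0 for r in scenario.reversals):
        raise ArmdynError("reversal counts must be >= 0")
    if scenario.n_genes < 2:
        raise ArmdynError("need at least 2 genes")
    genes = [f"g{k:03d}" for k in range(scenario.n_genes)]
    maps = []
    for lineage, (sp, n_rev) in enumerate(zip(scenario.species, scenario.reversals)):
        rng = _rng(scenario.seed, "rearrange", str(lineage))
        order = np.arange(scenario.n_genes)
        for _ in range(n_rev):
            i, j = _sample_segment(rng, scenario.n_genes, scenario)
            order = apply_reversal(order, i, j)
        positions = np.arange(scenario.n_genes) * scenario.unit_spacing
        maps.append(OrderedArmMap(sp, scenario.arm, [genes[k] for k in order], positions))
    return maps


def marker_map_from_order(om: OrderedArmMap, arm_length: float | None = None) -> MarkerMap:
    """Wrap an ordered arm map as a MarkerMap (marker ids derived per species)."""
    L = arm_length if arm_length is not None else float(om.positions[-1]) + 1.0
    markers = [Marker(f"{om.species}_{h}", h, float(p), "in-silico")
               for h, p in zip(om.homologs, om.positions)]
    return MarkerMap(om.species, om.arm, L, markers)


def write_fixture_dataset(out_dir, seed: int = 0) -> str:
    """Materialize the small standard synthetic dataset used by the test suite.

    Three species on one arm: gene orders diverged by a few random reversals
    from a common 60-gene ancestor, plus two inversions per species on the
    first two species' arms. Written in the io_maps TSV dialects together with
    a ready-to-run pipeline YAML config; returns the config path.
    """
    from pathlib import Path

    import yaml

    from .io_maps import write_marker_table, write_region_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = RearrangementScenario(n_genes=60, reversals=(4, 4, 4), seed=seed)
    orders = gen_rearranged_orders(scenario)
    maps = [marker_map_from_order(om, arm_length=60.0) for om in orders]
    write_marker_table(maps, out / "markers.tsv")

    regions = [
        ArmRegionSet.from_intervals(scenario.species[0], scenario.arm, 60.0,
                                    [("a1", 5.0, 20.0), ("a2", 30.0, 45.0)]),
        ArmRegionSet.from_intervals(scenario.species[1], scenario.arm, 60.0,
                                    [("b1", 8.0, 25.0), ("b2", 35.0, 50.0)]),
        ArmRegionSet.from_intervals(scenario.species[2], scenario.arm, 60.0,
                                    [("c1", 10.0, 28.0)]),
    ]
    write_region_table(regions, out / "regions.tsv")

    config = {
        "markers": str(out / "markers.tsv"),
        "regions": str(out / "regions.tsv"),
        "reference_species": scenario.species[0],
        "species": list(scenario.species),
        "arm_pairing": [{"label": scenario.arm, **{sp: scenario.arm for sp in scenario.species}}],
        "seed": seed,
        "share_test": {"draws": 2000},
        "intensity": {"run": False},
        "blocks": {"rel_tol": 0.5},
        "block_rates": {"samples": 20000, "prior": [0.001, 0.001]},
        "output_dir": str(out / "report"),
        "figures": False,
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return str(cfg_path)


def count_breakpoints(map_a: OrderedArmMap, map_b: OrderedArmMap) -> int:
    """Unsigned breakpoints between two orders over their shared homologs."""
    in_b = {h: i for i, h in enumerate(map_b.homologs)}
    ranks = [in_b[h] for h in map_a.homologs if h in in_b]
    return sum(1 for u, v in zip(ranks, ranks[1:]) if abs(u - v) != 1)


# ---------------------------------------------------------------------------
# Compound-Poisson block lengths
# ---------------------------------------------------------------------------

def gen_block_lengths(lambda_rate: float, gamma_rate: float, L: float,
                      seed: int | np.random.Generator = 0) -> tuple[int, np.ndarray]:
    """Draw a block count ~ Poisson(lambda*L) and lengths b = L * Exp(gamma).

    Scaled lengths b/L are exponential with rate gamma, so E[b] = L / gamma
    and the expected total block length is E[N] * L / gamma.
    """
    if lambda_rate <= 0 or gamma_rate <= 0 or L <= 0:
        raise ArmdynError("lambda_rate, gamma_rate and L must all be positive")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), "block_lengths")
    count = int(rng.poisson(lambda_rate * L))
    lengths = L * rng.exponential(1.0 / gamma_rate, size=count)
    return count, lengths
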