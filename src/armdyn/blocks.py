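"""Conserved gene-order (synteny) block detection and three-species classification.

A conserved block is a maximal run of >= 2 homologs that are consecutive among
shared homologs in both species, colinear in identical or fully reversed order,
and distance-conserved up to a relative tolerance. Blocks conserved in all
three species are *fully conserved*; blocks conserved in exactly two are
*partially conserved* (disrupted in the third lineage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_maps import ArmdynError, MarkerMap

FULLY = "fully_conserved"
PARTIAL = "partial"


@dataclass
class OrderedArmMap:
    """Ordered homolog ids with strictly increasing positions on one arm."""

    species: str
    arm: str
    homologs: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.homologs) != len(self.positions):
            raise ArmdynError("homologs and positions must have equal length")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ArmdynError("positions must be strictly increasing")

    @classmethod
    def from_marker_map(cls, mm: MarkerMap) -> "OrderedArmMap":
        return cls(mm.species, mm.arm, mm.homolog_groups, mm.positions)

    def position_of(self, homolog: str) -> float:
        return float(self.positions[self.homologs.index(homolog)])

    def __len__(self) -> int:
        return len(self.homologs)


@dataclass
class SyntenyBlock:
    """A run of >= 2 colinear homologs with per-species spans."""

    members: tuple[str, ...]                 # ordered by the first species' coordinates
    orientation: str                         # forward | reversed
    spans: dict[str, tuple[float, float]]    # species -> (start, end) in Mb
    conservation_class: str = PARTIAL        # fully_conserved | partial
    pair: tuple[str, str] | None = None      # surviving pair for partial blocks
    reference_species: str | None = None

    def length(self, species: str | None = None) -> float:
        sp = species or self.reference_species or next(iter(self.spans))
        s, e = self.spans[sp]
        return e - s

    def __len__(self) -> int:
        return len(self.members)


def _gap_conserved(g_a: float, g_b: float, rel_tol: float) -> bool:
    if math.isinf(rel_tol):
        return True
    return abs(g_a - g_b) <= rel_tol * max(g_a, g_b)


def _shared_in_a_order(map_a: OrderedArmMap, map_b: OrderedArmMap):
    """Shared homologs ordered by species-A position, with their B rank."""
    in_b = {h: i for i, h in enumerate(map_b.homologs)}
    shared = [(h, p) for h, p in zip(map_a.homologs, map_a.positions) if h in in_b]
    if not shared:
        return [], np.array([]), np.array([]), np.array([], dtype=int)
    homs = [h for h, _ in shared]
    pos_a = np.array([p for _, p in shared])
    pos_b = np.array([map_b.positions[in_b[h]] for h in homs])
    # rank among shared markers along the B arm
    rank_b = np.argsort(np.argsort(pos_b))
    return homs, pos_a, pos_b, rank_b


def find_pairwise_blocks(map_a: OrderedArmMap, map_b: OrderedArmMap,
                         rel_tol: float = 0.5) -> list[SyntenyBlock]:
    """All maximal colinear, distance-conserved runs of >= 2 shared homologs.

    Adjacent shared markers (k, k+1) in A order are linked when they are also
    consecutive among shared markers in B (rank step +-1) and their physical
    gaps agree: |g_A - g_B| <= rel_tol * max(g_A, g_B). Maximal chains with a
    constant rank step form blocks; step +1 is a forward block, -1 reversed.
    ``rel_tol=inf`` disables the distance criterion (pure colinearity).
    """
    if rel_tol < 0:
        raise ArmdynError("rel_tol must be >= 0")
    homs, pos_a, pos_b, rank_b = _shared_in_a_order(map_a, map_b)
    n = len(homs)
    if n < 2:
        return []

    steps = np.diff(rank_b)
    gaps_a = np.diff(pos_a)
    gaps_b = np.abs(np.diff(pos_b))
    linked = np.array([
        abs(int(steps[k])) == 1 and _gap_conserved(float(gaps_a[k]), float(gaps_b[k]), rel_tol)
        for k in range(n - 1)
    ])

    blocks: list[SyntenyBlock] = []
    k = 0
    while k < n - 1:
        if not linked[k]:
            k += 1
            continue
        sign = int(steps[k])
        j = k
        while j + 1 < n - 1 and linked[j + 1] and int(steps[j + 1]) == sign:
            j += 1
        members = tuple(homs[k:j + 2])
        a_span = (float(pos_a[k]), float(pos_a[j + 1]))
        b_vals = pos_b[k:j + 2]
        blocks.append(SyntenyBlock(
            members=members,
            orientation="forward" if sign == 1 else "reversed",
            spans={map_a.species: a_span,
                   map_b.species: (float(b_vals.min()), float(b_vals.max()))},
            conservation_class=PARTIAL,
            pair=(map_a.species, map_b.species),
            reference_species=map_a.species,
        ))
        k = j + 1
    return blocks


def _adjacency_pairs(blocks: Sequence[SyntenyBlock]) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    for b in blocks:
        for u, v in zip(b.members, b.members[1:]):
            pairs.add(frozenset((u, v)))
    return pairs


def classify_blocks(blocks_ab: Sequence[SyntenyBlock],
                    blocks_ac: Sequence[SyntenyBlock],
                    blocks_bc: Sequence[SyntenyBlock],
                    maps: Sequence[OrderedArmMap] | None = None,
                    ) -> list[SyntenyBlock]:
    """Classify runs as fully conserved (all three species) or partial.

    A marker run is fully conserved when every adjacent pair along it is
    adjacent inside a block of all three pairwise lists (an intersected,
    re-maximalized run). Each pairwise block then contributes its remainder —
    the maximal sub-runs not covered by a fully conserved run — as partial
    blocks (>= 2 markers), labelled with the surviving pair. Spans are
    re-derived from ``maps`` when given; the first map is the reference
    species for downstream length statistics.
    """
    lists = [tuple(blocks_ab), tuple(blocks_ac), tuple(blocks_bc)]
    universe: set[str] = set()
    for blist in lists:
        for b in blist:
            universe.update(b.members)
    if maps is not None:
        for b in [x for blist in lists for x in blist]:
            for sp in (b.pair or ()):
                m = next((mm for mm in maps if mm.species == sp), None)
                if m is not None and not set(b.members) <= set(m.homologs):
                    raise ArmdynError(f"inconsistent homolog universes: block members missing from {sp!r}")

    adj = [_adjacency_pairs(blist) for blist in lists]
    triple = adj[0] & adj[1] & adj[2]

    ref_map = maps[0] if maps else None

    def spans_for(members: tuple[str, ...], template: SyntenyBlock | None) -> dict:
        spans = {}
        if maps is not None:
            for mm in maps:
                try:
                    vals = [mm.position_of(h) for h in members]
                except ValueError:
                    continue
                spans[mm.species] = (min(vals), max(vals))
        elif template is not None:
            spans = dict(template.spans)
        return spans

    out: list[SyntenyBlock] = []

    # fully conserved maximal chains, walked in AB-block order (deduplicated)
    seen_fully: set[tuple[str, ...]] = set()
    for b in lists[0]:
        mem = b.members
        k = 0
        while k < len(mem) - 1:
            if frozenset((mem[k], mem[k + 1])) not in triple:
                k += 1
                continue
            j = k
            while j + 1 < len(mem) - 1 and frozenset((mem[j + 1], mem[j + 2])) in triple:
                j += 1
            run = mem[k:j + 2]
            if run not in seen_fully:
                seen_fully.add(run)
                out.append(SyntenyBlock(
                    members=run, orientation=b.orientation,
                    spans=spans_for(run, b), conservation_class=FULLY,
                    pair=None,
                    reference_species=ref_map.species if ref_map else b.reference_species,
                ))
            k = j + 1

    # partial remainders per pairwise list
    for blist in lists:
        for b in blist:
            mem = b.members
            is_triple = [frozenset((u, v)) in triple for u, v in zip(mem, mem[1:])]
            if all(is_triple):
                continue  # wholly fully conserved; already emitted
            k = 0
            while k < len(mem) - 1:
                if is_triple[k]:
                    k += 1
                    continue
                j = k
                while j + 1 < len(mem) - 1 and not is_triple[j + 1]:
                    j += 1
                run = mem[k:j + 2]
                if len(run) >= 2:
                    out.append(SyntenyBlock(
                        members=run, orientation=b.orientation,
                        spans=spans_for(run, b), conservation_class=PARTIAL,
                        pair=b.pair,
                        reference_species=ref_map.species if ref_map else b.reference_species,
                    ))
                k = j + 1
    return out


@dataclass
class BlockStats:
    arm: str
    arm_length: float
    counts: dict[str, int] = field(default_factory=dict)        # fully | partial | combined
    total_length: dict[str, float] = field(default_factory=dict)  # R = sum of block lengths
    mean_length: dict[str, float] = field(default_factory=dict)
    lengths: dict[str, list[float]] = field(default_factory=dict)


def block_stats(blocks: Sequence[SyntenyBlock], arm: str, arm_length: float,
                reference_species: str | None = None) -> BlockStats:
    """Count and measure blocks on one reference arm.

    Lengths are spans on the reference species. Reported separately for the
    fully conserved set (c), the partial set (d), and combined (c+d).
    """
    stats = BlockStats(arm=arm, arm_length=arm_length)
    groups = {
        "fully": [b for b in blocks if b.conservation_class == FULLY],
        "partial": [b for b in blocks if b.conservation_class == PARTIAL],
        "combined": list(blocks),
    }
    for label, blist in groups.items():
        lens = [b.length(reference_species) for b in blist]
        stats.lengths[label] = lens
        stats.counts[label] = len(lens)
        stats.total_length[label] = float(sum(lens))
        stats.mean_length[label] = float(np.mean(lens)) if lens else float("nan")
    return stats


# ---------------------------------------------------------------------------
# Brute-force oracle (small instances) — used for verification in tests
# ---------------------------------------------------------------------------

def brute_force_blocks(map_a: OrderedArmMap, map_b: OrderedArmMap,
                       rel_tol: float = 0.5) -> list[tuple[tuple[str, ...], str]]:
    """Enumerate every contiguous shared run, keep maximal conserved ones.

    Independent reference for :func:`find_pairwise_blocks` on instances with a
    handful of shared markers: checks consecutiveness in both species,
    colinearity (identical or fully reversed order) and gap agreement for all
    O(n^2) candidate runs directly.
    """
    homs, pos_a, pos_b, rank_b = _shared_in_a_order(map_a, map_b)
    n = len(homs)

    def conserved(i: int, j: int) -> str | None:
        ranks = rank_b[i:j + 1]
        fwd = all(ranks[t + 1] - ranks[t] == 1 for t in range(j - i))
        rev = all(ranks[t + 1] - ranks[t] == -1 for t in range(j - i))
        if not (fwd or rev):
            return None
        for t in range(i, j):
            if not _gap_conserved(float(pos_a[t + 1] - pos_a[t]),
                                  float(abs(pos_b[t + 1] - pos_b[t])), rel_tol):
                return None
        return "forward" if fwd else "reversed"

    found = []
    for i in range(n):
        for j in range(i + 1, n):
            ori = conserved(i, j)
            if ori is None:
                continue
            left = i > 0 and conserved(i - 1, j) is not None
            right = j < n - 1 and conserved(i, j + 1) is not None
            if not left and not right:
                found.append((tuple(homs[i:j + 1]), ori))
    return found
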