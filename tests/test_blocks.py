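"""Synteny block finding, three-species classification and block statistics."""

import numpy as np
import pytest

from armdyn import synthetic
from armdyn.blocks import (FULLY, PARTIAL, OrderedArmMap, block_stats,
                           brute_force_blocks, classify_blocks,
                           find_pairwise_blocks)
from armdyn.io_maps import ArmdynError


def arm(species, homologs, positions=None):
    if positions is None:
        positions = np.arange(len(homologs), dtype=float)
    return OrderedArmMap(species, "2R", list(homologs), np.asarray(positions, float))


class TestPairwise:
    def test_identical_maps_single_forward_block(self):
        a = arm("A", ["m1", "m2", "m3", "m4", "m5"])
        b = arm("B", ["m1", "m2", "m3", "m4", "m5"])
        blocks = find_pairwise_blocks(a, b)
        assert len(blocks) == 1
        assert blocks[0].members == ("m1", "m2", "m3", "m4", "m5")
        assert blocks[0].orientation == "forward"

    def test_five_marker_instance_forward_and_reversed(self):
        a = arm("A", ["m1", "m2", "m3", "m4", "m5"])
        b = arm("B", ["m1", "m2", "m3", "m5", "m4"])
        blocks = find_pairwise_blocks(a, b)
        found = {b_.members: b_.orientation for b_ in blocks}
        assert found == {("m1", "m2", "m3"): "forward", ("m4", "m5"): "reversed"}

    def test_distance_tolerance_breaks_adjacency(self):
        # gaps 1.0 vs 2.5 Mb: |1 - 2.5| = 1.5 > 0.5 * 2.5, not merged
        a = arm("A", ["m1", "m2"], [0.0, 1.0])
        b = arm("B", ["m1", "m2"], [0.0, 2.5])
        assert find_pairwise_blocks(a, b, rel_tol=0.5) == []
        assert len(find_pairwise_blocks(a, b, rel_tol=float("inf"))) == 1

    def test_fewer_than_two_shared_empty(self):
        a = arm("A", ["m1", "m2"])
        b = arm("B", ["x1", "m1"])
        assert find_pairwise_blocks(a, b) == []

    def test_symmetry_same_marker_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            perm = rng.permutation(8)
            a = arm("A", [f"m{i}" for i in range(8)])
            b = arm("B", [f"m{i}" for i in perm])
            ab = {frozenset(bl.members) for bl in find_pairwise_blocks(a, b, rel_tol=np.inf)}
            ba = {frozenset(bl.members) for bl in find_pairwise_blocks(b, a, rel_tol=np.inf)}
            assert ab == ba

    def test_no_overlap_within_one_comparison(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = 10
            a = arm("A", [f"m{i}" for i in range(n)], np.sort(rng.uniform(0, 30, n)))
            b = arm("B", [f"m{i}" for i in rng.permutation(n)], np.sort(rng.uniform(0, 30, n)))
            blocks = find_pairwise_blocks(a, b)
            members = [m for bl in blocks for m in bl.members]
            assert len(members) == len(set(members))

    def test_matches_bruteforce_enumeration(self):
        """Linear-scan finder equals exhaustive maximal-run enumeration."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            a = arm("A", [f"m{i}" for i in range(n)], np.sort(rng.uniform(0, 20, n)))
            b = arm("B", [f"m{i}" for i in rng.permutation(n)], np.sort(rng.uniform(0, 20, n)))
            rel_tol = float(rng.choice([0.2, 0.5, 1.0, np.inf]))
            got = {(bl.members, bl.orientation) for bl in find_pairwise_blocks(a, b, rel_tol)}
            expect = set(brute_force_blocks(a, b, rel_tol))
            assert got == expect

    def test_negative_tolerance_rejected(self):
        a = arm("A", ["m1", "m2"])
        with pytest.raises(ArmdynError):
            find_pairwise_blocks(a, a, rel_tol=-0.1)


class TestClassify:
    def three_maps(self, orders):
        return [arm(sp, order) for sp, order in zip("ABC", orders)]

    def classify(self, maps, rel_tol=0.5):
        ab = find_pairwise_blocks(maps[0], maps[1], rel_tol)
        ac = find_pairwise_blocks(maps[0], maps[2], rel_tol)
        bc = find_pairwise_blocks(maps[1], maps[2], rel_tol)
        return classify_blocks(ab, ac, bc, maps=maps)

    def test_three_identical_maps_single_fully_conserved(self):
        genes = [f"m{i}" for i in range(6)]
        out = self.classify(self.three_maps([genes, genes, genes]))
        assert len(out) == 1
        assert out[0].conservation_class == FULLY
        assert out[0].members == tuple(genes)

    def test_internal_reversal_in_third_lineage(self):
        """C reverses m2..m3 inside an A/B block of m0..m5 (unit gaps).

        Enumeration oracle on this instance: AB keeps one full block; the
        reversal breaks C's adjacency at both boundary gaps (the reversed
        interior keeps its internal adjacency but its boundary gaps change
        order), leaving fully conserved flanks and the reversed middle, with
        the boundary pairs surviving only in A/B.
        """
        genes = [f"m{i}" for i in range(6)]
        c_order = ["m0", "m1", "m3", "m2", "m4", "m5"]
        out = self.classify(self.three_maps([genes, genes, c_order]))
        fully = {b.members for b in out if b.conservation_class == FULLY}
        partial = {(b.members, b.pair) for b in out if b.conservation_class == PARTIAL}
        assert ("m0", "m1") in fully and ("m4", "m5") in fully
        assert ("m2", "m3") in fully          # reversed pair conserved in all three
        assert (("m1", "m2"), ("A", "B")) in partial
        assert (("m3", "m4"), ("A", "B")) in partial

    def test_zero_shared_blocks(self):
        out = classify_blocks([], [], [])
        assert out == []

    def test_partial_pair_labels(self):
        # C shuffles everything: AB blocks survive as partial (A, B) only
        genes = [f"m{i}" for i in range(5)]
        c_order = ["m2", "m0", "m3", "m1", "m4"]
        maps = self.three_maps([genes, genes, c_order])
        out = self.classify(maps, rel_tol=np.inf)
        assert {b.pair for b in out if b.conservation_class == PARTIAL} == {("A", "B")}
        assert not [b for b in out if b.conservation_class == FULLY]

    def test_inconsistent_universe_errors(self):
        a = arm("A", ["m1", "m2"]); b = arm("B", ["m1", "m2"])
        blocks_ab = find_pairwise_blocks(a, b)
        bad_maps = [arm("A", ["x1", "x2"]), b, arm("C", ["m1", "m2"])]
        with pytest.raises(ArmdynError, match="inconsistent"):
            classify_blocks(blocks_ab, [], [], maps=bad_maps)


class TestStats:
    def test_arithmetic(self):
        from armdyn.blocks import SyntenyBlock
        blocks = [
            SyntenyBlock(("m0", "m1"), "forward", {"A": (0.0, 1.0)}, FULLY, None, "A"),
            SyntenyBlock(("m2", "m3"), "forward", {"A": (5.0, 8.0)}, PARTIAL, ("A", "B"), "A"),
        ]
        st = block_stats(blocks, "2R", 10.0, reference_species="A")
        assert st.total_length["combined"] == pytest.approx(4.0)
        assert st.mean_length["combined"] == pytest.approx(2.0)
        assert st.counts == {"fully": 1, "partial": 1, "combined": 2}

    def test_matches_flat_recomputation(self, fixture_dataset):
        from armdyn import io_maps
        maps = io_maps.read_marker_table(fixture_dataset["dir"] / "markers.tsv")
        oms = [OrderedArmMap.from_marker_map(m) for m in maps.values()]
        out = classify_blocks(
            find_pairwise_blocks(oms[0], oms[1]),
            find_pairwise_blocks(oms[0], oms[2]),
            find_pairwise_blocks(oms[1], oms[2]), maps=oms)
        st = block_stats(out, "2R", 60.0, reference_species=oms[0].species)
        for label in ("fully", "partial", "combined"):
            blocks = [b for b in out if label == "combined" or
                      (label == "fully") == (b.conservation_class == FULLY)]
            lens = [b.spans[oms[0].species][1] - b.spans[oms[0].species][0] for b in blocks]
            assert st.counts[label] == len(lens)
            assert st.total_length[label] == pytest.approx(sum(lens))


def test_identity_self_comparison_via_generator():
    maps = synthetic.gen_rearranged_orders(
        synthetic.RearrangementScenario(n_genes=25, reversals=(3, 0, 0), seed=1))
    blocks = find_pairwise_blocks(maps[1], maps[2])   # both unrearranged
    assert len(blocks) == 1 and len(blocks[0]) == 25
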