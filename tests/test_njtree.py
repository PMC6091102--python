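"""Neighbor joining, bootstrap support, rooting, and monophyly."""

import math

import dendropy
import numpy as np
import pytest

from barcodekit.alnstats import validate_alignment
from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.errors import OutgroupError, UndefinedDistanceError
from barcodekit.njtree import (
    bipartition_sets,
    bootstrap_support,
    neighbor_joining,
    path_distance_matrix,
    random_additive_tree,
    root_with_outgroup,
    species_monophyly,
    to_newick,
)
from conftest import rec


def dm_from_array(ids, arr, species=None):
    species = species or {i: i for i in ids}
    return DistanceMatrix(ids, np.asarray(arr, dtype=float), species)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 0.3, 0.5, 0.6
        dm = dm_from_array(["a", "b", "c"],
                           [[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]])
        tree = neighbor_joining(dm)
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["c"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((a:0.1, b:0.2):0.05, c:0.3, d:0.4) with split ab|cd
        d = {("a", "b"): 0.3,
             ("a", "c"): 0.45, ("a", "d"): 0.55,
             ("b", "c"): 0.55, ("b", "d"): 0.65,
             ("c", "d"): 0.7}
        ids = ["a", "b", "c", "d"]
        arr = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            arr[i, j] = arr[j, i] = v
        tree = neighbor_joining(dm_from_array(ids, arr))
        assert bipartition_sets(tree) == {frozenset({"a", "b"})} or \
               bipartition_sets(tree) == {frozenset({"c", "d"})}
        paths = path_distance_matrix(tree, ids)
        assert np.allclose(paths, arr, atol=1e-12)

    def test_consistency_on_random_additive_matrices(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 11))
            true_tree, ids = random_additive_tree(n, rng)
            arr = path_distance_matrix(true_tree, ids)
            recovered = neighbor_joining(dm_from_array(ids, arr))
            assert np.allclose(path_distance_matrix(recovered, ids), arr, atol=1e-10)
            assert bipartition_sets(recovered) == bipartition_sets(true_tree)

    def test_agreement_with_skbio_on_additive_matrix(self, rng):
        """Independent NJ implementation recovers the same topology."""
        skbio = pytest.importorskip("skbio")
        true_tree, ids = random_additive_tree(8, rng)
        arr = path_distance_matrix(true_tree, ids)
        ours = neighbor_joining(dm_from_array(ids, arr))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(arr, ids))
        their_bps = set()
        all_tips = frozenset(ids)
        ref = min(ids)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_tips - side
            if 2 <= len(side) <= len(ids) - 2:
                their_bps.add(side)
        assert bipartition_sets(ours) == their_bps

    def test_undefined_entry_rejected_with_pair_named(self):
        arr = np.zeros((3, 3))
        arr[0, 1] = arr[1, 0] = math.nan
        with pytest.raises(UndefinedDistanceError, match="a.*b"):
            neighbor_joining(dm_from_array(["a", "b", "c"], arr))

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm_from_array(["a", "b"], np.zeros((2, 2))))

    def test_deterministic_under_ties(self):
        arr = np.full((4, 4), 0.2)
        np.fill_diagonal(arr, 0.0)
        t1 = to_newick(neighbor_joining(dm_from_array(list("abcd"), arr)))
        t2 = to_newick(neighbor_joining(dm_from_array(list("abcd"), arr)))
        assert t1 == t2


class TestBootstrap:
    def _block_alignment(self, rng, n_per_block=6, length=300):
        """Two clearly diverged sequence blocks -> one dominant bipartition."""
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        # blocks differ at 25% of sites (transversions), far from saturation
        other = list(base)
        for i in range(0, length, 4):
            other[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[i]]
        other = "".join(other)

        def mutate(s, k):
            s = list(s)
            for i in rng.integers(0, length, k):
                s[int(i)] = "ACGT"[int(rng.integers(0, 4))]
            return "".join(s)

        rows = [rec(f"x{i}", "Block x", mutate(base, 3), individual=f"V{i}")
                for i in range(n_per_block)]
        rows += [rec(f"y{i}", "Block y", mutate(other, 3), individual=f"V{i}")
                 for i in range(n_per_block)]
        return validate_alignment(rows)

    def test_block_separating_edge_has_high_support(self, rng):
        aln = self._block_alignment(rng)
        bs = bootstrap_support(aln, n_replicates=50, seed=7)
        split = frozenset(f"y{i}" for i in range(6))
        assert bs.support[split] >= 95.0

    def test_zero_replicates_returns_plain_tree(self, rng):
        aln = self._block_alignment(rng)
        bs = bootstrap_support(aln, n_replicates=0, seed=7)
        assert bs.support == {} and bs.n_completed == 0

    def test_same_seed_identical_supports(self, rng):
        aln = self._block_alignment(rng)
        a = bootstrap_support(aln, n_replicates=30, seed=11)
        b = bootstrap_support(aln, n_replicates=30, seed=11)
        assert a.support == b.support

    def test_supports_lie_in_percent_range(self, rng):
        aln = self._block_alignment(rng)
        bs = bootstrap_support(aln, n_replicates=30, seed=3)
        assert all(0.0 <= v <= 100.0 for v in bs.support.values())


class TestRooting:
    def _tree(self, newick):
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = False
        return t

    def test_single_tip_outgroup(self):
        t = self._tree("(a:1,b:1,(c:1,d:1):0.5);")
        rooted = root_with_outgroup(t, {"a"})
        children = rooted.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in ch.leaf_iter()) for ch in children]
        assert frozenset({"a"}) in sides

    def test_absent_outgroup_tip_errors(self):
        t = self._tree("(a:1,b:1,(c:1,d:1):0.5);")
        with pytest.raises(OutgroupError, match="absent"):
            root_with_outgroup(t, {"zz"})

    def test_two_tip_outgroup_clade(self):
        t = self._tree("(a:1,b:1,(c:1,d:1):0.5);")
        rooted = root_with_outgroup(t, {"c", "d"})
        sides = [frozenset(l.taxon.label for l in ch.leaf_iter())
                 for ch in rooted.seed_node.child_nodes()]
        assert frozenset({"c", "d"}) in sides

    def test_non_monophyletic_outgroup_errors(self):
        t = self._tree("((a:1,b:1):0.5,(c:1,d:1):0.5,e:1);")
        with pytest.raises(OutgroupError, match="not.*side of any edge|monophyletic"):
            root_with_outgroup(t, {"a", "c"})

    def test_input_tree_unchanged(self):
        t = self._tree("(a:1,b:1,(c:1,d:1):0.5);")
        before = t.as_string(schema="newick")
        root_with_outgroup(t, {"a"})
        assert t.as_string(schema="newick") == before


class TestMonophyly:
    def _rooted(self, newick):
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = True
        return t

    def test_contiguous_blocks_all_monophyletic(self):
        t = self._rooted("(((a1:1,a2:1):1,a3:1):1,((b1:1,b2:1):1,b3:1):1);")
        species = {x: x[0] for x in ("a1", "a2", "a3", "b1", "b2", "b3")}
        verdicts, rate = species_monophyly(t, species)
        assert verdicts == {"a": True, "b": True} and rate == 100.0

    def test_species_split_across_root_not_monophyletic(self):
        t = self._rooted("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        species = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        verdicts, rate = species_monophyly(t, species)
        assert verdicts == {"a": False, "b": False} and rate == 0.0

    def test_five_species_hand_drawn_topology(self):
        t = self._rooted(
            "(((a1:1,a2:1):1,(b1:1,c1:1):1):1,((b2:1,d1:1):1,(d2:1,e1:1):1):1);"
        )
        species = {x: x[0] for x in ("a1", "a2", "b1", "b2", "c1", "d1", "d2", "e1")}
        verdicts, rate = species_monophyly(t, species)
        # a coherent; b split; d split; c and e singletons
        assert verdicts["a"] is True and verdicts["b"] is False and verdicts["d"] is False
        assert verdicts["c"] is None and verdicts["e"] is None
        assert rate == pytest.approx(100.0 / 3)

    def test_singletons_counted_when_requested(self):
        t = self._rooted("((a1:1,a2:1):1,c1:1);")
        species = {"a1": "a", "a2": "a", "c1": "c"}
        _, rate_default = species_monophyly(t, species)
        _, rate_single = species_monophyly(t, species, count_singletons=True)
        assert rate_default == 100.0 and rate_single == 100.0

    def test_unknown_tip_species_errors(self):
        t = self._rooted("((a1:1,a2:1):1,c1:1);")
        with pytest.raises(ValueError, match="unknown species"):
            species_monophyly(t, {"a1": "a", "a2": "a"})

    def test_verdicts_ignore_branch_lengths(self):
        species = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        t1 = self._rooted("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        t2 = self._rooted("((a1:9,a2:0.1):5,(b1:2,b2:3):0.01);")
        assert species_monophyly(t1, species)[0] == species_monophyly(t2, species)[0]


class TestNewickOutput:
    def test_supports_above_cutoff_rendered(self, rng):
        aln = TestBootstrap()._block_alignment(rng)
        bs = bootstrap_support(aln, n_replicates=20, seed=1)
        nwk = bs.tree
        text = to_newick(nwk, min_support=50)
        assert text.endswith(";\n")
        reparsed = dendropy.Tree.get(data=text, schema="newick")
        labels = [n.label for n in reparsed.internal_nodes() if n.label]
        assert all(50 <= int(x) <= 100 for x in labels)
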