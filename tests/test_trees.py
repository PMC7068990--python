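"""NJ reconstruction, bootstrap supports and allele-to-genepool assignment."""

import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from agtbarcode.distances import DistanceMatrix
from agtbarcode.records import MarkerRecord, MsaBlock
from agtbarcode.trees import (TreeError, assign_alleles, bootstrap_support,
                              neighbor_joining, robinson_foulds)


def matrix_from(ids, arr):
    a = np.asarray(arr, dtype=float)
    return DistanceMatrix(ids=ids, values=a, mask=np.zeros(a.shape, bool))


def random_additive_matrix(n, seed):
    """Random binary tree -> (patristic matrix, dendropy tree)."""
    ns = dendropy.TaxonNamespace([f"t{i:02d}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=ns,
        num_extant_tips=n, rng=random.Random(seed))
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = round(e.length, 4) + 0.01   # keep edges positive
    pdm = tree.phylogenetic_distance_matrix()
    ids = [t.label for t in ns]
    arr = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                arr[i, j] = pdm.patristic_distance(ns[i], ns[j])
    tree.is_rooted = False
    return matrix_from(ids, arr), tree, ns


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) with internal edge 1
        ids = ["a", "b", "c", "d"]
        arr = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = neighbor_joining(matrix_from(ids, arr))
        newick = tree.as_string(schema="newick")
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        # a,b form a cherry
        ab = {lf.taxon.label for lf in tree.leaf_node_iter()} - {"c", "d"}
        for node in tree.preorder_internal_node_iter():
            leaves = {lf.taxon.label for lf in node.leaf_iter()}
            if leaves == {"a", "b"}:
                break
        else:
            pytest.fail(f"no (a,b) cherry in {newick}")

    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        arr = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        tree = neighbor_joining(matrix_from(ids, arr))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_random_additive_trees_recovered(self):
        for n, seed in [(4, 0), (6, 1), (8, 2), (10, 3)]:
            matrix, truth, ns = random_additive_matrix(n, seed)
            nj = neighbor_joining(matrix)
            assert robinson_foulds(nj, truth) == 0
            # cross-check with dendropy's own RF computation
            nj2 = dendropy.Tree.get(data=nj.as_string(schema="newick"),
                                    schema="newick", taxon_namespace=ns)
            nj2.is_rooted = False
            assert treecompare.symmetric_difference(nj2, truth) == 0

    def test_ultrametric_matches_single_linkage(self):
        # ultrametric 5-taxon matrix: NJ topology == single-linkage dendrogram
        from scipy.cluster.hierarchy import linkage, to_tree
        ids = ["a", "b", "c", "d", "e"]
        arr = np.array([[0, 2, 8, 8, 8], [2, 0, 8, 8, 8], [8, 8, 0, 4, 6],
                        [8, 8, 4, 0, 6], [8, 8, 6, 6, 0]], float)
        nj = neighbor_joining(matrix_from(ids, arr))
        from scipy.spatial.distance import squareform
        Z = linkage(squareform(arr), method="single")

        def leaves(node):
            return {ids[i] for i in node.pre_order(lambda x: x.id) if i < 5}

        root = to_tree(Z)
        sl_clades = []
        stack = [root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf():
                sl_clades.append(frozenset(leaves(nd)))
                stack.extend([nd.left, nd.right])
        anchor = "a"
        from agtbarcode.trees import _bipartitions
        nj_bips = _bipartitions(nj, anchor)
        sl_bips = {frozenset(set(ids) - c) if anchor in c else c
                   for c in sl_clades
                   if 1 < len(c) < 4}
        assert nj_bips == sl_bips

    def test_masked_matrix_rejected(self):
        m = matrix_from(["a", "b", "c"], [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        m.mask[0, 1] = m.mask[1, 0] = True
        with pytest.raises(TreeError, match="masked"):
            neighbor_joining(m)

    def test_too_few_taxa(self):
        with pytest.raises(TreeError):
            neighbor_joining(matrix_from(["a", "b"], [[0, 1], [1, 0]]))


class TestBootstrap:
    def _planted_msa(self, per_clade=4, diagnostic=30, noise=0):
        """Two clades separated by `diagnostic` fixed columns."""
        rng = np.random.default_rng(7)
        core = "".join(rng.choice(list("ACGT"), size=200))
        ids, rows = [], []
        for c, (old, new) in enumerate([("A", "A"), ("A", "G")]):
            for k in range(per_clade):
                row = list(core) + ["A"] * diagnostic
                if c == 1:
                    for j in range(diagnostic):
                        row[200 + j] = "G"
                # private mutation so rows are not identical
                row[k * 3] = "T"
                ids.append(f"c{c}x{k}")
                rows.append("".join(row))
        return MsaBlock(ids=ids, rows=rows)

    def test_planted_clades_high_support(self):
        msa = self._planted_msa()
        tree, skipped = bootstrap_support(msa, n_replicates=100, seed=42)
        assert skipped == 0
        supports = {}
        all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        for node in tree.preorder_internal_node_iter():
            if node is tree.seed_node or node.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            supports[side] = float(node.label)
        clade1 = frozenset(l for l in all_leaves if l.startswith("c1"))
        found = [v for k, v in supports.items()
                 if k == clade1 or k == frozenset(all_leaves - clade1)]
        assert found and found[0] >= 95

    def test_identical_sequences_no_crash(self):
        msa = MsaBlock(ids=[f"r{i}" for i in range(5)], rows=["ACGT" * 30] * 5)
        tree, skipped = bootstrap_support(msa, n_replicates=5, seed=1)
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(msa.ids)

    def test_single_replicate_quantized(self):
        msa = self._planted_msa()
        tree, _ = bootstrap_support(msa, n_replicates=1, seed=3)
        vals = [float(n.label) for n in tree.preorder_internal_node_iter()
                if n.label is not None]
        assert vals and all(v in (0.0, 100.0) for v in vals)

    def test_leaf_order_invariance(self):
        msa = self._planted_msa()
        rev = MsaBlock(ids=list(reversed(msa.ids)), rows=list(reversed(msa.rows)))
        t1, _ = bootstrap_support(msa, n_replicates=20, seed=9)
        t2, _ = bootstrap_support(rev, n_replicates=20, seed=9)
        def support_map(t):
            out = {}
            for n in t.preorder_internal_node_iter():
                if n.label is not None:
                    out[frozenset(lf.taxon.label for lf in n.leaf_iter())] = n.label
            return out
        anchored = lambda t: {k: v for k, v in support_map(t).items()}
        assert robinson_foulds(t1, t2) == 0


def allele(rid, seq, allele_id=None):
    return MarkerRecord(record_id=rid, species="x", genus="G", subfamily="SF",
                        provenance="HD", sequence=seq, allele_id=allele_id)


class TestAssignAlleles:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.pool_a = "".join(rng.choice(list("ACGT"), size=300))
        b = list(self.pool_a)
        for p in range(0, 300, 10):
            b[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[p]]
        self.pool_b = "".join(b)
        self.pools = {"poolA": [allele("refA", self.pool_a)],
                      "poolB": [allele("refB", self.pool_b)]}

    def test_identical_match(self):
        out = assign_alleles([allele("x", self.pool_a)], self.pools)
        assert out[0].assigned_genepool == "poolA"
        assert out[0].is_identical_match
        assert not out[0].putative_hybrid

    def test_planted_hybrid_flagged(self):
        alleles = [allele("hyb.a1", self.pool_a, "a1"),
                   allele("hyb.a2", self.pool_b, "a2")]
        out = assign_alleles(alleles, self.pools)
        assert {a.assigned_genepool for a in out} == {"poolA", "poolB"}
        assert all(a.putative_hybrid for a in out)
        assert out[0].individual_id == out[1].individual_id == "hyb"

    def test_non_hybrid_not_flagged(self):
        alleles = [allele("ind.a1", self.pool_a, "a1"),
                   allele("ind.a2", self.pool_a, "a2")]
        out = assign_alleles(alleles, self.pools)
        assert not any(a.putative_hybrid for a in out)

    def test_tie_goes_to_lexicographic_first(self):
        pools = {"zeta": [allele("r1", self.pool_a)],
                 "alpha": [allele("r2", self.pool_a)]}
        out = assign_alleles([allele("x", self.pool_a)], pools)
        assert out[0].assigned_genepool == "alpha"
        assert out[0].tie and out[0].margin == 0.0

    def test_margins_nonnegative(self):
        alleles = [allele(f"x{i}", self.pool_a if i % 2 else self.pool_b)
                   for i in range(4)]
        out = assign_alleles(alleles, self.pools)
        assert all(a.margin >= 0 for a in out)

    def test_empty_pool_rejected(self):
        with pytest.raises(TreeError):
            assign_alleles([allele("x", self.pool_a)], {"empty": []})
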