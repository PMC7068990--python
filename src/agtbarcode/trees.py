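"""Neighbor-joining trees, bootstrap supports and allele-to-genepool
assignment for hybrid detection.

NJ follows the Saitou–Nei agglomeration: at each step join the pair
minimising ``Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k)``.  Ties are
broken by the lexicographically smallest pair of node ids (an internal
node inherits the smallest leaf id beneath it), so topologies are
reproducible.  Negative branch lengths — a well-known NJ artefact — are
clamped to zero and flagged.  Additive matrices are reconstructed
exactly, topology and branch lengths.

Hybrid detection assigns each cloned allele to the genepool (a declared
set of reference records) containing its nearest reference by K2P
distance; an individual whose alleles land in two different genepools is
flagged as a putative hybrid, the signal a nuclear two-part barcode
offers for F1/allopolyploid origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np

from .distances import (DistanceMatrix, DistanceError, SaturationError,
                        distance_matrix, pairwise_k2p)
from .records import MarkerRecord, MsaBlock


class TreeError(ValueError):
    pass


@dataclass
class AlleleAssignment:
    allele_id: str
    individual_id: str
    assigned_genepool: str | None
    margin: float
    is_identical_match: bool
    distance: float
    tie: bool = False
    putative_hybrid: bool = False


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a complete distance matrix."""
    n = len(matrix.ids)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if not matrix.is_complete:
        raise TreeError(
            "matrix has masked entries; impute distances or drop the taxa involved")

    taxa = dendropy.TaxonNamespace(matrix.ids)
    nodes: dict[str, dendropy.Node] = {}
    for rid in matrix.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(rid))
        nodes[rid] = node
    # sort key per active node: smallest leaf id beneath it
    key = {rid: rid for rid in matrix.ids}
    D: dict[frozenset, float] = {}
    ids = matrix.ids
    for i in range(n):
        for j in range(i + 1, n):
            D[frozenset((ids[i], ids[j]))] = float(matrix.values[i, j])
    active = list(ids)
    negative_clamped = 0
    counter = 0

    def dist(x: str, y: str) -> float:
        return 0.0 if x == y else D[frozenset((x, y))]

    while len(active) > 3:
        m = len(active)
        r = {x: sum(dist(x, y) for y in active) for x in active}
        best = None
        best_pair = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                x, y = active[ii], active[jj]
                q = (m - 2) * dist(x, y) - r[x] - r[y]
                pair_key = tuple(sorted((key[x], key[y])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and pair_key < best[1]):
                    best = (q, pair_key)
                    best_pair = (x, y)
        x, y = best_pair
        d_xy = dist(x, y)
        lx = d_xy / 2.0 + (r[x] - r[y]) / (2.0 * (m - 2))
        ly = d_xy - lx
        if lx < 0:
            negative_clamped += 1
        if ly < 0:
            negative_clamped += 1
        lx = lx if lx > 0 else 0.0
        ly = ly if ly > 0 else 0.0
        counter += 1
        uid = f"__internal{counter}"
        parent = dendropy.Node()
        nodes[x].edge.length = lx
        nodes[y].edge.length = ly
        parent.add_child(nodes[x])
        parent.add_child(nodes[y])
        nodes[uid] = parent
        key[uid] = min(key[x], key[y])
        for z in active:
            if z in (x, y):
                continue
            D[frozenset((uid, z))] = (dist(x, z) + dist(y, z) - d_xy) / 2.0
        active = [z for z in active if z not in (x, y)] + [uid]

    a, b, c = sorted(active, key=lambda z: key[z])
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2.0
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2.0
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2.0
    center = dendropy.Node()
    for z, lz in ((a, la), (b, lb), (c, lc)):
        if lz < 0:
            negative_clamped += 1
        lz = lz if lz > 0 else 0.0
        nodes[z].edge.length = lz
        center.add_child(nodes[z])

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    tree.negative_branch_lengths_clamped = negative_clamped  # type: ignore[attr-defined]
    return tree


def _bipartitions(tree: dendropy.Tree, anchor: str) -> set[frozenset]:
    """Non-trivial leaf bipartitions, each normalised to the side without
    the anchor leaf."""
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(all_leaves - side)
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted RF distance via symmetric difference of bipartitions."""
    anchor = min(lf.taxon.label for lf in tree_a.leaf_node_iter())
    ba = _bipartitions(tree_a, anchor)
    bb = _bipartitions(tree_b, anchor)
    return len(ba ^ bb)


def bootstrap_support(msa: MsaBlock, n_replicates: int = 1000,
                      seed: int = 0) -> tuple[dendropy.Tree, int]:
    """NJ tree from an alignment with column-bootstrap supports.

    Columns are resampled with replacement per replicate; each replicate's
    NJ tree contributes its bipartitions.  Support on an internal edge of
    the full-data tree is the percentage of (non-skipped) replicates that
    contain the edge's bipartition, stored as the node label.  Replicates
    whose distance matrix has saturated (masked) pairs are skipped and
    counted; the count is returned alongside the tree.
    """
    if msa.n_rows < 4:
        raise TreeError("bootstrap needs at least 4 rows")
    if n_replicates < 1:
        raise TreeError("n_replicates must be >= 1")
    base_matrix = distance_matrix(msa)
    tree = neighbor_joining(base_matrix)
    anchor = min(msa.ids)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    used = 0
    skipped = 0
    ncol = msa.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r[j] for j in cols) for r in msa.rows]
        rep = distance_matrix(MsaBlock(ids=list(msa.ids), rows=rows))
        if not rep.is_complete:
            skipped += 1
            continue
        used += 1
        for bp in _bipartitions(neighbor_joining(rep), anchor):
            counts[bp] = counts.get(bp, 0) + 1

    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(all_leaves - side)
        if 1 < len(side) < len(all_leaves) - 1 and used > 0:
            node.label = f"{100.0 * counts.get(side, 0) / used:.0f}"
    return tree, skipped


def assign_alleles(alleles: Sequence[MarkerRecord],
                   genepools: dict[str, Sequence[MarkerRecord]],
                   distance_fn: Callable[[str, str], float] | None = None,
                   min_margin: float = 0.01) -> list[AlleleAssignment]:
    """Assign each allele to the genepool of its nearest reference.

    ``genepools`` maps a pool label (usually a candidate parent species)
    to its reference records.  Distances default to K2P over a banded
    global alignment with pairwise gap exclusion.  The margin is the gap
    between the best and second-best pool minima (infinite with a single
    pool); exact ties go to the lexicographically first pool and are
    flagged.  Alleles saturated against every reference stay unassigned.

    An individual whose alleles land in ≥2 pools *confidently* is flagged
    ``putative_hybrid`` on each of its assignments.  An assignment is
    confident when its margin is at least ``min_margin`` (default 0.01
    substitutions/site): an allele essentially equidistant from every
    candidate pool — typically one that belongs to none of them — carries
    no parentage signal and must not trigger hybrid calls.
    """
    if not genepools or any(len(v) == 0 for v in genepools.values()):
        raise TreeError("every genepool needs at least one reference record")
    if distance_fn is None:
        def distance_fn(a: str, b: str) -> float:
            return pairwise_k2p(a, b).d

    assignments: list[AlleleAssignment] = []
    for allele in alleles:
        pool_min: dict[str, float] = {}
        for label in sorted(genepools):
            dists = []
            for ref in genepools[label]:
                try:
                    dists.append(distance_fn(allele.sequence, ref.sequence))
                except (SaturationError, DistanceError):
                    continue
            if dists:
                pool_min[label] = min(dists)
        if not pool_min:
            assignments.append(AlleleAssignment(
                allele_id=allele.allele_id or allele.record_id,
                individual_id=allele.individual_id,
                assigned_genepool=None, margin=0.0,
                is_identical_match=False, distance=math.nan))
            continue
        ranked = sorted(pool_min.items(), key=lambda kv: (kv[1], kv[0]))
        best_label, best_d = ranked[0]
        tie = len(ranked) > 1 and math.isclose(ranked[1][1], best_d,
                                               rel_tol=0.0, abs_tol=1e-12)
        margin = (ranked[1][1] - best_d) if len(ranked) > 1 else math.inf
        assignments.append(AlleleAssignment(
            allele_id=allele.allele_id or allele.record_id,
            individual_id=allele.individual_id,
            assigned_genepool=best_label,
            margin=max(margin, 0.0),
            is_identical_match=best_d == 0.0,
            distance=best_d, tie=tie))

    by_ind: dict[str, set[str]] = {}
    for asg in assignments:
        if asg.assigned_genepool is not None and asg.margin >= min_margin:
            by_ind.setdefault(asg.individual_id, set()).add(asg.assigned_genepool)
    for asg in assignments:
        asg.putative_hybrid = len(by_ind.get(asg.individual_id, set())) >= 2
    return assignments


def assignments_to_rows(assignments: Iterable[AlleleAssignment]) -> list[dict]:
    return [{"allele_id": a.allele_id, "individual": a.individual_id,
             "genepool": a.assigned_genepool or "",
             "margin": "" if math.isinf(a.margin) else round(a.margin, 6),
             "identical": a.is_identical_match,
             "hybrid_flag": a.putative_hybrid} for a in assignments]
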