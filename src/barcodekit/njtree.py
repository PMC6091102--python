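"""Neighbor-joining trees, bootstrap support, rooting, and monophyly scoring.

NJ follows the classic agglomerative algorithm: at each step join the pair
(i, j) minimising Q(i, j) = (n-2)·d(i, j) - R(i) - R(j), where R is the
row sum over active nodes, with branch lengths from the standard split
formula.  Ties on Q are broken toward the lexicographically smallest pair
of minimum tip ids, so the result is deterministic across platforms.
Negative branch-length estimates are clamped to zero by default (the
clamped deficit is recorded on the tree).

Bootstrap support resamples alignment columns with replacement, rebuilds
the K2P + NJ tree per replicate, and scores each internal bipartition of
the original tree by the percentage of completed replicates containing it.
Replicates with any undefined (saturated) distance are skipped and
counted.  Support is keyed by bipartition, so it can be re-applied after
outgroup rooting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from barcodekit.alnstats import Alignment
from barcodekit.distances import DistanceMatrix, distance_matrix, k2p_matrix_from_codes
from barcodekit.errors import OutgroupError, UndefinedDistanceError


@dataclass
class _Active:
    node: dendropy.Node
    min_id: str


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> dendropy.Tree:
    """Build the unrooted NJ tree for a fully defined distance matrix.

    The returned dendropy tree has a trifurcating seed node (the standard
    unrooted representation), tip taxa labelled by record id, and an
    attribute ``clamped_deficit`` holding the total negative branch length
    that was clamped to zero (0.0 when none or when clamping is off).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 records")
    if not dm.is_fully_defined:
        bad = next((a, b) for a, b, d in dm.pairs() if math.isnan(d))
        raise UndefinedDistanceError(f"undefined distance for pair {bad}")

    tns = dendropy.TaxonNamespace()
    order = sorted(range(n), key=lambda i: dm.ids[i])
    active: list[_Active] = []
    for i in order:
        node = dendropy.Node(taxon=tns.new_taxon(dm.ids[i]))
        active.append(_Active(node, dm.ids[i]))
    d = dm.values[np.ix_(order, order)].astype(float).copy()
    deficit = 0.0

    def attach(parent: dendropy.Node, child: dendropy.Node, length: float) -> None:
        nonlocal deficit
        if clamp_negative and length < 0:
            deficit += -length
            length = 0.0
        parent.add_child(child)
        child.edge.length = length

    while len(active) > 3:
        m = len(active)
        r = d.sum(axis=1)
        # scan pairs in lexicographic order of (min_id_i, min_id_j); strict
        # improvement keeps the first minimiser, i.e. the smallest pair
        best_q, bi, bj = math.inf, -1, -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q:
                    best_q, bi, bj = q, i, j
        vi = 0.5 * d[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        vj = d[bi, bj] - vi
        parent = dendropy.Node()
        attach(parent, active[bi].node, vi)
        attach(parent, active[bj].node, vj)
        new_min = min(active[bi].min_id, active[bj].min_id)
        # distances from the new node to the remaining active nodes
        keep = [k for k in range(m) if k not in (bi, bj)]
        du = 0.5 * (d[bi, keep] + d[bj, keep] - d[bi, bj])
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = du
        d[:-1, -1] = du
        # keep the active list sorted by min tip id so the scan order stays
        # lexicographic; realign d to the sorted order
        new_active = [active[k] for k in keep] + [_Active(parent, new_min)]
        idx = sorted(range(len(new_active)), key=lambda k: new_active[k].min_id)
        d = d[np.ix_(idx, idx)]
        active = [new_active[k] for k in idx]

    root = dendropy.Node()
    d_ab, d_ac, d_bc = d[0, 1], d[0, 2], d[1, 2]
    attach(root, active[0].node, 0.5 * (d_ab + d_ac - d_bc))
    attach(root, active[1].node, 0.5 * (d_ab + d_bc - d_ac))
    attach(root, active[2].node, 0.5 * (d_ac + d_bc - d_ab))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    tree.clamped_deficit = deficit
    return tree


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def bipartition_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical tip-id sets.

    Each internal edge is represented by the side NOT containing the
    lexicographically smallest tip, so the encoding is orientation-free.
    """
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = min(all_tips)
    n = len(all_tips)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def path_distance_matrix(tree: dendropy.Tree, ids: list[str]) -> np.ndarray:
    """Tip-to-tip path-length matrix in the order of ``ids``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return out


@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    support: dict[frozenset[str], float]  # bipartition -> percent
    n_completed: int
    n_skipped: int


def bootstrap_support(
    aln: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    clamp_negative: bool = True,
) -> BootstrapResult:
    """Column-resampling bootstrap support for the NJ tree of an alignment.

    With ``n_replicates == 0`` the original tree is returned with no
    support values.  Saturated replicates (any undefined K2P entry) are
    skipped; support denominators use completed replicates only.  Raises
    if every replicate is saturated.
    """
    dm = distance_matrix(aln)
    tree = neighbor_joining(dm, clamp_negative)
    target = bipartition_sets(tree)
    if n_replicates == 0:
        return BootstrapResult(tree, {}, 0, 0)
    rng = np.random.default_rng(seed)
    hits = {bp: 0 for bp in target}
    completed = skipped = 0
    species_of = aln.species_of()
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.ncols, size=aln.ncols)
        vals = k2p_matrix_from_codes(aln.resample_columns(cols))
        if np.isnan(vals).any():
            skipped += 1
            continue
        rep_dm = DistanceMatrix(aln.ids, vals, species_of)
        rep_bps = bipartition_sets(neighbor_joining(rep_dm, clamp_negative))
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
        completed += 1
    if completed == 0:
        raise UndefinedDistanceError("all bootstrap replicates were saturated")
    support = {bp: 100.0 * h / completed for bp, h in hits.items()}
    annotate_support(tree, support)
    return BootstrapResult(tree, support, completed, skipped)


def annotate_support(tree: dendropy.Tree, support: dict[frozenset[str], float]) -> None:
    """Attach ``node.support`` (percent) to internal nodes by bipartition lookup."""
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = min(all_tips)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if ref in side:
            side = all_tips - side
        node.support = support.get(side)


def root_with_outgroup(tree: dendropy.Tree, outgroup_tips: set[str]) -> dendropy.Tree:
    """Root at the midpoint of the edge separating the outgroup tips.

    The input tree is not modified.  Raises :class:`OutgroupError` when an
    outgroup tip is absent or the outgroup set is not one side of any
    single edge (i.e. not clade-compatible on the unrooted tree).
    """
    all_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(outgroup_tips) - all_tips
    if missing:
        raise OutgroupError(f"outgroup tips absent from tree: {sorted(missing)}")
    og = frozenset(outgroup_tips)
    if not og or og == frozenset(all_tips):
        raise OutgroupError("outgroup must be a proper non-empty subset of tips")
    rooted = tree.clone(depth=1)
    target = None
    for node in rooted.preorder_node_iter():
        if node is rooted.seed_node:
            continue
        side = _leafset(node)
        if side == og or side == frozenset(all_tips) - og:
            target = node.edge
            break
    if target is None:
        raise OutgroupError(
            f"outgroup {sorted(og)} does not form one side of any edge "
            "(not monophyletic on the unrooted tree)"
        )
    length = target.length or 0.0
    rooted.reroot_at_edge(target, length1=length / 2.0, length2=length / 2.0)
    rooted.is_rooted = True
    return rooted


def species_monophyly(
    tree: dendropy.Tree,
    species_of: dict[str, str],
    count_singletons: bool = False,
    exclude_species: set[str] | None = None,
) -> tuple[dict[str, bool | None], float]:
    """Per-species monophyly on a rooted tree and the discrimination rate.

    A species with >= 2 tips is monophyletic iff the MRCA of its tips has
    exactly those tips as leaf descendants.  Singletons get verdict None
    and are excluded from the denominator unless ``count_singletons``
    treats them as (vacuously) monophyletic.  Returns ({species: verdict},
    rate-in-percent); the rate is NaN when nothing is assessable.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unknown = [t for t in tips if t not in species_of]
    if unknown:
        raise ValueError(f"tips with unknown species: {unknown}")
    exclude = exclude_species or set()
    groups: dict[str, list[str]] = {}
    for t in tips:
        groups.setdefault(species_of[t], []).append(t)
    verdicts: dict[str, bool | None] = {}
    n_mono = n_assessable = 0
    for sp, members in sorted(groups.items()):
        if sp in exclude:
            continue
        if len(members) < 2:
            verdicts[sp] = None
            if count_singletons:
                n_assessable += 1
                n_mono += 1
            continue
        mrca = tree.mrca(taxon_labels=members)
        mono = len(mrca.leaf_nodes()) == len(members)
        verdicts[sp] = mono
        n_assessable += 1
        n_mono += mono
    rate = 100.0 * n_mono / n_assessable if n_assessable else math.nan
    return verdicts, rate


def random_additive_tree(
    n_tips: int,
    rng: np.random.Generator,
    min_bl: float = 0.05,
    max_bl: float = 0.5,
) -> tuple[dendropy.Tree, list[str]]:
    """Random unrooted binary tree with uniform branch lengths.

    Its tip-to-tip path matrix is additive by construction, so NJ must
    recover both the topology and the branch lengths exactly — the
    standard consistency check for an NJ implementation.
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips for a non-trivial topology")
    ids = [f"t{i:02d}" for i in range(n_tips)]
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    for i in range(3):
        root.new_child(taxon=tns.new_taxon(ids[i]),
                       edge_length=float(rng.uniform(min_bl, max_bl)))
    for i in range(3, n_tips):
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        e = edges[int(rng.integers(len(edges)))]
        parent, child = e.tail_node, e.head_node
        total = e.length
        cut = float(rng.uniform(0.25, 0.75))
        parent.remove_child(child)
        mid = parent.new_child(edge_length=total * cut)
        mid.add_child(child)
        child.edge.length = total * (1.0 - cut)
        mid.new_child(taxon=tns.new_taxon(ids[i]),
                      edge_length=float(rng.uniform(min_bl, max_bl)))
    tree.is_rooted = False
    return tree, ids


def to_newick(tree: dendropy.Tree, min_support: float | None = 50.0) -> str:
    """Newick with branch lengths; integer support labels on internal nodes.

    Supports below ``min_support`` are omitted (``None`` keeps all).
    """
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        sup = getattr(node, "support", None)
        if sup is not None and (min_support is None or sup >= min_support):
            node.label = str(int(round(sup)))
        else:
            node.label = None
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"
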