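"""Gene-tree construction and reconciliation with a species tree.

The pipeline's trees are built by neighbor joining on pairwise distances,
rooted at the position minimizing implied gene duplications (ties broken by
losses), and labeled by standard LCA reconciliation: an internal node is a
duplication if it maps to the same species-tree node as one of its
children, a speciation otherwise.  Families are delineated by splitting
labeled trees at a designated speciation node of the species tree.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

import numpy as np

from .core_io import Node, SpeciesTree, Tree
from .molecular_rates import (
    CODONS,
    _GENETIC_CODE,
    encode_codons,
    ng86_pair,
    species_of_leaf,
)

logger = logging.getLogger("dupscape")

__all__ = [
    "pairwise_distance_matrix",
    "nj_tree",
    "root_min_dup",
    "reconcile_label",
    "split_at_speciation",
    "unrooted_edges",
    "root_on_edge",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

_AA_OF_CODON = np.array([_GENETIC_CODE[c] for c in CODONS])


def _aa_poisson(e1: np.ndarray, e2: np.ndarray) -> float:
    """Poisson-corrected amino-acid distance from encoded codon arrays."""
    ok = (e1 >= 0) & (e2 >= 0)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    p = float((_AA_OF_CODON[e1[ok]] != _AA_OF_CODON[e2[ok]]).mean())
    if p >= 1.0:
        return float("nan")
    return -float(np.log(1.0 - p))


def pairwise_distance_matrix(
    alignment: dict[str, str],
    metric: str = "aa_pdist_poisson",
) -> tuple[list[str], np.ndarray]:
    """Symmetric distance matrix over a codon alignment.

    ``metric`` is ``aa_pdist_poisson`` (Poisson-corrected amino-acid
    p-distance, robust at depth, used to feed NJ) or ``ds_ng86``.
    Saturated/undefined pairs are imputed with the matrix maximum (logged);
    if every pair is undefined this raises.
    """
    labels = list(alignment)
    if len(labels) < 3:
        raise ValueError("distance matrix requires >= 3 sequences")
    enc = {k: encode_codons(v) for k, v in alignment.items()}
    n = len(labels)
    D = np.zeros((n, n))
    n_undef = 0
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "aa_pdist_poisson":
                d = _aa_poisson(enc[labels[i]], enc[labels[j]])
            elif metric == "ds_ng86":
                d = ng86_pair(enc[labels[i]], enc[labels[j]]).dS
            else:
                raise ValueError(f"unknown metric {metric!r}")
            if not np.isfinite(d):
                n_undef += 1
                d = np.nan
            D[i, j] = D[j, i] = d
    if np.isnan(D).all(axis=None) or not np.isfinite(np.nanmax(D)):
        raise ValueError("all pairs saturated; no usable distances")
    if n_undef:
        mx = float(np.nanmax(D))
        logger.info("imputing %d saturated pairs with matrix max %.4f", n_undef, mx)
        D = np.where(np.isnan(D), mx, D)
    np.fill_diagonal(D, 0.0)
    return labels, D


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: np.ndarray, labels: Sequence[str]) -> Tree:
    """Classic Saitou-Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken by the smallest
    (i, j) index pair in the current working order.  Negative branch
    lengths are clamped to zero with the deficit moved to the sibling
    branch.  The result is an *unrooted* tree represented with a
    trifurcating root node; see :func:`root_min_dup` for rooting.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    n = D.shape[0]
    if n < 3:
        raise ValueError("NJ requires >= 3 taxa")
    if len(labels) != n:
        raise ValueError("labels/matrix size mismatch")

    nodes: list[Node] = [Node(name=l) for l in labels]
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties by smallest (i, j) position pair
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ties = ties[ties[:, 0] < ties[:, 1]]
        i_, j_ = min(map(tuple, ties))
        gi, gj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = Node()
        a, b = nodes[gi], nodes[gj]
        a.length, b.length = float(li), float(lj)
        parent.add_child(a)
        parent.add_child(b)
        # distances from the new node
        newrow = np.zeros(D.shape[0] + 1)
        for k_ in range(m):
            if k_ in (i_, j_):
                continue
            gk = active[k_]
            newrow[gk] = 0.5 * (sub[i_, k_] + sub[j_, k_] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # final three-way join (3-point formulas)
    gi, gj, gk = active
    dij, dik, djk = D[gi, gj], D[gi, gk], D[gj, gk]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = Node()
    for g, l in ((gi, li), (gj, lj), (gk, lk)):
        nodes[g].length = float(max(l, 0.0))
        root.add_child(nodes[g])
    return Tree(root)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def unrooted_edges(tree: Tree) -> list[tuple[Node, Node]]:
    """Edges of an unrooted-representation tree, in deterministic preorder.

    Each edge is (parent, child) in the current representation.
    """
    return [(n.parent, n) for n in tree.preorder() if n.parent is not None]


def _rehang(node: Node, exclude: Node) -> Optional[Node]:
    """Rebuild the tree hanging 'upward' of ``node``, excluding ``exclude``.

    Returns a Node whose subtree contains everything on the far side of
    ``node`` from ``exclude``, or None when nothing remains (root with a
    single other child collapses).
    """
    rest = [c for c in node.children if c is not exclude]
    up = None
    if node.parent is not None:
        up = _rehang(node.parent, node)
        if up is not None:
            # the edge above node is reassigned below 'up'; when an old
            # degree-2 root collapsed, 'up' already carries part of it
            up.length = (up.length or 0.0) + (node.length or 0.0)
    parts = [c.copy() for c in rest]
    if up is not None:
        parts.append(up)
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]
    new = Node(length=0.0)
    for p in parts:
        new.add_child(p)
    while len(new.children) > 2:  # trifurcating old root: keep binary
        a = new.children.pop()
        b = new.children.pop()
        m = Node(length=0.0)
        m.add_child(a)
        m.add_child(b)
        new.add_child(m)
        m.parent = new
    return new


def root_on_edge(tree: Tree, edge: tuple[Node, Node]) -> Tree:
    """Root the unrooted tree on the given edge, splitting its length."""
    parent, child = edge
    half = (child.length or 0.0) / 2.0
    below = child.copy()
    below.length = half
    above = _rehang(parent, child)
    if above is None:
        raise ValueError("cannot root on a pendant edge of a 2-taxon tree")
    above.length = (above.length or 0.0) + half
    root = Node()
    root.add_child(below)
    root.add_child(above)
    return Tree(root)


class _SpeciesIndex:
    """Constant-ish time LCA on the species tree via parent pointers."""

    def __init__(self, stree: SpeciesTree):
        self.stree = stree
        self.depth: dict[int, int] = {}
        for node in stree.preorder():
            self.depth[id(node)] = (
                0 if node.parent is None else self.depth[id(node.parent)] + 1
            )

    def lca(self, a: Node, b: Node) -> Node:
        while a is not b:
            if self.depth[id(a)] >= self.depth[id(b)]:
                a = a.parent
            else:
                b = b.parent
        return a

    def edge_dist(self, anc: Node, desc: Node) -> int:
        return self.depth[id(desc)] - self.depth[id(anc)]


def reconcile_label(
    tree: Tree,
    stree: SpeciesTree,
    species_of: Callable[[str], str] = species_of_leaf,
) -> tuple[int, int]:
    """Label a rooted binary gene tree by LCA reconciliation.

    Sets ``species_map`` on every node and ``event`` on internal nodes
    (duplication iff the node maps to the same species-tree node as at
    least one child).  Returns (duplication count, loss count); losses are
    counted as path-length excess of the child map below the parent map.
    """
    if not tree.is_binary():
        raise ValueError("gene tree must be binary for reconciliation")
    idx = _SpeciesIndex(stree)
    known = stree.species()
    for node in tree.postorder():
        if node.is_leaf:
            sp = species_of(node.name)
            if sp not in known:
                raise KeyError(f"leaf species {sp!r} absent from species tree")
            node.species_map = stree.leaf(sp)
        else:
            a, b = node.children
            node.species_map = idx.lca(a.species_map, b.species_map)
    n_dup = 0
    n_loss = 0
    for node in tree.preorder():
        if node.is_leaf:
            node.event = None
            continue
        dup = any(c.species_map is node.species_map for c in node.children)
        node.event = "duplication" if dup else "speciation"
        if dup:
            n_dup += 1
        for c in node.children:
            d = idx.edge_dist(node.species_map, c.species_map)
            n_loss += d if dup else max(d - 1, 0)
    return n_dup, n_loss


def root_min_dup(
    tree: Tree,
    stree: SpeciesTree,
    species_of: Callable[[str], str] = species_of_leaf,
) -> Tree:
    """Root an unrooted gene tree minimizing implied duplications.

    Every edge is evaluated as a root position via LCA reconciliation; ties
    are broken by fewer losses, then by the deepest species_map of the
    resulting root (map as far from the species-tree root as possible),
    then by the smallest edge index in deterministic preorder.  The
    returned tree is rooted, labeled, and reconciled.
    """
    edges = unrooted_edges(tree)
    if not edges:
        raise ValueError("tree has no edges")
    idx = _SpeciesIndex(stree)
    best = None
    best_key = None
    for e_i, edge in enumerate(edges):
        rooted = root_on_edge(tree, edge)
        n_dup, n_loss = reconcile_label(rooted, stree, species_of)
        root_depth = idx.depth[id(rooted.root.species_map)]
        key = (n_dup, n_loss, -root_depth, e_i)
        if best_key is None or key < best_key:
            best_key = key
            best = rooted
    return best


def split_at_speciation(
    tree: Tree,
    target: Node,
    required: set[str],
    species_of: Callable[[str], str] = species_of_leaf,
) -> list[Tree]:
    """Split a labeled gene tree into families at a species-tree node.

    Returns the maximal clades whose root maps to ``target`` and is a
    speciation node (leaves mapping to ``target`` cannot qualify), keeping
    only clades whose leaf species cover ``required``.  Returned families
    are copies; their leaf sets are disjoint by construction.
    """
    families: list[Tree] = []

    def walk(node: Node) -> None:
        if node.species_map is target and node.event == "speciation":
            species = {species_of(l.name) for l in node.leaves()}
            if required <= species:
                families.append(Tree(node.copy()))
            return
        for c in node.children:
            walk(c)

    walk(tree.root)
    return families
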