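"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import dupscape as d
from dupscape.core_io import Node, Tree


@pytest.fixture(scope="session")
def species_tree():
    return d.default_species_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


# ---------------------------------------------------------------------------
# Random tree generators (independent of the package's simulator)
# ---------------------------------------------------------------------------

def random_binary_tree(labels, rng, min_len=0.05, max_len=1.0) -> Tree:
    """Random rooted binary tree over given leaf labels with positive lengths."""
    nodes = [Node(name=l) for l in labels]
    for n in nodes:
        n.length = float(rng.uniform(min_len, max_len))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(min_len, max_len)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    nodes[0].length = None
    return Tree(nodes[0])


def tree_distances(tree: Tree) -> tuple[list, np.ndarray]:
    """Additive leaf-to-leaf path-length matrix."""
    leaves = tree.leaves()
    labels = [l.name for l in leaves]

    def path(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    paths = {l.name: path(l) for l in leaves}
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[labels[i]], paths[labels[j]]
            anc = {id(x) for x in pa}
            k = next(x for x in pb if id(x) in anc)
            da = 0.0
            for x in pa:
                if x is k:
                    break
                da += x.length or 0.0
            db = 0.0
            for x in pb:
                if x is k:
                    break
                db += x.length or 0.0
            D[i, j] = D[j, i] = da + db
    return labels, D


def unrooted_splits(tree: Tree) -> set:
    """Non-trivial bipartitions of the leaf set (unrooted topology)."""
    all_leaves = tree.leaf_names()
    splits = set()
    for node in tree.preorder():
        if node.parent is None:
            continue
        side = node.leaf_names()
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset({side, all_leaves - side}))
    return splits


# ---------------------------------------------------------------------------
# Independent NG86 enumeration oracle
# ---------------------------------------------------------------------------

_NT = "TCAG"
_CODE = {}
_bases = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_CODE.update(_bases)
ORACLE_STOPS = {c for c, a in _CODE.items() if a == "*"}
SENSE_CODONS = sorted(c for c in _CODE if c not in ORACLE_STOPS)


def oracle_syn_sites(codon: str) -> float:
    """Fractional synonymous sites of one codon, by direct enumeration."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for alt in _NT:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut in ORACLE_STOPS:
                continue
            valid += 1
            if _CODE[mut] == _CODE[codon]:
                syn += 1
        if valid:
            total += syn / valid
    return total


def oracle_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for a codon pair by enumerating minimal pathways."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(pos):
        cur = c1
        syn = non = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in ORACLE_STOPS and nxt != c2:
                blocked = True
            if _CODE[cur] == _CODE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        results.append((blocked, syn, non))
    usable = [(s, n) for b, s, n in results if not b]
    if not usable:
        usable = [(s, n) for _, s, n in results]
    return (
        float(np.mean([s for s, _ in usable])),
        float(np.mean([n for _, n in usable])),
    )
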