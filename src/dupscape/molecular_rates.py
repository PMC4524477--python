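"""Pairwise synonymous/nonsynonymous rates (NG86 counting) and node dating.

The counting method follows Nei & Gojobori (1986):

* per codon, each of the three positions contributes a fractional synonymous
  site count ``(# synonymous one-step changes) / (# non-stop one-step
  changes)`` at that position; sites are averaged over the two sequences of
  a pair;
* observed differences between two codons are resolved by averaging the
  synonymous/nonsynonymous step counts over all minimal substitution
  pathways, excluding pathways that pass through a stop codon (if every
  pathway is blocked, the average falls back to all pathways);
* proportions are corrected for multiple hits with the Jukes-Cantor formula
  ``d = -(3/4) ln(1 - (4/3) p)``; pairs where the correction is undefined
  (``1 - (4/3) p <= 0``) are flagged saturated and carry no distance.

Codons containing gaps, ambiguity characters, or stops are skipped pairwise.
Node dates are mean pairwise dS values over the descendant pairs whose
gene-tree LCA is the node: same-species (paralog) pairs for duplication
nodes, cross-species (ortholog) pairs for speciation nodes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .core_io import Node, Tree

logger = logging.getLogger("dupscape")

__all__ = [
    "PairwiseRates",
    "NodeDate",
    "GeneFamilyStats",
    "codon_tables",
    "encode_codons",
    "ng86_pair",
    "ng86_counts",
    "date_duplication_node",
    "date_speciation_node",
    "date_tree_nodes",
    "filter_duplication_nodes",
    "family_omega",
    "nearest_paralog_check",
    "species_of_leaf",
]

NUCS = "TCAG"
CODONS = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOPS = frozenset(c for c, aa in _GENETIC_CODE.items() if aa == "*")


def _is_syn(c1: str, c2: str) -> bool:
    return _GENETIC_CODE[c1] == _GENETIC_CODE[c2]


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over minimal pathways.

    Pathways through stop codons are excluded; if all are blocked the
    average is taken over every pathway instead.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            if nxt in STOPS and nxt != c2:
                blocked = True
            cur = nxt
        syn = sum(1.0 for a, b in steps if _is_syn(a, b))
        paths.append((blocked, syn, len(steps) - syn))
    usable = [(s, n) for blocked, s, n in paths if not blocked]
    if not usable:
        usable = [(s, n) for _, s, n in paths]
    syn = float(np.mean([s for s, _ in usable]))
    return syn, float(len(diff_pos)) - syn


_TABLES: Optional[dict] = None


def codon_tables() -> dict:
    """Lazily build and cache the NG86 lookup tables.

    Returns a dict with:
      ``syn_sites``  (64,)  fractional synonymous sites per codon (NaN: stop)
      ``sd``, ``nd`` (64,64) pathway-averaged syn/nonsyn differences
      ``sense``      (64,)  bool mask of sense codons
    """
    global _TABLES
    if _TABLES is not None:
        return _TABLES
    syn_sites = np.full(64, np.nan)
    sense = np.zeros(64, dtype=bool)
    for i, codon in enumerate(CODONS):
        if codon in STOPS:
            continue
        sense[i] = True
        total = 0.0
        for pos in range(3):
            syn = 0
            valid = 0
            for alt in NUCS:
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1:]
                if mut in STOPS:
                    continue
                valid += 1
                if _is_syn(codon, mut):
                    syn += 1
            total += syn / valid if valid else 0.0
        syn_sites[i] = total
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for i, c1 in enumerate(CODONS):
        if c1 in STOPS:
            continue
        for j, c2 in enumerate(CODONS):
            if c2 in STOPS:
                continue
            s, n = _pathway_counts(c1, c2)
            sd[i, j] = s
            nd[i, j] = n
    _TABLES = {"syn_sites": syn_sites, "sd": sd, "nd": nd, "sense": sense}
    return _TABLES


def encode_codons(seq: str) -> np.ndarray:
    """Encode a codon sequence as int indices; -1 marks unusable codons.

    Codons containing gaps or non-ACGT characters, and stop codons, are
    marked unusable (they are skipped pairwise downstream).
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    seq = seq.upper().replace("U", "T")
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        codon = seq[3 * k: 3 * k + 3]
        idx = CODON_INDEX.get(codon)
        if idx is not None and codon not in STOPS:
            out[k] = idx
    return out


@dataclass
class PairwiseRates:
    """NG86 quantities for one codon-sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when saturated
    dN: float  # NaN when saturated
    saturated: bool  # dS undefined
    dn_saturated: bool = False
    n_codons: int = 0


def _jc_correct(p: float) -> tuple[float, bool]:
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return float("nan"), True
    return -0.75 * float(np.log(arg)), False


def ng86_counts(e1: np.ndarray, e2: np.ndarray) -> tuple[int, float, float, float]:
    """Vectorized (compared codons, S sites, Sd, Nd) for two encoded sequences."""
    if e1.shape != e2.shape:
        raise ValueError("encoded sequences differ in codon count")
    tab = codon_tables()
    ok = (e1 >= 0) & (e2 >= 0)
    a, b = e1[ok], e2[ok]
    ncod = int(ok.sum())
    if ncod == 0:
        return 0, 0.0, 0.0, 0.0
    S = 0.5 * float(tab["syn_sites"][a].sum() + tab["syn_sites"][b].sum())
    Sd = float(tab["sd"][a, b].sum())
    Nd = float(tab["nd"][a, b].sum())
    return ncod, S, Sd, Nd


def ng86_pair(c1: str | np.ndarray, c2: str | np.ndarray) -> PairwiseRates:
    """NG86 rates for one pair of equal-length, in-frame codon sequences."""
    e1 = encode_codons(c1) if isinstance(c1, str) else c1
    e2 = encode_codons(c2) if isinstance(c2, str) else c2
    if e1.shape != e2.shape:
        raise ValueError("aligned codon sequences differ in length")
    ncod, S, Sd, Nd = ng86_counts(e1, e2)
    if ncod == 0:
        nan = float("nan")
        return PairwiseRates(0.0, 0.0, 0.0, 0.0, nan, nan, nan, nan, True, True, 0)
    N = 3.0 * ncod - S
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    dS, sat_s = _jc_correct(pS) if np.isfinite(pS) else (float("nan"), True)
    dN, sat_n = _jc_correct(pN) if np.isfinite(pN) else (float("nan"), True)
    return PairwiseRates(S, N, Sd, Nd, pS, pN, dS, dN, sat_s, sat_n, ncod)


# ---------------------------------------------------------------------------
# Node dating
# ---------------------------------------------------------------------------

def species_of_leaf(name: str, delimiter: str = "|") -> str:
    """Default convention: gene leaves are named ``Species|gene``."""
    return name.split(delimiter)[0]


@dataclass
class NodeDate:
    """A dated gene-tree node."""

    family_id: str
    node_id: str
    node_kind: str  # "duplication" | "speciation"
    ds_mean: Optional[float]
    pair_count: int
    passes_filters: bool = False
    species_map_leafset: Optional[frozenset] = None
    node: Optional[Node] = None


@dataclass
class GeneFamilyStats:
    """Family-wide selection summary."""

    family_id: str
    omega: Optional[float]
    n_members: int
    n_duplication_nodes: int
    total_dN: float
    total_dS: float
    expression_category: Optional[str] = None
    lineage_specific: Optional[bool] = None


def _cross_child_pairs(node: Node) -> list[tuple[Node, Node]]:
    """Leaf pairs whose LCA is exactly this (binary) node."""
    if len(node.children) != 2:
        return []
    left = node.children[0].leaves()
    right = node.children[1].leaves()
    return [(x, y) for x in left for y in right]


def _mean_pairwise_ds(
    pairs: Sequence[tuple[Node, Node]],
    encoded: dict[str, np.ndarray],
) -> tuple[Optional[float], int]:
    vals = []
    for x, y in pairs:
        r = ng86_pair(encoded[x.name], encoded[y.name])
        if not r.saturated and np.isfinite(r.dS):
            vals.append(r.dS)
    if not vals:
        return None, 0
    return float(np.mean(vals)), len(vals)


def date_duplication_node(
    node: Node,
    encoded: dict[str, np.ndarray],
    family_id: str = "",
    node_id: str = "",
    species_of: Callable[[str], str] = species_of_leaf,
) -> NodeDate:
    """Date a duplication node by mean pairwise dS of intraspecies paralogs.

    Only leaf pairs that are conspecific and whose LCA is this node enter
    the mean; saturated pairs are excluded.  A node with no usable pair is
    returned undated (``ds_mean`` None, ``pair_count`` 0).
    """
    pairs = [
        (x, y) for x, y in _cross_child_pairs(node)
        if species_of(x.name) == species_of(y.name)
    ]
    ds_mean, n = _mean_pairwise_ds(pairs, encoded)
    return NodeDate(family_id, node_id, "duplication", ds_mean, n, node=node)


def date_speciation_node(
    node: Node,
    encoded: dict[str, np.ndarray],
    family_id: str = "",
    node_id: str = "",
    species_of: Callable[[str], str] = species_of_leaf,
) -> NodeDate:
    """Date a speciation node by mean pairwise dS of cross-species orthologs."""
    pairs = [
        (x, y) for x, y in _cross_child_pairs(node)
        if species_of(x.name) != species_of(y.name)
    ]
    ds_mean, n = _mean_pairwise_ds(pairs, encoded)
    sp_set = None
    if node.species_map is not None:
        sp_set = node.species_map.leaf_names()
    return NodeDate(
        family_id, node_id, "speciation", ds_mean, n, species_map_leafset=sp_set,
        node=node,
    )


def date_tree_nodes(
    tree: Tree,
    alignment: dict[str, str] | dict[str, np.ndarray],
    family_id: str = "",
    species_of: Callable[[str], str] = species_of_leaf,
) -> list[NodeDate]:
    """Date every labeled internal node of a reconciled gene tree."""
    encoded = {
        k: (encode_codons(v) if isinstance(v, str) else v)
        for k, v in alignment.items()
    }
    out: list[NodeDate] = []
    for i, node in enumerate(tree.preorder()):
        if node.is_leaf or node.event not in ("duplication", "speciation"):
            continue
        nid = f"n{i}"
        if node.event == "duplication":
            out.append(
                date_duplication_node(node, encoded, family_id, nid, species_of)
            )
        else:
            out.append(
                date_speciation_node(node, encoded, family_id, nid, species_of)
            )
    return out


def filter_duplication_nodes(
    dates: Sequence[NodeDate], ds_min: float = 0.01, ds_max: float = 2.0
) -> list[NodeDate]:
    """Keep dated duplication nodes with ``ds_min <= ds_mean < ds_max``.

    The lower bound guards against allelic variants / isoforms being read
    as paralogs, the upper against saturation.  Boundary semantics: the
    lower bound is kept, the upper dropped.
    """
    out = []
    for d in dates:
        if d.node_kind != "duplication" or d.ds_mean is None:
            continue
        ok = ds_min <= d.ds_mean < ds_max
        d.passes_filters = ok
        if ok:
            out.append(d)
    log_in = sum(1 for d in dates if d.node_kind == "duplication")
    logger.info("duplication-node dS filter: %d -> %d", log_in, len(out))
    return out


def family_omega(
    alignment: dict[str, str] | dict[str, np.ndarray],
    family_id: str = "",
    n_duplication_nodes: int = 0,
) -> GeneFamilyStats:
    """Family-wide omega: mean pairwise dN / mean pairwise dS.

    Pairs with saturated dS (or undefined dN) are excluded.  Omega is
    missing (None) when fewer than 2 usable pairs remain or mean dS is 0 —
    a 0/0 is reported as missing, never infinity.  ``total_dN``/``total_dS``
    are sums of the usable pairwise corrected values, a proxy for tree
    length.
    """
    encoded = {
        k: (encode_codons(v) if isinstance(v, str) else v)
        for k, v in alignment.items()
    }
    names = sorted(encoded)
    if len(names) < 2:
        raise ValueError("family_omega requires >= 2 sequences")
    dn_vals, ds_vals = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = ng86_pair(encoded[names[i]], encoded[names[j]])
            if r.saturated or r.dn_saturated:
                continue
            if np.isfinite(r.dS) and np.isfinite(r.dN):
                ds_vals.append(r.dS)
                dn_vals.append(r.dN)
    total_dS = float(np.sum(ds_vals)) if ds_vals else 0.0
    total_dN = float(np.sum(dn_vals)) if dn_vals else 0.0
    omega: Optional[float] = None
    if len(ds_vals) >= 2:
        mean_ds = float(np.mean(ds_vals))
        mean_dn = float(np.mean(dn_vals))
        if mean_ds > 0:
            omega = mean_dn / mean_ds
    return GeneFamilyStats(
        family_id=family_id,
        omega=omega,
        n_members=len(names),
        n_duplication_nodes=n_duplication_nodes,
        total_dN=total_dN,
        total_dS=total_dS,
    )


def nearest_paralog_check(
    tree: Tree,
    alignment: dict[str, str] | dict[str, np.ndarray],
    species_of: Callable[[str], str] = species_of_leaf,
) -> list[float]:
    """dS of conspecific leaf pairs that are mutual nearest neighbors.

    Nearness is patristic (branch-length) distance on the gene tree.  Used
    as the control that recent within-species duplicates sit at small dS.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        return []
    # patristic distances via root paths
    def path(n: Node) -> list[Node]:
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    paths = {leaf.name: path(leaf) for leaf in leaves}

    def dist(a: Node, b: Node) -> float:
        pa, pb = paths[a.name], paths[b.name]
        seen = {id(n): i for i, n in enumerate(pa)}
        for j, n in enumerate(pb):
            if id(n) in seen:
                i = seen[id(n)]
                return sum(x.length or 0.0 for x in pa[:i]) + sum(
                    x.length or 0.0 for x in pb[:j]
                )
        raise RuntimeError("disconnected leaves")

    n = len(leaves)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = dist(leaves[i], leaves[j])
    np.fill_diagonal(dmat, np.inf)
    nn = dmat.argmin(axis=1)
    encoded = {
        k: (encode_codons(v) if isinstance(v, str) else v)
        for k, v in alignment.items()
    }
    out = []
    for i in range(n):
        j = int(nn[i])
        if j <= i or nn[j] != i:
            continue
        if species_of(leaves[i].name) != species_of(leaves[j].name):
            continue
        r = ng86_pair(encoded[leaves[i].name], encoded[leaves[j].name])
        if np.isfinite(r.dS):
            out.append(r.dS)
    return out
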