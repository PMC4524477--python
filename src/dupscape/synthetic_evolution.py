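"""Synthetic gene-family evolution with the statistical structure the
analysis assumes.

Families evolve along a dated arachnid species tree.  Node dates are in
*pairwise-dS* units: two lineages diverging at a node of date ``d`` are
expected to show a synonymous distance of ``d`` between their extant
sequences (each lineage accrues ``d/2``).  On top of the speciation
backbone the generator supports:

* one optional large-scale (whole-genome-like) duplication event at a fixed
  date on a chosen species-tree branch, retained in both copies with a
  probability that may differ between silk-specific (SST) and other
  families — the hypothesized retention bias;
* small (single-gene) duplications as a Poisson process along branches;
  the extra copy's lineage is subject to Poisson loss, so surviving small
  duplicates skew young, emulating the young peak of empirical dS
  distributions while keeping the species backbone intact;
* per-family lognormal rate multipliers (mean 1) producing the spread of
  mixture components;
* a simplified codon substitution process in which synonymous changes
  accrue at rate 1 per NG86 synonymous site per unit branch length and
  nonsynonymous changes at ``omega`` times that rate (stop codons
  forbidden), so simulated branch lengths are directly comparable to NG86
  dS estimates.

Sequences are gap-free true alignments; indels are not simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import AbundanceTable, Node, SpeciesTree, Transcript, Tree, parse_newick
from .molecular_rates import CODONS, STOPS, _GENETIC_CODE, codon_tables

logger = logging.getLogger("dupscape")

__all__ = [
    "DEFAULT_SPECIES_TREE_NEWICK",
    "default_species_tree",
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_gene_trees",
    "simulate_codon_alignment",
    "simulate_expression_and_abundance",
    "simulate_dataset",
]

#: Nine-taxon arachnid tree: three focal cobweb weavers (Lhes, Lgeo, Sgro),
#: another theridiid (Tgra), an araneoid (Gcan), an eresid (Smim), a
#: mygalomorph (Amyg), a scorpion (Msco) and the tick outgroup (Itick).
#: Branch lengths are node-date differences in pairwise-dS units, so the
#: speciation depths are 0.10, 0.18, 0.25, 0.33, 0.41 (eresid split),
#: 0.59 (Mygalomorphae-Araneomorphae), 0.72 (scorpion) and 0.90 (tick).
DEFAULT_SPECIES_TREE_NEWICK = (
    "((((((((Lhes:0.10,Lgeo:0.10)latrodectus:0.08,Sgro:0.18)latro_steatoda:0.07,"
    "Tgra:0.25)theridiidae:0.08,Gcan:0.33)araneoidea:0.08,Smim:0.41)"
    "araneomorphae:0.18,Amyg:0.59)araneae:0.13,Msco:0.72)arachnopulmonata:0.18,"
    "Itick:0.90)arachnida;"
)

FOCAL_SPECIES = frozenset({"Lhes", "Lgeo", "Sgro"})
ARANEOMORPH_SPECIES = frozenset({"Lhes", "Lgeo", "Sgro", "Tgra", "Gcan", "Smim"})
SPIDER_SPECIES = ARANEOMORPH_SPECIES | {"Amyg"}


def default_species_tree() -> SpeciesTree:
    return SpeciesTree(parse_newick(DEFAULT_SPECIES_TREE_NEWICK).root)


@dataclass
class SimulationConfig:
    """All knobs of the generator.

    Rates are events per unit of node-date (pairwise dS); probabilities in
    [0, 1].  ``wgd_branch`` names the species-tree branch carrying the
    large-scale duplication by the leaf set of its child node (or "stem"
    for the branch above the root); ``wgd_depth`` is the event date and
    must fall within that branch.
    """

    species_tree: SpeciesTree = field(default_factory=default_species_tree)
    n_families: int = 300
    wgd_branch: Optional[frozenset] = ARANEOMORPH_SPECIES
    wgd_depth: Optional[float] = 0.5
    wgd_retention_base: float = 0.6
    wgd_retention_sst: float = 0.9
    small_dup_rate: float = 0.3
    loss_rate: float = 10.0
    omega_sst_mean: float = 0.10
    omega_other_mean: float = 0.05
    omega_cv: float = 0.2
    rate_cv: float = 0.2
    codons_per_gene: int = 2000
    sst_fraction: float = 0.2
    low_fraction: float = 0.15
    n_contaminants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.wgd_retention_base, self.wgd_retention_sst,
                  self.sst_fraction, self.low_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        for r in (self.small_dup_rate, self.loss_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.omega_sst_mean < 0 or self.omega_other_mean < 0:
            raise ValueError("omega must be >= 0")
        if self.sst_fraction + self.low_fraction > 1.0:
            raise ValueError("sst_fraction + low_fraction must be <= 1")
        self._resolve_wgd()

    def _resolve_wgd(self) -> None:
        self.wgd_node: Optional[Node] = None
        if self.wgd_branch is None:
            return
        st = self.species_tree
        root_date = st.date(st.root)
        if self.wgd_branch == "stem":
            if self.wgd_depth is None or self.wgd_depth <= root_date:
                raise ValueError("stem WGD needs wgd_depth above the root date")
            self.wgd_node = st.root
            return
        try:
            child = st.node_by_leafset(self.wgd_branch)
        except KeyError as e:
            raise ValueError(f"wgd_branch is not an edge of the species tree: {e}")
        if child.parent is None:
            raise ValueError("use wgd_branch='stem' for the root edge")
        lo, hi = st.date(child), st.date(child.parent)
        if self.wgd_depth is None:
            self.wgd_depth = 0.5 * (lo + hi)
        if not (lo < self.wgd_depth <= hi):
            raise ValueError(
                f"wgd_depth {self.wgd_depth} outside branch dates ({lo}, {hi}]"
            )
        self.wgd_node = child


@dataclass
class SimulatedFamily:
    """One simulated gene family with full ground truth."""

    id: str
    tree: Tree  # per-node truth in node.meta: true_event, true_date
    category: str  # family-level: "SST" | "expressed" | "low"
    true_omega: float
    rate_multiplier: float
    n_codons: int = 0
    alignment: dict = field(default_factory=dict)  # leaf name -> codon string
    gene_categories: dict = field(default_factory=dict)  # leaf name -> category

    def leaf_species(self) -> set:
        return {l.name.split("|")[0] for l in self.tree.leaves()}

    def true_nodes(self, event: str) -> list[Node]:
        return [
            n for n in self.tree.preorder()
            if not n.is_leaf and n.meta.get("true_event") == event
        ]


# ---------------------------------------------------------------------------
# Gene-tree skeletons
# ---------------------------------------------------------------------------

def _simulate_one_tree(
    cfg: SimulationConfig, retention: float, rng: np.random.Generator,
    gene_counter: list[int], fam_id: str,
) -> Optional[Node]:
    """Walk the species tree from the root; returns the gene-tree root.

    Lineages flagged ``extra`` (descendants of a small duplication's new
    copy) are exposed to Poisson loss; the speciation backbone and WGD
    copies are not, so required-species coverage is governed by the WGD
    retention draw and small-duplicate turnover only.
    """
    st = cfg.species_tree

    def along_branch(sp_child: Node, t_top: float, extra: bool,
                     wgd_pending: bool) -> Optional[Node]:
        t = t_top
        t_end = st.date(sp_child)
        while True:
            t_dup = t - rng.exponential(1.0 / cfg.small_dup_rate) \
                if cfg.small_dup_rate > 0 else -np.inf
            t_loss = t - rng.exponential(1.0 / cfg.loss_rate) \
                if (cfg.loss_rate > 0 and extra) else -np.inf
            t_wgd = -np.inf
            if wgd_pending and cfg.wgd_node is sp_child and \
                    t >= cfg.wgd_depth > t_end:
                t_wgd = cfg.wgd_depth
            t_next = max(t_dup, t_loss, t_wgd)
            if t_next <= t_end:
                break
            if t_next == t_wgd:
                wgd_pending = False
                if rng.random() < retention:
                    left = along_branch(sp_child, t_wgd, extra, False)
                    right = along_branch(sp_child, t_wgd, extra, False)
                    if left is None and right is None:
                        return None
                    if left is None or right is None:
                        return left if right is None else right
                    node = Node()
                    node.meta = {"true_event": "wgd_duplication", "true_date": t_wgd}
                    node.add_child(left)
                    node.add_child(right)
                    return node
                t = t_wgd
                continue
            if t_next == t_loss:
                return None
            # small duplication: original continues, new copy is 'extra'
            keep = along_branch(sp_child, t_next, extra, wgd_pending)
            new = along_branch(sp_child, t_next, True, wgd_pending)
            if keep is None and new is None:
                return None
            if keep is None or new is None:
                return keep if new is None else new
            node = Node()
            node.meta = {"true_event": "small_duplication", "true_date": t_next}
            node.add_child(keep)
            node.add_child(new)
            return node

        # reached the species-tree node at t_end
        if sp_child.is_leaf:
            gene_counter[0] += 1
            leaf = Node(name=f"{sp_child.name}|{fam_id}_g{gene_counter[0]}")
            leaf.meta = {"true_event": None, "true_date": 0.0}
            return leaf
        kids = [
            along_branch(c, t_end, extra, wgd_pending) for c in sp_child.children
        ]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = Node()
        node.meta = {"true_event": "speciation", "true_date": t_end,
                     "species_leafset": sp_child.leaf_names()}
        for k in kids:
            node.add_child(k)
        return node

    root_date = st.date(st.root)
    t_top = root_date
    if cfg.wgd_branch == "stem":
        t_top = cfg.wgd_depth
    return along_branch(st.root, t_top, False, cfg.wgd_branch is not None)


def _assign_branch_lengths(root: Node, multiplier: float) -> None:
    """Per-lineage branch lengths: half the date difference, rate-scaled."""
    for node in root.preorder():
        if node.parent is None:
            node.length = 0.0
        else:
            dt = node.parent.meta["true_date"] - node.meta["true_date"]
            node.length = 0.5 * dt * multiplier


def simulate_gene_trees(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[SimulatedFamily]:
    """Generate family skeletons (trees + truth labels, no sequences)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma = float(np.sqrt(np.log(1.0 + cfg.rate_cv**2)))
    osigma = float(np.sqrt(np.log(1.0 + cfg.omega_cv**2)))
    families = []
    for i in range(cfg.n_families):
        u = rng.random()
        if u < cfg.sst_fraction:
            category = "SST"
        elif u < cfg.sst_fraction + cfg.low_fraction:
            category = "low"
        else:
            category = "expressed"
        retention = (
            cfg.wgd_retention_sst if category == "SST" else cfg.wgd_retention_base
        )
        mult = float(rng.lognormal(-0.5 * sigma**2, sigma)) if cfg.rate_cv > 0 else 1.0
        omega_mean = (
            cfg.omega_sst_mean if category == "SST" else cfg.omega_other_mean
        )
        omega = (
            float(rng.lognormal(np.log(omega_mean) - 0.5 * osigma**2, osigma))
            if (cfg.omega_cv > 0 and omega_mean > 0) else omega_mean
        )
        fam_id = f"fam{i}"
        root = _simulate_one_tree(cfg, retention, rng, [0], fam_id)
        if root is None or root.is_leaf:
            # whole family lost save at most one gene; keep a placeholder-free
            # dataset by skipping (delineation would drop it anyway)
            continue
        _assign_branch_lengths(root, mult)
        families.append(
            SimulatedFamily(
                id=fam_id, tree=Tree(root), category=category,
                true_omega=omega, rate_multiplier=mult,
            )
        )
    logger.info("simulated %d/%d families with >= 2 genes",
                len(families), cfg.n_families)
    return families


# ---------------------------------------------------------------------------
# Codon sequences
# ---------------------------------------------------------------------------

_SIM: Optional[dict] = None


def _sim_tables() -> dict:
    """Neighbor tables for the simulator (padded arrays for vector sampling)."""
    global _SIM
    if _SIM is not None:
        return _SIM
    tab = codon_tables()
    syn_nb = np.zeros((64, 9), dtype=np.int64)
    non_nb = np.zeros((64, 9), dtype=np.int64)
    syn_cnt = np.zeros(64, dtype=np.int64)
    non_cnt = np.zeros(64, dtype=np.int64)
    for i, codon in enumerate(CODONS):
        if codon in STOPS:
            continue
        for pos in range(3):
            for alt in "TCAG":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1:]
                if mut in STOPS:
                    continue
                j = CODONS.index(mut)
                if _GENETIC_CODE[codon] == _GENETIC_CODE[mut]:
                    syn_nb[i, syn_cnt[i]] = j
                    syn_cnt[i] += 1
                else:
                    non_nb[i, non_cnt[i]] = j
                    non_cnt[i] += 1
    S = np.nan_to_num(tab["syn_sites"])
    N = np.where(tab["sense"], 3.0 - S, 0.0)
    sense_idx = np.flatnonzero(tab["sense"])
    _SIM = {
        "syn_nb": syn_nb, "non_nb": non_nb, "syn_cnt": syn_cnt,
        "non_cnt": non_cnt, "S": S, "N": N, "sense_idx": sense_idx,
    }
    return _SIM


def _evolve_branch(
    enc: np.ndarray, t: float, omega: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve encoded codons for branch length t (expected dS units)."""
    if t <= 0:
        return enc.copy()
    sim = _sim_tables()
    S, N = sim["S"], sim["N"]
    e = enc.copy()
    rates = S[e] + omega * N[e]
    with np.errstate(divide="ignore"):
        wait = np.where(rates > 0, rng.exponential(1.0, e.size) / np.maximum(rates, 1e-300), np.inf)
    active = np.flatnonzero(wait < t)
    tleft = t - wait[active]
    while active.size:
        codes = e[active]
        tot = S[codes] + omega * N[codes]
        p_syn = np.where(tot > 0, S[codes] / np.maximum(tot, 1e-300), 0.0)
        is_syn = rng.random(active.size) < p_syn
        pick = rng.random(active.size)
        syn_idx = np.minimum(
            (pick * sim["syn_cnt"][codes]).astype(np.int64),
            np.maximum(sim["syn_cnt"][codes] - 1, 0),
        )
        non_idx = np.minimum(
            (pick * sim["non_cnt"][codes]).astype(np.int64),
            np.maximum(sim["non_cnt"][codes] - 1, 0),
        )
        new = np.where(
            is_syn,
            sim["syn_nb"][codes, syn_idx],
            sim["non_nb"][codes, non_idx],
        )
        e[active] = new
        rates = S[new] + omega * N[new]
        with np.errstate(divide="ignore"):
            wait = np.where(rates > 0, rng.exponential(1.0, active.size) / np.maximum(rates, 1e-300), np.inf)
        keep = wait < tleft
        tleft = tleft[keep] - wait[keep]
        active = active[keep]
    return e


def simulate_codon_alignment(
    tree: Tree,
    omega: float,
    codons: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    rate_multiplier: float = 1.0,
) -> dict[str, str]:
    """Evolve a gap-free codon alignment down a gene tree.

    Branch lengths must be per-lineage expected synonymous substitutions
    per synonymous site; ``rate_multiplier`` scales them all.  Deterministic
    under a fixed rng/seed.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    sim = _sim_tables()
    root_seq = rng.choice(sim["sense_idx"], size=codons)
    seqs: dict[int, np.ndarray] = {id(tree.root): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is not None:
            t = (node.length or 0.0) * rate_multiplier
            seqs[id(node)] = _evolve_branch(seqs[id(node.parent)], t, omega, rng)
        if node.is_leaf:
            e = seqs[id(node)]
            out[node.name] = "".join(CODONS[i] for i in e)
    return out


# ---------------------------------------------------------------------------
# Expression and abundance
# ---------------------------------------------------------------------------

LIBRARIES = ("silk", "venom", "ceph")


def simulate_expression_and_abundance(
    families: list[SimulatedFamily],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[AbundanceTable, pd.DataFrame, list[Transcript], set]:
    """Abundances, per-transcript expression categories and planted
    cross-species contaminants.

    SST-family silk transcripts get silk abundance >= 1 and dominant in the
    silk library; low-category transcripts stay < 1 everywhere.  Planted
    contaminants copy a donor transcript into another species at < 1% of
    the donor's species-summed abundance to exercise the contamination
    filter.  Returns (abundances, category table, contaminant transcripts,
    contaminant ids).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    records: list[tuple[str, str, str, float]] = []
    cat_rows: list[tuple[str, str]] = []

    def add_gene(name: str, species: str, gcat: str) -> None:
        if gcat == "SST":
            vals = {"silk": 1.0 + float(rng.lognormal(3.5, 1.0))}
            for lib in ("venom", "ceph"):
                vals[lib] = float(rng.uniform(0.0, 0.8))
        elif gcat == "expressed":
            vals = {lib: float(rng.lognormal(1.0, 1.0)) for lib in LIBRARIES}
            top = max(vals, key=vals.get)
            vals[top] = max(vals[top], 1.5)
        else:  # low
            vals = {lib: float(rng.uniform(0.0, 0.9)) for lib in LIBRARIES}
        for lib, v in vals.items():
            records.append((name, species, lib, v))
        cat_rows.append((name, gcat))

    for fam in families:
        leaves = fam.tree.leaves()
        gene_cats: dict[str, str] = {}
        if fam.category == "SST":
            # SSTs are typically a small minority of their family's members
            flags = rng.random(len(leaves)) < 0.25
            if not flags.any():
                flags[int(rng.integers(len(leaves)))] = True
            for leaf, f in zip(leaves, flags):
                gene_cats[leaf.name] = "SST" if f else "low"
        elif fam.category == "expressed":
            flags = rng.random(len(leaves)) < 0.7
            if not flags.any():
                flags[int(rng.integers(len(leaves)))] = True
            for leaf, f in zip(leaves, flags):
                gene_cats[leaf.name] = "expressed" if f else "low"
        else:
            for leaf in leaves:
                gene_cats[leaf.name] = "low"
        fam.gene_categories = gene_cats
        for leaf in leaves:
            add_gene(leaf.name, leaf.name.split("|")[0], gene_cats[leaf.name])

    # planted cross-species contaminants
    contaminants: list[Transcript] = []
    contam_ids: set = set()
    donors = [
        leaf for fam in families if fam.alignment for leaf in fam.tree.leaves()
    ]
    species_pool = sorted({l.name.split("|")[0] for l in donors})
    for k in range(cfg.n_contaminants):
        if not donors:
            break
        donor = donors[int(rng.integers(len(donors)))]
        donor_sp = donor.name.split("|")[0]
        others = [s for s in species_pool if s != donor_sp]
        recip_sp = others[int(rng.integers(len(others)))]
        fam = next(f for f in families if donor.name in f.alignment)
        seq = fam.alignment[donor.name].replace("-", "")
        cid = f"{recip_sp}|contam{k}"
        contaminants.append(Transcript(id=cid, species=recip_sp, sequence=seq))
        contam_ids.add(cid)
        donor_sum = sum(v for (n, s, l, v) in records if n == donor.name)
        donor_sum = max(donor_sum, 10.0)
        # top up the donor so the 1% rule has headroom, then plant recipient
        records.append((donor.name, donor_sp, "silk", donor_sum))
        for lib in LIBRARIES:
            records.append((cid, recip_sp, lib, 0.001 * donor_sum))
        cat_rows.append((cid, "low"))
    table = AbundanceTable.from_records(records)
    cats = pd.DataFrame(cat_rows, columns=["transcript_id", "category"])
    return table, cats, contaminants, contam_ids


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(
    cfg: SimulationConfig, seed: Optional[int] = None
) -> list[SimulatedFamily]:
    """Trees + sequences for every family (no expression tables)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    families = simulate_gene_trees(cfg, rng)
    for fam in families:
        fam.n_codons = cfg.codons_per_gene
        fam.alignment = simulate_codon_alignment(
            fam.tree, fam.true_omega, cfg.codons_per_gene, rng=rng
        )
    return families
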