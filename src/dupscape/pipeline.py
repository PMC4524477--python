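"""End-to-end analyses: simulated data through trees, dating and mixtures.

``run_wgd_analysis`` is the canonical path: simulate gene families on the
arachnid species tree (optionally with a planted large-scale duplication),
infer each family's tree by neighbor joining on Poisson-corrected
amino-acid distances, root it minimizing duplications, label events by
reconciliation, date duplication and speciation nodes by mean pairwise
NG86 dS, filter duplication ages to ``0.01 <= dS < 2``, decompose them
with a two-component Gaussian mixture, and place the older component
among the speciation-node age distributions.  Ground truth from the
simulator is carried along so recovery can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import SpeciesTree, Tree
from .mixture_stats import (
    Assignment,
    MixtureModel,
    PlacementReport,
    StatResult,
    assign_components,
    categorize_families,
    compare_dup_vs_speciation,
    detect_bimodality,
    fit_gmm,
    kruskal_wallis,
    older_component,
    older_peak_enrichment,
    omega_vs_size_fit,
    two_sample_t,
)
from .molecular_rates import (
    NodeDate,
    date_tree_nodes,
    family_omega,
    filter_duplication_nodes,
)
from .synthetic_evolution import (
    SimulatedFamily,
    SimulationConfig,
    simulate_dataset,
    simulate_expression_and_abundance,
)
from .tree_toolkit import nj_tree, pairwise_distance_matrix, reconcile_label, root_min_dup

logger = logging.getLogger("dupscape")

__all__ = ["WgdAnalysis", "analyze_family", "run_wgd_analysis", "sst_contrast"]


def analyze_family(
    alignment: dict[str, str],
    species_tree: SpeciesTree,
    family_id: str = "",
    metric: str = "ds_ng86",
) -> Optional[tuple[Tree, list[NodeDate]]]:
    """Tree inference, rooting, labeling and node dating for one family.

    Returns (labeled rooted tree, node dates), or None for families too
    small to build a tree (< 3 sequences).
    """
    if len(alignment) < 3:
        return None
    labels, D = pairwise_distance_matrix(alignment, metric)
    unrooted = nj_tree(D, labels)
    rooted = root_min_dup(unrooted, species_tree)
    dates = date_tree_nodes(rooted, alignment, family_id)
    return rooted, dates


@dataclass
class WgdAnalysis:
    """Everything the end-to-end run produces."""

    families: list
    trees: dict  # family id -> labeled rooted Tree
    dup_dates: list  # all dated duplication nodes
    filtered_dates: list  # passing the dS window
    spec_ds_by_node: dict  # species-node label -> [per-family node dS]
    model: Optional[MixtureModel]
    assignments: list
    placement: Optional[PlacementReport]
    bimodal: bool
    bimodal_details: dict
    family_stats: pd.DataFrame
    family_categories: dict
    node_categories: list  # per filtered node, its family's category
    # truth scoring
    n_true_wgd: int = 0
    n_true_wgd_matched: int = 0
    n_true_wgd_passing: int = 0
    n_true_wgd_older: int = 0

    @property
    def frac_true_wgd_older(self) -> Optional[float]:
        if self.n_true_wgd_passing == 0:
            return None
        return self.n_true_wgd_older / self.n_true_wgd_passing


def _species_node_label(species_tree: SpeciesTree, leafset) -> str:
    try:
        node = species_tree.node_by_leafset(leafset)
    except KeyError:
        return "+".join(sorted(leafset))
    return node.name or "+".join(sorted(leafset))


_CATEGORY_MAP = {"SST": "SST", "expressed": "non-SST", "low": "low"}


def run_wgd_analysis(
    cfg: SimulationConfig,
    seed: Optional[int] = None,
    gmm_k: int = 2,
    ds_min: float = 0.01,
    ds_max: float = 2.0,
    pp_cutoff: float = 0.95,
    families: Optional[list] = None,
) -> WgdAnalysis:
    """Simulate (unless given) and analyze a full dataset."""
    if families is None:
        families = simulate_dataset(cfg, seed)
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    _, cat_table, _, _ = simulate_expression_and_abundance(families, cfg, rng)
    tcats = dict(zip(cat_table["transcript_id"], cat_table["category"]))
    fam_members = {
        f.id: [l.name for l in f.tree.leaves()] for f in families
    }
    fam_cats = categorize_families(fam_members, tcats)

    trees: dict[str, Tree] = {}
    dup_dates: list[NodeDate] = []
    spec_ds_by_node: dict[str, list] = {}
    stats_rows = []
    true_wgd_total = 0
    matched: list[tuple[str, frozenset]] = []  # (family, leafset) of true WGD

    for fam in families:
        res = analyze_family(fam.alignment, cfg.species_tree, fam.id)
        n_species = len(fam.leaf_species())
        true_wgd_total += len(fam.true_nodes("wgd_duplication"))
        if res is None:
            continue
        tree, dates = res
        trees[fam.id] = tree
        fam_dup = [d for d in dates if d.node_kind == "duplication"]
        dup_dates.extend(fam_dup)
        for d in dates:
            if d.node_kind == "speciation" and d.ds_mean is not None:
                label = _species_node_label(
                    cfg.species_tree, d.species_map_leafset or frozenset()
                )
                spec_ds_by_node.setdefault(label, []).append(d.ds_mean)
        st = family_omega(fam.alignment, fam.id, len(fam_dup))
        stats_rows.append({
            "family_id": fam.id,
            "omega": st.omega,
            "n_members": st.n_members,
            "n_duplication_nodes": len(fam_dup),
            "additional_members": st.n_members - n_species,
            "category": fam_cats[fam.id],
            "true_omega": fam.true_omega,
            "true_category": _CATEGORY_MAP[fam.category],
        })
        for tn in fam.true_nodes("wgd_duplication"):
            matched.append((fam.id, tn.leaf_names()))

    filtered = filter_duplication_nodes(dup_dates, ds_min, ds_max)
    # a duplication node's expression class follows its descendants: SST
    # with any silk-specific descendant, non-SST with any significantly
    # expressed descendant, low otherwise
    gene_cats: dict[str, str] = {}
    for fam in families:
        gene_cats.update(fam.gene_categories)
    node_categories = []
    for d in filtered:
        cats = {gene_cats.get(l.name, "low") for l in d.node.leaves()}
        if "SST" in cats:
            node_categories.append("SST")
        elif "expressed" in cats:
            node_categories.append("non-SST")
        else:
            node_categories.append("low")

    model = None
    assignments: list[Assignment] = []
    placement = None
    bimodal, details = False, {}
    if len(filtered) > gmm_k:
        values = [d.ds_mean for d in filtered]
        model = fit_gmm(values, K=gmm_k)
        assignments = assign_components(
            values, model, cutoff=pp_cutoff,
            node_ids=[f"{d.family_id}:{d.node_id}" for d in filtered],
        )
        bimodal, details = detect_bimodality(values)
        old_k = older_component(model)
        older_vals = [
            a.value for a in assignments if a.assigned_component == old_k
        ]
        if older_vals and spec_ds_by_node:
            placement = compare_dup_vs_speciation(older_vals, spec_ds_by_node)

    # score truth: match true WGD nodes to filtered+assigned inferred nodes
    n_matched = n_passing = n_older = 0
    by_key = {}
    for d, a in zip(filtered, assignments):
        if d.node is not None:
            by_key[(d.family_id, d.node.leaf_names())] = (d, a)
    dated_keys = {
        (d.family_id, d.node.leaf_names())
        for d in dup_dates if d.node is not None and d.ds_mean is not None
    }
    old_k = older_component(model) if model is not None else None
    for key in matched:
        if key in dated_keys:
            n_matched += 1
        if key in by_key:
            n_passing += 1
            _, a = by_key[key]
            if old_k is not None and a.assigned_component == old_k:
                n_older += 1

    return WgdAnalysis(
        families=families,
        trees=trees,
        dup_dates=dup_dates,
        filtered_dates=filtered,
        spec_ds_by_node=spec_ds_by_node,
        model=model,
        assignments=assignments,
        placement=placement,
        bimodal=bimodal,
        bimodal_details=details,
        family_stats=pd.DataFrame(stats_rows),
        family_categories=fam_cats,
        node_categories=node_categories,
        n_true_wgd=true_wgd_total,
        n_true_wgd_matched=n_matched,
        n_true_wgd_passing=n_passing,
        n_true_wgd_older=n_older,
    )


def sst_contrast(result: WgdAnalysis) -> dict:
    """The SST comparative battery on an analyzed dataset.

    Returns a dict of StatResults: older-peak enrichment, Welch t on
    family omega (SST vs non-SST), Kruskal-Wallis on family size across
    the three categories, and per-category omega-vs-size OLS fits.
    """
    out: dict[str, object] = {}
    if result.model is not None and result.assignments:
        out["enrichment"] = older_peak_enrichment(
            result.assignments, result.node_categories, result.model
        )
    df = result.family_stats.dropna(subset=["omega"])
    sst = df[df["category"] == "SST"]["omega"]
    non = df[df["category"] == "non-SST"]["omega"]
    if len(sst) >= 2 and len(non) >= 2:
        out["omega_t"] = two_sample_t(sst, non)
    sizes = {
        cat: sub["additional_members"].tolist()
        for cat, sub in result.family_stats.groupby("category")
        if len(sub) > 0
    }
    if len(sizes) >= 2:
        out["size_kw"] = kruskal_wallis(sizes)
    out["omega_size_fits"] = omega_vs_size_fit(
        df[df["category"].isin(["SST", "non-SST"])]
    )
    return out
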