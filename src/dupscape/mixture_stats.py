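"""Gaussian-mixture decomposition of duplication ages and SST statistics.

Duplication-node dS values belonging to one large-scale event should be
approximately Gaussian around the event's age (family-to-family rate
variation provides the spread), sitting on top of a young component of
ongoing single-gene duplications.  A K-component univariate Gaussian
mixture is fitted by EM from quantile-based initialization; nodes are
assigned to a component only when its posterior responsibility reaches
0.95.  The "older" component is the one with the larger mean.

The comparative battery (silk-specific vs generally expressed vs low
expression families) delegates the standard tests to scipy/statsmodels:
Kruskal-Wallis with tie correction, Welch's t, per-category OLS of omega
on family size, and type-II two-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

logger = logging.getLogger("dupscape")

__all__ = [
    "MixtureModel",
    "Assignment",
    "StatResult",
    "fit_gmm",
    "assign_components",
    "older_component",
    "detect_bimodality",
    "PlacementReport",
    "compare_dup_vs_speciation",
    "categorize_families",
    "kruskal_wallis",
    "two_sample_t",
    "omega_vs_size_fit",
    "two_way_anova",
    "older_peak_enrichment",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureModel:
    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    seed: int = 0
    bic: float = 0.0
    loglik_history: list = field(default_factory=list)


@dataclass
class Assignment:
    value: float
    posteriors: np.ndarray
    assigned_component: Optional[int]
    pp_max: float
    node_id: Optional[str] = None


@dataclass
class StatResult:
    name: str
    statistic: object  # float or dict of named quantities
    p_value: Optional[float]
    group_summary: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def _log_resp(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray):
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    logp = -0.5 * z**2 - np.log(sd)[None, :] - 0.5 * _LOG2PI + np.log(w)[None, :]
    norm = logsumexp(logp, axis=1)
    return logp - norm[:, None], norm


def fit_gmm(
    values: Sequence[float],
    K: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    sigma_floor: float = 1e-4,
) -> MixtureModel:
    """Fit a K-component univariate Gaussian mixture by EM.

    Initialization is deterministic: component k starts at the
    ``(k+0.5)/K`` sample quantile with equal weights and the pooled ML
    standard deviation, so identical inputs give identical fits (``seed``
    is recorded for provenance only).  ``sigma_floor`` prevents component
    collapse onto duplicated values.  The log-likelihood is non-decreasing
    across iterations; convergence is a gain below ``tol``.  Components
    are reported sorted by mean.
    """
    x = np.asarray(list(values), dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if x.size <= K:
        raise ValueError(f"need more than K={K} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    q = (np.arange(K) + 0.5) / K
    mu = np.quantile(x, q)
    sd = np.full(K, max(float(x.std()), sigma_floor))
    w = np.full(K, 1.0 / K)
    history: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logr, norm = _log_resp(x, w, mu, sd)
        ll = float(norm.sum())
        history.append(ll)
        if ll + 1e-9 < prev:  # EM guarantees monotonicity
            raise RuntimeError("EM log-likelihood decreased")
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
        r = np.exp(logr)
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / x.size
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sigma_floor)
    order = np.argsort(mu)
    n_params = 3 * K - 1
    bic = -2.0 * history[-1] + n_params * float(np.log(x.size))
    return MixtureModel(
        K=K, weights=w[order], means=mu[order], sds=sd[order],
        loglik=history[-1], n_iter=it, converged=converged, seed=seed,
        bic=bic, loglik_history=history,
    )


def assign_components(
    values: Sequence[float],
    model: MixtureModel,
    cutoff: float = 0.95,
    node_ids: Optional[Sequence[str]] = None,
) -> list[Assignment]:
    """Posterior responsibilities and >= 0.95-PP component assignment.

    A value is assigned to its argmax component only when that component's
    posterior reaches the cutoff (boundary values are assigned); otherwise
    it stays unassigned.
    """
    x = np.asarray(list(values), dtype=float)
    logr, _ = _log_resp(x, model.weights, model.means, model.sds)
    resp = np.exp(logr)
    out = []
    for i in range(x.size):
        k = int(resp[i].argmax())
        pp = float(resp[i, k])
        out.append(
            Assignment(
                value=float(x[i]),
                posteriors=resp[i],
                assigned_component=k if pp >= cutoff else None,
                pp_max=pp,
                node_id=None if node_ids is None else node_ids[i],
            )
        )
    return out


def older_component(model: MixtureModel) -> int:
    """Index of the component with the largest mean."""
    return int(np.argmax(model.means))


def detect_bimodality(
    values: Sequence[float],
    bin_width: float = 0.05,
    young_max: float = 0.3,
    old_range: tuple = (0.3, 1.0),
    valley_ratio: float = 0.7,
) -> tuple[bool, dict]:
    """Histogram test for a two-peaked dS distribution with a valley.

    Counts are binned at ``bin_width`` and lightly smoothed; the rule
    requires a young-side peak (below ``young_max``), an old-side peak
    (within ``old_range``) and an intervening minimum no higher than
    ``valley_ratio`` times the smaller peak.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 10:
        return False, {"reason": "too few values"}
    hi = max(float(x.max()) + bin_width, old_range[1])
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    young_mask = centers < young_max
    old_mask = (centers >= old_range[0]) & (centers <= old_range[1])
    if not young_mask.any() or not old_mask.any():
        return False, {"reason": "range"}
    iy = int(np.flatnonzero(young_mask)[np.argmax(smooth[young_mask])])
    io = int(np.flatnonzero(old_mask)[np.argmax(smooth[old_mask])])
    if io <= iy:
        return False, {"reason": "no separated peaks"}
    valley = float(smooth[iy + 1: io].min()) if io > iy + 1 else float("inf")
    py, po = float(smooth[iy]), float(smooth[io])
    ok = py > 0 and po > 0 and valley <= valley_ratio * min(py, po)
    return ok, {
        "young_peak_ds": float(centers[iy]), "old_peak_ds": float(centers[io]),
        "young_height": py, "old_height": po, "valley": valley,
    }


# ---------------------------------------------------------------------------
# Placement against speciation nodes
# ---------------------------------------------------------------------------

@dataclass
class PlacementReport:
    dup_median: float
    speciation_medians: dict  # node label -> median dS
    lower_node: Optional[str]
    upper_node: Optional[str]
    placement: str
    indistinguishable: bool
    histograms: dict = field(default_factory=dict)


def compare_dup_vs_speciation(
    dup_ds: Sequence[float],
    speciation_ds: dict,
    bin_width: float = 0.05,
) -> PlacementReport:
    """Place the (older-component) duplication ages among speciation ages.

    ``speciation_ds`` maps a speciation-node label to its per-family dS
    values; medians are compared and the report names the flanking
    speciation events.  Histograms are normalized to their total count for
    overlaying.
    """
    dup = np.asarray(list(dup_ds), dtype=float)
    if dup.size == 0 or not speciation_ds:
        raise ValueError("both date sets must be non-empty")
    dmed = float(np.median(dup))
    meds = {k: float(np.median(np.asarray(list(v), float)))
            for k, v in speciation_ds.items() if len(v) > 0}
    below = {k: m for k, m in meds.items() if m <= dmed}
    above = {k: m for k, m in meds.items() if m > dmed}
    lower = max(below, key=lambda k: below[k]) if below else None
    upper = min(above, key=lambda k: above[k]) if above else None
    indist = any(abs(m - dmed) < 1e-9 for m in meds.values())
    if indist:
        placement = "indistinguishable"
    elif lower and upper:
        placement = f"between {lower} and {upper}"
    elif lower:
        placement = f"after {lower}"
    else:
        placement = f"before {upper}"
    hi = max([dmed] + list(meds.values())) + 0.3
    edges = np.arange(0.0, hi + bin_width, bin_width)
    hists = {"duplication": np.histogram(dup, bins=edges)[0] / dup.size}
    for k, v in speciation_ds.items():
        arr = np.asarray(list(v), float)
        if arr.size:
            hists[k] = np.histogram(arr, bins=edges)[0] / arr.size
    hists["bin_edges"] = edges
    return PlacementReport(
        dup_median=dmed, speciation_medians=meds, lower_node=lower,
        upper_node=upper, placement=placement, indistinguishable=indist,
        histograms=hists,
    )


# ---------------------------------------------------------------------------
# Expression categories and comparative statistics
# ---------------------------------------------------------------------------

def categorize_families(
    family_members: dict,
    transcript_categories: dict,
) -> dict:
    """Family-level expression category from member categories.

    A family is ``SST`` with >= 1 silk-specific member, else ``non-SST``
    with >= 1 significantly expressed member, else ``low``.  A member
    missing from the category table is an error.
    """
    out = {}
    for fam, members in family_members.items():
        cats = []
        for m in members:
            if m not in transcript_categories:
                raise KeyError(f"transcript {m!r} missing from category table")
            cats.append(transcript_categories[m])
        if "SST" in cats:
            out[fam] = "SST"
        elif "expressed" in cats:
            out[fam] = "non-SST"
        else:
            out[fam] = "low"
    return out


def _summaries(groups: dict) -> dict:
    return {
        k: {"n": len(v), "mean": float(np.mean(v)), "median": float(np.median(v))}
        for k, v in groups.items()
    }


def kruskal_wallis(groups: dict) -> StatResult:
    """Kruskal-Wallis rank test (tie-corrected H, chi-square p)."""
    for k, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"empty group {k!r}")
    vals = list(groups.values())
    if sum(len(v) for v in vals) < 3 or len(vals) < 2:
        raise ValueError("need >= 2 groups and >= 3 total observations")
    flat = np.concatenate([np.asarray(v, float) for v in vals])
    if np.ptp(flat) == 0:  # all identical: H is 0 by definition
        return StatResult("kruskal_wallis", 0.0, 1.0, _summaries(groups))
    h, p = sps.kruskal(*vals)
    return StatResult("kruskal_wallis", float(h), float(p), _summaries(groups))


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Welch's unequal-variance t test with degenerate-input guards."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    summ = _summaries({"a": a, "b": b})
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult("welch_t", 0.0, 1.0, summ)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return StatResult(
            "welch_t", sign * float("inf"), 0.0, summ,
            flags={"exact_separation": True, "capped": True},
        )
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return StatResult("welch_t", float(t), float(p), summ)


def omega_vs_size_fit(df: pd.DataFrame) -> dict:
    """Per-category OLS of family omega on additional-member count.

    ``df`` needs columns ``omega``, ``additional_members``, ``category``.
    Returns {category: StatResult} with slope, intercept, R^2 and the
    slope p-value; categories with no size variation get an
    ``undefined_slope`` flag.
    """
    import statsmodels.api as sm

    out = {}
    for cat, sub in df.groupby("category"):
        sub = sub.dropna(subset=["omega"])
        if len(sub) < 3:
            out[cat] = StatResult(
                "omega_vs_size", None, None, flags={"too_few": True}
            )
            continue
        x = sub["additional_members"].to_numpy(float)
        y = sub["omega"].to_numpy(float)
        if np.ptp(x) == 0:
            out[cat] = StatResult(
                "omega_vs_size",
                {"slope": None, "intercept": float(y.mean()), "r2": None},
                None, flags={"undefined_slope": True},
            )
            continue
        model = sm.OLS(y, sm.add_constant(x)).fit()
        out[cat] = StatResult(
            "omega_vs_size",
            {
                "slope": float(model.params[1]),
                "intercept": float(model.params[0]),
                "r2": float(model.rsquared),
            },
            float(model.pvalues[1]),
            group_summary={"n": len(sub)},
        )
    return out


def two_way_anova(
    omega: Sequence[float],
    factor_sst: Sequence,
    factor_lineage: Sequence,
) -> dict:
    """Type-II two-way ANOVA of omega on SST status and lineage specificity.

    Returns StatResults for both main effects and the interaction.
    Degenerate designs are guarded: with zero residual variance an effect
    with positive sum-of-squares reports infinite F (``exact_fit`` flag)
    and a zero-SS effect reports F = 0.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({
        "omega": np.asarray(list(omega), float),
        "sst": [str(v) for v in factor_sst],
        "lineage": [str(v) for v in factor_lineage],
    })
    if df["omega"].var(ddof=0) == 0:
        zero = StatResult("anova", 0.0, 1.0, flags={"constant_response": True})
        return {"sst": zero, "lineage": zero, "interaction": zero}
    model = ols("omega ~ C(sst) * C(lineage)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = float(table.loc["Residual", "df"])
    out = {}
    rows = {"sst": "C(sst)", "lineage": "C(lineage)",
            "interaction": "C(sst):C(lineage)"}
    for key, row in rows.items():
        if row not in table.index:
            out[key] = StatResult("anova", 0.0, 1.0, flags={"absent": True})
            continue
        ss = float(table.loc[row, "sum_sq"])
        dfx = float(table.loc[row, "df"])
        if resid_ss <= 1e-12 or resid_df <= 0:
            if ss <= 1e-12:
                out[key] = StatResult("anova", 0.0, 1.0, flags={"exact_fit": True})
            else:
                out[key] = StatResult(
                    "anova", float("inf"), 0.0, flags={"exact_fit": True}
                )
            continue
        f = (ss / dfx) / (resid_ss / resid_df)
        p = float(sps.f.sf(f, dfx, resid_df))
        out[key] = StatResult("anova", float(f), p)
    return out


def older_peak_enrichment(
    assignments: Sequence[Assignment],
    node_categories: Sequence[str],
    model: MixtureModel,
) -> StatResult:
    """Per-category fraction of duplication nodes assigned to the older peak.

    The older peak is the component with the larger mean.  Fractions are
    over all filtered nodes of the category (unassigned nodes count in the
    denominator).  SST vs non-SST is compared with a 2x2 chi-square
    (Fisher's exact test when expected counts are small).
    """
    if len(assignments) != len(node_categories):
        raise ValueError("assignments/categories length mismatch")
    old_k = older_component(model)
    counts: dict[str, list] = {}
    for a, cat in zip(assignments, node_categories):
        tot_old = counts.setdefault(cat, [0, 0])
        tot_old[0] += 1
        if a.assigned_component == old_k:
            tot_old[1] += 1
    fractions = {
        cat: (old / tot if tot else None) for cat, (tot, old) in counts.items()
    }
    p = None
    statistic = None
    flags = {}
    if "SST" in counts and "non-SST" in counts:
        t1, o1 = counts["SST"]
        t2, o2 = counts["non-SST"]
        table = np.array([[o1, t1 - o1], [o2, t2 - o2]])
        if (table.sum(axis=1) > 0).all():
            expected = sps.contingency.expected_freq(table)
            if (expected < 5).any():
                _, p = sps.fisher_exact(table)
                flags["fisher"] = True
                statistic = None
            else:
                chi2, p, _, _ = sps.chi2_contingency(table)
                statistic = float(chi2)
    return StatResult(
        "older_peak_enrichment", statistic, p,
        group_summary={
            cat: {"n": tot, "older": old, "fraction": fractions[cat]}
            for cat, (tot, old) in counts.items()
        },
        flags=flags,
    )
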