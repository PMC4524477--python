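import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dupscape.mixture_stats import (
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
    two_way_anova,
)


class TestFitGmm:
    def test_k1_matches_closed_form_mle(self, rng):
        x = rng.normal(0.4, 0.1, 500)
        m = fit_gmm(x, K=1)
        assert m.means[0] == pytest.approx(float(x.mean()), abs=1e-10)
        assert m.sds[0] == pytest.approx(float(x.std()), abs=1e-10)
        assert m.weights[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_loglik_monotone_every_iteration(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([
            rng.normal(0.05, 0.02, 200), rng.normal(0.5, 0.15, 300)
        ])
        m = fit_gmm(x, K=int(rng.integers(1, 4)))
        diffs = np.diff(m.loglik_history)
        assert (diffs >= -1e-9).all()

    def test_two_component_recovery(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([
            rng.normal(0.03, 0.015, 4000), rng.normal(0.53, 0.15, 6000)
        ])
        m = fit_gmm(x, K=2)
        assert m.means[0] == pytest.approx(0.03, abs=0.01)
        assert m.means[1] == pytest.approx(0.53, abs=0.03)
        assert m.weights[1] == pytest.approx(0.6, abs=0.05)

    def test_duplicated_dataset_identical_parameters(self, rng):
        x = rng.normal(0.3, 0.1, 200)
        m1 = fit_gmm(x, K=2, tol=1e-12)
        m2 = fit_gmm(np.concatenate([x, x]), K=2, tol=1e-12)
        assert np.allclose(m1.means, m2.means, atol=1e-6)
        assert np.allclose(m1.sds, m2.sds, atol=1e-6)
        assert np.allclose(m1.weights, m2.weights, atol=1e-6)

    def test_weights_sum_to_one_and_sigma_floor(self, rng):
        x = np.repeat(0.5, 50) + rng.normal(0, 1e-9, 50)
        m = fit_gmm(x, K=2, sigma_floor=1e-4)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (m.sds >= 1e-4).all()

    def test_extra_component_never_hurts_loglik(self, rng):
        x = np.concatenate([
            rng.normal(0.05, 0.02, 150), rng.normal(0.5, 0.1, 150)
        ])
        lls = [fit_gmm(x, K=k).loglik for k in (1, 2, 3)]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm([1.0, 2.0], K=2)
        with pytest.raises(ValueError):
            fit_gmm([1.0, 2.0, 3.0], K=0)
        with pytest.raises(ValueError):
            fit_gmm([1.0, np.nan, 3.0], K=1)


class TestAssignments:
    def _model(self):
        return fit_gmm(
            np.concatenate([
                np.random.default_rng(1).normal(0.05, 0.02, 300),
                np.random.default_rng(2).normal(0.6, 0.1, 300),
            ]),
            K=2,
        )

    def test_value_at_component_mean_assigned_with_high_pp(self):
        m = self._model()
        a = assign_components([float(m.means[1])], m)[0]
        assert a.assigned_component == 1
        assert a.pp_max > 0.99

    def test_equal_posterior_point_unassigned(self):
        m = self._model()
        # scan for the crossing point of posteriors
        xs = np.linspace(m.means[0], m.means[1], 4000)
        asg = assign_components(xs, m)
        crossing = [a for a in asg if a.pp_max < 0.6]
        assert crossing, "expected an ambiguous region between components"
        assert all(a.assigned_component is None for a in crossing)

    def test_responsibilities_match_density_ratio(self, rng):
        m = self._model()
        for x in rng.uniform(0, 1, 20):
            a = assign_components([x], m)[0]
            dens = m.weights * sps.norm.pdf(x, m.means, m.sds)
            assert np.allclose(a.posteriors, dens / dens.sum(), atol=1e-9)

    def test_partition_counts_sum_to_n(self, rng):
        m = self._model()
        xs = rng.uniform(0, 1, 200)
        asg = assign_components(xs, m)
        n_assigned = sum(a.assigned_component is not None for a in asg)
        n_un = sum(a.assigned_component is None for a in asg)
        assert n_assigned + n_un == 200


def test_detect_bimodality_flags_two_peaks_not_one(rng):
    bimodal = np.concatenate([
        rng.normal(0.05, 0.02, 300), rng.normal(0.55, 0.1, 300)
    ])
    unimodal = rng.normal(0.3, 0.08, 600)
    assert detect_bimodality(bimodal)[0]
    assert not detect_bimodality(unimodal)[0]


class TestPlacement:
    def test_worked_ordering_places_between_nodes(self, rng):
        dup = rng.normal(0.52, 0.001, 101)
        spec = {
            "entelegyne": rng.normal(0.41, 0.001, 51),
            "suborder": rng.normal(0.59, 0.001, 51),
            "scorpion": rng.normal(0.72, 0.001, 51),
        }
        rep = compare_dup_vs_speciation(dup, spec)
        assert rep.lower_node == "entelegyne"
        assert rep.upper_node == "suborder"
        assert "between entelegyne and suborder" == rep.placement
        assert not rep.indistinguishable

    def test_identical_distributions_indistinguishable(self):
        vals = [0.4, 0.5, 0.6]
        rep = compare_dup_vs_speciation(vals, {"node": list(vals)})
        assert rep.indistinguishable

    def test_histograms_normalized(self, rng):
        dup = rng.normal(0.5, 0.05, 200)
        rep = compare_dup_vs_speciation(dup, {"n1": rng.normal(0.6, 0.05, 50)})
        assert rep.histograms["duplication"].sum() == pytest.approx(1.0)
        assert rep.histograms["n1"].sum() == pytest.approx(1.0)


class TestCategorize:
    def test_category_rules(self):
        fams = {"f1": ["a", "b"], "f2": ["c", "d"], "f3": ["e"]}
        cats = {"a": "SST", "b": "low", "c": "expressed", "d": "low", "e": "low"}
        out = categorize_families(fams, cats)
        assert out == {"f1": "SST", "f2": "non-SST", "f3": "low"}

    def test_missing_member_is_error(self):
        with pytest.raises(KeyError, match="ghost"):
            categorize_families({"f": ["ghost"]}, {})


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        r = kruskal_wallis({"a": [1, 1, 1], "b": [1, 1, 1]})
        assert r.statistic == 0.0

    def test_hand_computed_tie_free_case(self):
        r = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert r.statistic == pytest.approx(3.857, abs=1e-3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0], "b": []})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_rank_implementation(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            "a": rng.integers(0, 10, 12).tolist(),
            "b": rng.integers(0, 10, 15).tolist(),
            "c": rng.integers(0, 10, 9).tolist(),
        }
        r = kruskal_wallis(groups)
        flat = np.concatenate([groups[k] for k in ("a", "b", "c")]).astype(float)
        ranks = sps.rankdata(flat)
        n = len(flat)
        idx = 0
        h = 0.0
        for k in ("a", "b", "c"):
            g = len(groups[k])
            rsum = ranks[idx: idx + g].sum()
            h += rsum**2 / g
            idx += g
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(flat, return_counts=True)
        tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
        h /= tie
        assert r.statistic == pytest.approx(h, abs=1e-9)

    def test_group_order_invariant(self, rng):
        g = {"a": [1, 5, 3], "b": [9, 2, 8], "c": [4, 7, 6]}
        r1 = kruskal_wallis(g)
        r2 = kruskal_wallis(dict(reversed(list(g.items()))))
        assert r1.statistic == pytest.approx(r2.statistic)


class TestWelchT:
    def test_equal_groups_t_zero(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0

    def test_exact_separation_capped_and_flagged(self):
        r = two_sample_t([0.0, 0.0], [1.0, 1.0])
        assert r.flags.get("exact_separation")
        assert not np.isfinite(r.statistic) or abs(r.statistic) > 1e6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_welch_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 2, 18)
        r = two_sample_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert r.statistic == pytest.approx(t, abs=1e-9)
        assert r.p_value == pytest.approx(p, abs=1e-9)


class TestOmegaVsSize:
    def test_perfectly_linear_r2_one(self):
        df = pd.DataFrame({
            "omega": [0.1, 0.2, 0.3, 0.4],
            "additional_members": [1, 2, 3, 4],
            "category": ["SST"] * 4,
        })
        fit = omega_vs_size_fit(df)["SST"]
        assert fit.statistic["r2"] == pytest.approx(1.0)
        assert fit.statistic["slope"] == pytest.approx(0.1)
        assert fit.statistic["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_design_variance_flagged(self):
        df = pd.DataFrame({
            "omega": [0.1, 0.2, 0.3],
            "additional_members": [2, 2, 2],
            "category": ["non-SST"] * 3,
        })
        fit = omega_vs_size_fit(df)["non-SST"]
        assert fit.flags.get("undefined_slope")
        assert fit.statistic["slope"] is None


class TestTwoWayAnova:
    def test_all_equal_f_zero(self):
        out = two_way_anova([0.1] * 8, ["y", "n"] * 4, ["y", "y", "n", "n"] * 2)
        assert all(r.statistic == 0.0 for r in out.values())

    def test_exact_additivity_interaction_zero_main_inf(self):
        sst = ["y", "y", "n", "n"] * 2
        lin = ["y", "n", "y", "n"] * 2
        omega = [0.3 + (0.1 if s == "y" else 0) + (0.05 if l == "y" else 0)
                 for s, l in zip(sst, lin)]
        out = two_way_anova(omega, sst, lin)
        assert out["interaction"].statistic == 0.0
        assert out["sst"].statistic == np.inf
        assert out["sst"].flags.get("exact_fit")

    def test_matches_direct_sums_of_squares_on_balanced_design(self, rng):
        # balanced 2x2 with replication: type II == classic factorial SS
        levels = [("y", "y"), ("y", "n"), ("n", "y"), ("n", "n")]
        sst, lin, y = [], [], []
        for s, l in levels:
            for _ in range(6):
                sst.append(s)
                lin.append(l)
                y.append(rng.normal(0.1 + (0.05 if s == "y" else 0), 0.02))
        y = np.array(y)
        out = two_way_anova(y, sst, lin)
        # direct balanced-design SS computation
        y_mean = y.mean()
        sst_arr, lin_arr = np.array(sst), np.array(lin)
        ss_a = sum(
            24 / 2 * (y[sst_arr == v].mean() - y_mean) ** 2 for v in ("y", "n")
        )
        ss_b = sum(
            24 / 2 * (y[lin_arr == v].mean() - y_mean) ** 2 for v in ("y", "n")
        )
        cell_means = {
            (s, l): y[(sst_arr == s) & (lin_arr == l)].mean() for s, l in levels
        }
        ss_ab = sum(
            6 * (cell_means[(s, l)]
                 - y[sst_arr == s].mean() - y[lin_arr == l].mean() + y_mean) ** 2
            for s, l in levels
        )
        ss_res = sum(
            (y[(sst_arr == s) & (lin_arr == l)] - cell_means[(s, l)]) ** 2
            for s, l in levels
        ).sum()
        f_a = (ss_a / 1) / (ss_res / 20)
        f_b = (ss_b / 1) / (ss_res / 20)
        f_ab = (ss_ab / 1) / (ss_res / 20)
        assert out["sst"].statistic == pytest.approx(f_a, rel=1e-9)
        assert out["lineage"].statistic == pytest.approx(f_b, rel=1e-9)
        assert out["interaction"].statistic == pytest.approx(f_ab, rel=1e-9)


class TestOlderPeakEnrichment:
    def _model_and_assignments(self, values):
        m = fit_gmm(
            np.concatenate([
                np.random.default_rng(3).normal(0.05, 0.02, 200),
                np.random.default_rng(4).normal(0.6, 0.08, 200),
            ]),
            K=2,
        )
        return m, assign_components(values, m)

    def test_clean_separation_fractions(self):
        m, asg = self._model_and_assignments([0.6, 0.6, 0.05, 0.05])
        r = older_peak_enrichment(asg, ["SST", "SST", "non-SST", "non-SST"], m)
        assert r.group_summary["SST"]["fraction"] == 1.0
        assert r.group_summary["non-SST"]["fraction"] == 0.0

    def test_category_with_no_nodes_missing(self):
        m, asg = self._model_and_assignments([0.6])
        r = older_peak_enrichment(asg, ["SST"], m)
        assert "non-SST" not in r.group_summary

    def test_length_mismatch_rejected(self):
        m, asg = self._model_and_assignments([0.6])
        with pytest.raises(ValueError):
            older_peak_enrichment(asg, ["SST", "non-SST"], m)
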