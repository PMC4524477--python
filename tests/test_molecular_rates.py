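import numpy as np
import pytest

import dupscape as d
from dupscape.core_io import Node, Tree, parse_newick
from dupscape.molecular_rates import (
    CODONS,
    NodeDate,
    STOPS,
    codon_tables,
    date_duplication_node,
    date_speciation_node,
    date_tree_nodes,
    encode_codons,
    family_omega,
    filter_duplication_nodes,
    nearest_paralog_check,
    ng86_pair,
)
from conftest import (
    SENSE_CODONS,
    oracle_pair_diffs,
    oracle_syn_sites,
)


class TestNG86Pair:
    def test_identical_sequences(self):
        r = ng86_pair("ATGAAATTT", "ATGAAATTT")
        assert r.Sd == 0 and r.Nd == 0
        assert r.dS == 0 and r.dN == 0
        assert not r.saturated

    def test_ttt_synonymous_site_fraction(self):
        # of TTT's 9 single-nt neighbors only TTC is synonymous
        r = ng86_pair("TTT", "TTT")
        assert r.S == pytest.approx(1.0 / 3.0)

    def test_worked_example_ten_codons_one_synonymous_change(self):
        r = ng86_pair("TTT" * 10, "TTC" + "TTT" * 9)
        assert r.S == pytest.approx(10.0 / 3.0)
        assert r.Sd == pytest.approx(1.0)
        assert r.pS == pytest.approx(0.3)
        assert r.dS == pytest.approx(-0.75 * np.log(0.6), abs=1e-12)

    def test_sites_and_differences_match_enumeration_oracle(self):
        # every sense codon's site count, and a sample of codon pairs
        tab = codon_tables()
        for codon in SENSE_CODONS:
            idx = CODONS.index(codon)
            assert tab["syn_sites"][idx] == pytest.approx(
                oracle_syn_sites(codon), abs=1e-12
            )
        rng = np.random.default_rng(0)
        for _ in range(300):
            c1, c2 = rng.choice(SENSE_CODONS, 2)
            idx1, idx2 = CODONS.index(c1), CODONS.index(c2)
            sd, nd = oracle_pair_diffs(c1, c2)
            assert tab["sd"][idx1, idx2] == pytest.approx(sd, abs=1e-12)
            assert tab["nd"][idx1, idx2] == pytest.approx(nd, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_site_sum_invariant(self, seed):
        rng = np.random.default_rng(seed)
        s1 = "".join(rng.choice(SENSE_CODONS, 30))
        s2 = "".join(rng.choice(SENSE_CODONS, 30))
        r12 = ng86_pair(s1, s2)
        r21 = ng86_pair(s2, s1)
        assert r12.dS == pytest.approx(r21.dS, nan_ok=True)
        assert r12.dN == pytest.approx(r21.dN, nan_ok=True)
        assert r12.S + r12.N == pytest.approx(3 * r12.n_codons, abs=1e-9)

    def test_gap_and_n_codons_skipped_pairwise(self):
        r = ng86_pair("ATG---TTT", "ATGAAATTC")
        assert r.n_codons == 2
        r2 = ng86_pair("ATGANATTT", "ATGAAATTT")
        assert r2.n_codons == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair("ATGAAA", "ATG")

    def test_saturation_flagged(self):
        # wildly different sequences at every codon
        s1 = "TTT" * 30
        s2 = "AGG" * 30
        r = ng86_pair(s1, s2)
        assert r.saturated or np.isfinite(r.dS)


class TestNodeDating:
    def _family(self):
        # ((Lhes|x1, Lhes|x2), Lgeo|y): duplication node above x1/x2
        root = Node()
        dup = Node()
        for nm in ("Lhes|x1", "Lhes|x2"):
            dup.add_child(Node(name=nm, length=0.1))
        dup.length = 0.1
        root.add_child(dup)
        root.add_child(Node(name="Lgeo|y", length=0.2))
        return Tree(root)

    def test_duplication_node_mean_of_conspecific_pairs(self):
        tree = self._family()
        aln = {
            "Lhes|x1": "TTT" * 10,
            "Lhes|x2": "TTC" + "TTT" * 9,
            "Lgeo|y": "TTT" * 10,
        }
        dup = tree.root.children[0]
        nd = date_duplication_node(dup, {k: encode_codons(v) for k, v in aln.items()})
        assert nd.pair_count == 1
        assert nd.ds_mean == pytest.approx(-0.75 * np.log(0.6))

    def test_mean_matches_independent_per_pair_recomputation(self):
        cfg = d.SimulationConfig(n_families=1, codons_per_gene=200, seed=13)
        fam = d.simulate_dataset(cfg)[0]
        res = d.analyze_family(fam.alignment, cfg.species_tree, fam.id)
        assert res is not None
        tree, dates = res
        for nd in dates:
            if nd.ds_mean is None:
                continue
            node = nd.node
            left = node.children[0].leaves()
            right = node.children[1].leaves()
            vals = []
            for x in left:
                for y in right:
                    same = x.name.split("|")[0] == y.name.split("|")[0]
                    if (nd.node_kind == "duplication") != same:
                        continue
                    r = ng86_pair(fam.alignment[x.name], fam.alignment[y.name])
                    if np.isfinite(r.dS):
                        vals.append(r.dS)
            assert nd.ds_mean == pytest.approx(float(np.mean(vals)))

    def test_all_cross_species_descendants_undated(self):
        root = Node()
        root.add_child(Node(name="Lhes|x", length=0.1))
        root.add_child(Node(name="Lgeo|y", length=0.1))
        nd = date_duplication_node(
            root, {"Lhes|x": encode_codons("TTT"), "Lgeo|y": encode_codons("TTT")}
        )
        assert nd.ds_mean is None and nd.pair_count == 0

    def test_speciation_node_dating(self):
        root = Node()
        root.add_child(Node(name="Lhes|x", length=0.1))
        root.add_child(Node(name="Lgeo|y", length=0.1))
        enc = {
            "Lhes|x": encode_codons("TTT" * 10),
            "Lgeo|y": encode_codons("TTC" + "TTT" * 9),
        }
        nd = date_speciation_node(root, enc)
        assert nd.ds_mean == pytest.approx(-0.75 * np.log(0.6))
        # single-species descendants -> undated
        root2 = Node()
        root2.add_child(Node(name="Lhes|a"))
        root2.add_child(Node(name="Lhes|b"))
        nd2 = date_speciation_node(root2, {
            "Lhes|a": encode_codons("TTT"), "Lhes|b": encode_codons("TTT")
        })
        assert nd2.ds_mean is None


class TestFilters:
    def _nd(self, ds):
        return NodeDate("f", "n", "duplication", ds, 1)

    def test_boundary_semantics(self):
        kept = filter_duplication_nodes(
            [self._nd(0.005), self._nd(0.01), self._nd(1.9), self._nd(2.0)]
        )
        assert [n.ds_mean for n in kept] == [0.01, 1.9]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_predicate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 2.5, 100)
        kept = filter_duplication_nodes([self._nd(v) for v in vals])
        want = [v for v in vals if 0.01 <= v < 2.0]
        assert [n.ds_mean for n in kept] == want


class TestFamilyOmega:
    def test_all_synonymous_differences_omega_zero(self):
        aln = {
            "a": "TTT" * 20,
            "b": "TTC" + "TTT" * 19,
            "c": "TTC" + "TTC" + "TTT" * 18,
        }
        st = family_omega(aln)
        assert st.omega == pytest.approx(0.0)

    def test_identical_sequences_omega_missing(self):
        aln = {k: "ATGAAATTT" * 5 for k in ("a", "b", "c")}
        st = family_omega(aln)
        assert st.omega is None

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            family_omega({"a": "ATG"})

    def test_recovers_generating_omega(self):
        # small-sample version of the estimator-vs-generator check
        means = {}
        for omega in (0.10, 0.05):
            vals = []
            for seed in range(12):
                cfg = d.SimulationConfig(
                    n_families=1, codons_per_gene=500, seed=seed,
                    small_dup_rate=0.0, wgd_branch=None,
                    omega_sst_mean=omega, omega_other_mean=omega,
                    omega_cv=0.0, rate_cv=0.0, sst_fraction=0.0,
                )
                fam = d.simulate_dataset(cfg)[0]
                st = family_omega(fam.alignment)
                if st.omega is not None:
                    vals.append(st.omega)
            means[omega] = float(np.mean(vals))
        assert means[0.10] == pytest.approx(0.10, abs=0.02)
        assert means[0.05] == pytest.approx(0.05, abs=0.02)


class TestEstimatorConsistency:
    def test_error_shrinks_with_codon_count(self):
        from dupscape.synthetic_evolution import simulate_codon_alignment

        target = 0.5
        maes = []
        for codons in (200, 2000, 20000):
            errs = []
            for seed in range(4):
                rng = np.random.default_rng(seed)
                root = Node()
                root.add_child(Node(name="A|x", length=target / 2))
                root.add_child(Node(name="B|y", length=target / 2))
                aln = simulate_codon_alignment(Tree(root), 0.0, codons, rng=rng)
                r = ng86_pair(aln["A|x"], aln["B|y"])
                errs.append(abs(r.dS - target))
            maes.append(float(np.mean(errs)))
        assert maes[0] > maes[1] > 0
        assert maes[2] <= maes[1] + 1e-3


class TestNearestParalog:
    def test_conspecific_cherry_listed(self):
        tree = parse_newick("((Lhes|a:0.01,Lhes|b:0.01):1,Lgeo|c:1);")
        aln = {
            "Lhes|a": "TTT" * 10, "Lhes|b": "TTC" + "TTT" * 9,
            "Lgeo|c": "AGG" * 10,
        }
        vals = nearest_paralog_check(tree, aln)
        assert len(vals) == 1
        assert vals[0] == pytest.approx(-0.75 * np.log(0.6))

    def test_no_conspecific_cherries_empty(self):
        tree = parse_newick("((Lhes|a:1,Lgeo|b:1):1,Sgro|c:1);")
        aln = {k: "TTT" * 5 for k in ("Lhes|a", "Lgeo|b", "Sgro|c")}
        assert nearest_paralog_check(tree, aln) == []

    def test_recent_duplicates_sit_at_small_ds(self):
        cfg = d.SimulationConfig(
            n_families=30, codons_per_gene=300, seed=17, wgd_branch=None,
        )
        fams = d.simulate_dataset(cfg)
        vals = []
        for fam in fams:
            vals.extend(nearest_paralog_check(fam.tree, fam.alignment))
        assert vals, "expected some conspecific cherries"
        assert float(np.median(vals)) < 0.2
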