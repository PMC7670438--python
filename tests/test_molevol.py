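"""Nei-Gojobori machinery, JC correction, codon usage, NJ and clade placement."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ng_pair, ng_pathways, ng_sites
from xeno.molevol import (
    MULTI_CODON_AAS,
    PhylogramTree,
    SaturationError,
    clade_nesting_check,
    codon_usage_profile,
    count_pathway_differences,
    count_sites,
    group_kaks,
    jukes_cantor_correct,
    nei_gojobori,
    nj_tree,
    p_distance_matrix,
    percent_identity,
    thread_codon_alignment,
)
from xeno.records import SENSE_CODONS


class TestSiteCounts:
    def test_phenylalanine_codon(self):
        sc = count_sites("TTT")
        assert sc.S == pytest.approx(1 / 3)
        assert sc.N == pytest.approx(8 / 3)

    def test_tryptophan_has_no_synonymous_sites(self):
        sc = count_sites("TGG")
        assert sc.S == 0.0 and sc.N == 3.0

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_sites_sum_to_three_and_match_oracle(self, codon):
        sc = count_sites(codon)
        assert sc.S + sc.N == pytest.approx(3.0, abs=1e-12)
        s_oracle, n_oracle = ng_sites(codon)
        assert sc.S == pytest.approx(s_oracle, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")


class TestPathwayDifferences:
    def test_single_nonsynonymous_step(self):
        assert count_pathway_differences("TTT", "TTA") == (0.0, 1.0)

    def test_two_pathway_average(self):
        assert count_pathway_differences("TTT", "GTA") == (0.5, 1.5)

    def test_identical_codons(self):
        assert count_pathway_differences("AAA", "AAA") == (0.0, 0.0)

    def test_symmetry_and_oracle_all_pairs(self):
        for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
            fwd = count_pathway_differences(ca, cb)
            rev = count_pathway_differences(cb, ca)
            assert fwd == pytest.approx(rev, abs=1e-12)
            assert fwd == pytest.approx(ng_pathways(ca, cb), abs=1e-12)


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor_correct(0.0) == 0.0

    def test_known_value(self):
        assert jukes_cantor_correct(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jukes_cantor_correct(0.75)

    @given(st.floats(min_value=0.001, max_value=0.74))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_convex(self, p):
        h = 0.002
        if p + 2 * h >= 0.75:
            return
        d0, d1, d2 = (jukes_cantor_correct(x) for x in (p, p + h, p + 2 * h))
        assert d1 > d0                       # monotone increasing
        assert (d2 - d1) >= (d1 - d0) - 1e-12  # convex


class TestNeiGojobori:
    def test_identical_sequences(self):
        seq = "ATGGCTTTTAAA"
        res = nei_gojobori(seq, seq)
        assert res.Ka == 0.0 and res.Ks == 0.0 and res.ratio is None

    def test_symmetric_in_pair_order(self):
        a = "ATGGCTTTTAAACCGGGT"
        b = "ATGGCCTTAAAACCAGGC"
        r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
        assert r1.Ks == pytest.approx(r2.Ks) and r1.Ka == pytest.approx(r2.Ka)

    def test_gap_and_n_codons_skipped(self):
        a = "ATGGCT---TTT"
        b = "ATGGCCNNATTC"
        res = nei_gojobori(a, b)
        assert res.codons_used == 3

    def test_matches_bruteforce_oracle_on_small_alignments(self):
        rng = np.random.default_rng(42)
        codons = [c for c in SENSE_CODONS]
        for _ in range(25):
            n = int(rng.integers(2, 11))
            a = "".join(codons[i] for i in rng.integers(0, 61, n))
            b = "".join(codons[i] for i in rng.integers(0, 61, n))
            try:
                mine = nei_gojobori(a, b)
            except ValueError:
                continue
            if mine.saturated:
                continue
            ref = ng_pair(a, b)
            assert mine.S == pytest.approx(ref["S"], abs=1e-12)
            assert mine.Sd == pytest.approx(ref["Sd"], abs=1e-12)
            assert mine.Ks == pytest.approx(ref["Ks"], abs=1e-12)
            assert mine.Ka == pytest.approx(ref["Ka"], abs=1e-12)


class TestGroupKaKs:
    def _pairs(self, ks_values, ka_values):
        out = []
        for i, (ks, ka) in enumerate(zip(ks_values, ka_values)):
            p = nei_gojobori("ATGGCTTTT", "ATGGCTTTT", id_a=f"a{i}", id_b=f"b{i}")
            p.Ks, p.Ka = ks, ka
            p.ratio = ka / ks if ks else None
            out.append(p)
        return out

    def test_rate_is_average_over_age(self):
        # two pairs averaging to the target mean; rates divide by T once
        pairs = self._pairs([0.26, 0.2934], [0.1041, 0.1041])
        g = group_kaks(pairs, 21.0, label="Triticeae-Poeae")
        assert g.Ks_avg == pytest.approx(0.2767)
        assert round(g.Ks_rate, 4) == 0.0132
        assert round(g.Ka_rate, 4) == 0.0050
        assert round(g.ratio, 3) == 0.376

    def test_single_pair_sdv_zero(self):
        g = group_kaks(self._pairs([0.1435], [0.0519]), 7.2)
        assert g.Ks_sdv == 0.0 and g.Ka_sdv == 0.0
        assert round(g.Ks_rate, 4) == 0.0199
        assert round(g.Ka_rate, 4) == 0.0072

    def test_ratio_modes(self):
        pairs = self._pairs([0.2, 0.4], [0.05, 0.2])
        roa = group_kaks(pairs, 10.0, ratio_mode="ratio_of_averages")
        aor = group_kaks(pairs, 10.0, ratio_mode="average_of_ratios")
        assert roa.ratio == pytest.approx(0.125 / 0.3)
        assert aor.ratio == pytest.approx((0.25 + 0.5) / 2)

    def test_invalid_age(self):
        with pytest.raises(ValueError):
            group_kaks(self._pairs([0.1], [0.1]), 0.0)


class TestCodonUsage:
    def test_single_gene_tga_termination(self):
        profile = codon_usage_profile(["ATGGCTTGA"])
        assert profile.ratios["*"] == {"TGA": 1.0}

    def test_five_of_thirteen_tga(self):
        seqs = ["ATGGCT" + stop for stop in ["TGA"] * 5 + ["TAA"] * 4 + ["TAG"] * 4]
        profile = codon_usage_profile(seqs)
        assert profile.ratios["*"]["TGA"] == pytest.approx(5 / 13)
        assert round(100 * profile.ratios["*"]["TGA"], 1) == 38.5

    def test_ratios_sum_to_one_per_amino_acid(self):
        rng = np.random.default_rng(7)
        seq = "ATG" + "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 500)) + "TAA"
        profile = codon_usage_profile([seq])
        for aa in MULTI_CODON_AAS:
            if aa in profile.ratios:
                assert sum(profile.ratios[aa].values()) == pytest.approx(1.0, abs=1e-9)

    def test_met_and_trp_excluded(self):
        profile = codon_usage_profile(["ATGTGGTGA"])
        assert "M" not in profile.ratios and "W" not in profile.ratios

    def test_missing_terminal_stop_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="xeno"):
            profile = codon_usage_profile(["ATGGCTAAA"])
        assert "terminal stop" in caplog.text
        assert profile.ratios.get("*", {}) == {}


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity("A" * 100, "A" * 100) == 100.0

    def test_96_of_100(self):
        a = "A" * 100
        b = "A" * 96 + "C" * 4
        assert percent_identity(a, b) == 96.0

    def test_double_gap_columns_excluded(self):
        assert percent_identity("AC--G", "AC--G") == 100.0
        assert percent_identity("AC-G", "ACTG") == pytest.approx(75.0)


def _tree_splits(newick: str) -> set[frozenset]:
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    taxa = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    splits = set()
    for node in t.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(leaves) < len(taxa) - 1:
            splits.add(min(leaves, taxa - leaves, key=sorted))
    return splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = nj_tree(d)
        import dendropy

        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_recovers_additive_four_taxon_tree(self):
        # ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        d = pd.DataFrame(0.0, index=list("ABCD"), columns=list("ABCD"))
        dist = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
                ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
        for (i, j), v in dist.items():
            d.at[i, j] = d.at[j, i] = float(v)
        tree = nj_tree(d)
        assert _tree_splits(tree.newick) == {frozenset("AB")} | set()

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(11)
        for rep in range(10):
            n = int(rng.integers(4, 9))
            names = [f"t{i}" for i in range(n)]
            # build a random binary tree with random positive branch lengths
            import dendropy

            taxa = dendropy.TaxonNamespace(names)
            gen = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                taxon_namespace=taxa, rng=__import__("random").Random(int(rng.integers(1e9))),
            )
            for edge in gen.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(rng.uniform(0.5, 2.0))
            pdm = gen.phylogenetic_distance_matrix()
            d = pd.DataFrame(0.0, index=names, columns=names)
            for t1 in taxa:
                for t2 in taxa:
                    d.at[t1.label, t2.label] = pdm.patristic_distance(t1, t2)
            tree = nj_tree(d)
            gen.is_rooted = False
            assert _tree_splits(tree.newick) == _tree_splits(
                gen.as_string(schema="newick").strip()
            )

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        n = 6
        names = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0.0)
        mine = nj_tree(pd.DataFrame(mat, index=names, columns=names))
        theirs = skbio_nj(DistanceMatrix(mat, ids=names))
        assert _tree_splits(mine.newick) == _tree_splits(str(theirs).strip())

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [1.1, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)

    def test_fewer_than_three_taxa_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            nj_tree(d)


class TestPDistance:
    def test_mismatch_proportions(self):
        aln = {"a": "AAAA", "b": "AAAT", "c": "TTTT"}
        d = p_distance_matrix(aln)
        assert d.at["a", "b"] == pytest.approx(0.25)
        assert d.at["a", "c"] == pytest.approx(1.0)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)


class TestCladeNesting:
    def test_nested_in_crown(self):
        nwk = "((out1:1,out2:1):1,((ref1:1,(focal1:1,focal2:1):0.5):1,ref2:1):1);"
        assert clade_nesting_check(
            PhylogramTree(nwk), ["focal1", "focal2"], ["ref1", "ref2"], ["out1", "out2"]
        ) == "nested_in_crown"

    def test_sister_to_crown(self):
        nwk = "((out1:1,out2:1):1,((focal1:1,focal2:1):1,(ref1:1,ref2:1):1):1);"
        assert clade_nesting_check(
            PhylogramTree(nwk), ["focal1", "focal2"], ["ref1", "ref2"], ["out1", "out2"]
        ) == "sister_to_crown"

    def test_polyphyletic_focal_is_other(self):
        nwk = "((out1:1,out2:1):1,((focal1:1,ref1:1):1,(focal2:1,out3:1):1):1);"
        assert clade_nesting_check(
            PhylogramTree(nwk), ["focal1", "focal2"], ["ref1"], ["out1", "out2"]
        ) == "other"

    def test_missing_taxa_listed(self):
        nwk = "((a:1,b:1):1,c:1);"
        with pytest.raises(ValueError, match="missing"):
            clade_nesting_check(PhylogramTree(nwk), ["a"], ["zz"], ["c"])


class TestCodonThreading:
    def test_threads_protein_gaps_to_codon_gaps(self):
        protein = {"x": "M-K", "y": "MAK"}
        cds = {"x": "ATGAAATAA", "y": "ATGGCTAAA"}
        out = thread_codon_alignment(protein, cds)
        assert out["x"] == "ATG---AAA"
        assert out["y"] == "ATGGCTAAA"
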