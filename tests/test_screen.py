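"""Read collapsing, Karlin-Altschul statistics, seeded local search, triage."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from oracles import smith_waterman_alignment, smith_waterman_score
from xeno.records import Read, ReadSet, SequenceRecord, revcomp
from xeno.screen import (
    Panels,
    SearchParams,
    TriageParams,
    candidate_summary,
    classify_hits,
    collapse_unique_reads,
    hits_to_outfmt6,
    local_search,
    solve_karlin_lambda,
)

def _readset(seqs):
    reads = [Read(id=f"r{i}", seq=s, library_id="lib") for i, s in enumerate(seqs)]
    return ReadSet(reads=reads, library_size=len(reads))


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestCollapse:
    def test_multiplicities(self):
        rs = _readset(["ACGT" * 10, "ACGT" * 10, "ACGA" * 10])
        unique = collapse_unique_reads(rs)
        assert len(unique) == 2
        assert unique.multiplicities == [2, 1]
        assert sum(unique.multiplicities) == 3

    def test_all_distinct(self):
        rng = np.random.default_rng(0)
        rs = _readset([_random_dna(rng, 40) for _ in range(20)])
        assert len(collapse_unique_reads(rs)) == 20

    def test_order_stable_by_first_occurrence(self):
        rs = _readset(["C" * 30, "A" * 30, "C" * 30])
        unique = collapse_unique_reads(rs)
        assert unique.sequences == ["C" * 30, "A" * 30]


class TestKarlinAltschul:
    def test_lambda_matches_rootfinding_oracle(self):
        lam, K = solve_karlin_lambda(1, -2)
        oracle = brentq(
            lambda l: 0.25 * math.exp(l) + 0.75 * math.exp(-2 * l) - 1, 1e-9, 5,
            xtol=1e-12,
        )
        assert lam == pytest.approx(oracle, abs=1e-9)
        assert K == 0.3

    def test_scaled_scheme_lambda_relation(self):
        lam1, _ = solve_karlin_lambda(1, -2)
        lam2, _ = solve_karlin_lambda(2, -3)
        # +2/-3 is a laxer scheme than 2x(+1/-2): lambda below lam1/2, within 5%
        assert lam2 < lam1 / 2
        assert abs(lam2 - lam1 / 2) / (lam1 / 2) < 0.05
        # exact halving for a genuinely doubled scheme
        lam4, _ = solve_karlin_lambda(2, -4)
        assert lam4 == pytest.approx(lam1 / 2, rel=1e-9)

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError, match="scoring"):
            solve_karlin_lambda(1, 1)


class TestLocalSearch:
    def test_verbatim_embedded_query(self):
        rng = np.random.default_rng(1)
        gene = _random_dna(rng, 300)
        subject = _random_dna(rng, 5000) + gene + _random_dna(rng, 4700)
        hits = local_search(
            [SequenceRecord(id="q", seq=gene)],
            [SequenceRecord(id="s", seq=subject)],
        )
        assert hits
        best = hits[0]
        assert best.identity == 100.0
        assert best.raw_score >= 300
        assert best.e_value <= 1e-10
        assert best.strand == "+"

    def test_strand_symmetry(self):
        rng = np.random.default_rng(2)
        gene = _random_dna(rng, 300)
        subject = _random_dna(rng, 2000) + gene + _random_dna(rng, 2000)
        fwd = local_search([SequenceRecord(id="q", seq=gene)],
                           [SequenceRecord(id="s", seq=subject)])
        rev = local_search([SequenceRecord(id="q", seq=revcomp(gene))],
                           [SequenceRecord(id="s", seq=subject)])
        assert fwd and rev
        assert rev[0].strand == "-"
        assert rev[0].raw_score == fwd[0].raw_score
        assert (rev[0].subject_start, rev[0].subject_end) == (
            fwd[0].subject_start, fwd[0].subject_end)

    def test_random_queries_find_nothing_at_threshold(self):
        rng = np.random.default_rng(3)
        subject = SequenceRecord(id="s", seq=_random_dna(rng, 10_000))
        queries = [SequenceRecord(id=f"q{i}", seq=_random_dna(rng, 60))
                   for i in range(100)]
        assert local_search(queries, [subject]) == []

    def test_query_shorter_than_word_size_skipped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="xeno"):
            hits = local_search([SequenceRecord(id="q", seq="ACGTACGT")],
                                [SequenceRecord(id="s", seq="ACGTACGT" * 20)])
        assert hits == []
        assert "word size" in caplog.text

    def test_protein_input_rejected(self):
        q = SequenceRecord(id="q", seq="MKV" * 20, moltype="protein")
        with pytest.raises(ValueError, match="DNA"):
            local_search([q], [SequenceRecord(id="s", seq="ACGT" * 30)])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        gene = _random_dna(rng, 200)
        mutated = list(gene)
        for i in rng.integers(0, 200, 8):
            mutated[int(i)] = "ACGT"[int(rng.integers(0, 4))]
        subject = SequenceRecord(id="s", seq=_random_dna(rng, 500) + "".join(mutated))
        query = SequenceRecord(id="q", seq=gene)
        strict = local_search([query], [subject],
                              SearchParams(word_size=16, e_value_threshold=1e-10))
        loose = local_search([query], [subject],
                             SearchParams(word_size=16, e_value_threshold=1e-2))
        key = lambda h: (h.query_id, h.subject_id, h.query_start, h.subject_start)
        assert {key(h) for h in strict} <= {key(h) for h in loose}

    def test_matches_smith_waterman_when_seed_in_optimal_alignment(self):
        """On small instances the seeded search attains the full SW optimum
        whenever an exact word of the seed length lies on the optimal path."""
        rng = np.random.default_rng(5)
        params = SearchParams(word_size=8, e_value_threshold=float("inf"))
        checked = 0
        for _ in range(40):
            qlen = int(rng.integers(20, 31))
            query = _random_dna(rng, qlen)
            # embed a mutated copy in the subject
            copy = list(query)
            for i in rng.integers(0, qlen, int(rng.integers(0, 4))):
                copy[int(i)] = "ACGT"[int(rng.integers(0, 4))]
            subject = (_random_dna(rng, int(rng.integers(20, 100)))
                       + "".join(copy)
                       + _random_dna(rng, int(rng.integers(20, 80))))
            sw, cols = smith_waterman_alignment(query, subject, params.match,
                                                params.mismatch, params.gap_cost)
            # longest run of consecutive exact-match columns on the optimal path
            run = best_run = 0
            for qi, sj in cols:
                if qi is not None and sj is not None and query[qi] == subject[sj]:
                    run += 1
                    best_run = max(best_run, run)
                else:
                    run = 0
            if best_run < params.word_size:
                continue
            hits = local_search([SequenceRecord(id="q", seq=query)],
                                [SequenceRecord(id="s", seq=subject)], params)
            fwd = [h for h in hits if h.strand == "+"]
            assert fwd, "seeded search missed an alignment with a seed on the optimal path"
            assert max(h.raw_score for h in fwd) == sw
            checked += 1
        assert checked >= 10

    def test_outfmt6_rendering(self):
        rng = np.random.default_rng(6)
        gene = _random_dna(rng, 200)
        subject = SequenceRecord(id="s", seq=gene)
        hits = local_search([SequenceRecord(id="q", seq=gene)], [subject])
        line = hits_to_outfmt6(hits)[0].split("\t")
        assert line[0] == "q" and line[1] == "s"
        assert float(line[2]) == 100.0
        assert int(line[6]) == 1 and int(line[7]) == 200   # 1-based inclusive
        assert int(line[8]) == 1 and int(line[9]) == 200


def _mutate(seq, n, rng):
    out = list(seq)
    for i in rng.choice(len(seq), size=n, replace=False):
        out[int(i)] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[int(i)]]
    return "".join(out)


class TestTriage:
    @pytest.fixture()
    def scenario(self):
        rng = np.random.default_rng(9)
        donor_gene = _random_dna(rng, 600)       # transferred gene, donor copy
        donor_only = _random_dna(rng, 600)       # donor-specific gene
        conserved = _random_dna(rng, 600)        # conserved across everything
        host_copy = _mutate(donor_gene, 24, rng)      # ~96% identity
        host_conserved = _mutate(conserved, 12, rng)  # ~98% to donor copy
        outgroup_conserved = _mutate(conserved, 18, rng)
        queries = [
            SequenceRecord(id="host_copy", seq=host_copy, taxon="host"),
            SequenceRecord(id="microbe_read", seq=donor_only[100:250], taxon="host"),
            SequenceRecord(id="conserved_read", seq=host_conserved[50:500], taxon="host"),
        ]
        subjects = [
            SequenceRecord(id="donor_gene", seq=donor_gene, taxon="donor"),
            SequenceRecord(id="donor_only", seq=donor_only, taxon="donor"),
            SequenceRecord(id="donor_conserved", seq=conserved, taxon="donor"),
        ]
        panels = Panels(
            outgroup_plant=[SequenceRecord(id="out_cons", seq=outgroup_conserved,
                                           taxon="outgroup")],
            host_assembly=[
                SequenceRecord(id="asm_copy", seq=host_copy, taxon="host"),
                SequenceRecord(id="asm_cons", seq=host_conserved, taxon="host"),
            ],
            donor=subjects,
        )
        hits = local_search(queries, subjects)
        return queries, subjects, panels, hits

    def test_categories_follow_rules(self, scenario):
        queries, _, panels, hits = scenario
        classifications, counts = classify_hits(hits, queries, panels)
        by_query = {}
        for cl in classifications:
            by_query.setdefault(cl.hit.query_id, set()).add(cl.category)
        assert by_query["host_copy"] == {"hgt_candidate"}
        assert by_query["microbe_read"] == {"microbiome"}
        assert by_query["conserved_read"] == {"conserved_eukaryote"}

    def test_partition_counts_sum_to_total(self, scenario):
        queries, _, panels, hits = scenario
        classifications, counts = classify_hits(hits, queries, panels)
        assert sum(counts.values()) == len(hits) == len(classifications)

    def test_evidence_nonempty_for_excluded_hits(self, scenario):
        queries, _, panels, hits = scenario
        classifications, _ = classify_hits(hits, queries, panels)
        for cl in classifications:
            if cl.category != "hgt_candidate":
                assert cl.evidence

    def test_low_similarity_rule_first(self, scenario):
        queries, _, panels, hits = scenario
        classifications, counts = classify_hits(
            hits, queries, panels, TriageParams(min_len=10_000)
        )
        assert counts["low_similarity"] == len(hits)

    def test_missing_panel_warns(self, scenario, caplog):
        import logging

        queries, _, _, hits = scenario
        with caplog.at_level(logging.WARNING, logger="xeno"):
            classify_hits(hits, queries, Panels())
        assert "panels missing" in caplog.text


class TestCandidateSummary:
    def _hit(self, query, subject, identity, s0, s1):
        from xeno.screen import SimilarityHit

        return SimilarityHit(
            query_id=query, subject_id=subject, query_start=0, query_end=s1 - s0,
            subject_start=s0, subject_end=s1, strand="+", aligned_len=s1 - s0,
            matches=s1 - s0, mismatches=0, gap_opens=0, identity=identity,
            raw_score=s1 - s0, bit_score=100.0, e_value=1e-30,
        )

    def _wrap(self, hits):
        from xeno.screen import HitClassification

        return [HitClassification(hit=h, category="hgt_candidate", evidence=[])
                for h in hits]

    def test_five_hits_three_genes(self):
        hits = [
            self._hit("q1", "geneA", 95.0, 0, 100),
            self._hit("q2", "geneA", 97.0, 50, 200),
            self._hit("q3", "geneB", 90.0, 0, 80),
            self._hit("q4", "geneC", 99.0, 0, 120),
            self._hit("q5", "geneC", 91.0, 200, 300),
        ]
        table = candidate_summary(self._wrap(hits))
        assert len(table) == 3
        row_a = table[table.subject_gene == "geneA"].iloc[0]
        assert row_a.best_identity == 97.0 and row_a.n_hits == 2
        assert row_a.coverage_nt == 200  # union of [0,100) and [50,200)
        row_c = table[table.subject_gene == "geneC"].iloc[0]
        assert row_c.coverage_nt == 220  # disjoint intervals

    def test_empty_input(self):
        assert len(candidate_summary([])) == 0
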