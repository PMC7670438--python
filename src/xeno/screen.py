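"""Similarity screening: read collapsing, seeded local alignment, hit triage.

The search is a megablast-style seed-and-extend: exact word hits on both
strands are extended first ungapped and then by banded gapped dynamic
programming with an X-drop cutoff, to a local optimum.  Raw scores are
converted to bit scores and E-values with Karlin–Altschul statistics
(lambda solved numerically for the scoring scheme; K is a configurable
constant, by default 0.3 — adequate at the thresholds used here).

Hit triage operationalises a manual curation step: hits are assigned, in
fixed rule order, to low-similarity, conserved-eukaryote (query co-hits an
outgroup-plant panel), microbiome (near-verbatim donor match with no support
in the host genome assembly), or HGT-candidate categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.optimize import brentq

from .records import Read, ReadSet, SequenceRecord, revcomp

logger = logging.getLogger("xeno")

CATEGORIES = ("low_similarity", "conserved_eukaryote", "microbiome", "hgt_candidate")


# ---------------------------------------------------------------------------
# read collapsing
# ---------------------------------------------------------------------------

@dataclass
class UniqueReadSet:
    """Exact-deduplicated reads with multiplicities, stable by first seen."""

    sequences: list[str]
    ids: list[str]
    multiplicities: list[int]
    library_id: str
    input_count: int

    def __len__(self) -> int:
        return len(self.sequences)


def collapse_unique_reads(reads: ReadSet) -> UniqueReadSet:
    seen: dict[str, int] = {}
    ids: list[str] = []
    counts: list[int] = []
    for r in reads:
        idx = seen.get(r.seq)
        if idx is None:
            seen[r.seq] = len(ids)
            ids.append(r.id)
            counts.append(1)
        else:
            counts[idx] += 1
    return UniqueReadSet(
        sequences=list(seen), ids=ids, multiplicities=counts,
        library_id=reads.library_id, input_count=len(reads),
    )


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics
# ---------------------------------------------------------------------------

def solve_karlin_lambda(
    match: float,
    mismatch: float,
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    *,
    K: float = 0.3,
) -> tuple[float, float]:
    """Solve for the Karlin–Altschul lambda of a match/mismatch scheme.

    Lambda is the unique positive root of sum_ij p_i p_j exp(lambda s_ij) = 1.
    K is returned as given (a configured constant, not estimated).
    """
    if match <= 0:
        raise ValueError("match score must be positive")
    p = base_freqs
    if abs(sum(p) - 1) > 1e-9 or any(x < 0 for x in p):
        raise ValueError("base frequencies must be nonnegative and sum to 1")
    p_match = sum(x * x for x in p)
    expected = p_match * match + (1 - p_match) * mismatch
    if expected >= 0:
        raise ValueError(
            f"expected score per aligned pair {expected:g} is nonnegative; "
            "invalid scoring scheme"
        )

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + (1 - p_match) * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e4:
            raise RuntimeError("failed to bracket lambda")
    lam = brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12)
    return (float(lam), K)


# ---------------------------------------------------------------------------
# local search
# ---------------------------------------------------------------------------

@dataclass
class SearchParams:
    """Scoring and thresholding for the seeded local search.

    Gaps cost ``gap_cost`` per gap column (linear gap penalty).
    """

    word_size: int = 28
    match: int = 1
    mismatch: int = -2
    gap_cost: int = 4
    e_value_threshold: float = 1e-10
    K: float = 0.3
    band: int = 16
    x_drop: int = 20
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def karlin(self) -> tuple[float, float]:
        return solve_karlin_lambda(self.match, self.mismatch, self.base_freqs, K=self.K)


#: BLASTN-like parameters for cross-species (lower-identity) searches
CROSS_SPECIES_PARAMS = dict(word_size=12, match=2, mismatch=-3, gap_cost=5)


@dataclass
class SimilarityHit:
    query_id: str
    subject_id: str
    query_start: int  # 0-based half-open, on the forward query
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    aligned_len: int
    matches: int
    mismatches: int
    gap_opens: int
    identity: float  # percent
    raw_score: float
    bit_score: float
    e_value: float


NEG = float("-inf")


def _extend_dir(q: str, s: str, params: SearchParams) -> tuple[float, int, int, int, int, int]:
    """Banded, X-dropped extension of alignments of prefixes of q against s.

    The alignment is anchored at DP(0,0)=0 and free to end anywhere; the band
    is around the main diagonal.  Returns (best score, qi, sj, matches,
    mismatches, gap_opens) for the best cell, where qi/sj are the prefix
    lengths consumed.
    """
    band, xd = params.band, params.x_drop
    gp, ma, mi = params.gap_cost, params.match, params.mismatch
    rows: list[dict[int, tuple[float, str]]] = [{0: (0.0, "*")}]  # j -> (score, move)
    best_cell = (0.0, 0, 0)
    for i in range(1, len(q) + 1):
        prev = rows[-1]
        cur: dict[int, tuple[float, str]] = {}
        lo, hi = max(0, i - band), min(len(s), i + band)
        row_best = NEG
        for j in range(lo, hi + 1):
            cands = []
            if j >= 1 and (j - 1) in prev:
                cands.append((prev[j - 1][0] + (ma if q[i - 1] == s[j - 1] else mi), "D"))
            if j in prev:
                cands.append((prev[j][0] - gp, "U"))
            if (j - 1) in cur:
                cands.append((cur[j - 1][0] - gp, "L"))
            if not cands:
                continue
            val, move = max(cands)
            if val < best_cell[0] - xd:
                continue  # X-drop prune
            cur[j] = (val, move)
            row_best = max(row_best, val)
            if val > best_cell[0]:
                best_cell = (val, i, j)
        rows.append(cur)
        if not cur or row_best < best_cell[0] - xd:
            break
    score, bi, bj = best_cell
    matches = mismatches = gap_opens = 0
    i, j = bi, bj
    last_move = ""
    while i > 0 or j > 0:
        move = rows[i][j][1]
        if move == "*":
            break
        if move == "D":
            if q[i - 1] == s[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i, j = i - 1, j - 1
        elif move == "U":
            if last_move != "U":
                gap_opens += 1
            i -= 1
        else:
            if last_move != "L":
                gap_opens += 1
            j -= 1
        last_move = move
    return score, bi, bj, matches, mismatches, gap_opens


def _extend_seed(
    q: str, s: str, qpos: int, spos: int, wlen: int, params: SearchParams
) -> tuple[float, int, int, int, int, int, int, int]:
    """Extend an exact seed q[qpos:qpos+wlen] == s[spos:spos+wlen].

    Returns (score, qstart, qend, sstart, send, matches, mismatches, gapopens).
    """
    ma = params.match
    seed_score = wlen * ma
    fs, fi, fj, fm, fx, fg = _extend_dir(q[qpos + wlen :], s[spos + wlen :], params)
    rs, ri, rj, rm, rx, rg = _extend_dir(q[:qpos][::-1], s[:spos][::-1], params)
    score = seed_score + fs + rs
    return (
        score,
        qpos - ri,
        qpos + wlen + fi,
        spos - rj,
        spos + wlen + fj,
        wlen + fm + rm,
        fx + rx,
        fg + rg,
    )


def _seed_positions(qseq: str, index: dict[str, list[tuple[int, int]]], w: int):
    for qpos in range(0, len(qseq) - w + 1):
        word = qseq[qpos : qpos + w]
        if "N" in word:
            continue
        for sub_idx, spos in index.get(word, ()):
            yield qpos, sub_idx, spos


def local_search(
    queries: list[SequenceRecord],
    subjects: list[SequenceRecord],
    params: SearchParams | None = None,
) -> list[SimilarityHit]:
    """Seeded local alignment of every query against all subjects.

    Both strands are searched; hits with E-value at most the configured
    threshold are returned sorted by E-value (ties by query then subject id).
    """
    params = params or SearchParams()
    for rec in list(queries) + list(subjects):
        if rec.moltype == "protein":
            raise ValueError(f"{rec.id}: local_search requires DNA input")
    lam, K = params.karlin()
    w = params.word_size
    n_total = sum(len(s) for s in subjects)
    index: dict[str, list[tuple[int, int]]] = {}
    for si, sub in enumerate(subjects):
        seq = sub.seq
        for pos in range(0, len(seq) - w + 1):
            word = seq[pos : pos + w]
            if "N" not in word:
                index.setdefault(word, []).append((si, pos))

    hits: list[SimilarityHit] = []
    for query in queries:
        if len(query.seq) < w:
            logger.warning("query %s shorter than word size %d; skipped", query.id, w)
            continue
        m = len(query.seq)
        for strand in "+-":
            qseq = query.seq if strand == "+" else revcomp(query.seq)
            covered: dict[int, list[tuple[int, int, int, int]]] = {}
            best_by_span: dict[tuple, tuple[float, tuple]] = {}
            for qpos, si, spos in _seed_positions(qseq, index, w):
                skip = False
                for qs, qe, ss, se in covered.get(si, ()):
                    if qs <= qpos < qe and ss <= spos < se and abs(
                        (spos - qpos) - (ss - qs)
                    ) <= params.band:
                        skip = True
                        break
                if skip:
                    continue
                score, qs, qe, ss, se, mt, mx, gp = _extend_seed(
                    qseq, subjects[si].seq, qpos, spos, w, params
                )
                covered.setdefault(si, []).append((qs, qe, ss, se))
                e_value = K * m * n_total * math.exp(-lam * score)
                if e_value > params.e_value_threshold:
                    continue
                # aligned columns = matches + mismatches + gap columns
                gaps = (qe - qs - mt - mx) + (se - ss - mt - mx)
                aligned_len = mt + mx + gaps
                if strand == "+":
                    q_start, q_end = qs, qe
                else:
                    q_start, q_end = m - qe, m - qs
                key = (si, strand, q_start, q_end, ss, se)
                bit = (lam * score - math.log(K)) / math.log(2)
                hit = SimilarityHit(
                    query_id=query.id, subject_id=subjects[si].id,
                    query_start=q_start, query_end=q_end,
                    subject_start=ss, subject_end=se, strand=strand,
                    aligned_len=aligned_len, matches=mt, mismatches=mx,
                    gap_opens=gp, identity=100.0 * mt / aligned_len,
                    raw_score=score, bit_score=bit, e_value=e_value,
                )
                old = best_by_span.get(key)
                if old is None or score > old[0]:
                    best_by_span[key] = (score, hit)
            hits.extend(h for _, h in best_by_span.values())
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.query_id, h.subject_id,
                             h.query_start, h.subject_start))
    return hits


def hits_to_outfmt6(hits: list[SimilarityHit]) -> list[str]:
    """Render hits in the 12-column tabular format (1-based inclusive coords).

    Field order: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Minus-strand hits have subject coordinates
    reversed, as in the de-facto convention.
    """
    lines = []
    for h in hits:
        if h.strand == "+":
            ss, se = h.subject_start + 1, h.subject_end
        else:
            ss, se = h.subject_end, h.subject_start + 1
        lines.append(
            "\t".join(
                [
                    h.query_id, h.subject_id, f"{h.identity:.3f}", str(h.aligned_len),
                    str(h.mismatches), str(h.gap_opens),
                    str(h.query_start + 1), str(h.query_end),
                    str(ss), str(se), f"{h.e_value:.2e}", f"{h.bit_score:.1f}",
                ]
            )
        )
    return lines


# ---------------------------------------------------------------------------
# triage
# ---------------------------------------------------------------------------

@dataclass
class Panels:
    """Reference panels used in hit triage."""

    outgroup_plant: list[SequenceRecord] = field(default_factory=list)
    host_assembly: list[SequenceRecord] = field(default_factory=list)
    donor: list[SequenceRecord] = field(default_factory=list)


@dataclass
class TriageParams:
    min_identity: float = 60.0
    min_len: int = 50
    microbiome_identity: float = 98.0
    panel_params: SearchParams | None = None


@dataclass
class HitClassification:
    hit: SimilarityHit
    category: str
    evidence: list[str]


def classify_hits(
    hits: list[SimilarityHit],
    queries: list[SequenceRecord],
    panels: Panels,
    triage: TriageParams | None = None,
    search_params: SearchParams | None = None,
) -> tuple[list[HitClassification], dict[str, int]]:
    """Triage similarity hits into four categories, in fixed rule order.

    1. low_similarity: identity below ``min_identity`` or aligned length
       below ``min_len``;
    2. conserved_eukaryote: the query also hits the outgroup-plant panel at
       the E-value threshold;
    3. microbiome: near-verbatim donor identity (>= ``microbiome_identity``)
       with no supporting match in the host genome assembly;
    4. hgt_candidate otherwise.
    """
    triage = triage or TriageParams()
    search_params = search_params or SearchParams()
    panel_params = triage.panel_params or search_params
    qmap = {q.id: q for q in queries}

    missing = []
    if not panels.outgroup_plant:
        missing.append("outgroup_plant")
    if not panels.host_assembly:
        missing.append("host_assembly")
    if missing:
        logger.warning("triage panels missing: %s; affected rules skipped", ", ".join(missing))

    # batch panel searches: one pass per panel over the queries that survive
    # the low-similarity rule
    survivors = sorted(
        {
            h.query_id
            for h in hits
            if h.identity >= triage.min_identity and h.aligned_len >= triage.min_len
        }
    )
    panel_queries = [qmap[qid] for qid in survivors if qid in qmap]

    def panel_hit_ids(panel: list[SequenceRecord]) -> set[str]:
        if not panel or not panel_queries:
            return set()
        return {h.query_id for h in local_search(panel_queries, panel, panel_params)}

    outgroup_hits = panel_hit_ids(panels.outgroup_plant)
    host_support_ids = panel_hit_ids(panels.host_assembly)

    out: list[HitClassification] = []
    counts = {c: 0 for c in CATEGORIES}
    for hit in hits:
        evidence: list[str] = []
        if hit.identity < triage.min_identity or hit.aligned_len < triage.min_len:
            evidence.append(
                f"identity {hit.identity:.1f}% < {triage.min_identity}% or "
                f"aligned_len {hit.aligned_len} < {triage.min_len}"
            )
            category = "low_similarity"
        else:
            qid = hit.query_id
            if panels.outgroup_plant and qid in outgroup_hits:
                evidence.append("query co-hits outgroup-plant panel at threshold")
                category = "conserved_eukaryote"
            else:
                if panels.host_assembly:
                    host_support = qid in host_support_ids
                else:
                    host_support = True  # rule skipped: cannot call microbiome
                if hit.identity >= triage.microbiome_identity and not host_support:
                    evidence.append(
                        f"identity {hit.identity:.1f}% >= {triage.microbiome_identity}% "
                        "to donor and no co-locating host-assembly match"
                    )
                    category = "microbiome"
                else:
                    category = "hgt_candidate"
        out.append(HitClassification(hit=hit, category=category, evidence=evidence))
        counts[category] += 1
    return out, counts


def candidate_summary(classifications: list[HitClassification]) -> pd.DataFrame:
    """Per-donor-gene summary of HGT-candidate hits.

    One row per subject gene: best identity, total subject coverage (union of
    subject intervals, nt) and supporting hit count.
    """
    by_gene: dict[str, list[SimilarityHit]] = {}
    for cl in classifications:
        if cl.category == "hgt_candidate":
            by_gene.setdefault(cl.hit.subject_id, []).append(cl.hit)
    rows = []
    for gene in sorted(by_gene):
        ghits = by_gene[gene]
        intervals = sorted((h.subject_start, h.subject_end) for h in ghits)
        cov = 0
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e:
                cov += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        cov += cur_e - cur_s
        rows.append(
            {
                "subject_gene": gene,
                "best_identity": max(h.identity for h in ghits),
                "coverage_nt": cov,
                "n_hits": len(ghits),
            }
        )
    return pd.DataFrame(rows, columns=["subject_gene", "best_identity", "coverage_nt", "n_hits"])
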