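"""Molecular-evolution statistics for codon alignments.

Implements the Nei–Gojobori (1986) counting estimator of synonymous (Ks) and
nonsynonymous (Ka) substitutions per site with the Jukes–Cantor multiple-hit
correction, divergence-age-normalised group summaries, synonymous codon-usage
profiles including the termination signal, p-distances, neighbour-joining
phylograms, and a clade-nesting test used to place horizontally transferred
sequences relative to a donor crown group.

Site counting follows the equal-weight pathway convention: mutations to stop
codons count as nonsynonymous when counting sites, and minimal mutational
pathways that pass through a stop codon are excluded when counting
differences (with a warned fallback if every pathway is excluded).
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .records import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, translate_codon

logger = logging.getLogger("xeno")

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# site and difference counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous (S) and nonsynonymous (N) site counts; S+N=3."""

    S: float
    N: float


@functools.lru_cache(maxsize=None)
def count_sites(codon: str) -> SiteCounts:
    """Nei–Gojobori fractional site counts for one sense codon.

    Each of the nine single-nucleotide neighbours is classified as synonymous
    or not under the standard code; changes producing a stop codon count as
    nonsynonymous.  S = 3 x (synonymous fraction of the nine changes).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in CODON_TO_AA:
        raise ValueError(f"invalid codon {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
    S = syn / 3.0
    return SiteCounts(S=S, N=3.0 - S)


@functools.lru_cache(maxsize=None)
def count_pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences (Sd, Nd).

    All minimal mutational pathways between the codons (1, 2 or 6 orderings
    of the differing positions) are enumerated; pathways passing through a
    stop codon are excluded.  If every pathway is excluded the average falls
    back to all pathways, with a warning.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in CODON_TO_AA:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    kept: list[tuple[int, int]] = []
    dropped: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        current = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if translate_codon(current) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        (dropped if through_stop else kept).append((sd, nd))
    if not kept:
        logger.warning(
            "all pathways between %s and %s pass through a stop codon; including them",
            codon_a, codon_b,
        )
        kept = dropped
    sd = sum(p[0] for p in kept) / len(kept)
    nd = sum(p[1] for p in kept) / len(kept)
    return (sd, nd)


def jukes_cantor_correct(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - (4/3) p); requires p < 0.75."""
    if p < 0:
        raise ValueError(f"proportion {p} < 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 0.75: distance saturated/undefined")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


class SaturationError(ValueError):
    """Observed difference proportion at or past the JC saturation point."""


# ---------------------------------------------------------------------------
# pairwise and group Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class PairwiseKaKs:
    id_a: str
    id_b: str
    Sd: float
    Nd: float
    S: float
    N: float
    ps: float
    pn: float
    Ks: float | None
    Ka: float | None
    ratio: float | None  # Ka/Ks; None if undefined, inf flag if Ks=0 < Ka
    saturated: bool = False
    codons_used: int = 0


def _countable_codons(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("alignment length not divisible by 3")
    out = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        out.append((ca, cb))
    return out


def nei_gojobori(seq_a: str, seq_b: str, *, id_a: str = "a", id_b: str = "b") -> PairwiseKaKs:
    """Nei–Gojobori Ka/Ks for one aligned CDS pair (gap/N codons skipped)."""
    pairs = _countable_codons(seq_a, seq_b)
    if not pairs:
        raise ValueError(f"{id_a} vs {id_b}: no countable codons")
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, sb = count_sites(ca), count_sites(cb)
        S += (sa.S + sb.S) / 2.0
        N += (sa.N + sb.N) / 2.0
        sd, nd = count_pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = False
    try:
        Ks: float | None = jukes_cantor_correct(ps)
    except SaturationError:
        Ks, saturated = None, True
    try:
        Ka: float | None = jukes_cantor_correct(pn)
    except SaturationError:
        Ka, saturated = None, True
    if Ks is None or Ka is None:
        ratio = None
    elif Ks > 0:
        ratio = Ka / Ks
    elif Ka > 0:
        ratio = math.inf
    else:
        ratio = None
    return PairwiseKaKs(
        id_a=id_a, id_b=id_b, Sd=Sd, Nd=Nd, S=S, N=N, ps=ps, pn=pn,
        Ks=Ks, Ka=Ka, ratio=ratio, saturated=saturated, codons_used=len(pairs),
    )


@dataclass
class GroupKaKsSummary:
    """Divergence-age-normalised Ka/Ks summary for a group of pairs.

    Rates divide the group-average distance by the divergence age T once
    (the convention of the source data tables), not by 2T.
    """

    label: str
    T: float
    n_pairs: int
    Ks_avg: float
    Ks_sdv: float
    Ks_rate: float
    Ka_avg: float
    Ka_sdv: float
    Ka_rate: float
    ratio: float
    ratio_mode: str = "ratio_of_averages"


def group_kaks(
    pairs: list[PairwiseKaKs],
    T: float,
    *,
    label: str = "",
    ratio_mode: str = "ratio_of_averages",
) -> GroupKaKsSummary:
    """Average pairwise Ka/Ks over a group and normalise by divergence age.

    ``ratio_mode`` chooses between Ka_avg/Ks_avg (``ratio_of_averages``) and
    the mean of per-pair ratios (``average_of_ratios``).
    """
    if T <= 0:
        raise ValueError(f"divergence age T={T} must be positive")
    usable = [p for p in pairs if not p.saturated and p.Ks is not None and p.Ka is not None]
    if not usable:
        raise ValueError(f"group {label!r}: no unsaturated pairs")
    ks = np.array([p.Ks for p in usable], dtype=float)
    ka = np.array([p.Ka for p in usable], dtype=float)
    ks_avg, ka_avg = float(ks.mean()), float(ka.mean())
    if ratio_mode == "ratio_of_averages":
        ratio = ka_avg / ks_avg if ks_avg > 0 else math.inf
    elif ratio_mode == "average_of_ratios":
        rs = [p.ratio for p in usable if p.ratio is not None and math.isfinite(p.ratio)]
        if not rs:
            raise ValueError(f"group {label!r}: no finite per-pair ratios")
        ratio = float(np.mean(rs))
    else:
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    return GroupKaKsSummary(
        label=label, T=T, n_pairs=len(usable),
        Ks_avg=ks_avg, Ks_sdv=float(ks.std()), Ks_rate=ks_avg / T,
        Ka_avg=ka_avg, Ka_sdv=float(ka.std()), Ka_rate=ka_avg / T,
        ratio=ratio, ratio_mode=ratio_mode,
    )


def group_kaks_table(groups: list[GroupKaKsSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "combination": g.label, "T_mya": g.T, "n_pairs": g.n_pairs,
                "Ks_avg": g.Ks_avg, "Ks_sdv": g.Ks_sdv, "Ks_rate": g.Ks_rate,
                "Ka_avg": g.Ka_avg, "Ka_sdv": g.Ka_sdv, "Ka_rate": g.Ka_rate,
                "Ka_Ks": g.ratio,
            }
            for g in groups
        ]
    )


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

#: amino acids with more than one codon under the standard code (18 of 20)
MULTI_CODON_AAS: tuple[str, ...] = tuple(
    sorted({aa for aa in CODON_TO_AA.values()
            if sum(1 for c, a in CODON_TO_AA.items() if a == aa) > 1})
)

TERMINATION = "*"


@dataclass
class CodonUsageProfile:
    """Per-amino-acid synonymous-codon usage ratios (plus termination)."""

    counts: dict[str, dict[str, int]]
    ratios: dict[str, dict[str, float]]

    def ratio(self, aa: str, codon: str) -> float:
        return self.ratios.get(aa, {}).get(codon, 0.0)

    def to_rows(self) -> list[dict]:
        rows = []
        for aa in list(MULTI_CODON_AAS) + [TERMINATION]:
            for codon, r in sorted(self.ratios.get(aa, {}).items()):
                rows.append({"amino_acid": aa, "codon": codon,
                             "count": self.counts[aa][codon], "ratio": r})
        return rows


def codon_usage_profile(cds_seqs: list[str], *, ids: list[str] | None = None) -> CodonUsageProfile:
    """Pooled synonymous codon-usage ratios over a CDS set.

    Ratios are computed per multi-codon amino acid (Met and Trp excluded) and
    for the termination signal over {TAA, TAG, TGA}.  A CDS without a
    terminal stop contributes no termination count (warned).
    """
    ids = ids or [f"cds{i}" for i in range(len(cds_seqs))]
    counts: dict[str, dict[str, int]] = {aa: {} for aa in MULTI_CODON_AAS}
    counts[TERMINATION] = {}
    for name, seq in zip(ids, cds_seqs):
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"CDS {name}: length not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            term = codons.pop()
            counts[TERMINATION][term] = counts[TERMINATION].get(term, 0) + 1
        else:
            logger.warning("CDS %s lacks a terminal stop codon; termination signal omitted", name)
        for codon in codons:
            aa = CODON_TO_AA.get(codon)
            if aa in counts:
                counts[aa][codon] = counts[aa].get(codon, 0) + 1
    ratios: dict[str, dict[str, float]] = {}
    for aa, cc in counts.items():
        total = sum(cc.values())
        if total:
            ratios[aa] = {codon: n / total for codon, n in cc.items()}
    return CodonUsageProfile(counts=counts, ratios=ratios)


# ---------------------------------------------------------------------------
# identity, distances, neighbour joining
# ---------------------------------------------------------------------------

def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent of matching columns among non-double-gap aligned columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    matches = columns = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    if columns == 0:
        raise ValueError("no countable columns")
    return 100.0 * matches / columns


def p_distance_matrix(alignment: dict[str, str]) -> pd.DataFrame:
    """Pairwise mismatch proportions over mutually ungapped columns."""
    names = list(alignment)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment[names[i]], alignment[names[j]]
            if len(a) != len(b):
                raise ValueError("alignment rows differ in length")
            diffs = cols = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                cols += 1
                diffs += x != y
            if cols == 0:
                raise ValueError(f"{names[i]} vs {names[j]}: no shared columns")
            mat[i, j] = mat[j, i] = diffs / cols
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass
class PhylogramTree:
    """Unrooted phylogram produced by neighbour joining."""

    newick: str

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick",
                                 preserve_underscores=True)

    def leaf_labels(self) -> set[str]:
        return {t.label for t in self.to_dendropy().taxon_namespace}


def nj_tree(dist: pd.DataFrame) -> PhylogramTree:
    """Canonical neighbour joining with deterministic tie-breaking.

    Joins minimise the Q criterion; ties are broken by the lexicographically
    smallest (name_i, name_j) pair.  Negative branch lengths are clamped to
    zero with the deficit transferred to the sibling branch.
    """
    names = list(dist.index)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    mat = dist.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(mat) != 0) or np.any(mat < 0):
        raise ValueError("distance matrix must be nonnegative with zero diagonal")

    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            d[(a, b)] = mat[i, j]
    subtree = {name: name for name in names}  # name -> newick fragment
    active = sorted(names)
    counter = 0

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            key = (a, b) if a < b else (b, a)
            q = (n - 2) * d[(a, b)] - r[a] - r[b]
            cand = (q, key)
            if best is None or cand < best:
                best = cand
        _, (a, b) = best
        la = d[(a, b)] / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d[(a, b)] - la
        la, lb = clamp(la, lb)
        counter += 1
        new = f"_nj{counter}"
        subtree[new] = f"({subtree[a]}:{la:.10g},{subtree[b]}:{lb:.10g})"
        for c in active:
            if c in (a, b):
                continue
            duc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2.0
            d[(new, c)] = d[(c, new)] = duc
        d[(new, new)] = 0.0
        active = sorted([c for c in active if c not in (a, b)] + [new])

    a, b, c = active
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2.0
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2.0
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2.0
    la = max(la, 0.0)
    lb = max(lb, 0.0)
    lc = max(lc, 0.0)
    newick = (
        f"({subtree[a]}:{la:.10g},{subtree[b]}:{lb:.10g},{subtree[c]}:{lc:.10g});"
    )
    return PhylogramTree(newick=newick)


# ---------------------------------------------------------------------------
# clade placement
# ---------------------------------------------------------------------------

def clade_nesting_check(
    tree: PhylogramTree,
    focal_taxa: list[str],
    reference_taxa: list[str],
    outgroup_taxa: list[str],
) -> str:
    """Place focal sequences relative to a reference crown group.

    Returns ``"nested_in_crown"`` if the focal clade attaches inside the
    reference crown (its smallest containing clade excludes part of the
    reference), ``"sister_to_crown"`` if it attaches on the crown's stem
    branch, and ``"other"`` otherwise.  The tree is rooted with the outgroup
    before the test.
    """
    focal, reference, outgroup = set(focal_taxa), set(reference_taxa), set(outgroup_taxa)
    dtree = tree.to_dendropy()
    dtree.is_rooted = True
    have = {t.label for t in dtree.taxon_namespace}
    missing = (focal | reference | outgroup) - have
    if missing:
        raise ValueError(f"taxa missing from tree: {sorted(missing)}")

    og_mrca = dtree.mrca(taxa=[t for t in dtree.taxon_namespace if t.label in outgroup])
    if og_mrca is not dtree.seed_node:
        dtree.reroot_at_edge(og_mrca.edge, update_bipartitions=True)

    def leafset(node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    focal_mrca = dtree.mrca(taxa=[t for t in dtree.taxon_namespace if t.label in focal])
    cover = leafset(focal_mrca)

    if cover == focal:
        parent = focal_mrca.parent_node
        if parent is None:
            return "other"
        sister = leafset(parent) - cover
        if sister == reference:
            return "sister_to_crown"
        if sister and sister < reference:
            return "nested_in_crown"
        # climb: focal may be one tip whose parent is inside the crown
        if cover | sister <= focal | reference and reference - (cover | sister):
            return "nested_in_crown"
        return "other"
    if cover <= focal | reference and reference - cover:
        return "nested_in_crown"
    return "other"


# ---------------------------------------------------------------------------
# codon threading
# ---------------------------------------------------------------------------

def thread_codon_alignment(protein_aln: dict[str, str], cds_map: dict[str, str]) -> dict[str, str]:
    """Map protein alignment columns back onto codons (no alignment inference).

    Each aligned amino acid becomes its source codon; gaps become ``---``.
    The CDS may carry a terminal stop codon, which is dropped.
    """
    out = {}
    for name, prot in protein_aln.items():
        cds = cds_map[name]
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        residues = prot.replace("-", "")
        if len(cds) != 3 * len(residues):
            raise ValueError(f"{name}: CDS length does not match ungapped protein length")
        codons = iter(cds[i : i + 3] for i in range(0, len(cds), 3))
        out[name] = "".join("---" if aa == "-" else next(codons) for aa in prot)
    return out
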