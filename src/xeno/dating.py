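"""Dating single gene-gain events on calibrated species trees.

A transferred gene is assumed to have been gained exactly once (a Dollo
model).  Given presence/absence calls across host taxa, the gain is placed
on the branch above the most recent common ancestor (MRCA) of the taxa that
carry the gene; the event time is then bounded below by the MRCA's age and
above by the age of the MRCA's parent — the split from the nearest lineage
lacking the gene.  A donor-side constraint (the age of the donor clade the
transferred sequences nest in) can cap the upper bound.

Also provides the presence/absence matrix builder (PCR evidence overrides
in-silico evidence) and an exact-match in-silico PCR assay.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .records import SequenceRecord, revcomp
from .tree import CalibratedTree

logger = logging.getLogger("xeno")

PRESENT, ABSENT, NOT_ANALYSED = "present", "absent", "not_analysed"


# ---------------------------------------------------------------------------
# presence/absence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceAbsenceMatrix:
    """taxon x gene presence calls with per-cell evidence provenance."""

    calls: pd.DataFrame      # values in {present, absent, not_analysed}
    evidence: pd.DataFrame   # values in {in_silico, pcr, both, ""}
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    low_confidence: list[tuple[str, str]] = field(default_factory=list)

    def call(self, taxon: str, gene: str) -> str:
        return self.calls.at[taxon, gene]

    def present_taxa(self, gene: str) -> list[str]:
        return [t for t in self.calls.index if self.calls.at[t, gene] == PRESENT]

    def absent_taxa(self, gene: str) -> list[str]:
        return [t for t in self.calls.index if self.calls.at[t, gene] == ABSENT]

    def to_rows(self) -> list[dict]:
        symbol = {PRESENT: "+", ABSENT: "-", NOT_ANALYSED: "NA"}
        rows = []
        for taxon in self.calls.index:
            row = {"taxon": taxon}
            for gene in self.calls.columns:
                ev = self.evidence.at[taxon, gene]
                row[gene] = symbol[self.calls.at[taxon, gene]] + (f"({ev})" if ev else "")
            rows.append(row)
        return rows


def build_presence_matrix(
    in_silico: dict[tuple[str, str], bool],
    pcr: dict[tuple[str, str], bool],
    taxa: list[str],
    genes: list[str],
) -> PresenceAbsenceMatrix:
    """Combine in-silico and PCR evidence into one matrix.

    PCR evidence overrides conflicting in-silico evidence; an in-silico
    absence with no PCR support is kept but flagged low-confidence (absence
    of evidence in a sequence database is weaker than a failed assay).
    """
    calls = pd.DataFrame(NOT_ANALYSED, index=taxa, columns=genes, dtype=object)
    evid = pd.DataFrame("", index=taxa, columns=genes, dtype=object)
    conflicts: list[tuple[str, str]] = []
    low_conf: list[tuple[str, str]] = []
    for taxon in taxa:
        for gene in genes:
            key = (taxon, gene)
            have_is, have_pcr = key in in_silico, key in pcr
            if not have_is and not have_pcr:
                continue
            if have_is and have_pcr:
                if in_silico[key] != pcr[key]:
                    conflicts.append(key)
                    logger.info("presence conflict for %s/%s resolved in favour of PCR", *key)
                calls.at[taxon, gene] = PRESENT if pcr[key] else ABSENT
                evid.at[taxon, gene] = "both"
            elif have_pcr:
                calls.at[taxon, gene] = PRESENT if pcr[key] else ABSENT
                evid.at[taxon, gene] = "pcr"
            else:
                calls.at[taxon, gene] = PRESENT if in_silico[key] else ABSENT
                evid.at[taxon, gene] = "in_silico"
                if not in_silico[key]:
                    low_conf.append(key)
    return PresenceAbsenceMatrix(calls=calls, evidence=evid,
                                 conflicts=conflicts, low_confidence=low_conf)


# ---------------------------------------------------------------------------
# transfer window inference
# ---------------------------------------------------------------------------

@dataclass
class TransferWindow:
    gene: str
    lower_mya: float
    upper_mya: float
    host_constraint: tuple[str, str]     # (MRCA label, parent label)
    donor_constraint_mya: float | None = None
    implied_losses: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.lower_mya <= self.upper_mya):
            raise ValueError(
                f"invalid window ({self.lower_mya}, {self.upper_mya}) for {self.gene}"
            )

    def contains(self, t: float) -> bool:
        return self.lower_mya <= t <= self.upper_mya


class LossViolationError(ValueError):
    """Absent taxa nested inside the presence clade under the strict policy."""


def infer_transfer_window(
    matrix: PresenceAbsenceMatrix,
    host_tree: CalibratedTree,
    gene: str,
    donor_constraint_mya: float | None = None,
    *,
    loss_policy: str = "strict",
) -> TransferWindow:
    """Bound the time of a single gene gain on the calibrated host tree.

    The gain branch is the branch above the MRCA of all gene-carrying taxa
    (not-analysed taxa are ignored): lower bound = MRCA age, upper bound =
    age of the MRCA's parent, optionally capped by the donor-side constraint.
    Absent taxa inside the presence clade raise an error under the default
    strict (no-loss) policy; under ``loss_policy="dollo_losses"`` they are
    reported as implied losses instead.
    """
    present = matrix.present_taxa(gene)
    if not present:
        raise ValueError(f"gene {gene!r}: no taxa called present")
    mrca = host_tree.mrca(present)
    clade = host_tree.tip_set(mrca)
    absent_inside = sorted(set(matrix.absent_taxa(gene)) & clade)
    if absent_inside:
        if loss_policy == "strict":
            raise LossViolationError(
                f"gene {gene!r}: absent taxa {absent_inside} descend from the presence "
                "MRCA; single-gain/no-loss model violated"
            )
        if loss_policy != "dollo_losses":
            raise ValueError(f"unknown loss_policy {loss_policy!r}")
        logger.warning("gene %s: treating %s as secondary losses", gene, absent_inside)
    lower = mrca.age
    if mrca.parent is not None:
        upper = mrca.parent.age
        parent_label = mrca.parent.label
    else:
        upper = math.inf
        parent_label = "<root>"
    if donor_constraint_mya is not None:
        upper = min(upper, donor_constraint_mya)
    if math.isinf(upper):
        raise ValueError(
            f"gene {gene!r}: presence MRCA is the tree root and no donor constraint "
            "was given; the upper bound is unconstrained"
        )
    return TransferWindow(
        gene=gene, lower_mya=lower, upper_mya=upper,
        host_constraint=(mrca.label, parent_label),
        donor_constraint_mya=donor_constraint_mya,
        implied_losses=absent_inside,
    )


def donor_divergence_constraint(
    donor_tree: CalibratedTree,
    placement: str,
    crown_taxa: list[str],
) -> float:
    """Donor-side age cap from the phylogenetic placement of the transfers.

    ``nested_in_crown``: the transferred sequences branch inside the donor
    crown group, so the transfer postdates the crown age.  ``sister_to_crown``:
    they attach on the crown's stem, so it postdates only the stem age.
    """
    mrca = donor_tree.mrca(crown_taxa)
    if placement == "nested_in_crown":
        return mrca.age
    if placement == "sister_to_crown":
        if mrca.parent is None:
            return donor_tree.root_age
        return mrca.parent.age
    raise ValueError(f"unknown placement {placement!r}")


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

@dataclass
class PrimerPair:
    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            seq = seq.upper()
            if not (15 <= len(seq) <= 35):
                raise ValueError(f"{self.name} {label} primer length {len(seq)} outside 15-35 nt")
            if set(seq) - set("ACGT"):
                raise ValueError(f"{self.name} {label} primer has non-ACGT characters")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


@dataclass
class AmpliconResult:
    template_id: str
    products: list[int]   # product lengths, bp

    @property
    def amplified(self) -> bool:
        return bool(self.products)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def insilico_pcr(
    primers: PrimerPair,
    templates: list[SequenceRecord],
    max_product_len: int = 250,
) -> list[AmpliconResult]:
    """Exact-match PCR simulation.

    On each strand, the forward primer must match verbatim and the reverse
    complement of the reverse primer must match downstream on the same
    strand; the product is the inclusive span, reported when it is at most
    ``max_product_len`` and longer than the two primers combined.
    """
    results = []
    rev_site = revcomp(primers.reverse)
    min_len = len(primers.forward) + len(primers.reverse)
    for template in templates:
        products: set[int] = set()
        for strand_seq in (template.seq, revcomp(template.seq)):
            for f in _find_all(strand_seq, primers.forward):
                for r in _find_all(strand_seq, rev_site):
                    end = r + len(rev_site)
                    length = end - f
                    if length > min_len and length <= max_product_len:
                        products.add(length)
        results.append(AmpliconResult(template_id=template.id, products=sorted(products)))
    return results


def design_cross_species_primers(
    seqs: list[str],
    *,
    name: str = "assay",
    primer_len: int = 20,
    max_product_len: int = 250,
) -> PrimerPair | None:
    """Design an exact-match primer pair inside fully conserved windows.

    Requires positionally homologous sequences of equal length (no indels):
    forward and reverse windows are chosen where all sequences agree, with a
    product at most ``max_product_len``.  Returns None when no conserved
    window pair exists.
    """
    if not seqs or len({len(s) for s in seqs}) != 1:
        return None
    ref = seqs[0]
    n = len(ref)
    conserved = [all(s[i] == ref[i] for s in seqs) for i in range(n)]
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if conserved[i] else 0
    starts = [i for i in range(n - primer_len + 1) if run[i] >= primer_len]
    for f in starts:
        for r in starts:
            end = r + primer_len
            length = end - f
            if 2 * primer_len < length <= max_product_len:
                return PrimerPair(
                    name=name,
                    forward=ref[f : f + primer_len],
                    reverse=revcomp(ref[r : r + primer_len]),
                )
    return None
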