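"""Read-count expression profiling by exact substring matching.

A read supports a gene when the two share an exact common substring of at
least ``min_perfect`` nucleotides (default 60) on either strand.  Raw counts
are normalised to counts per million (CPM) by library size.  The criterion
is implemented by hashing all ``min_perfect``-mers of the gene and its
reverse complement: a common substring of length >= k exists iff a common
k-mer exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import ReadSet, SequenceRecord, revcomp

logger = logging.getLogger("xeno")


@dataclass
class ExpressionRecord:
    gene_id: str
    sample_id: str
    tissue: str
    endophyte_status: str
    raw_count: int
    library_size: int
    cpm: float


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def count_matching_reads(gene: SequenceRecord, reads: ReadSet, min_perfect: int = 60) -> int:
    """Number of reads sharing a perfect >=min_perfect nt run with the gene.

    Duplicate reads count individually.  Both strands are considered; k-mers
    containing N never match.
    """
    if min_perfect < 1:
        raise ValueError("min_perfect must be >= 1")
    if len(gene.seq) < min_perfect:
        raise ValueError(
            f"gene {gene.id} ({len(gene.seq)} nt) shorter than min_perfect {min_perfect}"
        )
    kmers = {
        km
        for km in _kmer_set(gene.seq, min_perfect) | _kmer_set(revcomp(gene.seq), min_perfect)
        if "N" not in km
    }
    count = 0
    for read in reads:
        if len(read.seq) < min_perfect:
            continue
        if any(read.seq[i : i + min_perfect] in kmers
               for i in range(len(read.seq) - min_perfect + 1)):
            count += 1
    return count


def cpm_normalize(raw_count: int, library_size: int) -> float:
    """Counts per million: raw_count / library_size x 1e6."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return raw_count / library_size * 1e6


def expression_table(
    genes: list[SequenceRecord],
    libraries: list[ReadSet],
    min_perfect: int = 60,
) -> list[ExpressionRecord]:
    """One expression record per gene x library; zero = below detection."""
    seen: set[tuple[str, str]] = set()
    out: list[ExpressionRecord] = []
    for lib in libraries:
        if len(lib) == 0:
            logger.warning("library %s is empty; all counts zero", lib.library_id)
        for gene in genes:
            key = (gene.id, lib.library_id)
            if key in seen:
                raise ValueError(f"duplicate (gene, sample) pair {key}")
            seen.add(key)
            raw = count_matching_reads(gene, lib, min_perfect) if len(lib) else 0
            out.append(
                ExpressionRecord(
                    gene_id=gene.id,
                    sample_id=lib.library_id,
                    tissue=lib.tissue or "",
                    endophyte_status=lib.endophyte_status,
                    raw_count=raw,
                    library_size=lib.library_size,
                    cpm=cpm_normalize(raw, lib.library_size) if lib.library_size else 0.0,
                )
            )
    return out


def expression_rows(records: list[ExpressionRecord]) -> list[dict]:
    return [
        {
            "gene": r.gene_id, "sample": r.sample_id, "tissue": r.tissue,
            "status": r.endophyte_status, "count": r.raw_count,
            "library_size": r.library_size, "cpm": f"{r.cpm:.4f}",
        }
        for r in records
    ]
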