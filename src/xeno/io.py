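"""Standard-format I/O: FASTA, FASTQ, Newick, TSV and JSON reports.

FASTA/FASTQ parsing goes through Biopython's ``SeqIO``; this module only adds
the package's normalisation conventions (upper-casing, taxon extraction from
headers) and validation errors that name the offending entry.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable

from Bio import SeqIO

from .records import Read, ReadSet, SequenceRecord
from .tree import CalibratedTree

logger = logging.getLogger("xeno")


def read_fasta(
    path: str,
    *,
    moltype: str = "dna_genomic",
    taxon_field: str | None = "taxon",
) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The header token before the first whitespace becomes the record id.  The
    taxon is parsed from a ``key=value`` field of the description (default key
    ``taxon``); records without one get taxon ``"unknown"`` with a warning.
    """
    records: list[SequenceRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in ">;\n":
            raise ValueError(f"malformed FASTA in {path}: line 1 does not start with '>'")
    try:
        parsed = list(SeqIO.parse(path, "fasta"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    for entry in parsed:
        taxon = "unknown"
        if taxon_field:
            for token in entry.description.split()[1:]:
                if token.startswith(taxon_field + "="):
                    taxon = token.split("=", 1)[1]
                    break
            else:
                logger.warning("FASTA %s: record %s has no %s= field; taxon set to 'unknown'",
                               path, entry.id, taxon_field)
        records.append(
            SequenceRecord(id=entry.id, seq=str(entry.seq), taxon=taxon, moltype=moltype)
        )
    if not records:
        logger.warning("FASTA %s: no records (empty file)", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} taxon={rec.taxon} moltype={rec.moltype}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str, *, library_id: str | None = None) -> ReadSet:
    """Read FASTQ into a ReadSet; quality strings are parsed then discarded."""
    lib = library_id or os.path.splitext(os.path.basename(path))[0]
    reads: list[Read] = []
    try:
        for entry in SeqIO.parse(path, "fastq"):
            # SeqIO already validates seq/qual length agreement
            reads.append(Read(id=entry.id, seq=str(entry.seq).upper(), library_id=lib))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    return ReadSet(reads=reads, library_size=len(reads), library_id=lib)


def write_fastq(readset: ReadSet, path: str) -> None:
    with open(path, "w") as fh:
        for r in readset:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_newick(path: str) -> CalibratedTree:
    return CalibratedTree.from_newick(path)


def write_tsv(rows: list[dict], path: str, *, columns: list[str] | None = None) -> None:
    """Write a list of dict rows as TSV with a header line."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def read_tsv(path: str) -> list[dict]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh if line.strip()]


def write_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
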