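"""Core sequence containers: sequence records, reads, and alphabet handling.

Conventions used throughout the package:

* coordinates are 0-based, half-open; strand is ``"+"`` or ``"-"``;
* DNA is upper-cased on ingestion and IUPAC ambiguity codes other than ``N``
  are mapped to ``N`` (with a warning);
* coding sequences (``dna_cds``) must have a length divisible by three and no
  internal in-frame stop codon under the standard nuclear code (a terminal
  stop is allowed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

from Bio.Data import CodonTable

logger = logging.getLogger("xeno")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: the three termination codons of the standard nuclear code
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)

#: codon -> single-letter amino acid for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

#: the 61 sense codons, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_DNA_OK = set("ACGTN")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
_PROTEIN_OK = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MOLTYPES = ("dna_cds", "dna_genomic", "protein")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; ``*`` for a stop codon."""
    return CODON_TO_AA.get(codon, "*")


def translate_cds(seq: str) -> str:
    """Translate an in-frame CDS; a terminal stop becomes ``*``."""
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3))


def codons_of(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def normalize_dna(seq: str, *, context: str = "") -> str:
    """Upper-case DNA; IUPAC ambiguity codes other than N become N (warned)."""
    seq = seq.upper()
    bad = set(seq) - _DNA_OK
    if bad:
        amb = bad & _IUPAC_AMBIGUOUS
        if amb:
            logger.warning(
                "sequence %s: ambiguity codes %s mapped to N", context, "".join(sorted(amb))
            )
            seq = seq.translate(str.maketrans({c: "N" for c in amb}))
        illegal = set(seq) - _DNA_OK
        if illegal:
            raise ValueError(
                f"sequence {context or '<anon>'}: illegal DNA characters {sorted(illegal)}"
            )
    return seq


@dataclass
class SequenceRecord:
    """A named sequence with a taxon label and molecule type."""

    id: str
    seq: str
    taxon: str = "unknown"
    moltype: str = "dna_genomic"

    def __post_init__(self) -> None:
        if self.moltype not in MOLTYPES:
            raise ValueError(f"unknown moltype {self.moltype!r}")
        if not self.seq:
            raise ValueError(f"sequence {self.id}: empty sequence")
        if self.moltype == "protein":
            self.seq = self.seq.upper()
            bad = set(self.seq) - _PROTEIN_OK
            if bad:
                raise ValueError(f"sequence {self.id}: illegal protein characters {sorted(bad)}")
        else:
            self.seq = normalize_dna(self.seq, context=self.id)
            if self.moltype == "dna_cds":
                self._validate_cds()

    def _validate_cds(self) -> None:
        if len(self.seq) % 3 != 0:
            raise ValueError(f"CDS {self.id}: length {len(self.seq)} not divisible by 3")
        for i in range(0, len(self.seq) - 3, 3):
            if self.seq[i : i + 3] in STOP_CODONS:
                raise ValueError(f"CDS {self.id}: internal stop codon at nt {i}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codons(self) -> list[str]:
        return codons_of(self.seq)


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    library_id: str


@dataclass
class ReadSet:
    """Short reads from one sequencing library.

    ``library_size`` is the size of the originating library, which may exceed
    the number of reads held (e.g. after filtering).
    """

    reads: list[Read] = field(default_factory=list)
    library_size: int = 0
    library_id: str = "lib"
    tissue: str | None = None
    endophyte_status: str = "not_applicable"
    min_len: int = 20
    max_len: int = 300

    def __post_init__(self) -> None:
        if self.library_size < len(self.reads):
            raise ValueError(
                f"library_size {self.library_size} < number of reads {len(self.reads)}"
            )
        for r in self.reads:
            if not (self.min_len <= len(r.seq) <= self.max_len):
                raise ValueError(
                    f"read {r.id}: length {len(r.seq)} outside [{self.min_len}, {self.max_len}]"
                )

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)
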