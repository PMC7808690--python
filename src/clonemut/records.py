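"""Core record types shared across the pipeline.

Coordinates are 1-based inclusive throughout (VCF convention).  BED input is
converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class MutationRecord:
    """One somatic single-base substitution in one sample.

    ``vaf`` is the variant allele fraction; ``zygosity_call`` is set by the
    clonality filter (het / hom / subclonal) and is ``None`` on raw input.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float
    zygosity_call: Optional[str] = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"invalid alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class IndelRecord:
    """An insertion or deletion, VCF-style (pos = base before the event).

    Exactly one of ``ref_allele``/``alt_allele`` is a strict prefix of the
    other; ``length`` is the number of inserted or deleted bases.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based, anchor base before the inserted/deleted bases
    ref_allele: str
    alt_allele: str
    qual: float = 100.0
    vaf: float = 0.5
    zygosity_call: Optional[str] = None

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        r, a = self.ref_allele, self.alt_allele
        if len(r) == len(a):
            raise ValueError(f"not an indel: {r}>{a}")
        shorter, longer = (r, a) if len(r) < len(a) else (a, r)
        if not longer.startswith(shorter):
            raise ValueError(f"alleles {r}>{a} are not prefix-nested")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def kind(self) -> str:
        return "insertion" if len(self.alt_allele) > len(self.ref_allele) else "deletion"

    @property
    def length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def changed_seq(self) -> str:
        """The inserted or deleted bases."""
        if self.kind == "insertion":
            return self.alt_allele[len(self.ref_allele):]
        return self.ref_allele[len(self.alt_allele):]

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive span of changed reference bases.

        For an insertion (no reference base changes) this is the anchor base,
        so mask overlap still has a position to test.
        """
        if self.kind == "deletion":
            start = self.pos + len(self.alt_allele)
            return (start, start + self.length - 1)
        return (self.pos, self.pos)

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class SVRecord:
    """A somatic structural rearrangement with two breakpoints."""

    sample_id: str
    sv_type: str  # DEL / DUP / INV / TRA
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    junction_reads_variant: int = 0
    junction_reads_total: int = 0
    blood_variant_reads: int = 0
    inserted_or_mh_seq: Optional[str] = None
    pass_filter: bool = True  # False for LowQual / IMPRECISE caller flags

    def __post_init__(self) -> None:
        if self.sv_type not in {"DEL", "DUP", "INV", "TRA"}:
            raise ValueError(f"unknown sv_type {self.sv_type}")
        if self.sv_type != "TRA":
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{self.sv_type} must be intra-chromosomal")
            if not self.pos1 < self.pos2:
                raise ValueError("pos1 must be < pos2 for DEL/DUP/INV")
        if self.junction_reads_variant > self.junction_reads_total:
            raise ValueError("variant junction reads exceed total")

    @property
    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


@dataclass
class SampleMeta:
    """Donor/sample metadata for one sequenced clonal lineage."""

    sample_id: str
    donor_id: str
    age: float
    sex: str  # M / F
    race: str  # White / AfricanAmerican
    cell_type: str = "fibroblast"  # fibroblast / melanocyte
    wga: bool = False  # whole-genome amplified

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in {"M", "F"}:
            raise ValueError(f"sex must be M or F, got {self.sex}")
        if self.race not in {"White", "AfricanAmerican"}:
            raise ValueError(f"unknown race label {self.race}")
        if self.cell_type not in {"fibroblast", "melanocyte"}:
            raise ValueError(f"unknown cell type {self.cell_type}")


@dataclass
class ContextWindow:
    """Reference sequence window of 2*flank+1 bases centered on a position."""

    center_chrom: str
    center_pos: int
    flank: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.flank + 1:
            raise ValueError(
                f"window length {len(self.sequence)} != 2*{self.flank}+1"
            )

    @property
    def center_base(self) -> str:
        return self.sequence[self.flank]
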