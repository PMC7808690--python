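"""Reading and writing the standard formats the pipeline touches.

Supported inputs: VCF 4.x (via pysam) and a MAF-like tab-separated catalog
(columns sample, chrom, pos, ref, alt, vaf, qual) for substitutions and
indels; BED for masks and fragile-site intervals; BEDPE-like TSV for
structural variants; FASTA (indexed through pyfaidx) for reference access.

Internal coordinates are 1-based inclusive everywhere.  BED's 0-based
half-open convention is converted here and nowhere else.
"""

from __future__ import annotations

import os
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence, Union

import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .records import (
    ContextWindow,
    IndelRecord,
    MutationRecord,
    SampleMeta,
    SVRecord,
    revcomp,
)

Record = Union[MutationRecord, IndelRecord]

MAF_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "vaf", "qual"]


class CatalogError(ValueError):
    """Malformed catalog input; message names the offending line."""


# ---------------------------------------------------------------------------
# Reference access
# ---------------------------------------------------------------------------

class Reference:
    """Uniform reference-sequence access over a FASTA file or an in-memory
    dict of chromosome sequences.

    Positions are 1-based inclusive; requests beyond the contig ends are
    padded with N so that context windows always have full width.
    """

    def __init__(self, source: Union[str, os.PathLike, Mapping[str, str]]):
        if isinstance(source, (str, os.PathLike)):
            self._fasta = Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._seqs = None
        else:
            self._fasta = None
            self._seqs = {c: s.upper() for c, s in source.items()}

    @property
    def chroms(self) -> list[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def _raw(self, chrom: str, start: int, end: int) -> str:
        # start/end 1-based inclusive, assumed within bounds
        if self._seqs is not None:
            return self._seqs[chrom][start - 1:end]
        return str(self._fasta[chrom][start - 1:end])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence for [start, end] (1-based inclusive), N-padded outside."""
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end < start:
            return ""
        n = self.length(chrom)
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - n)
        core = ""
        if start <= n and end >= 1:
            core = self._raw(chrom, max(start, 1), min(end, n))
        return "N" * left_pad + core + "N" * right_pad

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def fetch_context(reference: Reference, chrom: str, pos: int, flank: int = 20,
                  expected_ref: Optional[str] = None) -> ContextWindow:
    """Reference window of ±flank bases around ``pos``.

    If ``expected_ref`` is given, the middle base must match it (a mismatch
    indicates a record/reference disagreement and raises).
    """
    seq = reference.fetch(chrom, pos - flank, pos + flank)
    win = ContextWindow(chrom, pos, flank, seq)
    if expected_ref is not None and win.center_base != expected_ref.upper():
        raise ValueError(
            f"reference base {win.center_base} at {chrom}:{pos} does not match "
            f"record ref {expected_ref}"
        )
    return win


# ---------------------------------------------------------------------------
# Catalog reading / writing
# ---------------------------------------------------------------------------

def _make_record(sample: str, chrom: str, pos: int, ref: str, alt: str,
                 vaf: float, qual: float, line_no: int) -> list[Record]:
    """One VCF/MAF allele row -> records.  DBS rows encoded as a single
    multi-base row (e.g. CC>TT) are split into per-base substitutions."""
    try:
        if len(ref) == len(alt):
            if len(ref) == 1:
                return [MutationRecord(sample, chrom, pos, ref, alt, vaf)]
            out = []
            for i, (r, a) in enumerate(zip(ref, alt)):
                if r != a:
                    out.append(MutationRecord(sample, chrom, pos + i, r, a, vaf))
            return out
        return [IndelRecord(sample, chrom, pos, ref, alt, qual=qual, vaf=vaf)]
    except ValueError as exc:
        raise CatalogError(f"line {line_no}: {exc}") from exc


def read_catalog(path: Union[str, os.PathLike], format: str = "maf_tsv") -> list[Record]:
    """Read a somatic catalog; returns substitution and indel records.

    ``format`` is ``"vcf"`` or ``"maf_tsv"``.  Multi-allelic VCF rows are
    split into one record per ALT allele; multi-base substitution rows are
    split into per-base records (the motif pipeline reconstructs adjacent
    pairs when counting dinucleotide changes).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "maf_tsv":
        return _read_maf(path)
    raise CatalogError(f"unknown catalog format {format!r}")


def _read_vcf(path) -> list[Record]:
    records: list[Record] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise CatalogError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    with vf:
        for i, row in enumerate(vf, start=1):
            if row.alts is None:
                continue
            qual = row.qual if row.qual is not None else 100.0
            for alt in row.alts:
                if samples:
                    for s in samples:
                        call = row.samples[s]
                        gt = call.get("GT")
                        if gt is None or not any(a and a > 0 for a in gt):
                            continue
                        vaf = _extract_vaf(row, call)
                        records.extend(_make_record(
                            s, row.chrom, row.pos, row.ref, alt, vaf, qual, i))
                else:
                    vaf = _extract_vaf(row, None)
                    records.extend(_make_record(
                        "sample", row.chrom, row.pos, row.ref, alt, vaf, qual, i))
    return records


def _extract_vaf(row, call) -> float:
    if call is not None and "AF" in call:
        af = call["AF"]
        return float(af[0] if isinstance(af, tuple) else af)
    if "AF" in row.info:
        af = row.info["AF"]
        return float(af[0] if isinstance(af, tuple) else af)
    return 0.5


def _read_maf(path) -> list[Record]:
    records: list[Record] = []
    with open(path) as fh:
        header = None
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in MAF_COLUMNS[:5] if c not in header]
                if missing:
                    raise CatalogError(f"line {i}: missing columns {missing}")
                continue
            if len(fields) < len(header):
                raise CatalogError(f"line {i}: expected {len(header)} fields")
            row = dict(zip(header, fields))
            try:
                vaf = float(row.get("vaf", 0.5) or 0.5)
                qual = float(row.get("qual", 100) or 100)
                pos = int(row["pos"])
            except ValueError as exc:
                raise CatalogError(f"line {i}: {exc}") from exc
            records.extend(_make_record(
                row["sample"], row["chrom"], pos, row["ref"], row["alt"],
                vaf, qual, i))
    return records


def write_catalog(records: Iterable[Record], path) -> None:
    """Write records as a MAF-like TSV (round-trips with read_catalog)."""
    with open(path, "w") as fh:
        fh.write("\t".join(MAF_COLUMNS) + "\n")
        for r in records:
            if isinstance(r, MutationRecord):
                ref, alt, qual = r.ref, r.alt, 100.0
            else:
                ref, alt, qual = r.ref_allele, r.alt_allele, r.qual
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.pos}\t{ref}\t{alt}\t"
                     f"{r.vaf:g}\t{qual:g}\n")


def group_by_sample(records: Iterable[Record]) -> dict[str, list[Record]]:
    out: dict[str, list[Record]] = defaultdict(list)
    for r in records:
        out[r.sample_id].append(r)
    return dict(out)


def split_records(records: Iterable[Record]) -> tuple[list[MutationRecord], list[IndelRecord]]:
    snvs, indels = [], []
    for r in records:
        (snvs if isinstance(r, MutationRecord) else indels).append(r)
    return snvs, indels


# ---------------------------------------------------------------------------
# Indel left-normalization
# ---------------------------------------------------------------------------

def left_normalize(indel: IndelRecord, reference: Reference) -> IndelRecord:
    """Shift an indel to the smallest position with the identical allele
    change, so downstream homopolymer logic is deterministic.

    Uses the standard roll: while the last base of the changed sequence
    equals the reference base at the anchor, rotate the event one base left.
    """
    seq = list(indel.changed_seq)
    pos = indel.pos
    while pos > 1:
        anchor = reference.base(indel.chrom, pos)
        if anchor != seq[-1] or anchor == "N":
            break
        seq = [anchor] + seq[:-1]
        pos -= 1
    changed = "".join(seq)
    anchor_base = reference.base(indel.chrom, pos)
    if indel.kind == "insertion":
        ref_a, alt_a = anchor_base, anchor_base + changed
    else:
        ref_a, alt_a = anchor_base + changed, anchor_base
    return IndelRecord(indel.sample_id, indel.chrom, pos, ref_a, alt_a,
                       qual=indel.qual, vaf=indel.vaf,
                       zygosity_call=indel.zygosity_call)


# ---------------------------------------------------------------------------
# Interval sets (BED)
# ---------------------------------------------------------------------------

class GenomeIntervals:
    """Per-chromosome interval sets with 1-based inclusive semantics.

    Overlapping input intervals are preserved (not merged); each carries its
    optional name.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)

    def add(self, chrom: str, start: int, end: int, name: Optional[str] = None) -> None:
        """Add [start, end], 1-based inclusive."""
        if end < start:
            raise ValueError(f"interval end {end} < start {start}")
        # intervaltree is half-open; store [start, end+1)
        self._trees[chrom].addi(start, end + 1, name)

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        return chrom in self._trees and bool(self._trees[chrom][pos])

    def overlaps_range(self, chrom: str, start: int, end: int) -> bool:
        """True iff any interval overlaps [start, end] by >= 1 base."""
        return chrom in self._trees and bool(self._trees[chrom].overlap(start, end + 1))

    def hits(self, chrom: str, start: int, end: int) -> list[tuple[int, int, Optional[str]]]:
        if chrom not in self._trees:
            return []
        return sorted((iv.begin, iv.end - 1, iv.data)
                      for iv in self._trees[chrom].overlap(start, end + 1))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def items(self):
        for chrom, tree in self._trees.items():
            for iv in sorted(tree):
                yield chrom, iv.begin, iv.end - 1, iv.data


def read_intervals(path, format: str = "bed") -> GenomeIntervals:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    if format != "bed":
        raise CatalogError(f"unknown interval format {format!r}")
    out = GenomeIntervals()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise CatalogError(f"line {i}: BED needs >= 3 columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CatalogError(f"line {i}: {exc}") from exc
            if start0 >= end0:
                raise CatalogError(f"line {i}: start {start0} >= end {end0}")
            name = fields[3] if len(fields) > 3 else None
            out.add(fields[0], start0 + 1, end0, name)
    return out


def write_intervals(intervals: GenomeIntervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals.items():
            cols = [chrom, str(start - 1), str(end)]
            if name is not None:
                cols.append(str(name))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Structural variants (BEDPE-like TSV) and metadata
# ---------------------------------------------------------------------------

SV_COLUMNS = ["sample", "sv_type", "chrom1", "pos1", "chrom2", "pos2",
              "junction_reads_variant", "junction_reads_total",
              "blood_variant_reads", "inserted_or_mh_seq", "pass_filter"]


def read_sv_table(path) -> list[SVRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in SV_COLUMNS[:6] if c not in header]
        if missing:
            raise CatalogError(f"line 1: missing columns {missing}")
        out = []
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                seq = row.get("inserted_or_mh_seq") or None
                if seq in {".", ""}:
                    seq = None
                out.append(SVRecord(
                    row["sample"], row["sv_type"], row["chrom1"], int(row["pos1"]),
                    row["chrom2"], int(row["pos2"]),
                    int(row.get("junction_reads_variant", 0) or 0),
                    int(row.get("junction_reads_total", 0) or 0),
                    int(row.get("blood_variant_reads", 0) or 0),
                    seq,
                    (row.get("pass_filter", "1") or "1") not in {"0", "False", "false"},
                ))
            except ValueError as exc:
                raise CatalogError(f"line {i}: {exc}") from exc
    return out


def write_sv_table(svs: Sequence[SVRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SV_COLUMNS) + "\n")
        for s in svs:
            fh.write("\t".join(map(str, [
                s.sample_id, s.sv_type, s.chrom1, s.pos1, s.chrom2, s.pos2,
                s.junction_reads_variant, s.junction_reads_total,
                s.blood_variant_reads, s.inserted_or_mh_seq or ".",
                int(s.pass_filter)])) + "\n")


META_COLUMNS = ["sample_id", "donor_id", "age", "sex", "race", "cell_type", "wga"]


def read_metadata(path) -> list[SampleMeta]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        out = []
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                out.append(SampleMeta(
                    row["sample_id"], row["donor_id"], float(row["age"]),
                    row["sex"], row["race"], row.get("cell_type", "fibroblast"),
                    row.get("wga", "0") in {"1", "True", "true"}))
            except (KeyError, ValueError) as exc:
                raise CatalogError(f"line {i}: {exc}") from exc
    return out


def write_metadata(meta: Sequence[SampleMeta], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(META_COLUMNS) + "\n")
        for m in meta:
            fh.write(f"{m.sample_id}\t{m.donor_id}\t{m.age:g}\t{m.sex}\t"
                     f"{m.race}\t{m.cell_type}\t{int(m.wga)}\n")


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    """Write chromosome sequences as FASTA (pyfaidx can index the result)."""
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
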