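"""Clonality filtering: raw per-caller somatic call sets -> clonal catalogs.

A clonal lineage grown from a single founder cell carries that founder's true
somatic variants at ~50% (heterozygous) or ~100% (homozygous) allele
fraction.  Calls outside those bands are sub-clonal — culture- or
amplification-induced — and are removed.  Substitutions must additionally be
called by every caller (three-caller consensus in the source pipeline) and
fall outside repeat masks and known germline variant sets.  Structural
variants are clonal when >= 30% of junction reads support the variant and the
donor's blood carries no supporting reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Union

from .catalog_io import GenomeIntervals
from .records import IndelRecord, MutationRecord, SVRecord

Record = Union[MutationRecord, IndelRecord]


@dataclass
class FilterConfig:
    """Thresholds for the clonality filters.

    The heterozygous band is closed ([het_lo, het_hi]); the homozygous rule
    is strict (> hom_lo) for substitutions and inclusive (>= hom_lo) for
    indels, reflecting the stated 90%-100% indel band.
    """

    het_lo: float = 0.45
    het_hi: float = 0.55
    hom_lo: float = 0.90
    indel_min_qual: float = 50.0
    sv_min_junction_fraction: float = 0.30
    sv_max_blood_reads: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.het_lo < self.het_hi <= self.hom_lo <= 1.0):
            raise ValueError("require 0 <= het_lo < het_hi <= hom_lo <= 1")


def consensus_snvs(call_sets: Sequence[Set[tuple]]) -> Set[tuple]:
    """Intersection of per-caller SNV key-sets.

    Keys are (sample, chrom, pos, ref, alt); only substitutions detected by
    every caller survive.
    """
    if not call_sets:
        raise ValueError("need at least one call set")
    out = set(call_sets[0])
    for s in call_sets[1:]:
        out &= s
    return out


def _zygosity(vaf: float, cfg: FilterConfig, is_indel: bool) -> Optional[str]:
    if cfg.het_lo <= vaf <= cfg.het_hi:
        return "het"
    if (vaf >= cfg.hom_lo) if is_indel else (vaf > cfg.hom_lo):
        return "hom"
    return None


def filter_clonal_af(records: Iterable[Record],
                     cfg: FilterConfig = FilterConfig()
                     ) -> tuple[list[Record], list[Record]]:
    """Partition records into (clonal kept, sub-clonal removed) by VAF.

    Kept records get ``zygosity_call`` set to "het" or "hom"; removed records
    are marked "subclonal".  The partition is exhaustive.
    """
    kept, removed = [], []
    for r in records:
        if not (0.0 <= r.vaf <= 1.0):
            raise ValueError(f"vaf {r.vaf} outside [0, 1] for {r}")
        z = _zygosity(r.vaf, cfg, isinstance(r, IndelRecord))
        if z is None:
            r.zygosity_call = "subclonal"
            removed.append(r)
        else:
            r.zygosity_call = z
            kept.append(r)
    return kept, removed


def filter_indel_quality(indels: Iterable[IndelRecord],
                         cfg: FilterConfig = FilterConfig()) -> list[IndelRecord]:
    """Drop indel calls below the minimum caller quality score."""
    return [r for r in indels if r.qual >= cfg.indel_min_qual]


def filter_masks(records: Iterable[Record],
                 masks: Sequence[GenomeIntervals] = (),
                 known_variants: Optional[Set[tuple]] = None,
                 position_only_known: bool = False) -> list[Record]:
    """Remove records overlapping any mask interval or a known-variant key.

    For indels the whole changed span is tested (a deletion straddling a mask
    edge is removed).  Known variants are matched on (chrom, pos, ref, alt)
    by default; ``position_only_known`` matches on (chrom, pos) alone.
    """
    known_variants = known_variants or set()
    kept = []
    for r in records:
        if isinstance(r, IndelRecord):
            start, end = r.span
            key = (r.chrom, r.pos, r.ref_allele, r.alt_allele)
        else:
            start = end = r.pos
            key = (r.chrom, r.pos, r.ref, r.alt)
        if any(m.overlaps_range(r.chrom, start, end) for m in masks):
            continue
        if position_only_known:
            if any(k[:2] == (r.chrom, r.pos) for k in known_variants):
                continue
        elif key in known_variants:
            continue
        kept.append(r)
    return kept


def filter_sv_clonality(svs: Iterable[SVRecord],
                        cfg: FilterConfig = FilterConfig()) -> list[SVRecord]:
    """Keep SVs with >= 30% variant junction reads, no blood support, and a
    passing caller filter."""
    kept = []
    for s in svs:
        if not s.pass_filter:
            continue
        if s.junction_reads_total == 0:
            raise ValueError(f"SV {s.sample_id} {s.chrom1}:{s.pos1} has zero "
                             "total junction reads")
        frac = s.junction_reads_variant / s.junction_reads_total
        if frac >= cfg.sv_min_junction_fraction and \
                s.blood_variant_reads <= cfg.sv_max_blood_reads:
            kept.append(s)
    return kept
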