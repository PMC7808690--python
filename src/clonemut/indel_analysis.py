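"""Indel biology of clonal skin-cell catalogs.

Two indel classes dominate somatic catalogs from skin clones:

* single-base insertions/deletions inside homopolymer runs — replication
  polymerase slippage (ID1/ID2-like), accumulating linearly with donor age;
* deletions of five or more bases, frequently with microhomology of one or
  more bases at the junction — end-joining repair of UV-induced double-strand
  breaks (ID8-like), tracking the UV substitution load rather than age.

Insertions are additionally screened for local templating (the inserted
sequence copied from the immediately adjacent reference), the hallmark of
polymerase-theta-mediated end joining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .catalog_io import Reference, left_normalize
from .records import IndelRecord

# Templated-insertion mismatch tolerance applies only to insertions longer
# than this (single/di-base insertions must match exactly).
MISMATCH_MIN_LEN = 3


@dataclass
class IndelClassification:
    indel: IndelRecord
    is_homopolymer_1bp: bool
    homopolymer_run_length: int
    is_deletion_ge5: bool
    mh_length: int
    templated: str  # none / adjacent_copy / adjacent_copy_with_mismatch
    template_side: str  # left / right / none
    mismatches: int
    flank_truncated: bool = False


def _run_length(reference: Reference, chrom: str, pos: int, base: str,
                max_scan: int = 200) -> int:
    """Length of the maximal run of ``base`` containing position ``pos``."""
    if reference.base(chrom, pos) != base:
        return 0
    length = 1
    p = pos - 1
    while p >= 1 and length < max_scan and reference.base(chrom, p) == base:
        length += 1
        p -= 1
    p = pos + 1
    while length < max_scan and reference.base(chrom, p) == base:
        length += 1
        p += 1
    return length


def classify_homopolymer(indel: IndelRecord, reference: Reference,
                         min_run: int = 2) -> tuple[bool, int]:
    """Is this a single-base slippage event in a homopolymer run?

    True iff the indel has length 1 and the inserted/deleted base
    extends/shrinks a reference run of that base of length >= ``min_run``.
    For a deletion the run containing the deleted base is measured; for a
    (left-normalized) insertion the run starting just right of the anchor.
    Returns (flag, run_length).
    """
    if indel.length != 1:
        return False, 0
    base = indel.changed_seq
    if base not in "ACGT":
        return False, 0
    if indel.kind == "deletion":
        run = _run_length(reference, indel.chrom, indel.span[0], base)
    else:
        run = _run_length(reference, indel.chrom, indel.pos + 1, base)
        if run == 0 and reference.base(indel.chrom, indel.pos) == base:
            # non-normalized input: the run ends at the anchor instead
            run = _run_length(reference, indel.chrom, indel.pos, base)
    return run >= min_run, run


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        n += 1
    return n


def junction_microhomology(deletion: IndelRecord, reference: Reference,
                           max_flank: int = 200) -> int:
    """Microhomology at a deletion junction.

    The longer of (a) the common prefix of the deleted sequence and the
    right flank and (b) the common suffix of the deleted sequence and the
    left flank, capped at the deletion length.  A deletion inside a long
    homopolymer therefore caps at its own length.
    """
    if deletion.kind != "deletion":
        raise ValueError("junction_microhomology needs a deletion")
    start, end = deletion.span
    deleted = deletion.changed_seq
    L = len(deleted)
    right = reference.fetch(deletion.chrom, end + 1, end + min(L, max_flank))
    left = reference.fetch(deletion.chrom, max(1, start - min(L, max_flank)),
                           start - 1)
    mh = max(_lcp(deleted, right), _lcp(deleted[::-1], left[::-1]))
    return min(mh, L)


def detect_templated_insertion(insertion: IndelRecord, reference: Reference,
                               max_mismatch: int = 1
                               ) -> tuple[str, str, int, bool]:
    """Check whether an inserted sequence is a copy of the adjacent
    reference (left preferred on ties).

    Returns (templated, side, mismatches, flank_truncated) where templated is
    "adjacent_copy", "adjacent_copy_with_mismatch" or "none".  Mismatches are
    only tolerated for insertions of length >= 3; near contig edges the
    comparison runs over the available bases and is flagged truncated.
    """
    if insertion.kind != "insertion":
        raise ValueError("detect_templated_insertion needs an insertion")
    s = insertion.changed_seq
    L = len(s)
    chrom, pos = insertion.chrom, insertion.pos
    left = reference.fetch(chrom, pos - L + 1, pos)
    right = reference.fetch(chrom, pos + 1, pos + L)

    def compare(flank: str, seq: str) -> tuple[int, int, bool]:
        truncated = "N" in flank
        usable = [(a, b) for a, b in zip(seq, flank) if b != "N"]
        mism = sum(a != b for a, b in usable)
        return mism, len(usable), truncated

    lm, ln, ltr = compare(left, s)
    rm, rn, rtr = compare(right, s)
    candidates = [("left", lm, ln, ltr), ("right", rm, rn, rtr)]
    for side, mism, n_used, trunc in candidates:
        if n_used > 0 and mism == 0:
            return "adjacent_copy", side, 0, trunc or n_used < L
    if L >= MISMATCH_MIN_LEN:
        best = None
        for side, mism, n_used, trunc in candidates:
            if n_used > 0 and mism <= max_mismatch:
                if best is None or mism < best[1]:
                    best = (side, mism, trunc or n_used < L)
        if best is not None:
            return "adjacent_copy_with_mismatch", best[0], best[1], best[2]
    return "none", "none", min(lm, rm) if max(ln, rn) else 0, ltr and rtr


def classify_indel(indel: IndelRecord, reference: Reference,
                   min_run: int = 2, normalize: bool = True
                   ) -> IndelClassification:
    """Full classification of one indel (left-normalizing first by default)."""
    rec = left_normalize(indel, reference) if normalize else indel
    is_hp, run = classify_homopolymer(rec, reference, min_run)
    is_del5 = rec.kind == "deletion" and rec.length >= 5
    mh = junction_microhomology(rec, reference) if rec.kind == "deletion" else 0
    if rec.kind == "insertion":
        templated, side, mism, trunc = detect_templated_insertion(rec, reference)
    else:
        templated, side, mism, trunc = "none", "none", 0, False
    return IndelClassification(rec, is_hp, run, is_del5, mh, templated,
                               side, mism, trunc)


def summarize_indels(indels: Sequence[IndelRecord], reference: Reference,
                     min_run: int = 2) -> pd.DataFrame:
    """Per-sample indel counts: total, ins, del, homopolymer_1bp,
    deletions_ge5, templated (insertions copied from adjacent sequence)."""
    rows: dict[str, dict[str, int]] = {}
    cols = ["total", "ins", "del", "homopolymer_1bp", "deletions_ge5",
            "templated"]
    for indel in indels:
        c = classify_indel(indel, reference, min_run)
        row = rows.setdefault(indel.sample_id, {k: 0 for k in cols})
        row["total"] += 1
        row["ins" if c.indel.kind == "insertion" else "del"] += 1
        row["homopolymer_1bp"] += int(c.is_homopolymer_1bp)
        row["deletions_ge5"] += int(c.is_deletion_ge5)
        row["templated"] += int(c.templated != "none")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "sample_id"
    return df.sort_index()
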