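"""Structural-variant hotspots, common-fragile-site colocalization, and
breakpoint microhomology.

A hotspot is a genomic locus where rearrangement breakpoints from at least
two different samples fall within 1 Mbp of each other (single-linkage
chaining of breakpoints per chromosome).  Deletions, duplications and
inversions colocalize with a common fragile site (CFS) when their interval
intersects it; translocations when a breakpoint lies within 10 kb of one.
Junction microhomology of >= 2 bases marks candidate microhomology-mediated
end joining; a Fisher exact test asks whether its use differs inside vs
outside CFSs, and a chi-square test whether the SV-type mix differs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog_io import GenomeIntervals, Reference
from .records import SVRecord, revcomp


@dataclass
class Hotspot:
    id: str
    chrom: str
    members: list[SVRecord]
    span: tuple[int, int]

    @property
    def n_samples(self) -> int:
        return len({m.sample_id for m in self.members})


@dataclass
class CfsAnnotation:
    sv: SVRecord
    overlaps_cfs: bool
    cfs_names: list[str]
    rule_used: str  # interval_intersection / breakpoint_window
    in_hotspot: bool = False
    mh_length: Optional[int] = None


# ---------------------------------------------------------------------------
# Hotspot chaining
# ---------------------------------------------------------------------------

def call_hotspots(svs: Sequence[SVRecord], max_gap: int = 1_000_000
                  ) -> tuple[list[Hotspot], list[bool]]:
    """Single-linkage chaining of SV breakpoints into recurrent hotspots.

    Every SV contributes both breakpoints as points on their own
    chromosomes.  Consecutive points <= max_gap apart chain; a chain is a
    hotspot iff it contains breakpoints of >= 2 SVs from >= 2 distinct
    samples.  Returns the hotspots and a per-SV membership flag (an SV is in
    a hotspot iff any of its breakpoints is).
    """
    points: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(pos, sv_idx)]
    for i, sv in enumerate(svs):
        for chrom, pos in sv.breakpoints:
            points.setdefault(chrom, []).append((pos, i))
    hotspots: list[Hotspot] = []
    in_hotspot = [False] * len(svs)
    for chrom in sorted(points):
        pts = sorted(points[chrom])
        chain: list[tuple[int, int]] = []
        for pt in pts:
            if chain and pt[0] - chain[-1][0] > max_gap:
                _close_chain(chain, chrom, svs, hotspots, in_hotspot)
                chain = []
            chain.append(pt)
        _close_chain(chain, chrom, svs, hotspots, in_hotspot)
    return hotspots, in_hotspot


def _close_chain(chain, chrom, svs, hotspots, in_hotspot) -> None:
    if not chain:
        return
    idxs = sorted({i for _, i in chain})
    samples = {svs[i].sample_id for i in idxs}
    if len(idxs) >= 2 and len(samples) >= 2:
        hs = Hotspot(f"hs_{chrom}_{chain[0][0]}", chrom,
                     [svs[i] for i in idxs], (chain[0][0], chain[-1][0]))
        hotspots.append(hs)
        for i in idxs:
            in_hotspot[i] = True


# ---------------------------------------------------------------------------
# Common-fragile-site annotation
# ---------------------------------------------------------------------------

def annotate_cfs(svs: Sequence[SVRecord], cfs: GenomeIntervals,
                 tra_window: int = 10_000) -> list[CfsAnnotation]:
    """Flag each SV for CFS colocalization.

    DEL/DUP/INV: the [pos1, pos2] interval intersects a CFS by >= 1 bp.
    TRA: either breakpoint lies inside a CFS or within ``tra_window`` of its
    boundary.
    """
    out = []
    for sv in svs:
        if sv.sv_type == "TRA":
            names = set()
            for chrom, pos in sv.breakpoints:
                for _, _, name in cfs.hits(chrom, pos - tra_window,
                                           pos + tra_window):
                    names.add(name)
            out.append(CfsAnnotation(sv, bool(names),
                                     sorted(n for n in names if n),
                                     "breakpoint_window"))
        else:
            hits = cfs.hits(sv.chrom1, sv.pos1, sv.pos2)
            names = sorted({n for _, _, n in hits if n})
            out.append(CfsAnnotation(sv, bool(hits), names,
                                     "interval_intersection"))
    return out


# ---------------------------------------------------------------------------
# Breakpoint microhomology
# ---------------------------------------------------------------------------

def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        n += 1
    return n


def breakpoint_microhomology(sv: SVRecord, reference: Reference,
                             max_mh: int = 50) -> int:
    """Maximal identical sequence shared by the two ends joined at the SV
    junction (same prefix/suffix logic as deletion junction microhomology,
    taken in junction orientation for each SV type).

    For a deletion the removed segment's ends are compared with the retained
    flanks; a tandem duplication's junction is ambiguous where the sequence
    after the start of the duplicated segment matches the sequence after its
    end; inversions and translocations compare the joined flanks directly
    (reverse-complemented for the inverted end).  Contig edges are handled by
    comparing the available bases.
    """
    w = max_mh
    c1, p1, c2, p2 = sv.chrom1, sv.pos1, sv.chrom2, sv.pos2
    if sv.sv_type == "DEL":
        # deleted segment [p1+1, p2-1]; same rule as small deletions
        deleted = reference.fetch(c1, p1 + 1, min(p2 - 1, p1 + w))
        right = reference.fetch(c1, p2, p2 + w - 1)
        left = reference.fetch(c1, max(1, p1 - w + 1), p1)
        deleted_tail = reference.fetch(c1, max(p1 + 1, p2 - w), p2 - 1)
        mh = max(_lcp(deleted, right), _lcp(deleted_tail[::-1], left[::-1]))
        return min(mh, max(p2 - p1 - 1, 0))
    if sv.sv_type == "DUP":
        # tandem junction: ...p2 | p1...; ambiguity where seq from p1
        # matches seq from p2+1 (and symmetrically leftward)
        a = reference.fetch(c1, p1, p1 + w - 1)
        b = reference.fetch(c1, p2 + 1, p2 + w)
        fwd = _lcp(a, b)
        a2 = reference.fetch(c1, max(1, p1 - w), p1 - 1)
        b2 = reference.fetch(c1, max(1, p2 - w + 1), p2)
        rev = _lcp(a2[::-1], b2[::-1])
        return max(fwd, rev)
    if sv.sv_type == "INV":
        # joined ends: forward strand up to p1 meets reverse strand from p2
        left_end = reference.fetch(c1, max(1, p1 - w + 1), p1)
        other = revcomp(reference.fetch(c1, p2, p2 + w - 1))
        return _lcp(left_end[::-1], other[::-1])
    # TRA: forward flank ending at breakpoint 1 joined to flank starting at
    # breakpoint 2; homology where the sequences entering the junction agree
    left_end = reference.fetch(c1, max(1, p1 - w + 1), p1)
    right_ctx = reference.fetch(c2, max(1, p2 - w + 1), p2)
    return _lcp(left_end[::-1], right_ctx[::-1])


# ---------------------------------------------------------------------------
# Association tests
# ---------------------------------------------------------------------------

def mh_cfs_fisher(mh_present: Sequence[bool], overlaps_cfs: Sequence[bool]
                  ) -> tuple[np.ndarray, float]:
    """Fisher exact test (two-sided) for microhomology use inside vs outside
    common fragile sites.

    Table rows are CFS / non-CFS, columns MH-present / MH-absent:
    [[MH&CFS, noMH&CFS], [MH&noCFS, noMH&noCFS]].
    """
    mh = np.asarray(mh_present, dtype=bool)
    cfs = np.asarray(overlaps_cfs, dtype=bool)
    if mh.size == 0 or mh.size != cfs.size:
        raise ValueError("need matched, non-empty flag vectors")
    table = np.array([
        [int((mh & cfs).sum()), int((~mh & cfs).sum())],
        [int((mh & ~cfs).sum()), int((~mh & ~cfs).sum())],
    ])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return table, p


def svtype_cfs_chisq(sv_types: Sequence[str], overlaps_cfs: Sequence[bool]
                     ) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square (no continuity correction) for SV type mix inside
    vs outside CFSs.  Returns (statistic, p, expected-count table); all-zero
    rows/columns are dropped with a warning.
    """
    df = pd.crosstab(pd.Series(sv_types, name="sv_type"),
                     pd.Series(np.asarray(overlaps_cfs, dtype=bool),
                               name="cfs"))
    keep_rows = df.sum(axis=1) > 0
    keep_cols = df.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping all-zero rows/columns from contingency table")
        df = df.loc[keep_rows, keep_cols]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and columns")
    stat, p, _, expected = stats.chi2_contingency(df.to_numpy(),
                                                  correction=False)
    exp = pd.DataFrame(expected, index=df.index, columns=df.columns)
    return float(stat), float(p), exp


def annotate_all(svs: Sequence[SVRecord], cfs: GenomeIntervals,
                 reference: Optional[Reference] = None,
                 max_gap: int = 1_000_000, tra_window: int = 10_000,
                 mh_min: int = 2) -> pd.DataFrame:
    """Full per-SV annotation table: hotspot flag, CFS flag and names, and
    microhomology length (from the reference where available, else from the
    junction sequence recorded on the SV call)."""
    annos = annotate_cfs(svs, cfs, tra_window)
    _, flags = call_hotspots(svs, max_gap)
    rows = []
    for anno, flag in zip(annos, flags):
        sv = anno.sv
        anno.in_hotspot = flag
        if reference is not None and sv.chrom1 in reference.chroms \
                and sv.chrom2 in reference.chroms:
            mh = breakpoint_microhomology(sv, reference)
        elif sv.inserted_or_mh_seq is not None:
            mh = len(sv.inserted_or_mh_seq)
        else:
            mh = 0
        anno.mh_length = mh
        rows.append({
            "sample_id": sv.sample_id, "sv_type": sv.sv_type,
            "chrom1": sv.chrom1, "pos1": sv.pos1,
            "chrom2": sv.chrom2, "pos2": sv.pos2,
            "in_hotspot": flag, "overlaps_cfs": anno.overlaps_cfs,
            "cfs_names": ",".join(anno.cfs_names),
            "mh_length": mh, "mh_present": mh >= mh_min,
        })
    return pd.DataFrame(rows)
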