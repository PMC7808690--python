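"""Knowledge-based trinucleotide-motif mutation-signature pipeline.

For a motif signature such as yCn->yTn (y = pyrimidine, n = any base,
mutated base capitalized) and one sample's clonal substitution catalog, the
pipeline

1. excludes "complex" mutations (same-sample substitutions < 10 bp apart,
   which likely arise from a single translesion-synthesis event),
2. collects +/-20 base reference windows around every mutation of the
   base-change class (all C->T for yCn->yTn, reverse complements included),
3. counts mutated bases in vs out of the motif and unmutated context bases
   in vs out of the motif,
4. computes the fold enrichment

       enrichment = (mut_in_motif * ctx_base) / (mut_in_class * ctx_motif),

5. tests it with a one-sided Fisher exact test, corrects across samples by
   Benjamini-Hochberg, and
6. for significantly enriched samples reports the minimum mutation load

       min_load = mut_in_motif * (enrichment - 1) / enrichment,

   a conservative count of mutations attributable to the motif-specific
   process (0 when enrichment <= 1 or q >= alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog_io import Reference
from .records import COMPLEMENT, MutationRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BYTE = {b: ord(b) for b in "ACGTN"}


def _sym_lut(symbol: str) -> np.ndarray:
    """256-entry boolean lookup: does this byte match the IUPAC symbol?

    The fully degenerate symbol N imposes no constraint and matches anything,
    including reference N and off-window padding; every other symbol matches
    only its concrete bases (never N).
    """
    lut = np.zeros(256, dtype=bool)
    sym = symbol.upper()
    if sym == "N":
        lut[:] = True
        return lut
    for b in IUPAC[sym]:
        lut[_BYTE[b]] = True
    return lut


def _comp_lut(symbol: str) -> np.ndarray:
    """Lookup for matching the symbol on the opposite strand."""
    lut = np.zeros(256, dtype=bool)
    sym = symbol.upper()
    if sym == "N":
        lut[:] = True
        return lut
    for b in IUPAC[sym]:
        lut[_BYTE[COMPLEMENT[b]]] = True
    return lut


@dataclass(frozen=True)
class MotifSignature:
    """A trinucleotide motif with a concrete mutated middle base.

    ``motif`` is three IUPAC symbols with the middle base capitalized in
    display (e.g. yCn); ``to_base`` is the target of the substitution.
    """

    name: str
    motif: str
    to_base: str

    def __post_init__(self) -> None:
        if len(self.motif) != 3:
            raise ValueError("motif must have exactly 3 symbols")
        mid = self.motif[1].upper()
        if mid not in "ACGT":
            raise ValueError("middle motif symbol must be a concrete base")
        for s in self.motif:
            if s.upper() not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {s!r}")
        if self.to_base.upper() not in "ACGT" or self.to_base.upper() == mid:
            raise ValueError("to_base must be a concrete base != middle base")

    @property
    def from_base(self) -> str:
        return self.motif[1].upper()

    @property
    def label(self) -> str:
        m = self.motif
        return f"{m}>{m[0]}{self.to_base.upper()}{m[2]}"


# The three motif processes analyzed throughout: CpG deamination, UV
# photoproduct bypass, and UV-associated T->C.
SIG_CPG = MotifSignature("nCg>nTg", "nCg", "T")
SIG_UV = MotifSignature("yCn>yTn", "yCn", "T")
SIG_NTT = MotifSignature("nTt>nCt", "nTt", "C")
DEFAULT_SIGNATURES = (SIG_CPG, SIG_UV, SIG_NTT)


@dataclass
class EnrichmentResult:
    """All quantities of the enrichment calculation for one (sample,
    signature) pair."""

    sample_id: str
    signature: str
    mut_in_motif: int
    mut_in_class: int
    ctx_motif: int
    ctx_base: int
    enrichment: float
    p: float
    q: float = math.nan
    min_load: float = math.nan
    undefined: bool = False  # zero-denominator enrichment

    @property
    def motif_fraction_of_context(self) -> float:
        """Motif availability p = ctx_motif / ctx_base among unmutated
        context bases."""
        return self.ctx_motif / self.ctx_base if self.ctx_base else math.nan

    @property
    def process_load(self) -> float:
        """min_load rescaled by 1 / (1 - motif availability): an unbiased
        point estimate of the total number of class mutations generated by
        the motif-specific process (the plain minimum load undercounts by
        the fraction of process mutations a uniform process would also have
        placed in the motif)."""
        p = self.motif_fraction_of_context
        if not (0 <= p < 1):
            return math.nan
        return self.min_load / (1.0 - p)


# ---------------------------------------------------------------------------
# Complex-mutation exclusion
# ---------------------------------------------------------------------------

def exclude_complex(records: Sequence[MutationRecord],
                    min_spacing: int = 10) -> list[MutationRecord]:
    """Drop substitutions with another same-sample substitution < min_spacing
    bases away on the same chromosome (both members of a close pair go)."""
    by_key: dict[tuple, list[MutationRecord]] = {}
    for r in records:
        by_key.setdefault((r.sample_id, r.chrom), []).append(r)
    kept: list[MutationRecord] = []
    for group in by_key.values():
        group.sort(key=lambda r: r.pos)
        n = len(group)
        drop = [False] * n
        for i in range(n - 1):
            if group[i + 1].pos - group[i].pos < min_spacing:
                drop[i] = drop[i + 1] = True
        kept.extend(r for r, d in zip(group, drop) if not d)
    return kept


# ---------------------------------------------------------------------------
# Window construction and counting
# ---------------------------------------------------------------------------

def class_windows(records: Sequence[MutationRecord], reference: Reference,
                  from_base: str, to_base: str, flank: int = 20,
                  guard: int = 1) -> np.ndarray:
    """Byte array of reference windows around every mutation of the
    base-change class, pyrimidine/strand-normalized.

    Records whose ref/alt are the reverse complement of the class (e.g. G->A
    for the C->T class) contribute the reverse complement of their window, so
    the returned array is uniformly oriented with ``from_base`` at center.

    ``guard`` extra bases are fetched on each side: they are never counted as
    context but supply the real genomic neighbors of the outermost context
    bases, so motif matching carries no window-edge artifact.
    """
    from_base, to_base = from_base.upper(), to_base.upper()
    cf, ct = COMPLEMENT[from_base], COMPLEMENT[to_base]
    w = flank + guard
    rows = []
    for r in records:
        if r.ref == from_base and r.alt == to_base:
            seq = reference.fetch(r.chrom, r.pos - w, r.pos + w)
        elif r.ref == cf and r.alt == ct:
            seq = reference.fetch(r.chrom, r.pos - w, r.pos + w)
            seq = "".join(COMPLEMENT[b] for b in reversed(seq))
        else:
            continue
        rows.append(seq)
    if not rows:
        return np.empty((0, 2 * w + 1), dtype=np.uint8)
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(rows), 2 * w + 1).copy()


def count_motif_and_base(windows: np.ndarray, signature: MotifSignature,
                         guard: int = 0) -> tuple[int, int, int, int]:
    """Count (mut_in_motif, mut_in_class, ctx_motif, ctx_base) from windows.

    ``windows`` is the (n_mutations, 2*(flank+guard)+1) byte array from
    :func:`class_windows`.  The mutated center base of each window is counted
    in the mutation columns and excluded from the context columns; every
    other occurrence of the class base (on either strand) is an unmutated
    context base, in-motif when its own trinucleotide matches the motif on
    that strand.  The outer ``guard`` columns on each side are used only as
    neighbors of the outermost context bases, never counted themselves.
    N is never a context base; bases beyond the fetched window only satisfy
    the unconstrained symbol n.
    """
    if windows.ndim != 2:
        raise ValueError("windows must be 2-D")
    n, width = windows.shape
    if n == 0:
        return 0, 0, 0, 0
    if guard < 0 or 2 * guard >= width:
        raise ValueError("invalid guard width")
    valid = np.zeros(256, dtype=bool)
    for b in "ACGTN":
        valid[_BYTE[b]] = True
    if not valid[windows].all():
        raise ValueError("windows contain symbols outside A/C/G/T/N")
    center = width // 2
    m0, m1, m2 = signature.motif
    b = signature.from_base
    cb = COMPLEMENT[b]

    padded = np.full((n, width + 2), _BYTE["N"], dtype=np.uint8)
    padded[:, 1:-1] = windows
    left = padded[:, :-2]
    mid = padded[:, 1:-1]
    right = padded[:, 2:]

    fwd_mid = mid == _BYTE[b]
    rev_mid = mid == _BYTE[cb]
    motif_fwd = _sym_lut(m0)[left] & fwd_mid & _sym_lut(m2)[right]
    # opposite strand: 5' motif symbol reads the complementary base 3' on
    # the reference, and vice versa
    motif_rev = _comp_lut(m0)[right] & rev_mid & _comp_lut(m2)[left]

    mut_in_class = n
    mut_in_motif = int((motif_fwd[:, center] | motif_rev[:, center]).sum())

    ctx_hit = fwd_mid | rev_mid
    ctx_motif_hit = motif_fwd | motif_rev
    ctx_hit[:, center] = False
    ctx_motif_hit[:, center] = False
    if guard:
        ctx_hit[:, :guard] = False
        ctx_hit[:, width - guard:] = False
        ctx_motif_hit[:, :guard] = False
        ctx_motif_hit[:, width - guard:] = False
    return mut_in_motif, mut_in_class, int(ctx_motif_hit.sum()), int(ctx_hit.sum())


# ---------------------------------------------------------------------------
# Enrichment statistic, test, correction, minimum load
# ---------------------------------------------------------------------------

def enrichment(mut_in_motif: int, mut_in_class: int,
               ctx_motif: int, ctx_base: int) -> tuple[float, bool]:
    """Fold enrichment and an undefined-denominator flag.

    Returns (value, undefined).  ``undefined`` is True when mut_in_class or
    ctx_motif is zero; the value is then +inf (signal with no motif context)
    or nan (no class mutations at all).
    """
    if mut_in_class == 0:
        return math.nan, True
    if ctx_motif == 0:
        return (math.inf if mut_in_motif > 0 else math.nan), True
    return (mut_in_motif * ctx_base) / (mut_in_class * ctx_motif), False


def enrichment_test(mut_in_motif: int, mut_in_class: int,
                    ctx_motif: int, ctx_base: int,
                    alternative: str = "greater") -> float:
    """Fisher exact p for the 2x2 table

        [[mut_in_motif, mut_in_class - mut_in_motif],
         [ctx_motif,    ctx_base    - ctx_motif   ]]

    one-sided toward enrichment by default.
    """
    a, b = mut_in_motif, mut_in_class - mut_in_motif
    c, d = ctx_motif, ctx_base - ctx_motif
    if min(a, b, c, d) < 0:
        raise ValueError("negative contingency cell")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def bh_correct(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def minimum_mutation_load(mut_in_motif: int, enrichment_value: float,
                          q: float, alpha: float = 0.05) -> float:
    """Conservative mutation count for the motif process.

    mut_in_motif * (enrichment - 1) / enrichment when the enrichment is both
    > 1 and significant after correction; otherwise 0.
    """
    if not (enrichment_value > 1.0) or not (q < alpha):
        return 0.0
    if math.isinf(enrichment_value):
        return float(mut_in_motif)
    return mut_in_motif * (enrichment_value - 1.0) / enrichment_value


# ---------------------------------------------------------------------------
# Dinucleotide CC->TT counting
# ---------------------------------------------------------------------------

def count_cc_tt(records: Sequence[MutationRecord]) -> int:
    """Number of CC->TT dinucleotide changes in one sample's catalog.

    Counted as same-sample C->T substitutions at adjacent positions (GG->AA
    on the reference is the reverse-complement form); each adjacent pair is
    counted once.
    """
    by_chrom: dict[str, dict[int, str]] = {}
    for r in records:
        if (r.ref, r.alt) in {("C", "T"), ("G", "A")}:
            by_chrom.setdefault(r.chrom, {})[r.pos] = r.ref
    count = 0
    for positions in by_chrom.values():
        for pos, ref in positions.items():
            if positions.get(pos + 1) == ref:  # CC or GG run of the change
                count += 1
    return count


# ---------------------------------------------------------------------------
# Full panel
# ---------------------------------------------------------------------------

def run_panel(records: Sequence[MutationRecord], reference: Reference,
              signatures: Sequence[MotifSignature] = DEFAULT_SIGNATURES,
              flank: int = 20, min_spacing: int = 10, alpha: float = 0.05,
              fisher_alternative: str = "greater"
              ) -> tuple[list[EnrichmentResult], dict[str, int]]:
    """Run the enrichment pipeline for every sample and signature.

    Returns per-(sample, signature) EnrichmentResults (BH-corrected across
    samples within each signature) and per-sample CC->TT dinucleotide counts
    (computed on the unexcluded catalog, since the complex-mutation rule
    would remove exactly the adjacent pairs being counted).
    """
    by_sample: dict[str, list[MutationRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    sample_ids = sorted(by_sample)

    cc_tt = {s: count_cc_tt(by_sample[s]) for s in sample_ids}
    simple = {s: exclude_complex(by_sample[s], min_spacing) for s in sample_ids}

    results: list[EnrichmentResult] = []
    for sig in signatures:
        sig_results = []
        for s in sample_ids:
            windows = class_windows(simple[s], reference, sig.from_base,
                                    sig.to_base, flank, guard=1)
            mm, mc, cm, cb = count_motif_and_base(windows, sig, guard=1)
            e, undefined = enrichment(mm, mc, cm, cb)
            p = enrichment_test(mm, mc, cm, cb, fisher_alternative) \
                if mc > 0 else 1.0
            sig_results.append(EnrichmentResult(
                s, sig.name, mm, mc, cm, cb, e, p, undefined=undefined))
        qs = bh_correct([r.p for r in sig_results])
        for r, q in zip(sig_results, qs):
            r.q = float(q)
            e = r.enrichment
            r.min_load = minimum_mutation_load(
                r.mut_in_motif, e if not math.isnan(e) else 0.0, r.q, alpha)
        results.extend(sig_results)
    return results, cc_tt
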