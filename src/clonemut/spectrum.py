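"""Mutation-spectrum matrices and signature similarity/refitting.

Builds the standard 96-channel single-base-substitution spectrum
(pyrimidine-strand trinucleotide channels) and the 83-channel indel spectrum
(1 bp events by homopolymer base and run length; longer events by length
class, tandem-repeat content and junction microhomology), computes cosine
similarities against reference signature catalogs, and refits spectra as
non-negative combinations of catalog signatures by least squares.

A small bundled catalog of synthetic stand-in signatures (flat, CpG-C>T,
UV-like C>T, oxidative C>A; slippage and microhomology-deletion indel
signatures) supports offline tests; users can point the same loaders at
full published catalogs.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalog_io import Reference, left_normalize
from .indel_analysis import junction_microhomology
from .records import COMPLEMENT, IndelRecord, MutationRecord, revcomp

logger = logging.getLogger(__name__)

PYRIMIDINE_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"

SBS96_LABELS = [
    f"{l}[{cls}]{r}"
    for cls in PYRIMIDINE_CLASSES
    for l in BASES
    for r in BASES
]


def _id83_labels() -> list[str]:
    labels = []
    for base in "CT":
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for d in range(2, 6):
        labels += [f"{d}:Del:R:{i}" for i in range(6)]
    for d in range(2, 6):
        labels += [f"{d}:Ins:R:{i}" for i in range(6)]
    labels += ["2:Del:M:1"]
    labels += [f"3:Del:M:{i}" for i in (1, 2)]
    labels += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    labels += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    return labels


ID83_LABELS = _id83_labels()
assert len(ID83_LABELS) == 83


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

def sbs96_channel(trinuc: str, ref: str, alt: str) -> Optional[str]:
    """Channel label for one substitution given its reference trinucleotide;
    None when the context contains N."""
    if len(trinuc) != 3 or any(b not in "ACGT" for b in trinuc):
        return None
    if ref not in "ACGT" or alt not in "ACGT" or trinuc[1] != ref:
        return None
    if ref in "AG":  # purine center: read the opposite strand
        trinuc = revcomp(trinuc)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


def sbs96(records: Sequence[MutationRecord], reference: Reference) -> pd.DataFrame:
    """96-channel spectrum matrix, channels x samples.

    Each substitution lands in exactly one channel after pyrimidine-strand
    normalization; records with N in their trinucleotide context are dropped
    (count in ``df.attrs['dropped']`` and the log).
    """
    samples = sorted({r.sample_id for r in records})
    df = pd.DataFrame(0, index=SBS96_LABELS, columns=samples, dtype=int)
    dropped = 0
    for r in records:
        trinuc = reference.fetch(r.chrom, r.pos - 1, r.pos + 1)
        channel = sbs96_channel(trinuc, r.ref, r.alt)
        if channel is None:
            dropped += 1
            continue
        df.loc[channel, r.sample_id] += 1
    if dropped:
        logger.warning("sbs96: dropped %d records with N context", dropped)
    df.attrs["dropped"] = dropped
    return df


# ---------------------------------------------------------------------------
# Cosine similarity and signature refitting
# ---------------------------------------------------------------------------

def cosine(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Cosine similarity of two non-negative spectra."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("profiles must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero profile")
    return float(a @ b / (na * nb))


def cosine_table(spectra: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Cosine similarity of every sample spectrum against every catalog
    signature (samples x signatures)."""
    _check_channels(spectra.index, catalog.index)
    out = pd.DataFrame(index=spectra.columns, columns=catalog.columns,
                       dtype=float)
    for s in spectra.columns:
        for g in catalog.columns:
            out.loc[s, g] = cosine(spectra[s].to_numpy(), catalog[g].to_numpy())
    return out


def _check_channels(a, b) -> None:
    if list(a) != list(b):
        raise ValueError("channel labels of profile and catalog do not match")


def refit(profile: Sequence[float], catalog: pd.DataFrame
          ) -> tuple[pd.Series, float]:
    """Non-negative least-squares exposures of catalog signatures.

    Returns (exposures indexed by signature, reconstruction residual
    ||profile - catalog @ exposures||_2).  Works for any channel scheme whose
    labels match the catalog (96 SBS or 83 indel channels alike).
    """
    y = np.asarray(profile, dtype=float)
    A = catalog.to_numpy(dtype=float)
    if y.shape[0] != A.shape[0]:
        raise ValueError(
            f"profile has {y.shape[0]} channels, catalog {A.shape[0]}")
    x, rnorm = nnls(A, y)
    return pd.Series(x, index=catalog.columns), float(rnorm)


def refit_table(spectra: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Refit every sample column; returns exposures (signatures x samples)
    with the residual in the last row."""
    _check_channels(spectra.index, catalog.index)
    cols = {}
    for s in spectra.columns:
        expo, resid = refit(spectra[s].to_numpy(), catalog)
        cols[s] = pd.concat([expo, pd.Series({"residual": resid})])
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# ID83 indel channels
# ---------------------------------------------------------------------------

def _tandem_copies(reference: Reference, chrom: str, start: int, end: int,
                   unit: str, max_copies: int = 10) -> int:
    """Number of additional tandem copies of ``unit`` adjacent to the
    reference span [start, end] (both directions)."""
    L = len(unit)
    copies = 0
    p = end + 1
    while copies < max_copies and reference.fetch(chrom, p, p + L - 1) == unit:
        copies += 1
        p += L
    p = start - L
    while copies < max_copies and p >= 1 and \
            reference.fetch(chrom, p, p + L - 1) == unit:
        copies += 1
        p -= L
    return copies


def indel83_channel(indel: IndelRecord, reference: Reference,
                    normalize: bool = True) -> Optional[str]:
    """Assign one indel to its 83-channel label; None for ambiguous
    (N-containing) sequence."""
    rec = left_normalize(indel, reference) if normalize else indel
    seq = rec.changed_seq
    if any(b not in "ACGT" for b in seq):
        return None
    L = rec.length
    if L == 1:
        base = seq if seq in "CT" else COMPLEMENT[seq]
        if rec.kind == "deletion":
            start = rec.span[0]
            copies = _tandem_copies(reference, rec.chrom, start, start, seq)
            return f"1:Del:{base}:{min(copies, 5)}"
        copies = _tandem_copies(reference, rec.chrom, rec.pos + 1, rec.pos, seq)
        return f"1:Ins:{base}:{min(copies, 5)}"
    d = min(L, 5)
    if rec.kind == "insertion":
        copies = _tandem_copies(reference, rec.chrom, rec.pos + 1, rec.pos, seq)
        return f"{d}:Ins:R:{min(copies, 5)}"
    start, end = rec.span
    copies = _tandem_copies(reference, rec.chrom, start, end, seq)
    if copies >= 1:
        return f"{d}:Del:R:{min(copies, 5)}"
    mh = junction_microhomology(rec, reference)
    if mh >= 1:
        return f"{d}:Del:M:{min(mh, d if d == 5 else d - 1)}"
    return f"{d}:Del:R:0"


def indel83(indels: Sequence[IndelRecord], reference: Reference) -> pd.DataFrame:
    """83-channel indel spectrum matrix, channels x samples.

    Classified + dropped (N-context) counts equal the input size; the dropped
    count is in ``df.attrs['dropped']``.
    """
    samples = sorted({r.sample_id for r in indels})
    df = pd.DataFrame(0, index=ID83_LABELS, columns=samples, dtype=int)
    dropped = 0
    for r in indels:
        channel = indel83_channel(r, reference)
        if channel is None:
            dropped += 1
            continue
        df.loc[channel, r.sample_id] += 1
    if dropped:
        logger.warning("indel83: dropped %d records with ambiguous context",
                       dropped)
    df.attrs["dropped"] = dropped
    return df


# ---------------------------------------------------------------------------
# Signature catalogs
# ---------------------------------------------------------------------------

def load_signature_catalog(path) -> pd.DataFrame:
    """Load a channels x signatures TSV; columns are renormalized to sum
    to 1 (within 1e-6 on input)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("signature columns must have positive mass")
    if np.max(np.abs(sums - 1.0)) > 1e-6:
        raise ValueError("signature columns must each sum to 1 (±1e-6)")
    return df / sums


def bundled_catalog(kind: str) -> pd.DataFrame:
    """Bundled synthetic stand-in signature catalog: ``"sbs96"`` or
    ``"id83"``.  These are package-made test signatures shaped like the
    well-known processes (clock-like flat, CpG C>T, UV C>T, oxidative C>A;
    slippage and MH-deletion indel classes), not published matrices."""
    name = {"sbs96": "sbs96_synthetic_v1.tsv",
            "id83": "id83_synthetic_v1.tsv"}[kind]
    with resources.files("clonemut.data").joinpath(name).open() as fh:
        return load_signature_catalog(fh)
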