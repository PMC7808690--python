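"""Synthetic cohort generator with exported ground truth.

Emulates the statistical structure of somatic catalogs from single-cell
clonal skin lineages so that every pipeline stage is testable without
protected sequencing data:

* substitutions: a CpG-deamination process (count linear in donor age,
  placed at nCg sites), a UV process (age-independent, race-dependent
  amplitude, placed at yCn sites, with a fraction emitted as adjacent CC->TT
  pairs and a companion nTt->nCt component), and uniform background;
* clonal allele fractions near 0.5 (het) / 0.97 (hom) plus sub-clonal
  artifact calls below 0.40 for the clonality filter to remove;
* indels: single-base slippage in homopolymer runs (linear in age),
  deletions >= 5 bp with junction microhomology (count coupled to the
  sample's UV load), locally templated insertions, background and
  low-quality calls;
* structural variants on virtual chromosomes, placed with elevated
  probability inside planted fragile-site intervals so recurrent hotspots
  exist by construction.

The generator records per-variant process labels and per-sample process
counts (SyntheticTruth) against which pipeline estimates are tested.
Identical configuration (including the seed) yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .records import COMPLEMENT, IndelRecord, MutationRecord, SampleMeta, SVRecord

_B2I = {b: i for i, b in enumerate("ACGT")}
_I2B = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generator parameters.  Defaults are the cohort conditions the
    analysis targets: 39 clonal lineages from 21 donors aged 25-79, mostly
    White with a smaller African American group, per-sample substitution
    catalogs in the hundreds-to-thousands range, a CpG-deamination process
    gaining 0.4 mutations per year, an age-independent UV process with a
    White-donor median of ~200 in-motif events and none in African American
    donors, homopolymer indels gaining 0.22 per year, UV-coupled deletions
    of >= 5 bp, and 1-14 structural variants per sample concentrated at
    planted fragile sites."""

    seed: int = 0
    # reference
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.41
    cpg_enrichment: float = 1.0
    homopolymer_density: float = 5e-4  # planted runs (>= 5 bp) per base
    # cohort
    n_samples: int = 39
    n_donors: int = 21
    age_range: tuple[float, float] = (25.0, 79.0)
    race_mix: tuple[tuple[str, float], ...] = (("White", 16 / 21),
                                               ("AfricanAmerican", 5 / 21))
    melanocyte_fraction: float = 5 / 39
    # substitution processes
    background_median: float = 1000.0
    background_sigma: float = 0.8  # log-scale spread
    cpg_slope: float = 0.4  # mutations per year
    cpg_intercept: float = 27.0
    uv_load_median: tuple[tuple[str, float], ...] = (("White", 200.0),
                                                      ("AfricanAmerican", 0.0))
    uv_sigma: float = 0.5
    cc_tt_fraction: float = 0.05  # of UV events emitted as CC->TT pairs
    ntt_fraction: float = 0.10  # companion nTt->nCt count, relative to UV
    # allele fractions
    clonal_vaf_sd: float = 0.02
    hom_fraction: float = 0.05
    artifact_rate: float = 0.25  # artifact records per clonal record
    artifact_vaf_range: tuple[float, float] = (0.05, 0.35)
    # indel processes
    homopolymer_indel_slope: float = 0.22  # per year
    homopolymer_indel_intercept: float = 2.0
    background_indel_mean: float = 3.0
    lowqual_indel_mean: float = 2.0
    deletion_ge5_base: float = 2.0
    deletion_ge5_per_uv: float = 0.035  # extra deletions per UV event
    del5_len_range: tuple[int, int] = (5, 30)
    mh_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.10, 0.05)  # MH 0..4
    templated_ins_mean: float = 0.5
    templated_mismatch_prob: float = 1 / 6
    # structural variants (virtual chromosomes; coordinates only)
    sv_chrom_sizes: tuple[tuple[str, int], ...] = (
        ("sv1", 60_000_000), ("sv2", 60_000_000),
        ("sv3", 60_000_000), ("sv4", 60_000_000))
    n_fragile_sites: int = 6
    fragile_site_length: int = 300_000
    fragile_min_spacing: int = 3_000_000
    sv_count_range: tuple[int, int] = (1, 14)
    sv_count_mean: float = 3.4  # 1 + Poisson(mean - 1), clipped to the range
    sv_hotspot_weight: float = 0.6
    sv_mh_prob: float = 0.125
    sv_subclonal_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("background_median", "cpg_slope", "cpg_intercept",
                     "cc_tt_fraction", "ntt_fraction", "artifact_rate",
                     "homopolymer_indel_slope", "deletion_ge5_base",
                     "deletion_ge5_per_uv", "templated_ins_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(w for _, w in self.race_mix) - 1) > 1e-9:
            raise ValueError("race_mix weights must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth exported by the generator."""

    per_sample: dict[str, dict[str, int]]
    variant_labels: list[tuple]  # (sample_id, chrom, pos, process)
    fragile_intervals: list[tuple[str, int, int]]
    mh_lengths: dict[str, list[int]]  # per-sample planted deletion MH
    sv_mh_lengths: dict[str, list[int]]
    ages: dict[str, float]
    races: dict[str, str]
    uv_counts: dict[str, int]
    cpg_counts: dict[str, int]
    hp_indel_counts: dict[str, int]
    del5_counts: dict[str, int]


@dataclass
class SyntheticCohort:
    snvs: list[MutationRecord]
    indels: list[IndelRecord]
    svs: list[SVRecord]
    meta: list[SampleMeta]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def make_reference(cfg: SimConfig) -> dict[str, str]:
    """Random reference sequences with the configured base composition,
    CpG dinucleotide enrichment, and planted homopolymer runs."""
    if cfg.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    if not (0 < cfg.gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    per_chrom = cfg.genome_length // cfg.n_chromosomes
    probs = np.array([(1 - cfg.gc_fraction) / 2, cfg.gc_fraction / 2,
                      cfg.gc_fraction / 2, (1 - cfg.gc_fraction) / 2])
    out = {}
    for ci in range(cfg.n_chromosomes):
        arr = rng.choice(4, size=per_chrom, p=probs).astype(np.int8)
        _plant_homopolymers(arr, cfg, rng)
        _adjust_cpg(arr, cfg, rng)
        out[f"chr{ci + 1}"] = "".join(_I2B[arr])
    return out


def _plant_homopolymers(arr: np.ndarray, cfg: SimConfig, rng) -> None:
    n_runs = int(round(cfg.homopolymer_density * arr.size))
    for _ in range(n_runs):
        start = int(rng.integers(0, arr.size - 12))
        length = int(rng.integers(5, 13))
        arr[start:start + length] = rng.integers(0, 4)


def _adjust_cpg(arr: np.ndarray, cfg: SimConfig, rng) -> None:
    c, g = _B2I["C"], _B2I["G"]

    def cpg_idx():
        return np.nonzero((arr[:-1] == c) & (arr[1:] == g))[0]

    idx = cpg_idx()
    p_c = (arr == c).mean()
    p_g = (arr == g).mean()
    target = int(round(cfg.cpg_enrichment * p_c * p_g * (arr.size - 1)))
    if cfg.cpg_enrichment == 0:
        target = 0
    current = idx.size
    if current > target:
        kill = rng.choice(idx, size=current - target, replace=False)
        arr[kill + 1] = rng.choice([_B2I["A"], _B2I["T"]], size=kill.size)
        # flipping may create new CpGs upstream; iterate until clean
        while cfg.cpg_enrichment == 0:
            idx = cpg_idx()
            if idx.size == 0:
                break
            arr[idx + 1] = rng.choice([_B2I["A"], _B2I["T"]], size=idx.size)
    elif current < target:
        # planting can overwrite existing CpGs; iterate to the target
        for _ in range(30):
            current = cpg_idx().size
            if current >= target:
                break
            spots = rng.choice(arr.size - 1, size=target - current,
                               replace=False)
            arr[spots] = c
            arr[spots + 1] = g


# ---------------------------------------------------------------------------
# Site indexes
# ---------------------------------------------------------------------------

class _SiteIndex:
    """Per-chromosome numpy indexes of motif-eligible positions.

    Each site array holds (pos0, strand) with strand 0 = the motif read on
    the reference strand, 1 = on the reverse complement.
    """

    def __init__(self, seqs: dict[str, str]):
        self.chroms = list(seqs)
        self.arrays: dict[str, np.ndarray] = {}
        self.sites: dict[str, dict[str, np.ndarray]] = {}
        self.runs: list[tuple[str, int, int, str]] = []  # chrom, start0, len, base
        for chrom, seq in seqs.items():
            a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            self.arrays[chrom] = a
            C, G, T, A = (ord(x) for x in "CGTA")
            prev = np.concatenate(([0], a[:-1]))
            nxt = np.concatenate((a[1:], [0]))
            is_c, is_g, is_t, is_a = a == C, a == G, a == T, a == A
            pyr_prev = (prev == C) | (prev == T)
            pur_next = (nxt == A) | (nxt == G)
            sites = {}
            sites["uv"] = _stack(np.nonzero(is_c & pyr_prev)[0],
                                 np.nonzero(is_g & pur_next)[0])
            sites["cpg"] = _stack(np.nonzero(is_c & (nxt == G))[0],
                                  np.nonzero(is_g & (prev == C))[0])
            sites["ntt"] = _stack(np.nonzero(is_t & (nxt == T))[0],
                                  np.nonzero(is_a & (prev == A))[0])
            sites["cc"] = _stack(np.nonzero(is_c & (nxt == C))[0],
                                 np.nonzero(is_g & (prev == G))[0])
            sites["all"] = _stack(np.arange(a.size), np.empty(0, dtype=np.int64))
            self.sites[chrom] = sites
            self._find_runs(chrom, a)

    def _find_runs(self, chrom: str, a: np.ndarray) -> None:
        boundaries = np.nonzero(np.diff(a) != 0)[0]
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries, [a.size - 1]))
        lengths = ends - starts + 1
        for s, l in zip(starts[lengths >= 2], lengths[lengths >= 2]):
            self.runs.append((chrom, int(s), int(l), chr(a[int(s)])))

    def base(self, chrom: str, pos0: int) -> str:
        return chr(self.arrays[chrom][pos0])


def _stack(fwd: np.ndarray, rev: np.ndarray) -> np.ndarray:
    return np.concatenate([
        np.stack([fwd, np.zeros_like(fwd)], axis=1),
        np.stack([rev, np.ones_like(rev)], axis=1),
    ]).astype(np.int64)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig, reference: dict[str, str]) -> SyntheticCohort:
    """Generate catalogs, metadata and truth for one cohort."""
    index = _SiteIndex(reference)
    total_sites = sum(len(s) for s in reference.values())
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    meta = _draw_metadata(cfg, rng)
    snvs: list[MutationRecord] = []
    indels: list[IndelRecord] = []
    svs: list[SVRecord] = []
    fragile = _plant_fragile_sites(cfg, rng)

    truth = SyntheticTruth({}, [], fragile, {}, {}, {}, {}, {}, {}, {}, {})
    uv_medians = dict(cfg.uv_load_median)
    for si, m in enumerate(meta):
        srng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3, si]))
        counts: dict[str, int] = {}
        used: set[tuple[str, int]] = set()

        bg_n = int(round(float(srng.lognormal(np.log(max(cfg.background_median, 1e-9)),
                                              cfg.background_sigma)))) \
            if cfg.background_median > 0 else 0
        cpg_n = int(srng.poisson(cfg.cpg_slope * m.age + cfg.cpg_intercept)) \
            if (cfg.cpg_slope or cfg.cpg_intercept) else 0
        med = uv_medians.get(m.race, 0.0)
        uv_n = int(round(float(srng.lognormal(np.log(med), cfg.uv_sigma)))) \
            if med > 0 else 0
        cc_pairs = int(round(cfg.cc_tt_fraction * uv_n))
        uv_single = uv_n - 2 * cc_pairs if uv_n >= 2 * cc_pairs else 0
        ntt_n = int(round(cfg.ntt_fraction * uv_n))
        if bg_n + cpg_n + uv_n + ntt_n > total_sites // 4:
            raise ValueError("reference too small for requested mutation counts")

        sample_records: list[MutationRecord] = []
        _place_snvs(sample_records, truth, m, index, srng, used,
                    "cpg", "cpg", cpg_n, "C", "T")
        _place_snvs(sample_records, truth, m, index, srng, used,
                    "uv", "uv", uv_single, "C", "T")
        _place_cc_tt(sample_records, truth, m, index, srng, used, cc_pairs)
        _place_snvs(sample_records, truth, m, index, srng, used,
                    "ntt", "ntt", ntt_n, "T", "C")
        _place_background(sample_records, truth, m, index, srng, used, bg_n)
        _assign_vafs(sample_records, cfg, srng)
        n_art = int(round(cfg.artifact_rate * len(sample_records)))
        _place_artifacts(sample_records, truth, m, index, srng, used, n_art, cfg)
        snvs.extend(sample_records)

        counts.update({
            "snv_cpg": cpg_n, "snv_uv": uv_single,
            "snv_cc_tt_records": 2 * cc_pairs, "snv_ntt": ntt_n,
            "snv_background": bg_n, "snv_artifact": n_art,
        })
        truth.uv_counts[m.sample_id] = uv_n
        truth.cpg_counts[m.sample_id] = cpg_n

        sample_indels, icounts, mh_list = _simulate_indels(
            cfg, m, index, srng, uv_n)
        indels.extend(sample_indels)
        counts.update(icounts)
        truth.mh_lengths[m.sample_id] = mh_list
        truth.hp_indel_counts[m.sample_id] = icounts["indel_homopolymer"]
        truth.del5_counts[m.sample_id] = icounts["indel_del_ge5"]

        if not m.wga:
            sample_svs, scounts, sv_mh = _simulate_svs(cfg, m, srng, fragile)
            svs.extend(sample_svs)
            counts.update(scounts)
            truth.sv_mh_lengths[m.sample_id] = sv_mh
        truth.per_sample[m.sample_id] = counts
        truth.ages[m.sample_id] = m.age
        truth.races[m.sample_id] = m.race
    return SyntheticCohort(snvs, indels, svs, meta, truth)


def _draw_metadata(cfg: SimConfig, rng) -> list[SampleMeta]:
    races = [r for r, _ in cfg.race_mix]
    weights = [w for _, w in cfg.race_mix]
    donor_race = [races[rng.choice(len(races), p=weights)]
                  for _ in range(cfg.n_donors)]
    donor_age = rng.uniform(*cfg.age_range, size=cfg.n_donors)
    donor_sex = ["M" if rng.random() < 0.4 else "F"
                 for _ in range(cfg.n_donors)]
    meta = []
    n_mel = int(round(cfg.melanocyte_fraction * cfg.n_samples))
    for i in range(cfg.n_samples):
        d = i % cfg.n_donors
        is_mel = i >= cfg.n_samples - n_mel
        meta.append(SampleMeta(
            sample_id=f"S{i:02d}", donor_id=f"D{d:02d}",
            age=float(donor_age[d]), sex=donor_sex[d], race=donor_race[d],
            cell_type="melanocyte" if is_mel else "fibroblast",
            wga=is_mel and i != cfg.n_samples - 1))  # one melanocyte unamplified
    return meta


def _pick_sites(index: _SiteIndex, rng, used: set, kind: str, n: int
                ) -> list[tuple[str, int, int]]:
    """Draw n distinct (chrom, pos0, strand) sites of a kind."""
    chroms = index.chroms
    sizes = np.array([len(index.sites[c][kind]) for c in chroms], dtype=float)
    if sizes.sum() == 0:
        raise ValueError(f"reference has no {kind} sites")
    out = []
    attempts = 0
    while len(out) < n and attempts < 50 * n + 1000:
        attempts += 1
        c = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
        arr = index.sites[c][kind]
        pos0, strand = arr[rng.integers(0, len(arr))]
        if (c, int(pos0)) in used:
            continue
        used.add((c, int(pos0)))
        out.append((c, int(pos0), int(strand)))
    if len(out) < n:
        raise ValueError(f"could not place {n} {kind} sites without collision")
    return out


def _place_snvs(records, truth, m, index, rng, used, kind, label, n,
                from_base, to_base) -> None:
    comp_f, comp_t = COMPLEMENT[from_base], COMPLEMENT[to_base]
    for chrom, pos0, strand in _pick_sites(index, rng, used, kind, n):
        ref, alt = (from_base, to_base) if strand == 0 else (comp_f, comp_t)
        records.append(MutationRecord(m.sample_id, chrom, pos0 + 1, ref, alt, 0.5))
        truth.variant_labels.append((m.sample_id, chrom, pos0 + 1, label))


def _place_cc_tt(records, truth, m, index, rng, used, n_pairs) -> None:
    placed = 0
    attempts = 0
    while placed < n_pairs and attempts < 50 * n_pairs + 1000:
        attempts += 1
        try:
            [(chrom, pos0, strand)] = _pick_sites(index, rng, used, "cc", 1)
        except ValueError:
            break
        second = pos0 + 1 if strand == 0 else pos0 - 1
        if (chrom, second) in used or second < 0:
            continue
        used.add((chrom, second))
        ref, alt = ("C", "T") if strand == 0 else ("G", "A")
        for p in sorted((pos0, second)):
            records.append(MutationRecord(m.sample_id, chrom, p + 1, ref, alt, 0.5))
            truth.variant_labels.append((m.sample_id, chrom, p + 1, "cc_tt"))
        placed += 1
    if placed < n_pairs:
        raise ValueError("could not place requested CC->TT pairs")


def _place_background(records, truth, m, index, rng, used, n) -> None:
    alts = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    for chrom, pos0, _ in _pick_sites(index, rng, used, "all", n):
        ref = index.base(chrom, pos0)
        alt = alts[ref][rng.integers(0, 3)]
        records.append(MutationRecord(m.sample_id, chrom, pos0 + 1, ref, alt, 0.5))
        truth.variant_labels.append((m.sample_id, chrom, pos0 + 1, "background"))


def _assign_vafs(records, cfg: SimConfig, rng) -> None:
    for r in records:
        if rng.random() < cfg.hom_fraction:
            r.vaf = float(np.clip(rng.normal(0.97, 0.015), 0.905, 1.0))
        else:
            # truncated so clonal calls stay clear of the artifact band
            r.vaf = float(np.clip(rng.normal(0.5, cfg.clonal_vaf_sd), 0.40, 0.60))


def _place_artifacts(records, truth, m, index, rng, used, n, cfg) -> None:
    alts = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    lo, hi = cfg.artifact_vaf_range
    for chrom, pos0, _ in _pick_sites(index, rng, used, "all", n):
        ref = index.base(chrom, pos0)
        alt = alts[ref][rng.integers(0, 3)]
        records.append(MutationRecord(m.sample_id, chrom, pos0 + 1, ref, alt,
                                      float(rng.uniform(lo, hi))))
        truth.variant_labels.append((m.sample_id, chrom, pos0 + 1, "artifact"))


# ---------------------------------------------------------------------------
# Indels
# ---------------------------------------------------------------------------

def _run_bounds(a: np.ndarray, pos0: int) -> tuple[int, int]:
    b = a[pos0]
    s = pos0
    while s > 0 and a[s - 1] == b:
        s -= 1
    e = pos0
    while e < a.size - 1 and a[e + 1] == b:
        e += 1
    return s, e


def _mh_of(a: np.ndarray, start0: int, length: int) -> int:
    """Junction microhomology of deleting a[start0:start0+length]."""
    deleted = a[start0:start0 + length]
    right = a[start0 + length:start0 + 2 * length]
    k1 = 0
    for x, y in zip(deleted, right):
        if x != y:
            break
        k1 += 1
    left = a[max(0, start0 - length):start0]
    k2 = 0
    for x, y in zip(deleted[::-1], left[::-1]):
        if x != y:
            break
        k2 += 1
    return min(max(k1, k2), length)


def _simulate_indels(cfg: SimConfig, m: SampleMeta, index: _SiteIndex, rng,
                     uv_n: int):
    indels: list[IndelRecord] = []
    mh_list: list[int] = []
    chroms = index.chroms

    def het_vaf():
        return float(np.clip(rng.normal(0.5, cfg.clonal_vaf_sd), 0.40, 0.60))

    # 1 bp slippage events in homopolymer runs (>= 2 bp), rate linear in age
    hp_rate = cfg.homopolymer_indel_slope * m.age + cfg.homopolymer_indel_intercept
    hp_n = int(rng.poisson(hp_rate)) if hp_rate > 0 else 0
    placed_hp = 0
    attempts = 0
    while placed_hp < hp_n and attempts < 100 * hp_n + 100:
        attempts += 1
        chrom, start0, length, base = index.runs[rng.integers(0, len(index.runs))]
        if start0 == 0:
            continue
        anchor0 = start0 - 1
        anchor = index.base(chrom, anchor0)
        if anchor == base:
            continue
        if rng.random() < 0.5:
            ref_a, alt_a = anchor, anchor + base  # insertion
        else:
            ref_a, alt_a = anchor + base, anchor  # deletion
        indels.append(IndelRecord(m.sample_id, chrom, anchor0 + 1, ref_a,
                                  alt_a, qual=100.0, vaf=het_vaf()))
        placed_hp += 1

    # deletions >= 5 bp with planted junction microhomology, UV-coupled
    del5_rate = cfg.deletion_ge5_base + cfg.deletion_ge5_per_uv * uv_n
    del5_n = int(rng.poisson(del5_rate)) if del5_rate > 0 else 0
    mh_probs = np.asarray(cfg.mh_probs) / np.sum(cfg.mh_probs)
    for _ in range(del5_n):
        want_mh = int(rng.choice(len(mh_probs), p=mh_probs))
        length = int(rng.integers(cfg.del5_len_range[0],
                                  cfg.del5_len_range[1] + 1))
        got = None
        for _attempt in range(400):
            chrom = chroms[rng.integers(0, len(chroms))]
            a = index.arrays[chrom]
            start0 = int(rng.integers(length + 1, a.size - 2 * length - 1))
            if _mh_of(a, start0, length) == want_mh:
                got = (chrom, start0, want_mh)
                break
        if got is None:  # fall back to whatever the last draw produced
            got = (chrom, start0, _mh_of(a, start0, length))
        chrom, start0, mh = got
        a = index.arrays[chrom]
        anchor0 = start0 - 1
        seq = "".join(chr(x) for x in a[anchor0:start0 + length])
        indels.append(IndelRecord(m.sample_id, chrom, anchor0 + 1, seq,
                                  seq[0], qual=100.0, vaf=het_vaf()))
        mh_list.append(mh)

    # larger templated insertions (local duplications, rare mismatches)
    tmpl_n = int(rng.poisson(cfg.templated_ins_mean)) \
        if cfg.templated_ins_mean > 0 else 0
    n_tmpl_mm = 0
    for _ in range(tmpl_n):
        length = int(rng.integers(3, 11))
        chrom = chroms[rng.integers(0, len(chroms))]
        a = index.arrays[chrom]
        pos0 = int(rng.integers(length + 1, a.size - length - 1))
        ins = [chr(x) for x in a[pos0 - length + 1:pos0 + 1]]  # copy left flank
        if rng.random() < cfg.templated_mismatch_prob:
            j = int(rng.integers(0, length))
            ins[j] = [b for b in "ACGT" if b != ins[j]][rng.integers(0, 3)]
            n_tmpl_mm += 1
        anchor = chr(a[pos0])
        indels.append(IndelRecord(m.sample_id, chrom, pos0 + 1, anchor,
                                  anchor + "".join(ins), qual=100.0,
                                  vaf=het_vaf()))

    # background small indels (1-3 bp, outside homopolymer runs for 1 bp)
    bg_n = int(rng.poisson(cfg.background_indel_mean)) \
        if cfg.background_indel_mean > 0 else 0
    for _ in range(bg_n):
        indels.append(_random_small_indel(cfg, m, index, rng, qual=100.0,
                                          vaf=het_vaf()))
    # low-quality calls, to be removed by the quality filter
    lq_n = int(rng.poisson(cfg.lowqual_indel_mean)) \
        if cfg.lowqual_indel_mean > 0 else 0
    for _ in range(lq_n):
        indels.append(_random_small_indel(cfg, m, index, rng,
                                          qual=float(rng.uniform(5, 49)),
                                          vaf=het_vaf()))
    counts = {
        "indel_homopolymer": placed_hp,
        "indel_del_ge5": del5_n,
        "indel_templated_large": tmpl_n,
        "indel_templated_mismatch": n_tmpl_mm,
        "indel_background": bg_n,
        "indel_lowqual": lq_n,
    }
    return indels, counts, mh_list


def _random_small_indel(cfg, m, index, rng, qual, vaf) -> IndelRecord:
    chroms = index.chroms
    for _ in range(500):
        chrom = chroms[rng.integers(0, len(chroms))]
        a = index.arrays[chrom]
        length = int(rng.integers(1, 4))
        pos0 = int(rng.integers(1, a.size - length - 2))
        anchor = chr(a[pos0])
        if rng.random() < 0.5:  # deletion of the next `length` bases
            seq = "".join(chr(x) for x in a[pos0:pos0 + length + 1])
            if length == 1 and _in_run(a, pos0 + 1):
                continue
            return IndelRecord(m.sample_id, chrom, pos0 + 1, seq, anchor,
                               qual=qual, vaf=vaf)
        ins = "".join("ACGT"[rng.integers(0, 4)] for _ in range(length))
        if length == 1 and (ins == chr(a[pos0 + 1]) or ins == anchor):
            continue  # would read as slippage / be subject to normalization
        return IndelRecord(m.sample_id, chrom, pos0 + 1, anchor, anchor + ins,
                           qual=qual, vaf=vaf)
    raise RuntimeError("could not draw a background indel")


def _in_run(a: np.ndarray, pos0: int) -> bool:
    s, e = _run_bounds(a, pos0)
    return e - s + 1 >= 2


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

_SV_TYPES = ["DEL", "DUP", "INV", "TRA"]
_SV_TYPE_P = [0.4, 0.25, 0.2, 0.15]


def _plant_fragile_sites(cfg: SimConfig, rng) -> list[tuple[str, int, int]]:
    sizes = dict(cfg.sv_chrom_sizes)
    chroms = list(sizes)
    out: list[tuple[str, int, int]] = []
    attempts = 0
    while len(out) < cfg.n_fragile_sites and attempts < 10_000:
        attempts += 1
        c = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(1, sizes[c] - cfg.fragile_site_length))
        end = start + cfg.fragile_site_length - 1
        if any(cc == c and abs(start - s) < cfg.fragile_min_spacing
               for cc, s, _ in out):
            continue
        out.append((c, start, end))
    return sorted(out)


def _simulate_svs(cfg: SimConfig, m: SampleMeta, rng,
                  fragile: list[tuple[str, int, int]]):
    sizes = dict(cfg.sv_chrom_sizes)
    chroms = list(sizes)
    lo, hi = cfg.sv_count_range
    n_sv = int(np.clip(lo + rng.poisson(max(cfg.sv_count_mean - lo, 0)), lo, hi))
    svs: list[SVRecord] = []
    sv_mh: list[int] = []
    n_hot = 0
    for _ in range(n_sv):
        sv_type = _SV_TYPES[rng.choice(4, p=_SV_TYPE_P)]
        in_fragile = rng.random() < cfg.sv_hotspot_weight and fragile
        if in_fragile:
            c1, fs, fe = fragile[rng.integers(0, len(fragile))]
            pos1 = int(rng.integers(fs, fe + 1))
            n_hot += 1
        else:
            c1 = chroms[rng.integers(0, len(chroms))]
            pos1 = int(rng.integers(1, sizes[c1]))
        if sv_type == "TRA":
            others = [c for c in chroms if c != c1]
            c2 = others[rng.integers(0, len(others))]
            pos2 = int(rng.integers(1, sizes[c2]))
        else:
            span = int(np.exp(rng.uniform(np.log(5_000), np.log(2_000_000))))
            c2 = c1
            pos2 = min(pos1 + span, sizes[c1])
        total = int(rng.integers(10, 61))
        frac = float(rng.uniform(0.35, 0.6))
        mh_seq = None
        mh_len = 0
        if rng.random() < cfg.sv_mh_prob:
            mh_len = int(rng.integers(2, 4))
            mh_seq = "".join("ACGT"[rng.integers(0, 4)] for _ in range(mh_len))
        svs.append(SVRecord(m.sample_id, sv_type, c1, pos1, c2, pos2,
                            junction_reads_variant=max(1, int(round(frac * total))),
                            junction_reads_total=total,
                            blood_variant_reads=0,
                            inserted_or_mh_seq=mh_seq))
        sv_mh.append(mh_len)
    # sub-clonal SVs the clonality filter should drop
    n_sub = int(rng.poisson(cfg.sv_subclonal_rate * n_sv))
    for _ in range(n_sub):
        c1 = chroms[rng.integers(0, len(chroms))]
        pos1 = int(rng.integers(1, sizes[c1] - 100_000))
        total = int(rng.integers(10, 61))
        svs.append(SVRecord(m.sample_id, "DEL", c1, pos1, c1,
                            pos1 + int(rng.integers(1_000, 100_000)),
                            junction_reads_variant=max(0, int(round(
                                float(rng.uniform(0.02, 0.25)) * total))),
                            junction_reads_total=total,
                            blood_variant_reads=int(rng.integers(0, 3))))
    counts = {"sv_clonal": n_sv, "sv_in_fragile": n_hot, "sv_subclonal": n_sub}
    return svs, counts, sv_mh
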