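# Methods

`clonemut` analyzes somatic genome changes in single-cell-derived clonal
lineages — the experimental design in which a single skin fibroblast or
melanocyte is expanded in culture so that every true somatic variant of the
founder cell appears at ~50% (heterozygous) or ~100% (homozygous) allele
fraction, cleanly separated from culture artifacts and sequencing noise.
This note records the models, the parameter choices, and the numerical
decisions made where the design was genuinely open.

## Clonality filtering

A call is clonal when its variant allele fraction (VAF) lies in the
heterozygous band [0.45, 0.55] or the homozygous band (> 0.90 for
substitutions; [0.90, 1.00] for indels, whose stated band is inclusive).
Everything else is sub-clonal and removed.  Substitutions additionally
require consensus across all provided caller key-sets (the intersection),
exclusion of known-variant keys (allele-aware by default, position-only
behind a flag), and no overlap with repeat masks; for indels the whole
changed span is tested against the masks, and calls with caller quality
< 50 are dropped.  Structural variants (SVs) are clonal when variant
junction reads are ≥ 30% of total junction reads and the donor's blood
carries zero supporting reads; caller-level LowQual/IMPRECISE flags are a
boolean on the record set by the reader.

## Trinucleotide-motif enrichment and minimum mutation load

For a motif signature (e.g. yCn→yTn: mutated middle base capitalized, y =
pyrimidine, n = any base) and one sample:

1. **Complex-mutation exclusion.** Same-sample substitutions < 10 bp apart
   are removed (both members), since clustered changes likely arise from a
   single translesion-synthesis event and would distort motif counts.
   Adjacent CC→TT pairs are therefore counted separately (below), on the
   unexcluded catalog.
2. **Windows.** Every mutation of the base-change class (all C→T when
   testing yCn→yTn) contributes a ±20 base reference window,
   reverse-complemented when the record is on the purine strand, so all
   windows are pyrimidine-oriented.
3. **Counts.** `mut_in_motif` counts centers whose trinucleotide matches
   the motif on either strand; `ctx_base` counts unmutated occurrences of
   the middle base (both strands) at non-center window positions;
   `ctx_motif` counts those in motif context.  N is never a context base.
   The fully degenerate symbol n imposes no constraint, so the degenerate
   motif nCn reduces exactly to the base class (enrichment ≡ 1).
4. **Statistic.**

       enrichment = (mut_in_motif × ctx_base) / (mut_in_class × ctx_motif)

   tested one-sided toward enrichment with Fisher's exact test on
   [[mut_in_motif, mut_in_class − mut_in_motif],
   [ctx_motif, ctx_base − ctx_motif]], then Benjamini–Hochberg corrected
   across samples within each signature.  Sidedness and the BH family are
   arguments.
5. **Minimum mutation load.** For samples with enrichment > 1 and q < 0.05,

       min_load = mut_in_motif × (enrichment − 1) / enrichment,

   otherwise 0.  This is deliberately conservative: a motif-specific
   process with true event count S yields E[min_load] ≈ S·(1 − p), where
   p = ctx_motif/ctx_base is the motif availability, because a uniform
   process would have placed a fraction p of its events in the motif
   anyway.  `EnrichmentResult.process_load` therefore exposes
   min_load/(1 − p) as an unbiased point estimate of S; recovery tests and
   the acceptance script use it where the generator truth is the target.

**Window-edge guard.** A context base at the extreme ±20 position has a
real genomic neighbor just outside the window.  Windows are fetched with
one extra guard base per side, used only as a neighbor during motif
matching and never counted.  Without the guard, motif availability is
biased low by ~2% and the null Fisher test becomes measurably
anticonservative (~10% of null samples significant after BH in a family
containing true positives; ~2% with the guard).

**Degenerate counts.** ctx_motif = 0 with mut_in_motif > 0 reports
enrichment as +inf with an `undefined` flag (min_load falls back to
mut_in_motif); mut_in_class = 0 reports NaN and p = 1.

**CC→TT.** Dinucleotide UV changes are counted as same-sample C→T calls at
adjacent positions (GG→AA via reverse complement), each pair once.
nTt→nCt is reported both as an enrichment result and as a direct count.

## Spectra and signature refitting

`sbs96` builds the standard 96-channel substitution spectrum
(pyrimidine-strand trinucleotide channels); records with N context are
dropped and counted.  `indel83` implements the standard 83-channel indel
scheme: 1 bp events split by C/T (strand-normalized) and homopolymer run
length; longer events by length class (2, 3, 4, 5+) and tandem-repeat
copies; deletions without adjacent repeat copies but with junction
microhomology go to the microhomology channels.  Run length and repeat
copies are measured on the reference after left-normalization.  `refit`
solves non-negative least squares (scipy `nnls`) against a channels ×
signatures catalog and reports the reconstruction residual; `cosine` is
the plain cosine similarity.  The bundled catalogs are synthetic stand-in
signatures (flat clock-like, CpG C>T, UV-like C>T, oxidative C>A;
slippage-insertion, slippage-deletion and microhomology-deletion indel
shapes) for offline tests; the loaders accept full published catalogs.

## Indel biology

* **Homopolymer slippage:** an indel of length 1 whose base extends or
  shrinks a reference run of that base of length ≥ 2 (the minimum run is
  configurable; no published threshold exists, and 2 makes a deletion
  from a dinucleotide run the smallest slippage event).
* **Junction microhomology (MH):** max(longest common prefix of the
  deleted sequence with the right flank, longest common suffix with the
  left flank), capped at the deletion length.  On iid random sequence each
  side is geometric with ratio 1/4, so the reported maximum obeys
  P(MH ≥ k) = 1 − (1 − 4^(−k))²; tests check that law.
* **Templated insertions:** the inserted sequence is compared with the
  L bases immediately left and right of the insertion point; an exact
  match is `adjacent_copy` (left preferred on ties — both comparisons are
  retrievable), and for L ≥ 3 a Hamming distance ≤ 1 is
  `adjacent_copy_with_mismatch` (single-base insertions must match
  exactly).  Contig-edge comparisons use the available bases and are
  flagged truncated.
* **Deletions ≥ 5 bp** are tallied separately (boundary inclusive); in
  this biology they track UV-induced double-strand-break repair rather
  than replication slippage.

## Structural variants

Breakpoints of every SV (both ends; translocation ends on their own
chromosomes) are chained per chromosome by single linkage with a 1 Mbp
gap; a chain is a **hotspot** when it contains breakpoints of ≥ 2 SVs from
≥ 2 distinct samples, and an SV is in a hotspot when any of its
breakpoints is.  Distances are measured between breakpoints, not interval
gaps.  DEL/DUP/INV colocalize with a common fragile site (CFS) when
[pos1, pos2] intersects the interval by ≥ 1 bp; translocations when a
breakpoint lies within 10 kb of one.  Junction microhomology reuses the
deletion prefix/suffix logic in junction orientation per SV type
(deletion ends vs retained flanks; tandem-duplication junction ambiguity;
reverse-complemented flank for inversions).  The association tests are a
two-sided Fisher exact test on MH-use (MH ≥ 2, matching the observed 2–3
base junctions; configurable) inside vs outside CFSs, and a Pearson
chi-square without continuity correction on SV type × CFS overlap
(all-zero rows/columns dropped with a warning).

## Cohort statistics

Each clonal lineage is one observation; multiple clones per donor count
separately, matching the per-sample points of the source figures.  Age
regressions and signature–signature correlations are ordinary least
squares with t-based 95% confidence intervals.  Group comparisons use the
two-sided Mann–Whitney U test — exact for combined n ≤ 25 without ties,
tie-corrected normal approximation otherwise — with an explicit Bonferroni
family size (the race comparison family spans 6 endpoints) and an
`exclude` flag for sensitivity analyses such as dropping the
whole-genome-amplified melanocytes.

## Synthetic cohort generator

The generator's defaults are the cohort conditions the analysis targets;
they are fixed, not tuning knobs.

* **Cohort:** 39 clonal lineages from 21 donors, ages uniform on 25–79;
  race mix 16:5 White:African American assigned per donor; ~13%
  melanocytes, whole-genome amplified except one (amplified samples get no
  SV calls, mirroring the study design).
* **Reference:** 2 Mbp over 2 chromosomes, GC fraction 0.41, CpG
  dinucleotide frequency at the iid expectation (enrichment factor 1.0;
  configurable, 0 removes every CpG), planted homopolymer runs of 5–12 bp
  at 5×10⁻⁴ per base.  2 Mbp keeps per-site mutation densities realistic
  at catalog sizes of hundreds to thousands while every test and the
  acceptance script run on one CPU in seconds per cohort.
* **Substitutions per sample:** background count lognormal (median 1000,
  log-sd 0.8, giving the broad few-hundred-to-ten-thousand range observed
  in such catalogs) placed uniformly with random alternate alleles; CpG
  deamination ~ Poisson(0.4·age + 27) placed at nCg sites (slope 0.4/year;
  the intercept sets the mid-cohort median near the observed ~48);
  UV ~ lognormal with White median 200 in-motif events at yCn sites
  (log-sd 0.5) and 0 for African American donors, age-independent; 5% of
  UV events emitted as adjacent CC→TT pairs and a companion nTt→nCt count
  at 10% of UV.  Clonal VAFs are N(0.5, 0.02) truncated to [0.40, 0.60]
  (5% homozygous near 0.97); artifact calls at 25% of the clonal count
  have VAF uniform on [0.05, 0.35], so the artifact and clonal bands are
  disjoint by construction.
* **Indels:** homopolymer 1 bp slippage ~ Poisson(0.22·age + 2) at run
  sites; deletions ≥ 5 bp ~ Poisson(2 + 0.035·UV), i.e. coupled to the
  sample's UV load, with junction MH planted by rejection sampling from
  {0:0.35, 1:0.30, 2:0.20, 3:0.10, 4:0.05}; occasional larger templated
  insertions (local duplications, 1/6 with a single mismatch); background
  1–3 bp indels (1 bp ones placed outside runs so generator truth and
  classifier counts reconcile exactly) and low-quality calls (qual < 50)
  for the quality filter to remove.
* **SVs:** counts 1 + Poisson(2.4) clipped to [1, 14] per unamplified
  sample (matching the reported per-isolate range and a ~3.4 mean), 60%
  placed inside 6 planted fragile-site intervals (300 kb, ≥ 3 Mbp apart)
  on virtual 4 × 60 Mbp chromosomes — virtual because recurrent-hotspot
  geometry needs ~100 Mbp of breakpoint space that would be wasteful to
  materialize as sequence; junction MH, when planted (12.5% of SVs, 2–3
  bp), travels on the record.  Sub-clonal SVs (low junction fraction or
  blood support) are added for the clonality filter to remove.
* **Truth:** per-variant process labels, per-sample process counts,
  fragile intervals, planted MH lengths, ages and races are exported and
  reconcile exactly with catalog sizes.

**What the generator does not emulate:** real human genome composition
(CpG islands, repeat families, chromatin-dependent mutation rates),
sequencing-error processes, caller-specific artifacts, donor-level
correlation beyond shared age/race, and SV breakpoint sequence context.
Passing tests therefore demonstrate that the statistical machinery
recovers known structure under the stated model, not that the pipeline is
robust to every artifact of real sequencing data.

## Numerical choices

* Coordinates are 1-based inclusive internally; BED converts at the I/O
  boundary and nowhere else.  Indels are left-normalized on read.
* Determinism: every random draw descends from numpy `SeedSequence`
  streams keyed by (seed, purpose, sample index); identical configuration
  gives byte-identical output.
* Monte-Carlo test tolerances are 3–4 standard errors of the measured
  quantity (binomial or across-replicate), with small a-priori absolute
  floors where a ratio estimator carries O(1/n) bias.
* The acceptance script pools 8 default cohorts (312 samples) so the
  regression slopes it prints have standard errors well under 10% of the
  generating values, and scales the null calibration to 500 samples and
  the spike recovery to 6 replicates of 2000 mutations; the test suite
  runs the full 1000-sample null and 20-seed end-to-end recovery.

## Known limitations

* The enrichment context is window-based (counts per occurrence, no
  deduplication of overlapping windows; a dedup flag exists), which
  matches the per-window reading of the method but slightly reweights
  densely mutated regions.
* Minimum load is conservative by design (factor 1 − p); cross-sample
  comparisons of min_load are fine, absolute process intensities should
  use `process_load`.
* SV microhomology for inversions and translocations compares flanks in a
  fixed junction orientation; callers reporting strand-annotated
  breakpoints may need their orientation mapped onto it.
* The Mann–Whitney exact/asymptotic switch at combined n = 25 follows the
  classical rule; the two agree within 0.01 at n₁ = n₂ = 12 (tested).
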