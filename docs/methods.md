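# Methods

## Coordinate and read conventions

All intervals are 0-based half-open; human-facing output converts to
1-based inclusive. For a plus-strand read the 5′ end is `start` and the 3′
end is `end − 1`; for a minus-strand read the 5′ end is `end − 1` and the 3′
end is `start`. Read sequences, when carried, are stored in reference
(plus-strand) orientation, so the base a read places at reference position
`p` is `sequence[p − start]` regardless of strand. Alignments are consumed
from a plain BED-like TSV (`ref start end strand [read_id sequence
n_mismatches]`) rather than BAM: the statistics operate on placements, and a
text dialect keeps fixtures inspectable; converting BAM to this stream is a
one-line `samtools`/`pysam` exercise outside this package's scope.

## Small-RNA signature statistics

**Ping-pong.** Reciprocal piRNA amplification produces sense/antisense
pairs whose 5′ ends overlap by exactly 10 nt. For every (plus, minus) read
pair on one reference the overlap is d = minus₅′ − plus₅′ + 1; the histogram
c_d is collected for d ∈ 1..30 and scored as
z₁₀ = (c₁₀ − mean(c_d, d ≠ 10)) / sd(c_d, d ≠ 10), with the sample standard
deviation. All qualifying pairs are counted by default; an option collapses
duplicate 5′-end pairs, since both conventions are in use in the field.

**Phasing.** Zucchini-dependent processing lays same-strand piRNAs
head-to-tail, so the 5′ end of one read falls directly after the 3′ end of
the previous one. Distances run in the direction of transcription
(next₅′ − prev₃′ on plus; prev₃′ − next₅′ on minus, so adjacency is 1 on
both strands), are computed per strand and summed, and are scored as
Z₁ = (c₁ − mean(c₂..₅₁)) / sd(c₂..₅₁). The background windows (1..30 less
the focal 10 for ping-pong; 2..51 for phasing) are the conventional choices
and are configurable; when the background variance is zero the z-score is
reported as undefined rather than ±∞.

Both histograms are validated against an independent O(n²) all-pairs
enumeration in the test suite, and both statistics are invariant under a
global coordinate shift. Under a null of uniformly placed reads the mean
z₁₀ across 100 libraries of 1,000 reads is within ±0.5 of zero.

## Degradome overlap calling and permutation tests

A slicing Piwi protein cuts its target between the bases paired to guide
positions 10 and 11, so a degradome fragment 5′ end at plus-strand position
d is supported when an antisense piRNA has its 5′ end at d + 9 (overlap
exactly 10). Two resampling tests ask whether the observed positions are
special, both with B = 1,000 permutations by default and sampling distinct
positions without replacement:

1. *Abundance*: draw |observed| positions from those carrying ≥1 piRNA 5′
   end and compare piRNA counts with the observed set. Two comparison
   statistics are provided because the descriptive criterion "same or more
   piRNAs at each location" is ambiguous: `dominance` (sorted count vectors,
   elementwise ≥) and `sum` (total counts). Elementwise dominance is a
   useful detection criterion but not a proper tail probability — its null
   p-values are not uniform — so calibration claims and inferential use
   attach to the `sum` statistic, whose null p-values are uniform to
   Kolmogorov–Smirnov distance < 0.1 in the test suite.
2. *Overlap count*: draw n_observed positions uniformly from the region and
   count how many have an antisense piRNA 5′ end 9 nt downstream; compare to
   the observed overlap count. The statistic is informative when piRNA
   positions are sparse relative to the region; a dense piRNA background
   honestly dilutes it.

Reported p-values default to (k + 1)/(B + 1), which cannot reach 0; a
`paper_style` option reports the plain k/B for concordance with analyses
that used that convention.

## Allele-specific counting

Diagnostic sites are alignment columns where the TE and the gene carry
different unambiguous bases; columns with gaps, N, or IUPAC codes yield no
site. Read bases are classified per (read, site) incidence — a read
covering k sites contributes k bases — which matches the published
denominator convention for the 9,301-base tally. Percentages are rounded
for reporting (one decimal by default; two available, as the small fractions
are printed at two decimals).

The TE's 5′-UTR copy of the captured segment is character-identical to the
3′-UTR copy, so positions map between the copies by the translation
`utr5_offset + (p − captured_start)`, a bijection used to mirror sites and
masks between the two copies. Masking replaces interval unions with N,
preserving length.

## Copy number and the truncation mixture model

Copy number is C = median nonzero per-base coverage over the TE CDS
(ORF1+ORF2) divided by the strain's median coverage over uniquely mappable
genome positions. The genome-side median is consumed as a precomputed
scalar: read trimming, downsampling, GC correction and mappability are
upstream data preparation, not part of the statistic.

Because the captured segment appears twice in the TE reference, reads from
it are ambiguous between the two copies; this package models an even 50/50
split (the symmetric limit of probabilistic assignment when the two copies
are equally abundant; real assigners weight by local unique coverage, which
the data here cannot resolve). If a fraction f of TE copies lack the 5′
UTR, segment-derived reads total n·λ·(2 − f) across both genomic instances
per position, so each reference copy sits at expected relative coverage
r(f) = (2 − f)/2 against a 3′-UTR-only flank — at most a 50% reduction at
f = 1 — inverted as f̂ = 2(1 − r), clamped to [0, 1] with a logged warning.
Regional coverage is ORF-median-normalized; an optional fixed-width window
summary reproduces figure-style granularity.

## Relative-rate test and substitution timing

From a gapless 3-way alignment (ingroup 1, ingroup 2, outgroup), a column
with ingroup1 ≠ ingroup2 and ingroup2 = outgroup is an ingroup-1-specific
substitution (and symmetrically); columns with gaps, ambiguity codes, three
distinct states, or outgroup-only differences are excluded and counted.
The test statistic is χ² = (m₁ − m₂)²/(m₁ + m₂) with 1 df and a continuous
(uncorrected) upper-tail p — (13, 3) gives exactly 6.25 and p = 0.012.
Each ingroup-1-specific site is then dated against a TE that captured the
region from lineage 1: a TE carrying the ingroup-2 (ancestral-proxy) allele
implies the substitution postdates the capture; the derived ingroup-1 allele
implies it predates it.

## Expression ranking

Size factors follow the median-of-ratios formula: s_j = median over genes
with all-positive counts of count_gj / geometric-mean_g (cross-checked
against the pyDESeq2 implementation in the tests). Size factors are only
identifiable jointly, so the control and knockdown libraries are
concatenated, normalized together, and split. Fold changes use a
pseudocount of 0.5 ((kd + ε)/(ctrl + ε)) to keep zero knockdown counts
finite without reordering expressed genes; "expressed" means nonzero control
count, and non-expressed genes are dropped and reported. The ranking counts
genes (excluding the focal gene; inclusion is a flag) whose fold change is ≥
the focal gene's in every experiment, with the expressed-gene count as the
percentile denominator; each knockdown's own target can be masked from its
experiment. Group comparisons use the two-sided Wilcoxon rank-sum test
(exact for n ≤ 8 without ties, tie-corrected normal approximation
otherwise) and Spearman correlation with average ranks.

## Synthetic data

The generators emulate the statistical structure of the study's data at
desk scale; one integer seed drives fixed-index child generators per stage,
so outputs are byte-identical for identical parameters.

- **Locus** (defaults): 3,000-nt gene transcript; 700-nt captured segment
  mirrored into the TE 5′ UTR; 17 diagnostic substitutions; 3,600-nt
  combined ORF region; 600/200-nt 3′-UTR flanks around the captured copy;
  11 cleavage positions inside the captured region (placed so each 10-nt
  overlap partner stays inside it).
- **Small RNA**: 20,000 reads of 23–30 nt; 40% ping-pong pair reads / 30%
  phased-trail reads (geometric trail lengths, mean ≈ 6) / 30% background;
  59% antisense bias for non-pair reads; per-base error rate 10⁻³.
  Ping-pong pairs are symmetric by construction, so the antisense share is
  exactly reproduced only by pair-free libraries.
- **Degradome**: ≥1 plus-strand fragment with 5′ end at each cleavage
  position (Poisson mean 5) and a pile of partner antisense piRNAs at +9
  (Poisson mean 50), over 20 decoy fragments and 200 background piRNAs.
- **Genomic coverage**: 4 TE copies at per-haploid depth 50 (recovery tests
  use depth 30); each copy loses its 5′ UTR independently with probability
  f = 0.6 (the regime of a ~30% duplicated-segment reduction). Coverage is
  Poisson around the mixture expectation with the even multiread split.
  Truth records the *realized* truncated fraction, which with few copies is
  the quantity the coverage actually reflects and is the recovery target.
- **Counts**: 12,000 genes × (1 control + 16 knockdowns); log-normal
  baseline means, Gamma–Poisson (negative binomial) counts with dispersion
  0.1; planted fold changes multiply knockdown means; optional per-library
  size factors.
- **Triplet**: 2,000-nt ancestor (retained by the outgroup); Poisson
  numbers of substitutions per ingroup branch at *disjoint* sites, so
  planted lineage counts are recovered exactly. Multiple hits, convergence
  and back-substitution are deliberately outside the noise model — the
  target is the counting and test machinery, not a substitution process.
  A capture planted after fraction q (default 0.23) of ingroup-1
  substitutions fixes the TE's pre/post-capture allele pattern.

What passing tests on these data do **not** show: robustness to alignment
error, multimapping-weight estimation, indels, sequencing-quality artifacts,
GC bias, or real population structure — all delegated upstream or out of
scope.

## Numerical choices and degenerate inputs

z-scores use the sample (ddof = 1) standard deviation and are flagged
undefined when the background variance is zero. Permutation p-values use
(k + 1)/(B + 1) unless `paper_style`. χ² is undefined (an error) at
m₁ + m₂ = 0. Truncation f̂ is clamped to [0, 1] with a warning. Spearman
correlation of a constant vector returns NaN with a warning. Median
coverage over all-zero regions returns 0 with a warning rather than
erroring, since fully absent TEs are a legitimate observation. Problem
sizes in the test suite (e.g., 1,000-read null libraries, 200 calibration
runs, 50–500 simulation seeds) were chosen as the smallest sizes at which
the asserted statistical properties are stable.
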