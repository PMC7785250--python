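# piconflict

Analyses for a genetic conflict in which a telomeric retrotransposon has
captured a segment of a host gene and, via the piRNA pathway, turned that
homology against the gene. In *Drosophila melanogaster* the telomeric
retrotransposon TART-A carries a ~700-bp segment of the nuclear export
factor gene *nxf2* in its 3′ UTR, mirrored again in its 5′ UTR; piRNAs
produced from the TE can then target *nxf2* transcripts. `piconflict`
implements the computational analyses that establish and quantify this
relationship, as a tested, reusable library with synthetic-data generators
that plant known truth for every stage:

- **Small-RNA signatures** — piRNA length filtering (23–30 nt), stranded
  coverage with RPM scaling, the ping-pong 10-nt 5′:5′ overlap z-score
  (z₁₀), and the phased-piRNA 3′→5′ distance-1 z-score (Z₁).
- **Degradome analysis** — calling cleavage positions whose 5′ end lies
  exactly 10 nt inside an antisense piRNA (the slicer signature), plus two
  permutation tests (B = 1,000) for piRNA abundance at, and overlap counts
  of, the observed positions.
- **Allele-specific counting** — diagnostic sites where TE and gene carry
  different bases, and per-incidence assignment of read bases to the TE or
  gene allele.
- **Copy number and truncation** — TE copy number C = median nonzero CDS
  coverage / genome-wide median coverage, and a mixture model for copies
  missing the 5′ UTR: the duplicated segment's expected relative coverage is
  r(f) = (2 − f)/2 for truncation fraction f, inverted as f = 2(1 − r).
- **Relative-rate test** — lineage-specific substitution counts m₁, m₂
  polarized by an outgroup, χ² = (m₁ − m₂)²/(m₁ + m₂) with 1 df, and
  classification of each substitution as pre- or post-capture from the TE's
  allele.
- **Knockdown ranking** — median-of-ratios size-factor normalization, fold
  changes over a shared control, and the genome-wide count of genes whose
  fold change ≥ the focal gene's in *every* knockdown.

## Worked example

Generate a synthetic conflict locus and run the pipeline on it:

```bash
piconflict simulate --seed 1 --outdir demo
piconflict pingpong demo/smallrna.tsv
piconflict truncation demo/coverage.tsv --captured 5050-5750 \
    --flank 4450-5050 --orf 850-4450
piconflict relrate demo/triplet.fasta
```

With seed 1 the simulated library of 20,000 piRNA-length reads (40%
ping-pong pairs, 30% phased trails, 30% background) gives `z = 33.5` for the
ping-pong signature and `Z₁ = 19.6` for phasing — both far above the ~0
expected for a library with no planted structure. The coverage track was
simulated from 4 TE copies of which 3 lost their 5′ UTR, and the truncation
command prints

```json
{"r": 0.621, "f": 0.757, "clamped": false}
```

recovering the realized truncated fraction 3/4 from the ~38% coverage
reduction of the duplicated segment. The relative-rate command on the
simulated three-species alignment prints `m1 = 31, m2 = 7, chi2 = 15.16,
p = 1e-4`, matching the planted 10-fold rate asymmetry, and
`piconflict degradome-test` reports permutation p-values of 0.001
(abundance) and 0.006 (overlap count) for the 11 planted cleavage sites.

On the printed tallies of the real locus the same machinery gives the
published numbers: allele counts 9,244/27/30 over 9,301 diagnostic bases
summarize to 99.4% TE-matching, and substitution counts (13, 3) give
χ² = 6.25, p = 0.012.

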