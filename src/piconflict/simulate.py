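"""Synthetic data with planted truth for every pipeline stage.

The generators emulate a host-gene/retrotransposon conflict locus: a TE whose
3' UTR contains a segment captured from a host gene (with a handful of
diagnostic substitutions accumulated since the capture) and whose 5' UTR
carries a character-identical mirror of that segment; piRNA libraries with
planted ping-pong pairs and phased trails; degradome fragments whose 5' ends
mark slicer cleavage positions; genomic read depth from a mixture of
full-length and 5'-truncated TE copies; negative-binomial knockdown count
matrices; and 3-taxon alignments with asymmetric lineage-specific
substitution rates.

Every generator is driven by one integer seed; each stage derives its own
child generator deterministically, so identical parameters give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .types import (
    AlignedRead,
    CountMatrix,
    CoverageTrack,
    DiagnosticSite,
    GenomicInterval,
    SequenceRecord,
)

_BASES = np.array(list("ACGT"))

# fixed stage ids so child generators are independent of call order
_STAGE_LOCUS = 0
_STAGE_SMALLRNA = 1
_STAGE_DEGRADOME = 2
_STAGE_COVERAGE = 3
_STAGE_COUNTS = 4
_STAGE_TRIPLET = 5


@dataclass
class SimulationParams:
    """All generator knobs, with defaults emulating the study conditions.

    The locus carries 17 diagnostic substitutions in the captured segment;
    piRNA reads are 23-30 nt with a 59% antisense bias; the genomic mixture
    defaults to 4 TE copies with truncation fraction 0.6 (a ~30% coverage
    reduction of the duplicated segment); the knockdown panel has 16
    experiments over ~12,000 genes.
    """

    seed: int = 0
    # locus geometry (nt)
    gene_length: int = 3000
    captured_length: int = 700
    capture_offset_gene: int = 1500
    n_diagnostic_sites: int = 17
    utr5_extra: int = 150
    orf_length: int = 3600
    utr3_flank_up: int = 600
    utr3_flank_down: int = 200
    n_cleavage_sites: int = 11
    # small-RNA library
    n_reads: int = 20000
    pingpong_pair_fraction: float = 0.4
    phased_fraction: float = 0.3
    background_fraction: float = 0.3
    pirna_length_range: tuple[int, int] = (23, 30)
    antisense_fraction: float = 0.59
    error_rate: float = 0.001
    mean_trail_length: float = 5.0
    # degradome library (gene-transcript frame)
    degradome_depth: float = 5.0
    pirnas_per_cleavage: float = 50.0
    n_decoy_degradome: int = 20
    n_background_pirnas: int = 200
    # genomic coverage
    read_depth: float = 50.0
    n_te_copies: int = 4
    truncation_fraction: float = 0.6
    # knockdown counts
    n_genes: int = 12000
    n_knockdowns: int = 16
    nb_dispersion: float = 0.1
    planted_fold_changes: dict = field(default_factory=dict)
    library_size_factors: Optional[Sequence[float]] = None
    # 3-taxon alignment
    triplet_length: int = 2000
    lineage_rates: tuple[float, float] = (0.02, 0.002)
    capture_fraction: float = 0.23

    def __post_init__(self) -> None:
        fracs = (
            self.pingpong_pair_fraction,
            self.phased_fraction,
            self.background_fraction,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("read-class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"read-class fractions must sum to 1, got {sum(fracs)}")
        lo, hi = self.pirna_length_range
        if not (18 <= lo <= hi <= 35):
            raise ValueError("piRNA length range must lie within [18, 35]")
        if not 0 <= self.antisense_fraction <= 1:
            raise ValueError("antisense_fraction must lie in [0, 1]")
        if not 0 <= self.truncation_fraction <= 1:
            raise ValueError("truncation_fraction must lie in [0, 1]")
        if self.n_te_copies < 0:
            raise ValueError("n_te_copies must be >= 0")
        if self.n_diagnostic_sites > self.captured_length:
            raise ValueError(
                "captured segment shorter than the number of diagnostic sites"
            )
        if self.capture_offset_gene + self.captured_length > self.gene_length:
            raise ValueError("captured segment extends beyond the gene transcript")


def _stage_rng(params: SimulationParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, params.seed])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(3)]


# ---------------------------------------------------------------------------
# Locus


@dataclass
class ConflictLocusTruth:
    """Complete planted description of the conflict locus."""

    te_sequence: SequenceRecord
    gene_sequence: SequenceRecord
    te_orf_interval: GenomicInterval
    te_utr3_interval: GenomicInterval
    te_utr5_interval: GenomicInterval
    captured_interval_gene: GenomicInterval
    captured_interval_te3: GenomicInterval
    captured_interval_te5: GenomicInterval
    diagnostic_sites: list[DiagnosticSite]
    n_te_copies: int
    truncation_fraction: float
    cleavage_positions: list[int]


def make_conflict_locus(params: SimulationParams) -> ConflictLocusTruth:
    """Build the TE/gene pair with a captured, mirrored, substituted segment.

    TE layout: [captured-segment mirror | extra 5' UTR | ORF1+ORF2 |
    3'-UTR upstream flank | captured segment | downstream flank]. The gene
    carries the ancestral (gene-allele) copy of the segment; the TE carries
    the derived alleles at the planted diagnostic sites, identically in both
    UTR copies.
    """
    rng = _stage_rng(params, _STAGE_LOCUS)
    L = params.captured_length
    gene_seq = _random_seq(rng, params.gene_length)
    g0 = params.capture_offset_gene
    captured_gene = gene_seq[g0 : g0 + L]

    # plant diagnostic substitutions into the TE's copy of the segment
    site_offsets = np.sort(rng.choice(L, size=params.n_diagnostic_sites, replace=False))
    te_segment = list(captured_gene)
    sites: list[DiagnosticSite] = []
    utr5_len = L + params.utr5_extra
    te3_start = utr5_len + params.orf_length + params.utr3_flank_up
    for off in site_offsets:
        gene_allele = captured_gene[off]
        te_allele = _substitute(rng, gene_allele)
        te_segment[off] = te_allele
        sites.append(
            DiagnosticSite(
                gene_pos=g0 + int(off),
                te_pos=te3_start + int(off),
                gene_allele=gene_allele,
                te_allele=te_allele,
            )
        )
    te_segment = "".join(te_segment)

    te_seq = (
        te_segment  # 5'-UTR mirror of the captured segment
        + _random_seq(rng, params.utr5_extra)
        + _random_seq(rng, params.orf_length)
        + _random_seq(rng, params.utr3_flank_up)
        + te_segment
        + _random_seq(rng, params.utr3_flank_down)
    )
    te_len = len(te_seq)

    # keep the 10-nt overlap partner (at p + 9) inside the captured region
    cleavage = np.sort(
        rng.choice(L - 10, size=params.n_cleavage_sites, replace=False)
    )
    cleavage_positions = [g0 + int(c) for c in cleavage]

    return ConflictLocusTruth(
        te_sequence=SequenceRecord(id="te", sequence=te_seq),
        gene_sequence=SequenceRecord(id="gene", sequence=gene_seq),
        te_orf_interval=GenomicInterval("te", utr5_len, utr5_len + params.orf_length),
        te_utr3_interval=GenomicInterval("te", utr5_len + params.orf_length, te_len),
        te_utr5_interval=GenomicInterval("te", 0, utr5_len),
        captured_interval_gene=GenomicInterval("gene", g0, g0 + L),
        captured_interval_te3=GenomicInterval("te", te3_start, te3_start + L),
        captured_interval_te5=GenomicInterval("te", 0, L),
        diagnostic_sites=sites,
        n_te_copies=params.n_te_copies,
        truncation_fraction=params.truncation_fraction,
        cleavage_positions=cleavage_positions,
    )


# ---------------------------------------------------------------------------
# Small RNA


@dataclass
class SmallRnaSim:
    reads: list[AlignedRead]
    n_pingpong_pairs: int
    n_phased_reads: int
    n_background_reads: int


def _read_sequence(
    rng: np.random.Generator, ref_seq: str, start: int, end: int, error_rate: float
) -> str:
    seq = list(ref_seq[start:end])
    if error_rate > 0:
        errors = np.nonzero(rng.random(len(seq)) < error_rate)[0]
        for i in errors:
            seq[i] = _substitute(rng, seq[i])
    return "".join(seq)


def simulate_small_rna(truth: ConflictLocusTruth, params: SimulationParams) -> SmallRnaSim:
    """piRNA library on the TE reference with planted signature structure.

    Reads are a mixture of ping-pong pairs (sense/antisense with exact 10-nt
    5':5' overlap), phased same-strand head-to-tail trails, and uniform
    background. Lengths are uniform in the configured range; sequences are
    copied from the TE haplotype with per-base substitution errors and stored
    in reference orientation.
    """
    rng = _stage_rng(params, _STAGE_SMALLRNA)
    te = truth.te_sequence.sequence
    te_len = len(te)
    lo, hi = params.pirna_length_range
    reads: list[AlignedRead] = []
    counter = 0

    def emit(start: int, end: int, strand: str) -> None:
        nonlocal counter
        counter += 1
        reads.append(
            AlignedRead(
                read_id=f"sr{counter}",
                interval=GenomicInterval("te", start, end, strand),
                sequence=_read_sequence(rng, te, start, end, params.error_rate),
            )
        )

    def rand_len() -> int:
        return int(rng.integers(lo, hi + 1))

    n_pp_reads = int(round(params.n_reads * params.pingpong_pair_fraction / 2)) * 2
    n_pairs = n_pp_reads // 2
    n_phased = int(round(params.n_reads * params.phased_fraction))
    n_background = max(params.n_reads - n_pp_reads - n_phased, 0)

    # ping-pong pairs: sense 5' at x, antisense 5' at x + 9
    for _ in range(n_pairs):
        x = int(rng.integers(hi, te_len - hi - 10))
        ls, la = rand_len(), rand_len()
        emit(x, x + ls, "+")
        emit(x + 10 - la, x + 10, "-")

    # phased trails: same-strand runs with 3'->5' distance exactly 1
    emitted_phased = 0
    while emitted_phased < n_phased:
        strand = "-" if rng.random() < params.antisense_fraction else "+"
        trail = 1 + rng.geometric(1.0 / params.mean_trail_length)
        trail = int(min(trail, n_phased - emitted_phased, 50))
        if strand == "+":
            pos = int(rng.integers(0, te_len - hi * (trail + 1)))
            for _ in range(trail):
                ln = rand_len()
                if pos + ln > te_len:
                    break
                emit(pos, pos + ln, "+")
                emitted_phased += 1
                pos += ln
        else:
            pos = int(rng.integers(hi * (trail + 1), te_len - 1))  # 5' end coordinate
            for _ in range(trail):
                ln = rand_len()
                if pos - ln + 1 < 0:
                    break
                emit(pos - ln + 1, pos + 1, "-")
                emitted_phased += 1
                pos -= ln

    # uniform background
    for _ in range(n_background):
        ln = rand_len()
        start = int(rng.integers(0, te_len - ln))
        strand = "-" if rng.random() < params.antisense_fraction else "+"
        emit(start, start + ln, strand)

    return SmallRnaSim(
        reads=reads,
        n_pingpong_pairs=n_pairs,
        n_phased_reads=emitted_phased,
        n_background_reads=n_background,
    )


# ---------------------------------------------------------------------------
# Degradome


@dataclass
class DegradomeSim:
    degradome_reads: list[AlignedRead]
    pirna_reads: list[AlignedRead]
    cleavage_positions: list[int]


def simulate_degradome(truth: ConflictLocusTruth, params: SimulationParams) -> DegradomeSim:
    """Degradome fragments and partner antisense piRNAs on the gene transcript.

    Every planted cleavage position p receives >= 1 plus-strand degradome
    read with 5' end exactly at p and a pile of antisense piRNAs with 5' end
    at p + 9 (the 10-nt overlap partner). Decoy degradome reads and sparse
    background piRNAs are placed uniformly over the captured region.
    """
    rng = _stage_rng(params, _STAGE_DEGRADOME)
    gene = truth.gene_sequence.sequence
    gene_len = len(gene)
    region = truth.captured_interval_gene
    lo, hi = params.pirna_length_range
    degradome: list[AlignedRead] = []
    pirnas: list[AlignedRead] = []

    def emit_degradome(p: int, tag: str) -> None:
        ln = int(rng.integers(20, 31))
        end = min(p + ln, gene_len)
        degradome.append(
            AlignedRead(
                read_id=f"deg_{tag}_{len(degradome)}",
                interval=GenomicInterval("gene", p, end, "+"),
                sequence=_read_sequence(rng, gene, p, end, params.error_rate),
            )
        )

    def emit_pirna(five_prime: int, tag: str) -> None:
        ln = int(rng.integers(lo, hi + 1))
        start = max(five_prime - ln + 1, 0)
        pirnas.append(
            AlignedRead(
                read_id=f"pi_{tag}_{len(pirnas)}",
                interval=GenomicInterval("gene", start, five_prime + 1, "-"),
                sequence=_read_sequence(rng, gene, start, five_prime + 1, params.error_rate),
            )
        )

    for p in truth.cleavage_positions:
        for _ in range(max(1, rng.poisson(params.degradome_depth))):
            emit_degradome(p, "site")
        for _ in range(max(1, rng.poisson(params.pirnas_per_cleavage))):
            emit_pirna(p + 9, "site")

    cleavage_set = set(truth.cleavage_positions)
    for _ in range(params.n_decoy_degradome):
        p = int(rng.integers(region.start, region.end - 31))
        if p in cleavage_set:
            continue
        emit_degradome(p, "decoy")
    for _ in range(params.n_background_pirnas):
        p = int(rng.integers(region.start + lo, region.end))
        emit_pirna(p, "bg")

    return DegradomeSim(
        degradome_reads=degradome,
        pirna_reads=pirnas,
        cleavage_positions=list(truth.cleavage_positions),
    )


# ---------------------------------------------------------------------------
# Genomic coverage


@dataclass
class CoverageSim:
    track: CoverageTrack
    genome_background_median: float
    n_truncated: int
    realized_truncation_fraction: float


def simulate_genomic_coverage(truth: ConflictLocusTruth, params: SimulationParams) -> CoverageSim:
    """Poisson read depth over the TE from a full-length/truncated copy mixture.

    Each of the n TE copies contributes per-haploid depth over the ORFs and
    3' UTR; with probability 1 - f it also contributes over the 5' UTR.
    Reads arising from the duplicated captured segment are ambiguous between
    its two reference copies and are split evenly, so both copies' expected
    depth is n * depth * (2 - f_realized) / 2. The genome background median
    equals the per-haploid depth.
    """
    rng = _stage_rng(params, _STAGE_COVERAGE)
    te_len = len(truth.te_sequence)
    n = params.n_te_copies
    depth = params.read_depth
    if n == 0:
        return CoverageSim(
            track=CoverageTrack(ref="te", values=np.zeros(te_len)),
            genome_background_median=depth,
            n_truncated=0,
            realized_truncation_fraction=0.0,
        )
    n_truncated = int(rng.binomial(n, params.truncation_fraction))
    f_real = n_truncated / n
    n_full = n - n_truncated

    mean = np.full(te_len, n * depth)
    # 5' UTR present only in full-length copies
    u5 = truth.te_utr5_interval
    mean[u5.start : u5.end] = n_full * depth
    # duplicated captured segment: reads from both UTR instances split evenly
    dup_mean = n * depth * (2 - f_real) / 2.0
    for iv in (truth.captured_interval_te3, truth.captured_interval_te5):
        mean[iv.start : iv.end] = dup_mean

    values = rng.poisson(mean).astype(float)
    return CoverageSim(
        track=CoverageTrack(ref="te", values=values),
        genome_background_median=depth,
        n_truncated=n_truncated,
        realized_truncation_fraction=f_real,
    )


# ---------------------------------------------------------------------------
# Knockdown counts


@dataclass
class CountsSim:
    control: CountMatrix
    knockdowns: list[CountMatrix]
    gene_means: "np.ndarray"
    planted_fold_changes: dict
    size_factors: "np.ndarray"  # control first, then one per knockdown


def simulate_counts(params: SimulationParams) -> CountsSim:
    """Negative-binomial count matrices for a control and k knockdowns.

    Per-gene baseline means are log-normal; planted fold changes multiply a
    gene's mean in every knockdown; optional per-library size factors scale
    whole samples. Counts are Gamma-Poisson with the configured dispersion.
    """
    import pandas as pd

    rng = _stage_rng(params, _STAGE_COUNTS)
    G, K = params.n_genes, params.n_knockdowns
    genes = [f"g{i + 1:05d}" for i in range(G)]
    gene_means = rng.lognormal(mean=4.0, sigma=1.5, size=G)
    fc = np.ones(G)
    for gene, mult in params.planted_fold_changes.items():
        if gene not in genes:
            raise ValueError(f"unknown gene {gene!r} in planted_fold_changes")
        fc[genes.index(gene)] = mult
    sf = np.asarray(
        params.library_size_factors
        if params.library_size_factors is not None
        else np.ones(K + 1),
        dtype=float,
    )
    if len(sf) != K + 1:
        raise ValueError("need one size factor for the control plus one per knockdown")

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        if params.nb_dispersion <= 0:
            return rng.poisson(mu)
        shape = 1.0 / params.nb_dispersion
        lam = rng.gamma(shape, mu * params.nb_dispersion)
        return rng.poisson(lam)

    control = CountMatrix(
        counts=pd.DataFrame({"control": nb_draw(gene_means * sf[0])}, index=genes)
    )
    knockdowns = [
        CountMatrix(
            counts=pd.DataFrame(
                {f"kd{j + 1}": nb_draw(gene_means * fc * sf[j + 1])}, index=genes
            )
        )
        for j in range(K)
    ]
    return CountsSim(
        control=control,
        knockdowns=knockdowns,
        gene_means=gene_means,
        planted_fold_changes=dict(params.planted_fold_changes),
        size_factors=sf,
    )


# ---------------------------------------------------------------------------
# 3-taxon alignment


@dataclass
class TripletSim:
    ingroup1: SequenceRecord
    ingroup2: SequenceRecord
    outgroup: SequenceRecord
    te_sequence: SequenceRecord
    m1: int
    m2: int
    m1_sites: list[int]
    m2_sites: list[int]
    n_pre_capture: int


def simulate_triplet(params: SimulationParams) -> TripletSim:
    """Gapless 3-way alignment with planted lineage-specific substitutions.

    Starting from a random ancestor (which the outgroup retains), Poisson
    numbers of substitutions are placed on the two ingroup branches at
    disjoint sites, so the planted counts are recovered exactly by
    polarized counting. A TE capture is planted along the ingroup-1 branch
    after a fraction ``capture_fraction`` of its substitutions: the TE
    sequence carries the derived allele at the pre-capture sites and the
    ancestral allele elsewhere.
    """
    rng = _stage_rng(params, _STAGE_TRIPLET)
    L = params.triplet_length
    r1, r2 = params.lineage_rates
    ancestor = _random_seq(rng, L)
    m1 = int(min(rng.poisson(r1 * L), L // 2))
    m2 = int(min(rng.poisson(r2 * L), L - m1))
    all_sites = rng.choice(L, size=m1 + m2, replace=False)
    m1_sites = sorted(int(s) for s in all_sites[:m1])
    m2_sites = sorted(int(s) for s in all_sites[m1:])

    seq1 = list(ancestor)
    subs1: dict[int, str] = {}
    for s in m1_sites:
        subs1[s] = _substitute(rng, ancestor[s])
        seq1[s] = subs1[s]
    seq2 = list(ancestor)
    for s in m2_sites:
        seq2[s] = _substitute(rng, ancestor[s])

    # capture: the TE branched off ingroup-1 after a fraction q of its
    # substitutions had occurred (in random order)
    n_pre = int(round(params.capture_fraction * m1))
    order = rng.permutation(m1_sites) if m1 else np.array([], dtype=int)
    te = list(ancestor)
    for s in order[:n_pre]:
        te[int(s)] = subs1[int(s)]

    return TripletSim(
        ingroup1=SequenceRecord(id="ingroup1", sequence="".join(seq1)),
        ingroup2=SequenceRecord(id="ingroup2", sequence="".join(seq2)),
        outgroup=SequenceRecord(id="outgroup", sequence=ancestor),
        te_sequence=SequenceRecord(id="te_capture", sequence="".join(te)),
        m1=m1,
        m2=m2,
        m1_sites=m1_sites,
        m2_sites=m2_sites,
        n_pre_capture=n_pre,
    )


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
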