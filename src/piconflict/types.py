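"""Core domain types shared by every stage of the pipeline.

Coordinate conventions
----------------------
All intervals are 0-based, half-open ``[start, end)``. Human-facing reports
(CLI output, tables) convert to 1-based inclusive at the edge.

For a read on the plus strand the 5' end is ``start`` and the 3' end is
``end - 1``. For a read on the minus strand the 5' end is ``end - 1`` and the
3' end is ``start``. Every small-RNA signature statistic in the package relies
on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = frozenset("ACGT")
ALPHABET = frozenset("ACGTN")
STRANDS = ("+", "-")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (upper-case, over {A,C,G,T,N})."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for record {self.id!r} is empty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named reference."""

    ref: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.ref!r}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class AlignedRead:
    """One read placement on a reference.

    ``sequence``, when present, is stored in *reference orientation* (the
    plus-strand bases the read aligns to), so ``sequence[i]`` is the read's
    base at reference position ``interval.start + i`` regardless of strand.
    """

    read_id: str
    interval: GenomicInterval
    sequence: Optional[str] = None
    n_mismatches: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.interval.length:
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= interval length {self.interval.length}"
            )

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def five_prime(self) -> int:
        """5' end position (strand aware)."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def three_prime(self) -> int:
        """3' end position (strand aware)."""
        if self.strand == "+":
            return self.interval.end - 1
        return self.interval.start

    def base_at(self, pos: int) -> Optional[str]:
        """Read base (reference orientation) at reference position ``pos``."""
        if self.sequence is None or not self.interval.contains(pos):
            return None
        return self.sequence[pos - self.interval.start]


@dataclass
class CoverageTrack:
    """Per-base read depth over one reference sequence."""

    ref: str
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.normalization not in ("raw", "RPM", "orf_relative"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CountMatrix:
    """Gene x sample raw (or normalized) count matrix."""

    counts: pd.DataFrame
    size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be strictly positive")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class DiagnosticSite:
    """An aligned position where the TE and gene carry different nucleotides.

    Positions are 0-based ungapped coordinates in each sequence's own frame.
    """

    gene_pos: int
    te_pos: int
    gene_allele: str
    te_allele: str

    def __post_init__(self) -> None:
        for allele in (self.gene_allele, self.te_allele):
            if allele not in NUCLEOTIDES:
                raise ValueError(f"allele {allele!r} not in A/C/G/T")
        if self.gene_allele == self.te_allele:
            raise ValueError("diagnostic site requires gene_allele != te_allele")


@dataclass
class AlleleCounts:
    """Per-incidence allele-assignment tallies over diagnostic sites."""

    n_te: int = 0
    n_gene: int = 0
    n_other: int = 0
    n_skipped_reads: int = 0

    @property
    def total(self) -> int:
        return self.n_te + self.n_gene + self.n_other

    def percentages(self, decimals: int = 1) -> dict[str, float]:
        """Percentages of each class among all counted bases."""
        if self.total == 0:
            raise ValueError("no diagnostic bases counted")
        return {
            "te": round(100.0 * self.n_te / self.total, decimals),
            "gene": round(100.0 * self.n_gene / self.total, decimals),
            "other": round(100.0 * self.n_other / self.total, decimals),
        }


@dataclass
class SignatureProfile:
    """A distance histogram plus the z-score of its focal distance.

    ``kind`` is ``pingpong`` (5':5' overlap lengths, focal 10) or ``phasing``
    (3'->5' distances, focal 1). ``z`` is the focal count standardized against
    the remaining (background) distances; ``z_defined`` is False when the
    background variance vanishes.
    """

    kind: str
    distances: np.ndarray
    counts: np.ndarray
    focal_distance: int
    z: float
    z_defined: bool

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "focal_distance": int(self.focal_distance),
            "z": float(self.z) if self.z_defined else None,
            "z_defined": self.z_defined,
            "histogram": {int(d): int(c) for d, c in zip(self.distances, self.counts)},
        }


@dataclass(frozen=True)
class OverlapCall:
    """A degradome cleavage position supported by a 10-nt piRNA overlap."""

    position: int
    n_degradome: int
    n_pirnas: int

    def __post_init__(self) -> None:
        if self.n_degradome < 1 or self.n_pirnas < 1:
            raise ValueError("a reported call requires >=1 read of each kind")


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    B: int
    k: int
    p: float
    seed: int
    paper_style: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.B):
            raise ValueError("k must lie in [0, B]")


@dataclass(frozen=True)
class CopyNumberResult:
    med_te: float
    med_genome: float
    copy_number: float


@dataclass(frozen=True)
class TruncationResult:
    """Relative coverage r of the duplicated segment and inferred truncation f."""

    r: float
    f: float
    clamped: bool = False


@dataclass
class RateTestResult:
    m1: int
    m2: int
    chi2: float
    p: float
    df: int = 1
    m1_sites: Sequence[int] = field(default_factory=list)
    m2_sites: Sequence[int] = field(default_factory=list)
    n_excluded_columns: int = 0


@dataclass(frozen=True)
class TimingCounts:
    """How TE alleles split the ingroup-1-specific substitution sites."""

    n_te_matches_ingroup2: int
    n_te_matches_ingroup1: int
    n_other: int
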