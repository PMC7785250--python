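"""Read-depth TE copy number and the 5'-UTR truncation mixture model.

Copy number is the ratio of the median nonzero per-base coverage over the TE
CDS (ORF1 + ORF2) to the strain's median coverage over uniquely mappable
genome positions (supplied as a precomputed scalar).

The TE carries the captured gene segment twice (3' UTR and mirrored 5' UTR);
reads from that segment are ambiguous between the two reference copies and
are modelled as split evenly. If a fraction f of TE copies lack the 5' UTR,
the expected coverage of the duplicated segment relative to a 3'-UTR-only
flank is r(f) = (2 - f) / 2 — at most a 50% reduction when every copy is
truncated — which inverts to f = 2(1 - r).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .types import CopyNumberResult, CoverageTrack, GenomicInterval, TruncationResult

logger = logging.getLogger("piconflict")


def _interval_union_positions(
    track: CoverageTrack, intervals: Iterable[GenomicInterval]
) -> np.ndarray:
    mask = np.zeros(len(track.values), dtype=bool)
    any_iv = False
    for iv in intervals:
        any_iv = True
        if iv.end > len(track.values):
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) outside track of length "
                f"{len(track.values)}"
            )
        mask[iv.start : iv.end] = True
    if not any_iv:
        raise ValueError("empty interval list")
    return track.values[mask]


def median_nonzero_coverage(
    track: CoverageTrack, intervals: Sequence[GenomicInterval]
) -> float:
    """Median depth over the interval union, excluding zero-coverage positions."""
    values = _interval_union_positions(track, intervals)
    nonzero = values[values > 0]
    if len(nonzero) == 0:
        logger.warning("median_nonzero_coverage: no covered positions; returning 0")
        return 0.0
    return float(np.median(nonzero))


def estimate_copy_number(
    te_track: CoverageTrack,
    orf_intervals: Sequence[GenomicInterval],
    genome_median: float,
) -> CopyNumberResult:
    """Copy number C = median nonzero CDS coverage / genome-wide median."""
    if genome_median <= 0:
        raise ValueError(f"genome median must be > 0, got {genome_median}")
    med_te = median_nonzero_coverage(te_track, orf_intervals)
    return CopyNumberResult(
        med_te=med_te,
        med_genome=float(genome_median),
        copy_number=med_te / genome_median,
    )


def region_relative_coverage(
    te_track: CoverageTrack,
    region: GenomicInterval,
    orf_intervals: Sequence[GenomicInterval],
    window: int | None = None,
) -> float | np.ndarray:
    """Mean coverage of ``region`` divided by the median nonzero ORF coverage.

    With ``window`` set, returns one ORF-normalized mean per non-overlapping
    window of that many bases instead of a single scalar.
    """
    orf_median = median_nonzero_coverage(te_track, orf_intervals)
    if orf_median == 0:
        raise ValueError("ORF coverage is zero; cannot normalize")
    values = _interval_union_positions(te_track, [region])
    if window is None:
        return float(values.mean() / orf_median)
    n_windows = len(values) // window
    if n_windows == 0:
        raise ValueError(f"region shorter than one {window}-bp window")
    trimmed = values[: n_windows * window].reshape(n_windows, window)
    return trimmed.mean(axis=1) / orf_median


def truncation_expected_ratio(f: float) -> float:
    """Expected duplicated-segment : 3'-only-flank coverage ratio, (2 - f)/2."""
    if not 0 <= f <= 1:
        raise ValueError(f"truncation fraction must lie in [0, 1], got {f}")
    return (2.0 - f) / 2.0


def truncation_fraction_estimate(r: float) -> TruncationResult:
    """Invert the mixture model: f = 2(1 - r), clamped to [0, 1]."""
    if r <= 0:
        raise ValueError(f"relative coverage must be > 0, got {r}")
    raw = 2.0 * (1.0 - r)
    clamped = not (0.0 <= raw <= 1.0)
    if clamped:
        logger.warning(
            "truncation_fraction_estimate: raw f = %.3f outside [0, 1]; clamped", raw
        )
    return TruncationResult(r=float(r), f=float(np.clip(raw, 0.0, 1.0)), clamped=clamped)
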