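"""Small-RNA signature statistics: length filter, stranded coverage,
ping-pong 10-nt 5':5' overlap z-score, and phased-trail 3'->5' distance
z-score.

Ping-pong amplification leaves sense/antisense piRNA pairs whose 5' ends
overlap by exactly 10 nt; phased (Zucchini) processing leaves same-strand
piRNAs laid head-to-tail, so the 5' end of one read sits directly after the
3' end of the previous one (distance 1). Both signatures are scored as the
z-score of the focal distance count against the remaining distances of the
histogram.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Optional, Sequence

import numpy as np

from .types import AlignedRead, CoverageTrack, SignatureProfile


def filter_pirna_lengths(
    reads: Sequence[AlignedRead], min_len: int = 23, max_len: int = 30
) -> list[AlignedRead]:
    """Keep reads whose length is consistent with piRNAs (default 23-30 nt)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= r.length <= max_len]


def stranded_coverage(
    reads: Sequence[AlignedRead],
    ref_length: int,
    normalize: str = "raw",
    library_total: Optional[int] = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Per-base coverage split by strand; optionally reads-per-million scaled."""
    if normalize not in ("raw", "RPM"):
        raise ValueError(f"normalize must be 'raw' or 'RPM', got {normalize!r}")
    if normalize == "RPM" and not (library_total and library_total > 0):
        raise ValueError("RPM normalization requires library_total > 0")
    plus = np.zeros(ref_length)
    minus = np.zeros(ref_length)
    ref = reads[0].interval.ref if reads else "ref"
    for r in reads:
        if r.interval.end > ref_length:
            raise ValueError(
                f"read {r.read_id!r} extends to {r.interval.end} beyond "
                f"reference length {ref_length}"
            )
        track = plus if r.strand == "+" else minus
        track[r.interval.start : r.interval.end] += 1
    if normalize == "RPM":
        scale = 1e6 / library_total
        plus *= scale
        minus *= scale
    return (
        CoverageTrack(ref=ref, values=plus, normalization=normalize),
        CoverageTrack(ref=ref, values=minus, normalization=normalize),
    )


def _z_against_background(counts: np.ndarray, focal_idx: int) -> tuple[float, bool]:
    background = np.delete(counts, focal_idx)
    if len(background) < 2:
        return float("nan"), False
    sd = background.std(ddof=1)
    if sd == 0:
        return float("nan"), False
    return float((counts[focal_idx] - background.mean()) / sd), True


def _five_prime_counts_by_ref(reads: Sequence[AlignedRead], strand: str) -> dict[str, Counter]:
    out: dict[str, Counter] = defaultdict(Counter)
    for r in reads:
        if r.strand == strand:
            out[r.interval.ref][r.five_prime] += 1
    return out


def pingpong_signature(
    reads: Sequence[AlignedRead],
    max_overlap: int = 30,
    focal_distance: int = 10,
    collapse_duplicates: bool = False,
) -> SignatureProfile:
    """Histogram of sense:antisense 5':5' overlap lengths and its z10.

    For every (plus read, minus read) pair on the same reference the overlap
    is ``d = minus_5p - plus_5p + 1``; ``c_d`` counts pairs with
    ``1 <= d <= max_overlap``. By default every qualifying read pair counts;
    ``collapse_duplicates`` counts each distinct (plus 5' position, minus 5'
    position) pair once.
    """
    plus_by_ref = _five_prime_counts_by_ref(reads, "+")
    minus_by_ref = _five_prime_counts_by_ref(reads, "-")
    counts = np.zeros(max_overlap, dtype=np.int64)
    for ref, minus_counter in minus_by_ref.items():
        plus_counter = plus_by_ref.get(ref)
        if not plus_counter:
            continue
        for minus_pos, n_minus in minus_counter.items():
            for d in range(1, max_overlap + 1):
                n_plus = plus_counter.get(minus_pos - d + 1, 0)
                if n_plus:
                    counts[d - 1] += 1 if collapse_duplicates else n_minus * n_plus
    z, defined = _z_against_background(counts, focal_distance - 1)
    return SignatureProfile(
        kind="pingpong",
        distances=np.arange(1, max_overlap + 1),
        counts=counts,
        focal_distance=focal_distance,
        z=z,
        z_defined=defined,
    )


def phasing_signature(
    reads: Sequence[AlignedRead],
    max_distance: int = 51,
    focal_distance: int = 1,
) -> SignatureProfile:
    """Histogram of same-strand 3'->5' distances and its Z1.

    Distances run in the direction of transcription on each strand: for an
    ordered same-strand pair, ``distance = next_5p - prev_3p`` on the plus
    strand and ``prev_3p - next_5p`` on the minus strand, so immediate
    head-to-tail adjacency gives 1. Computed per strand and summed.
    """
    counts = np.zeros(max_distance, dtype=np.int64)
    for strand, sign in (("+", +1), ("-", -1)):
        three_by_ref: dict[str, Counter] = defaultdict(Counter)
        five_by_ref: dict[str, Counter] = defaultdict(Counter)
        for r in reads:
            if r.strand == strand:
                three_by_ref[r.interval.ref][r.three_prime] += 1
                five_by_ref[r.interval.ref][r.five_prime] += 1
        for ref, three_counter in three_by_ref.items():
            five_counter = five_by_ref.get(ref, Counter())
            for three_pos, n_three in three_counter.items():
                for d in range(1, max_distance + 1):
                    n_five = five_counter.get(three_pos + sign * d, 0)
                    if n_five:
                        counts[d - 1] += n_three * n_five
    z, defined = _z_against_background(counts, focal_distance - 1)
    return SignatureProfile(
        kind="phasing",
        distances=np.arange(1, max_distance + 1),
        counts=counts,
        focal_distance=focal_distance,
        z=z,
        z_defined=defined,
    )
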