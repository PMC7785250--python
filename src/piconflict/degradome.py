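"""Degradome cleavage-site detection and permutation tests.

A slicing Piwi protein cuts its target between the bases paired to guide
positions 10 and 11, so the 5' end of the resulting degradome fragment sits
exactly 10 nt inside the guide: a cleavage product 5' end at plus-strand
position d is diagnostic when an antisense piRNA has its 5' end at d + 9.

Two permutation tests ask whether observed cleavage positions are special:

* :func:`permutation_test_abundance` — are the piRNA abundances at the
  observed positions higher than at randomly chosen piRNA positions?
* :func:`permutation_test_overlap_count` — do more of the observed degradome
  positions carry the 10-nt overlap than random positions would?
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np

from .types import AlignedRead, GenomicInterval, OverlapCall, PermutationResult


def pirna_five_prime_counts(
    pirnas: Sequence[AlignedRead], region: GenomicInterval
) -> dict[int, int]:
    """Count antisense (minus-strand) piRNA 5' ends per position in region."""
    counts: Counter = Counter()
    for r in pirnas:
        if r.strand == "-" and region.contains(r.five_prime):
            counts[r.five_prime] += 1
    return dict(counts)


def call_overlaps(
    degradome_reads: Sequence[AlignedRead],
    antisense_pirnas: Sequence[AlignedRead],
    region: GenomicInterval,
) -> list[OverlapCall]:
    """Report degradome 5' positions with an exact 10-nt sense:antisense overlap.

    A call is made at plus-strand 5' position d iff at least one antisense
    piRNA has its 5' end at d + 9 (overlap length exactly 10).
    """
    pirna_counts = pirna_five_prime_counts(antisense_pirnas, region)
    degradome_counts: Counter = Counter()
    for r in degradome_reads:
        if r.strand == "+" and region.contains(r.five_prime):
            degradome_counts[r.five_prime] += 1
    calls = []
    for pos in sorted(degradome_counts):
        n_pirnas = pirna_counts.get(pos + 9, 0)
        if n_pirnas >= 1:
            calls.append(
                OverlapCall(
                    position=pos,
                    n_degradome=degradome_counts[pos],
                    n_pirnas=n_pirnas,
                )
            )
    return calls


def _p_value(k: int, B: int, paper_style: bool) -> float:
    # (k+1)/(B+1) avoids reporting p = 0; paper_style reports the plain k/B.
    return k / B if paper_style else (k + 1) / (B + 1)


def permutation_test_abundance(
    observed_positions: Sequence[int],
    pirna_5p_counts: Mapping[int, int],
    B: int = 1000,
    seed: int = 0,
    statistic: str = "dominance",
    paper_style: bool = False,
) -> PermutationResult:
    """Are the observed positions unusually piRNA-abundant?

    Each permutation samples ``len(observed_positions)`` distinct positions
    from the positions carrying at least one piRNA 5' end, and compares the
    sampled count vector to the observed one. With ``statistic='dominance'``
    (default) a permutation counts toward k when the sorted-descending sample
    vector is elementwise >= the sorted observed vector ("same or more piRNAs
    at each location"); ``statistic='sum'`` compares total piRNA counts.
    """
    if statistic not in ("dominance", "sum"):
        raise ValueError(f"unknown statistic {statistic!r}")
    candidates = np.array(sorted(p for p, c in pirna_5p_counts.items() if c > 0))
    n_obs = len(observed_positions)
    if n_obs == 0:
        raise ValueError("no observed positions")
    for p in observed_positions:
        if pirna_5p_counts.get(p, 0) < 1:
            raise ValueError(f"observed position {p} has no piRNA 5' ends")
    if len(candidates) < n_obs:
        raise ValueError(
            f"only {len(candidates)} candidate positions for {n_obs} observed"
        )
    counts_arr = np.array([pirna_5p_counts[p] for p in candidates])
    observed_sorted = np.sort([pirna_5p_counts[p] for p in observed_positions])[::-1]
    observed_stat = float(observed_sorted.sum())
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(B):
        idx = rng.choice(len(candidates), size=n_obs, replace=False)
        sample = counts_arr[idx]
        if statistic == "dominance":
            if np.all(np.sort(sample)[::-1] >= observed_sorted):
                k += 1
        else:
            if sample.sum() >= observed_stat:
                k += 1
    return PermutationResult(
        observed_statistic=observed_stat,
        B=B,
        k=k,
        p=_p_value(k, B, paper_style),
        seed=seed,
        paper_style=paper_style,
    )


def permutation_test_overlap_count(
    n_observed_locations: int,
    n_with_overlap: int,
    pirna_5p_counts: Mapping[int, int],
    region: GenomicInterval,
    B: int = 1000,
    seed: int = 0,
    paper_style: bool = False,
) -> PermutationResult:
    """Do more observed degradome positions carry the 10-nt overlap than chance?

    Each permutation samples ``n_observed_locations`` distinct positions
    uniformly from the region and counts how many have an antisense piRNA 5'
    end exactly 9 nt downstream; k counts permutations whose statistic is
    >= ``n_with_overlap``.
    """
    if n_with_overlap > n_observed_locations:
        raise ValueError("n_with_overlap cannot exceed n_observed_locations")
    positions = np.arange(region.start, region.end)
    if len(positions) < n_observed_locations:
        raise ValueError(
            f"region length {len(positions)} < {n_observed_locations} sampled positions"
        )
    has_overlap = np.array(
        [pirna_5p_counts.get(p + 9, 0) >= 1 for p in positions], dtype=bool
    )
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(B):
        idx = rng.choice(len(positions), size=n_observed_locations, replace=False)
        if int(has_overlap[idx].sum()) >= n_with_overlap:
            k += 1
    return PermutationResult(
        observed_statistic=float(n_with_overlap),
        B=B,
        k=k,
        p=_p_value(k, B, paper_style),
        seed=seed,
        paper_style=paper_style,
    )
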