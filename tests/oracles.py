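"""Independent brute-force oracles used by the test suite.

These enumerate all read pairs in O(n^2) and never share code with the
histogram implementations they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_pingpong_histogram(reads, max_overlap=30):
    """Count, for every (plus, minus) read pair on the same reference, the
    5':5' overlap d = minus_5p - plus_5p + 1, for 1 <= d <= max_overlap."""
    counts = np.zeros(max_overlap, dtype=int)
    for a in reads:
        if a.strand != "+":
            continue
        for b in reads:
            if b.strand != "-" or b.interval.ref != a.interval.ref:
                continue
            d = (b.interval.end - 1) - a.interval.start + 1
            if 1 <= d <= max_overlap:
                counts[d - 1] += 1
    return counts


def brute_force_phasing_histogram(reads, max_distance=51):
    """Count same-strand ordered-pair 3'->5' distances (adjacency = 1)."""
    counts = np.zeros(max_distance, dtype=int)
    for a in reads:
        for b in reads:
            if a is b or b.strand != a.strand or b.interval.ref != a.interval.ref:
                continue
            if a.strand == "+":
                d = b.interval.start - (a.interval.end - 1)
            else:
                d = a.interval.start - (b.interval.end - 1)
            if 1 <= d <= max_distance:
                counts[d - 1] += 1
    return counts
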