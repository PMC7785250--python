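"""Diagnostic-site extraction and allele-specific read assignment.

A TE that captured a segment of a host gene accumulates substitutions after
the capture; each aligned position where the TE and gene now differ is a
*diagnostic site*. A small-RNA read covering such a site can then be
attributed to the TE or the gene by the base it carries. Because the TE
additionally mirrors the captured 3'-UTR segment into its 5' UTR, positions
in the 3'-UTR copy have a deterministic image in the 5'-UTR copy
(:func:`mirror_coordinate`).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .types import AlignedRead, AlleleCounts, DiagnosticSite, GenomicInterval, NUCLEOTIDES, SequenceRecord

logger = logging.getLogger("piconflict")


def diagnostic_sites_from_alignment(te_aligned: str, gene_aligned: str) -> list[DiagnosticSite]:
    """Extract diagnostic sites from a gapped pairwise TE/gene alignment.

    A site is reported for every column where both characters are ungapped,
    unambiguous (A/C/G/T) and unequal. Per-sequence ungapped coordinates are
    tracked through the gaps. Columns containing N or IUPAC ambiguity codes
    in either sequence yield no site.
    """
    if len(te_aligned) != len(gene_aligned):
        raise ValueError(
            f"aligned lengths differ: {len(te_aligned)} vs {len(gene_aligned)}"
        )
    sites: list[DiagnosticSite] = []
    te_pos = gene_pos = 0
    for te_char, gene_char in zip(te_aligned.upper(), gene_aligned.upper()):
        te_gap = te_char == "-"
        gene_gap = gene_char == "-"
        if (
            not te_gap
            and not gene_gap
            and te_char in NUCLEOTIDES
            and gene_char in NUCLEOTIDES
            and te_char != gene_char
        ):
            sites.append(
                DiagnosticSite(
                    gene_pos=gene_pos,
                    te_pos=te_pos,
                    gene_allele=gene_char,
                    te_allele=te_char,
                )
            )
        if not te_gap:
            te_pos += 1
        if not gene_gap:
            gene_pos += 1
    return sites


def mirror_coordinate(p: int, captured_te3: GenomicInterval, utr5_offset: int) -> int:
    """Map a TE 3'-UTR position into the mirrored 5'-UTR copy.

    The 5'-UTR copy of the captured segment starts at ``utr5_offset`` and is
    character-identical to the 3'-UTR copy, so the map is the translation
    ``utr5_offset + (p - captured_te3.start)``; it is a bijection between the
    two copies.
    """
    if not captured_te3.contains(p):
        raise ValueError(
            f"position {p} outside captured interval "
            f"[{captured_te3.start}, {captured_te3.end})"
        )
    return utr5_offset + (p - captured_te3.start)


def inverse_mirror_coordinate(q: int, captured_te3: GenomicInterval, utr5_offset: int) -> int:
    """Inverse of :func:`mirror_coordinate` (5'-UTR copy -> 3'-UTR copy)."""
    p = captured_te3.start + (q - utr5_offset)
    if not captured_te3.contains(p):
        raise ValueError(f"position {q} outside the mirrored 5'-UTR copy")
    return p


def mask_intervals(seq: SequenceRecord, intervals: Iterable[GenomicInterval]) -> SequenceRecord:
    """Replace the bases in the union of ``intervals`` with N."""
    chars = list(seq.sequence)
    n = len(chars)
    for iv in intervals:
        if iv.end > n:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) outside sequence of length {n}"
            )
        for i in range(iv.start, iv.end):
            chars[i] = "N"
    return SequenceRecord(id=seq.id, sequence="".join(chars))


def assign_alleles(
    reads: Sequence[AlignedRead],
    sites: Sequence[DiagnosticSite],
    frame: str = "te",
) -> AlleleCounts:
    """Classify read bases at diagnostic sites as TE-, gene-, or other-matching.

    ``frame`` names the coordinate system the reads are aligned to (``te`` or
    ``gene``); site positions are taken in that frame. Counting is per
    (read, site) incidence: a read covering k sites contributes k bases.
    Reads without a stored sequence are skipped and tallied.
    """
    if frame not in ("te", "gene"):
        raise ValueError(f"frame must be 'te' or 'gene', got {frame!r}")
    positions = [(s.te_pos if frame == "te" else s.gene_pos, s) for s in sites]
    out = AlleleCounts()
    for read in reads:
        if read.sequence is None:
            out.n_skipped_reads += 1
            continue
        for pos, site in positions:
            base = read.base_at(pos)
            if base is None:
                continue
            if base == site.te_allele:
                out.n_te += 1
            elif base == site.gene_allele:
                out.n_gene += 1
            else:
                out.n_other += 1
    if out.n_skipped_reads:
        logger.info("assign_alleles: skipped %d reads without sequence", out.n_skipped_reads)
    return out


def summarize_allele_counts(counts: AlleleCounts, decimals: int = 1) -> dict:
    """Printable summary: raw tallies plus rounded percentages."""
    pct = counts.percentages(decimals=decimals)
    return {
        "n_te": counts.n_te,
        "n_gene": counts.n_gene,
        "n_other": counts.n_other,
        "total": counts.total,
        "pct_te": pct["te"],
        "pct_gene": pct["gene"],
        "pct_other": pct["other"],
    }
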