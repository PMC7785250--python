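"""Readers and writers for the plain-text formats the pipeline exchanges.

Alignments travel as a BED-like TSV dialect with columns
``ref  start  end  strand  [read_id  sequence  n_mismatches]`` (0-based
half-open coordinates, header optional). Count matrices are TSV with gene ids
in the first column. Coverage tracks are TSV with ``ref  pos  depth`` rows.
Writing then reading any of these reproduces the objects exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import AlignedRead, CountMatrix, CoverageTrack, GenomicInterval, SequenceRecord

logger = logging.getLogger("piconflict")

PathLike = Union[str, Path]

ALIGNMENT_COLUMNS = ("ref", "start", "end", "strand", "read_id", "sequence", "n_mismatches")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="[%(levelname)s] %(message)s",
    )


# ---------------------------------------------------------------------------
# FASTA


def _find_header_line(path: PathLike, record_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [record_id]:
                return i
    return 0


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    Sequences are upper-cased and U is mapped to T. An empty sequence or a
    record whose sequence contains characters outside A/C/G/T/N raises
    :class:`FormatError` naming the offending header line.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        try:
            records.append(SequenceRecord(id=rec.id, sequence=seq))
        except ValueError as exc:
            line = _find_header_line(path, rec.id)
            raise FormatError(f"{path}: line {line}: {exc}") from exc
    return records


def write_fasta(path: PathLike, records: Iterable[SequenceRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignment tables


def _parse_alignment_row(row_num: int, fields: Sequence[str]) -> AlignedRead:
    if len(fields) < 4:
        raise FormatError(f"row {row_num}: expected >=4 columns, got {len(fields)}")
    ref = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"row {row_num}: non-integer coordinates") from exc
    strand = fields[3]
    if strand not in ("+", "-"):
        raise FormatError(f"row {row_num}: unknown strand symbol {strand!r}")
    if start >= end:
        raise FormatError(
            f"row {row_num}: empty or inverted interval [{start}, {end})"
        )
    read_id = fields[4] if len(fields) > 4 and fields[4] not in ("", ".") else f"read{row_num}"
    sequence = fields[5] if len(fields) > 5 and fields[5] not in ("", ".") else None
    n_mm = None
    if len(fields) > 6 and fields[6] not in ("", "."):
        n_mm = int(fields[6])
    try:
        return AlignedRead(
            read_id=read_id,
            interval=GenomicInterval(ref=ref, start=start, end=end, strand=strand),
            sequence=sequence,
            n_mismatches=n_mm,
        )
    except ValueError as exc:
        raise FormatError(f"row {row_num}: {exc}") from exc


def read_alignment_table(path: PathLike) -> list[AlignedRead]:
    """Read a BED-like alignment TSV, preserving row order."""
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for row_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if row_num == 1 and fields[0] == "ref":
                continue  # optional header
            reads.append(_parse_alignment_row(row_num, fields))
    return reads


def write_alignment_table(path: PathLike, reads: Iterable[AlignedRead], header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                "\t".join(
                    [
                        r.interval.ref,
                        str(r.interval.start),
                        str(r.interval.end),
                        r.interval.strand,
                        r.read_id,
                        r.sequence if r.sequence is not None else ".",
                        str(r.n_mismatches) if r.n_mismatches is not None else ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Count matrices


def read_count_matrix(path: PathLike) -> CountMatrix:
    """Read a gene x sample TSV of raw counts (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate gene ids {dupes}")
    for sample in df.columns:
        col = pd.to_numeric(df[sample], errors="coerce")
        bad = df.index[col.isna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric count for gene {bad[0]!r}, sample {sample!r}"
            )
        neg = df.index[col < 0]
        if len(neg):
            raise FormatError(
                f"{path}: negative count for gene {neg[0]!r}, sample {sample!r}"
            )
        if not np.allclose(col, np.round(col)):
            frac = df.index[~np.isclose(col, np.round(col))]
            raise FormatError(
                f"{path}: non-integer count for gene {frac[0]!r}, sample {sample!r}"
            )
        df[sample] = col.astype(np.int64)
    return CountMatrix(counts=df)


def write_count_matrix(path: PathLike, matrix: CountMatrix) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Coverage tracks


def read_coverage_track(path: PathLike, normalization: str = "raw") -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", comment="#", names=["ref", "pos", "depth"], header=0)
    refs = df["ref"].unique()
    if len(refs) != 1:
        raise FormatError(f"{path}: expected a single reference, found {len(refs)}")
    length = int(df["pos"].max()) + 1
    values = np.zeros(length)
    values[df["pos"].to_numpy()] = df["depth"].to_numpy()
    return CoverageTrack(ref=str(refs[0]), values=values, normalization=normalization)


def write_coverage_track(path: PathLike, track: CoverageTrack) -> None:
    with open(path, "w") as fh:
        fh.write("ref\tpos\tdepth\n")
        for pos, depth in enumerate(track.values):
            fh.write(f"{track.ref}\t{pos}\t{depth:g}\n")


# ---------------------------------------------------------------------------
# Diagnostic site tables


def read_sites_table(path: PathLike):
    from .types import DiagnosticSite

    df = pd.read_csv(path, sep="\t")
    return [
        DiagnosticSite(
            gene_pos=int(r.gene_pos),
            te_pos=int(r.te_pos),
            gene_allele=str(r.gene_allele),
            te_allele=str(r.te_allele),
        )
        for r in df.itertuples()
    ]


def write_sites_table(path: PathLike, sites) -> None:
    with open(path, "w") as fh:
        fh.write("gene_pos\tte_pos\tgene_allele\tte_allele\n")
        for s in sites:
            fh.write(f"{s.gene_pos}\t{s.te_pos}\t{s.gene_allele}\t{s.te_allele}\n")


def load_config(path: PathLike) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
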