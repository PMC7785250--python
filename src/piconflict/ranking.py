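"""Knockdown expression analysis: size-factor normalization, fold changes,
and the genome-wide "fold change >= focal gene in every knockdown" ranking.

The ranking asks, for a focal gene up-regulated across a panel of k
knockdowns, how many other expressed genes show a fold change at least as
large in *every one* of the k experiments — a simple, test-free way to place
the focal gene's pattern of up-regulation on a genome-wide percentile scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CountMatrix

logger = logging.getLogger("piconflict")


@dataclass
class FoldChangeTable:
    """Per-gene, per-experiment fold changes over a common control.

    ``fc`` is genes x experiments; entries may be NaN where the targeted gene
    was excluded from its own knockdown. Only genes expressed in the control
    (nonzero control count) are retained; the dropped ids are recorded.
    """

    fc: pd.DataFrame
    pseudocount: float
    not_expressed: list[str]


@dataclass(frozen=True)
class RankResult:
    focal_gene: str
    n_expressed: int
    n_dominating: int

    @property
    def percentile(self) -> float:
        return self.n_dominating / self.n_expressed


def median_of_ratios_normalize(m: CountMatrix) -> CountMatrix:
    """DESeq2-style median-of-ratios size factors; returns normalized counts.

    s_j = median over genes with all-positive counts of count_gj / geomean_g;
    normalized_gj = count_gj / s_j.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in every sample")
    ref = counts[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    log_ratios = np.log(ref) - log_geomean[:, None]
    size_factors = np.exp(np.median(log_ratios, axis=0))
    normalized = pd.DataFrame(
        counts / size_factors, index=m.counts.index, columns=m.counts.columns
    )
    return CountMatrix(
        counts=normalized,
        size_factors=pd.Series(size_factors, index=m.counts.columns),
    )


def normalize_experiment(
    control: CountMatrix, knockdowns: Sequence[CountMatrix]
) -> tuple[CountMatrix, list[CountMatrix]]:
    """Jointly size-factor-normalize a control and its knockdown libraries.

    Size factors are only identifiable across libraries, so the matrices are
    column-concatenated, normalized together, and split back apart.
    """
    pieces = [control.counts] + [kd.counts for kd in knockdowns]
    genes = control.counts.index
    for i, piece in enumerate(pieces[1:]):
        if not piece.index.equals(genes):
            raise ValueError(f"knockdown {i} gene set differs from control")
    joint = median_of_ratios_normalize(CountMatrix(counts=pd.concat(pieces, axis=1)))
    boundaries = np.cumsum([p.shape[1] for p in pieces])
    cols = joint.counts.columns
    out = []
    start = 0
    for stop in boundaries:
        out.append(
            CountMatrix(
                counts=joint.counts[cols[start:stop]],
                size_factors=joint.size_factors[cols[start:stop]],
            )
        )
        start = stop
    return out[0], out[1:]


def fold_changes(
    control: CountMatrix,
    knockdowns: Sequence[CountMatrix],
    pseudocount: float = 0.5,
    experiment_names: Optional[Sequence[str]] = None,
    targeted_genes: Optional[Sequence[Optional[str]]] = None,
) -> FoldChangeTable:
    """FC_gj = (knockdown_gj + eps) / (control_g + eps) over expressed genes.

    Matrices must be normalized and share one gene set; multi-sample matrices
    are averaged per gene. ``targeted_genes`` (one per knockdown, or None)
    masks each knockdown's own target to NaN, excluding it from that
    experiment's comparison.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    genes = control.counts.index
    for i, kd in enumerate(knockdowns):
        if not kd.counts.index.equals(genes):
            raise ValueError(f"knockdown {i} gene set differs from control")
    if experiment_names is None:
        experiment_names = [f"kd{i + 1}" for i in range(len(knockdowns))]
    ctrl = control.counts.mean(axis=1)
    expressed = ctrl > 0
    not_expressed = list(genes[~expressed])
    if not_expressed:
        logger.info("fold_changes: %d genes with zero control expression excluded",
                    len(not_expressed))
    fc = pd.DataFrame(index=genes[expressed], columns=list(experiment_names), dtype=float)
    for name, kd in zip(experiment_names, knockdowns):
        kd_mean = kd.counts.mean(axis=1)[expressed]
        fc[name] = (kd_mean + pseudocount) / (ctrl[expressed] + pseudocount)
    if targeted_genes is not None:
        if len(targeted_genes) != len(knockdowns):
            raise ValueError("need one targeted gene (or None) per knockdown")
        for name, target in zip(experiment_names, targeted_genes):
            if target is not None and target in fc.index:
                fc.loc[target, name] = np.nan
    return FoldChangeTable(fc=fc, pseudocount=pseudocount, not_expressed=not_expressed)


def rank_across_knockdowns(
    fc_table: FoldChangeTable, focal_gene: str, include_focal: bool = False
) -> RankResult:
    """Count genes whose fold change >= the focal gene's in every experiment.

    A gene with a masked (NaN) entry is compared over its defined experiments
    only. The focal gene is excluded from its own dominating count unless
    ``include_focal``; the percentile denominator is the number of expressed
    genes.
    """
    fc = fc_table.fc
    if focal_gene not in fc.index:
        raise ValueError(f"focal gene {focal_gene!r} is not expressed")
    focal = fc.loc[focal_gene].to_numpy(dtype=float)
    if np.isnan(focal).any():
        raise ValueError("focal gene has masked fold changes")
    values = fc.to_numpy(dtype=float)
    geq = (values >= focal) | np.isnan(values)
    dominating = geq.all(axis=1)
    n_dominating = int(dominating.sum())
    if not include_focal:
        n_dominating -= int(dominating[fc.index.get_loc(focal_gene)])
    return RankResult(
        focal_gene=focal_gene,
        n_expressed=len(fc.index),
        n_dominating=n_dominating,
    )


def compare_groups_ranksum(
    values_group1: Sequence[float], values_group2: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Exact null distribution when both groups have n <= 8 and no ties;
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN (with a warning) when either vector is constant, where the
    correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("spearman: constant input vector; correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
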