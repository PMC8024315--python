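"""Scoring predicted networks against gold standards.

Directed-edge precision/recall/F1 inside an explicit gene universe,
TF-binding precision against peak intervals, target-assignment
fold-change enrichment, the nearest-TSS proximity baseline, and the
distal-assignment fraction it enables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io import EdgeList, GenomicInterval, ValidationError
from .networks import ConsensusNetwork

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeMetrics:
    predicted: int
    gold: int
    true_positives: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class EnrichmentCounts:
    """Counts for gene-level fold-change enrichment.

    n_pb: predicted genes that are also biased; n_p: predicted genes;
    n_b: biased genes; n: all genes.
    """

    n_pb: int
    n_p: int
    n_b: int
    n: int

    def __post_init__(self) -> None:
        if self.n_pb > min(self.n_p, self.n_b):
            raise ValidationError("n_pb cannot exceed min(n_p, n_b)")
        if self.n < max(self.n_p, self.n_b) or max(self.n_p, self.n_b) <= 0:
            raise ValidationError("require n >= max(n_p, n_b) > 0")


def edge_metrics(predicted: EdgeList, gold: EdgeList, universe: set[str]) -> EdgeMetrics:
    """Directed-edge precision, recall and F1 with both edge sets restricted
    to pairs whose endpoints are inside the gene universe."""
    if not universe:
        raise ValidationError("universe must be non-empty")
    pred = predicted.restricted(universe).edges
    gld = gold.restricted(universe).edges
    if not gld:
        raise ValidationError("gold standard empty after universe restriction")
    tp = len(pred & gld)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(gld)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EdgeMetrics(len(pred), len(gld), tp, precision, recall, f1)


def binding_precision(
    network: ConsensusNetwork, tf: str, peaks: Sequence[GenomicInterval]
) -> tuple[float, int, int]:
    """Fraction of the TF's distinct CRM elements overlapping any peak.

    Returns (fraction, overlapping, total)."""
    res = {
        (iv.chrom, iv.start, iv.end)
        for t in network
        if t.tf == tf
        for iv in t.crm
    }
    if not res:
        raise ValidationError(f"TF {tf!r} has no triplets in the network")
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    hit = sum(
        1
        for chrom, start, end in res
        if chrom in trees and trees[chrom].overlap(start, end)
    )
    return hit / len(res), hit, len(res)


def target_enrichment_fc(counts: EnrichmentCounts) -> float:
    """Fold change F = (n_pb/n_p) / (n_b/n); zero when no overlap."""
    if counts.n_p == 0 or counts.n_b == 0:
        raise ValidationError("n_p and n_b must be positive")
    if counts.n_pb == 0:
        return 0.0
    return (counts.n_pb / counts.n_p) / (counts.n_b / counts.n)


def human_biased_genes(
    expr_a: Mapping[str, np.ndarray],
    expr_b: Mapping[str, np.ndarray],
    p_cutoff: float = 0.05,
    equal_var: bool = False,
) -> set[str]:
    """Genes higher on average in group A with a two-sample t-test
    p <= cutoff (Welch by default)."""
    biased = set()
    for gene, a in expr_a.items():
        if gene not in expr_b:
            continue
        b = np.asarray(expr_b[gene], dtype=float)
        a = np.asarray(a, dtype=float)
        if a.mean() <= b.mean():
            continue
        _, p = stats.ttest_ind(a, b, equal_var=equal_var)
        if np.isfinite(p) and p <= p_cutoff:
            biased.add(gene)
    return biased


def nearest_tss_baseline(
    enhancers: Sequence[GenomicInterval],
    tss: Mapping[str, tuple[str, int]],
) -> dict[GenomicInterval, str]:
    """Assign each enhancer the gene whose TSS is closest to its midpoint.

    Distance ties break toward the lexicographically smaller gene id;
    enhancers on chromosomes without any TSS are left unassigned (logged).
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene, (chrom, pos) in tss.items():
        by_chrom.setdefault(chrom, []).append((pos, gene))
    assignments: dict[GenomicInterval, str] = {}
    for enh in enhancers:
        candidates = by_chrom.get(enh.chrom)
        if not candidates:
            log.warning("enhancer %s: no TSS on its chromosome", enh.region_string())
            continue
        mid = (enh.start + enh.end) / 2.0
        assignments[enh] = min(
            candidates, key=lambda item: (abs(item[0] - mid), item[1])
        )[1]
    return assignments


def distal_assignment_fraction(n_distal: int, n_total: int) -> float:
    """Fraction of predicted target assignments that are distal, i.e. not
    recoverable by the nearest-TSS rule."""
    if not (0 <= n_distal <= n_total) or n_total <= 0:
        raise ValidationError("require 0 <= n_distal <= n_total, n_total > 0")
    return n_distal / n_total
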