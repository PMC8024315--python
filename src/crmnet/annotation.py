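"""Annotating genetic variants and genomic elements against a network.

Subnetworks are extracted by target-gene sets, by SNPs falling inside
binarized CRM bases, or by genomic regions overlapping CRMs; a per-gene
z-score filter keeps only the strongest CRMs.  SNP enrichment is the
fold change of SNP density inside a region set over the genome-wide
density along a p-value threshold ladder; element overlap significance
comes from a length-preserving shuffle null; and allele-dependent motif
gain/loss rescans PWMs across windows covering the variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import (
    GenomeIndex,
    GenomicInterval,
    PWM,
    SnpRecord,
    ValidationError,
    merge_intervals,
)
from .netbuild import scan_scores
from .networks import ConsensusNetwork, Triplet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Subnetwork extraction (gene / SNP / region selectors)
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedSubnetwork:
    """Triplets retained by a selector, with per-triplet matches recorded."""

    network: ConsensusNetwork
    selector_kind: str  # "genes" | "snps" | "regions"
    matches: dict[tuple[str, str], list] = field(default_factory=dict)
    z_lambda: float | None = None

    def __len__(self) -> int:
        return len(self.network)

    def edges(self) -> set[tuple[str, str]]:
        return self.network.edges()


def _crm_trees(net: ConsensusNetwork) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in net:
        for iv in t.crm:
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, t.edge
            )
    return trees


def extract_subnetwork(
    net: ConsensusNetwork,
    genes: Sequence[str] | None = None,
    snps: Sequence[SnpRecord] | None = None,
    regions: Sequence[GenomicInterval] | None = None,
) -> AnnotatedSubnetwork:
    """Union-extract triplets matching a gene set (TG membership), SNP set
    (position inside a binarized CRM base) or region set (>= 1 bp CRM
    overlap).  Exactly one selector must be given; an empty result is valid.
    """
    selectors = [s is not None for s in (genes, snps, regions)]
    if sum(selectors) != 1:
        raise ValidationError("provide exactly one of genes / snps / regions")

    matches: dict[tuple[str, str], list] = {}
    if genes is not None:
        gene_set = set(genes)
        for t in net:
            if t.tg in gene_set:
                matches.setdefault(t.edge, []).append(t.tg)
    else:
        trees = _crm_trees(net)
        if snps is not None:
            for snp in snps:
                tree = trees.get(snp.chrom)
                if tree is None:
                    continue
                for hit in tree.at(snp.pos):
                    matches.setdefault(hit.data, []).append(snp)
        else:
            for region in regions:
                tree = trees.get(region.chrom)
                if tree is None:
                    continue
                for hit in tree.overlap(region.start, region.end):
                    matches.setdefault(hit.data, []).append(region)

    kept = [net[edge] for edge in sorted(matches)]
    kind = "genes" if genes is not None else ("snps" if snps is not None else "regions")
    return AnnotatedSubnetwork(ConsensusNetwork(kept, net.diagnostics), kind, matches)


def filter_by_zscore(sub: AnnotatedSubnetwork, z_lambda: float) -> AnnotatedSubnetwork:
    """Per target gene, z-score its CRM strengths (population sd) and drop
    those with z below ``z_lambda``.

    Genes with fewer than two CRMs or zero spread are kept untouched
    (z := 0 convention: no spread, nothing to rank).
    """
    if not np.isfinite(z_lambda):
        raise ValidationError("lambda must be finite")
    by_tg: dict[str, list[Triplet]] = {}
    for t in sub.network:
        by_tg.setdefault(t.tg, []).append(t)
    kept: list[Triplet] = []
    for tg, triplets in by_tg.items():
        scores = np.array([t.score for t in triplets])
        sd = scores.std()  # population sd
        if len(triplets) < 2 or sd == 0:
            kept.extend(triplets)
            continue
        z = (scores - scores.mean()) / sd
        kept.extend(t for t, zi in zip(triplets, z) if zi >= z_lambda)
    matches = {t.edge: sub.matches.get(t.edge, []) for t in kept}
    return AnnotatedSubnetwork(
        ConsensusNetwork(kept, sub.network.diagnostics),
        sub.selector_kind,
        matches,
        z_lambda=z_lambda,
    )


# ---------------------------------------------------------------------------
# SNP fold-change enrichment along a p-value ladder
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentCurve:
    thresholds: list[float]
    snps_total: list[int]  # P per threshold
    snps_in_regions: list[int]  # P_r per threshold
    region_length: int  # L_r
    genome_length: int  # L
    fold_changes: list[float | None]  # None where P = 0

    def at(self, threshold: float) -> float | None:
        return self.fold_changes[self.thresholds.index(threshold)]


DEFAULT_LADDER = [1.0] + [10.0 ** -k for k in range(1, 10)]


def snp_region_fc(
    snps: Sequence[SnpRecord],
    regions: Sequence[GenomicInterval],
    genome: GenomeIndex,
    ladder: Sequence[float] | None = None,
) -> EnrichmentCurve:
    """Fold change FC = (P_r / L_r) / (P / L) per p-value threshold.

    Each SNP's p-value is the minimum over its traits; regions are merged
    before length computation; FC is reported as missing where no SNP
    passes a threshold.
    """
    ladder = list(DEFAULT_LADDER if ladder is None else ladder)
    if any(b >= a for a, b in zip(ladder, ladder[1:])):
        raise ValidationError("threshold ladder must be strictly decreasing")
    merged = merge_intervals(regions)
    l_r = sum(len(iv) for iv in merged)
    if l_r == 0:
        raise ValidationError("region set has zero total length")
    l_genome = genome.total_length
    trees: dict[str, IntervalTree] = {}
    for iv in merged:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    pvals = np.array([s.min_pvalue for s in snps])
    inside = np.array(
        [s.chrom in trees and bool(trees[s.chrom].at(s.pos)) for s in snps]
    )
    totals, in_regions, fcs = [], [], []
    for threshold in ladder:
        mask = pvals <= threshold
        p_total = int(mask.sum())
        p_r = int((mask & inside).sum())
        totals.append(p_total)
        in_regions.append(p_r)
        if p_total == 0:
            fcs.append(None)
        else:
            fcs.append((p_r / l_r) / (p_total / l_genome))
    return EnrichmentCurve(ladder, totals, in_regions, l_r, l_genome, fcs)


def snp_top_trait(snp: SnpRecord) -> tuple[str, float]:
    """The trait with the smallest p-value; ties break lexicographically."""
    if not snp.pvalues:
        raise ValidationError(f"SNP {snp.rsid}: no trait p-values")
    trait = min(snp.pvalues, key=lambda t: (snp.pvalues[t], t))
    return trait, snp.pvalues[trait]


# ---------------------------------------------------------------------------
# Allele-dependent motif gain / loss
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifDiff:
    motif_id: str
    best_ref: float
    best_alt: float
    delta: float
    gained: bool
    lost: bool


def allele_motif_diff(
    sequence: str,
    offset: int,
    ref: str,
    alt: str,
    pwms: Sequence[PWM],
) -> dict[str, MotifDiff]:
    """Best both-strand motif score around a variant under each allele.

    Only windows covering the variant position are scored.  A motif is
    gained when only the alternate allele reaches the PWM threshold, lost
    when only the reference does.
    """
    if not (0 <= offset < len(sequence)):
        raise ValidationError("variant offset outside sequence")
    if sequence[offset].upper() != ref.upper():
        raise ValidationError(
            f"reference mismatch: sequence has {sequence[offset]!r} at offset "
            f"{offset}, expected {ref!r}"
        )
    alt_seq = sequence[:offset] + alt.upper() + sequence[offset + 1 :]
    out: dict[str, MotifDiff] = {}
    for pwm in pwms:
        w = pwm.width
        lo = max(0, offset - w + 1)
        hi = min(len(sequence), offset + w)
        window_ref = sequence[lo:hi]
        window_alt = alt_seq[lo:hi]
        best_ref = best_alt = -np.inf
        if len(window_ref) >= w:
            best_ref = float(scan_scores(window_ref, pwm).max())
            best_alt = float(scan_scores(window_alt, pwm).max())
        gained = best_alt >= pwm.threshold > best_ref
        lost = best_ref >= pwm.threshold > best_alt
        delta = best_alt - best_ref if np.isfinite(best_alt - best_ref) else 0.0
        out[pwm.id] = MotifDiff(pwm.id, best_ref, best_alt, float(delta), gained, lost)
    return out


# ---------------------------------------------------------------------------
# Empirical overlap p-value via length-preserving shuffles
# ---------------------------------------------------------------------------


def empirical_pvalue(exceedances: int, n_shuffles: int) -> float:
    """One-sided empirical p: the fraction of null draws at least as
    extreme as the observation."""
    if n_shuffles <= 0 or not (0 <= exceedances <= n_shuffles):
        raise ValidationError("require 0 <= exceedances <= n_shuffles > 0")
    return exceedances / n_shuffles


@dataclass
class OverlapNull:
    observed: int
    exceedance_ge: int  # shuffles with count >= observed
    exceedance_gt: int  # strict variant: shuffles with count > observed
    n_shuffles: int
    p_ge: float
    p_gt: float
    p_plus_one: float
    null_counts: np.ndarray


def empirical_overlap_pvalue(
    elements: Sequence[GenomicInterval],
    res: Sequence[GenomicInterval],
    genome: GenomeIndex,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> OverlapNull:
    """Shuffle-based significance of element/RE overlap.

    Each shuffle relocates every element uniformly on its own chromosome,
    preserving its length (overlaps among shuffled elements allowed); the
    statistic is the number of elements overlapping at least one RE by
    >= 1 bp.  Reported: p with the standard >= exceedance rule, the
    strict > variant, and the plus-one-corrected p.
    """
    if n_shuffles < 100:
        raise ValidationError("n_shuffles must be >= 100")
    for el in elements:
        if el.chrom not in genome or len(el) > genome[el.chrom]:
            raise ValidationError(
                f"element {el.region_string()} does not fit its chromosome"
            )
    trees: dict[str, IntervalTree] = {}
    for iv in res:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def count(starts: np.ndarray) -> int:
        hits = 0
        for el, start in zip(elements, starts):
            tree = trees.get(el.chrom)
            if tree is not None and tree.overlap(int(start), int(start) + len(el)):
                hits += 1
        return hits

    observed = count(np.array([el.start for el in elements]))
    rng = np.random.default_rng(seed)
    max_start = np.array([genome[el.chrom] - len(el) for el in elements])
    null = np.empty(n_shuffles, dtype=int)
    for s in range(n_shuffles):
        starts = rng.integers(0, max_start + 1)
        null[s] = count(starts)
    ge = int((null >= observed).sum())
    gt = int((null > observed).sum())
    return OverlapNull(
        observed=observed,
        exceedance_ge=ge,
        exceedance_gt=gt,
        n_shuffles=n_shuffles,
        p_ge=empirical_pvalue(ge, n_shuffles),
        p_gt=empirical_pvalue(gt, n_shuffles),
        p_plus_one=(ge + 1) / (n_shuffles + 1),
        null_counts=null,
    )
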