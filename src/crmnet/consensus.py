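"""Consensus integration of replicate regulatory networks.

Given R replicate networks (S^r, C^r), the consensus (S, C) minimizes

    Q = sum_{i,j,r} w_r [ (S_ij - S^r_ij)^2 + a ||C_ij - C^r_ij||_2^2 ]
        - b sum_{i,j} S_ij ||C_ij||_1
        - g sum_{i,j,q} C_ijq C_ij(q-1)
        + mu ||S||_1

subject to S_ij >= 0 and, after relaxing the 0-1 CRM base variables,
C_ijq in [0, 1] with the boundary convention C_ij0 = 0.  The first term
pulls the consensus toward each replicate, the second couples strength
with CRM support, the third rewards base continuity along the genome,
and the last sparsifies the edge set.

The solver is the projected fixed-point iteration derived from the
first-order stationarity conditions (Jacobi updates on the previous
iterate, then projection onto the feasible box):

    S_ij  <- [ (2 sum_r w_r S^r_ij + b ||C_ij||_1 - mu) / (2w) ]_+
    C_ijq <- [ (1/w) sum_r w_r C^r_ijq + b/(2wa) S_ij
               + g/(2wa) (C_ij(q-1) + C_ij(q+1)) ]_0^1

with w = sum_r w_r.  CRM base vectors of all pairs are laid out in one
guarded global array so both updates are single vectorized operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import GenomicInterval, ValidationError, merge_intervals
from .networks import ConsensusNetwork, ReplicateNetwork, SolverDiagnostics, Triplet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CRM frames: a union coordinate span per (TF, TG) pair
# ---------------------------------------------------------------------------


@dataclass
class CrmFrame:
    """Union coordinate frame for one (TF, TG) pair across replicates.

    ``pieces`` are per-chromosome spans (chrom, start, end) covering every
    replicate's CRM intervals; ``replicate_vectors`` is a boolean
    (R, L) array over the concatenated pieces, 1 exactly on the bases a
    replicate's REs cover.
    """

    pieces: list[tuple[str, int, int]]
    replicate_vectors: np.ndarray  # bool, (R, L)

    @property
    def length(self) -> int:
        return int(self.replicate_vectors.shape[1])

    def piece_offsets(self) -> list[int]:
        offsets, cursor = [], 0
        for _, start, end in self.pieces:
            offsets.append(cursor)
            cursor += end - start
        return offsets

    def intervals_from_mask(self, mask: np.ndarray) -> tuple[GenomicInterval, ...]:
        """Turn a boolean base mask over the frame into genomic intervals."""
        out: list[GenomicInterval] = []
        for (chrom, start, _end), offset in zip(self.pieces, self.piece_offsets()):
            width = _end - start
            sub = mask[offset : offset + width].astype(np.int8)
            if not sub.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate([[0], sub, [0]])))
            for a, b in zip(edges[::2], edges[1::2]):
                out.append(GenomicInterval(chrom, start + int(a), start + int(b)))
        return tuple(out)


def align_crm_frames(
    replicates: Sequence[ReplicateNetwork],
) -> dict[tuple[str, str], CrmFrame]:
    """Build the per-pair union frame and per-replicate base vectors.

    A pair absent from a replicate contributes an all-zero vector: absence
    is no support, not missing data.
    """
    edges = sorted(set().union(*(r.edges() for r in replicates)))
    frames: dict[tuple[str, str], CrmFrame] = {}
    for edge in edges:
        per_rep: list[tuple[GenomicInterval, ...]] = [
            r[edge].crm if edge in r else () for r in replicates
        ]
        by_chrom: dict[str, list[int]] = {}
        for crm in per_rep:
            for iv in crm:
                lo, hi = by_chrom.get(iv.chrom, [iv.start, iv.end])
                by_chrom[iv.chrom] = [min(lo, iv.start), max(hi, iv.end)]
        pieces = [(c, lo, hi) for c, (lo, hi) in sorted(by_chrom.items())]
        length = sum(hi - lo for _, lo, hi in pieces)
        vectors = np.zeros((len(replicates), length), dtype=bool)
        offset = 0
        for chrom, lo, hi in pieces:
            for r_idx, crm in enumerate(per_rep):
                for iv in crm:
                    if iv.chrom == chrom:
                        vectors[r_idx, offset + iv.start - lo : offset + iv.end - lo] = True
            offset += hi - lo
        frames[edge] = CrmFrame(pieces, vectors)
    return frames


@dataclass
class RelaxedCrm:
    """Solver output for one pair: the frame plus relaxed base values."""

    frame: CrmFrame
    values: np.ndarray  # float in [0, 1], length frame.length


# ---------------------------------------------------------------------------
# The optimization problem and solver
# ---------------------------------------------------------------------------


@dataclass
class ConsensusProblem:
    replicates: Sequence[ReplicateNetwork]
    alpha: float = 1.0
    beta: float = 0.0
    gamma: float = 0.0
    mu: float = 0.0
    weights: Sequence[float] | None = None  # overrides per-replicate weights
    eps: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValidationError("need at least one replicate")
        if self.weights is not None and len(self.weights) != len(self.replicates):
            raise ValidationError("weights length != number of replicates")
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")
        if self.alpha == 0 and (self.beta > 0 or self.gamma > 0):
            raise ValidationError(
                "alpha must be > 0 when beta or gamma couple to the CRM term"
            )
        for p in (self.alpha, self.beta, self.gamma, self.mu):
            if not np.isfinite(p) or p < 0:
                raise ValidationError("parameters must be finite and >= 0")

    @property
    def omega(self) -> np.ndarray:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
        else:
            w = np.array([r.weight for r in self.replicates], dtype=float)
        if (w <= 0).any():
            raise ValidationError("replicate weights must be > 0")
        return w


def consensus_optimize(problem: ConsensusProblem) -> ConsensusNetwork:
    """Run the projected fixed-point iteration to convergence.

    Returns a network whose triplets carry the consensus strengths; the
    relaxed CRM vectors are attached as ``network.relaxed`` for
    :func:`finalize_network` to binarize.  Initialization is the
    weight-averaged replicate solution (the exact optimum at
    beta = gamma = mu = 0).
    """
    reps = list(problem.replicates)
    w = problem.omega
    omega = float(w.sum())
    alpha, beta, gamma, mu = problem.alpha, problem.beta, problem.gamma, problem.mu

    frames = align_crm_frames(reps)
    edges = sorted(frames)
    n_pairs = len(edges)
    if n_pairs == 0:
        return ConsensusNetwork([], SolverDiagnostics(0, 0.0, 0.0, True))

    # weighted replicate sums per pair
    T = np.array(
        [sum(wr * (r[e].score if e in r else 0.0) for wr, r in zip(w, reps))
         for e in edges]
    )

    # Global guarded base layout: every pair occupies one contiguous region;
    # a zero guard base separates chromosome pieces within a pair (the
    # continuity term must not couple across chromosomes) and another guard
    # trails each pair (C_ij0 = C_ij(L+1) = 0 boundary convention).
    region_lengths = np.array(
        [frames[e].length + len(frames[e].pieces) for e in edges], dtype=int
    )
    starts = np.concatenate([[0], np.cumsum(region_lengths)])[:-1]
    total = int(region_lengths.sum())
    base_mean = np.zeros(total)
    pair_of_base = np.full(total, -1, dtype=int)
    frame_to_global: list[np.ndarray] = []
    for idx, e in enumerate(edges):
        frame = frames[e]
        mean_vec = (w[:, None] * frame.replicate_vectors).sum(axis=0) / omega
        gidx = np.empty(frame.length, dtype=int)
        cursor = starts[idx]
        frame_offset = 0
        for _, lo, hi in frame.pieces:
            width = hi - lo
            gidx[frame_offset : frame_offset + width] = np.arange(cursor, cursor + width)
            cursor += width + 1  # skip guard after the piece
            frame_offset += width
        frame_to_global.append(gidx)
        base_mean[gidx] = mean_vec
        pair_of_base[gidx] = idx
    interior = pair_of_base >= 0

    S = np.clip(T / omega, 0.0, None)
    C = base_mean.copy()

    crm_static = beta == 0.0 and gamma == 0.0
    bcoef = beta / (2.0 * omega * alpha) if alpha > 0 else 0.0
    gcoef = gamma / (2.0 * omega * alpha) if alpha > 0 else 0.0

    diag = SolverDiagnostics()
    for iteration in range(1, problem.max_iter + 1):
        l1 = np.add.reduceat(C, starts) if total else np.zeros(n_pairs)
        S_new = np.clip((2.0 * T + beta * l1 - mu) / (2.0 * omega), 0.0, None)
        if crm_static:
            C_new = C
        else:
            left = np.concatenate([[0.0], C[:-1]])
            right = np.concatenate([C[1:], [0.0]])
            s_per_base = np.where(interior, S[np.maximum(pair_of_base, 0)], 0.0)
            C_new = base_mean + bcoef * s_per_base + gcoef * (left + right)
            C_new = np.clip(C_new, 0.0, 1.0)
            C_new[~interior] = 0.0
        diag.max_delta_s = float(np.abs(S_new - S).max()) if n_pairs else 0.0
        diag.max_delta_c = float(np.abs(C_new - C).max()) if total else 0.0
        S, C = S_new, C_new
        diag.iterations = iteration
        if iteration % 10 == 0:
            log.debug(
                "iter %d: max|dS|=%.3g max|dC|=%.3g",
                iteration, diag.max_delta_s, diag.max_delta_c,
            )
        if diag.max_delta_s < problem.eps and diag.max_delta_c < problem.eps:
            diag.converged = True
            break
    if not diag.converged:
        log.warning(
            "consensus did not converge in %d iterations (max|dS|=%.3g)",
            problem.max_iter, diag.max_delta_s,
        )

    triplets = []
    relaxed: dict[tuple[str, str], RelaxedCrm] = {}
    for idx, e in enumerate(edges):
        values = C[frame_to_global[idx]].copy()
        relaxed[e] = RelaxedCrm(frames[e], values)
        triplets.append(Triplet(e[0], e[1], float(S[idx]), ()))
    return ConsensusNetwork(triplets, diag, relaxed)


def finalize_network(
    cn: ConsensusNetwork, c_threshold: float = 0.5, keep_s_min: float = 0.0
) -> ConsensusNetwork:
    """Binarize relaxed CRM vectors and drop weak or CRM-less triplets.

    Bases at or above ``c_threshold`` become 1; maximal runs of 1s become
    CRM intervals.  Triplets with strength <= ``keep_s_min`` or an empty
    binarized CRM are dropped.
    """
    kept = []
    for t in cn:
        if t.score <= keep_s_min:
            continue
        rc = cn.relaxed.get(t.edge)
        if rc is None:
            crm = t.crm
        else:
            crm = rc.frame.intervals_from_mask(rc.values >= c_threshold)
        if not crm:
            continue
        kept.append(Triplet(t.tf, t.tg, t.score, crm))
    return ConsensusNetwork(kept, cn.diagnostics)


# ---------------------------------------------------------------------------
# Naive baselines
# ---------------------------------------------------------------------------


def _intersect_interval_lists(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    out = []
    for x in a:
        for y in b:
            if x.chrom == y.chrom:
                lo, hi = max(x.start, y.start), min(x.end, y.end)
                if lo < hi:
                    out.append(GenomicInterval(x.chrom, lo, hi))
    return merge_intervals(out)


def baseline_integrate(
    replicates: Sequence[ReplicateNetwork], mode: str
) -> ConsensusNetwork:
    """Naive replicate integration: ``union`` keeps a pair present in any
    replicate, ``intersection`` a pair present in every replicate; the
    score is the mean over supporting replicates and the CRM the interval
    union or intersection respectively."""
    if mode not in {"union", "intersection"}:
        raise ValueError(f"unknown mode {mode!r}")
    edge_sets = [r.edges() for r in replicates]
    if mode == "union":
        edges = set().union(*edge_sets)
    else:
        edges = set.intersection(*edge_sets)
    triplets = []
    for e in sorted(edges):
        supporting = [r[e] for r in replicates if e in r]
        score = float(np.mean([t.score for t in supporting]))
        if mode == "union":
            crm: Sequence[GenomicInterval] = merge_intervals(
                iv for t in supporting for iv in t.crm
            )
        else:
            crm = list(supporting[0].crm)
            for t in supporting[1:]:
                crm = _intersect_interval_lists(crm, t.crm)
            if not crm:
                continue
        triplets.append(Triplet(e[0], e[1], score, tuple(crm)))
    return ConsensusNetwork(triplets, SolverDiagnostics(0, 0.0, 0.0, True))


# ---------------------------------------------------------------------------
# F1-driven parameter selection
# ---------------------------------------------------------------------------


def select_parameters(
    grid: Iterable[tuple[float, float, float, float]],
    replicates: Sequence[ReplicateNetwork],
    gold,
    universe: set[str],
    c_threshold: float = 0.5,
    keep_s_min: float = 0.0,
    eps: float = 1e-8,
    max_iter: int = 1000,
    weights: Sequence[float] | None = None,
):
    """Run consensus per (alpha, beta, gamma, mu) setting and pick the one
    with the best edge F1 against the gold standard, restricted to the gene
    universe.  Ties break toward larger recall, then smaller mu.

    Returns ``(best_setting, best_network, records)`` where records is a
    list of dicts with per-setting metrics.
    """
    from .validation import edge_metrics

    grid = list(grid)
    if not grid:
        raise ValidationError("parameter grid is empty")
    records = []
    best = None
    for setting in grid:
        alpha, beta, gamma, mu = setting
        problem = ConsensusProblem(
            replicates, alpha, beta, gamma, mu,
            weights=weights, eps=eps, max_iter=max_iter,
        )
        network = finalize_network(
            consensus_optimize(problem), c_threshold, keep_s_min
        )
        if len(network) == 0:
            records.append(
                {"alpha": alpha, "beta": beta, "gamma": gamma, "mu": mu,
                 "edges": 0, "precision": 0.0, "recall": 0.0, "f1": 0.0}
            )
            continue
        m = edge_metrics(network.to_edge_list(), gold, universe)
        records.append(
            {"alpha": alpha, "beta": beta, "gamma": gamma, "mu": mu,
             "edges": len(network), "precision": m.precision,
             "recall": m.recall, "f1": m.f1}
        )
        key = (m.f1, m.recall, -mu)
        if best is None or key > best[0]:
            best = (key, setting, network)
    if best is None:
        raise ValidationError("every grid setting produced an empty network")
    return best[1], best[2], records
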