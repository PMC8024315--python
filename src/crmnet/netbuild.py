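"""Build one replicate's regulatory network from paired expression and
chromatin accessibility.

The trans-regulation score of TF i on target gene j is

    S_ij = ( sum_k B_ik * RE_k * I_kj ) * 2**|R_ij| * sqrt(TFA_i * TG_j)

where B_ik is the summed log-odds motif binding strength of TF i on
regulatory element k, RE_k the element's normalized accessibility, I_kj
the element-to-gene interaction weight learned by regressing gene
expression on element accessibility across a panel of paired samples,
R_ij the TF-TG expression correlation across that panel, TFA_i the TF
activity (geometric mean of expression and motif enrichment on open
elements), and TG_j the target's expression.  The CRM of a retained
(i, j) edge is the merged set of candidate elements the TF binds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import ExpressionMatrix, GenomicInterval, PWM, ValidationError, merge_intervals
from .networks import ReplicateNetwork, Triplet

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class RegulatoryElement:
    """An accessible genomic interval with signal and (optionally) sequence."""

    interval: GenomicInterval
    accessibility: float
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.accessibility < 0:
            raise ValidationError(
                f"RE {self.interval.region_string()}: accessibility < 0"
            )
        if self.sequence is not None and len(self.sequence) != len(self.interval):
            raise ValidationError(
                f"RE {self.interval.region_string()}: sequence length "
                f"{len(self.sequence)} != interval length {len(self.interval)}"
            )


@dataclass
class InteractionModel:
    """Element-to-gene regression: TG_j ~ I_0j + sum_{k in D_j} I_kj RE_k."""

    candidates: dict[str, list[int]]  # TG -> candidate RE indices (D_j)
    weights: dict[str, np.ndarray]  # TG -> I_kj aligned with candidates[tg]
    intercepts: dict[str, float]  # TG -> I_0j

    def weight_vector(self, tg: str, n_res: int) -> np.ndarray:
        """Dense I_{.j} over all REs (zero outside D_j)."""
        col = np.zeros(n_res)
        col[self.candidates.get(tg, [])] = self.weights.get(tg, np.empty(0))
        return col


@dataclass
class TfProfile:
    """Per-TF summary: binding row, activity, expression."""

    tf: str
    binding: np.ndarray
    activity: float
    expression: float

    def __post_init__(self) -> None:
        if self.activity < 0 or (self.binding < 0).any():
            raise ValidationError(f"TF {self.tf}: negative binding/activity")


@dataclass
class PairedSample:
    """One replicate's paired data: REs with accessibility + an expression
    vector over all genes (TFs and TGs) for that sample."""

    sample_id: str
    res: list[RegulatoryElement]
    expression: Mapping[str, float]


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; non-ACGT becomes -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return out


def scan_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Log-odds score at every offset on both strands.

    Returns an array of shape (2, n_offsets) (forward, reverse); windows
    containing non-ACGT bases score -inf.  Empty second axis when the PWM
    is wider than the sequence.
    """
    w = pwm.width
    codes = encode_sequence(seq)
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty((2, 0))
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)  # (n, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    cols = np.arange(w)
    fwd = pwm.matrix[safe, cols].sum(axis=1)
    rev = pwm.reverse_complement_matrix()[safe, cols].sum(axis=1)
    scores = np.vstack([fwd, rev])
    scores[:, ~valid] = -np.inf
    return scores


def count_hits(seq: str, pwm: PWM) -> int:
    scores = scan_scores(seq, pwm)
    return int((scores >= pwm.threshold).sum())


def motif_binding_matrix(
    res: Sequence[RegulatoryElement], pwms: Sequence[PWM]
) -> np.ndarray:
    """B[i, k] = sum of above-threshold log-odds hits of PWM i on RE k."""
    for re_ in res:
        if re_.sequence is None:
            raise ValidationError(
                f"RE {re_.interval.region_string()} lacks a sequence"
            )
    B = np.zeros((len(pwms), len(res)))
    for i, pwm in enumerate(pwms):
        for k, re_ in enumerate(res):
            scores = scan_scores(re_.sequence, pwm)
            passing = scores[scores >= pwm.threshold]
            if passing.size:
                B[i, k] = passing.sum()
    return B


# ---------------------------------------------------------------------------
# Panel regression and correlation
# ---------------------------------------------------------------------------


def fit_interaction_model(
    panel_expr: ExpressionMatrix,
    panel_access: np.ndarray,
    candidates: Mapping[str, Sequence[int]],
    ridge_lambda: float = 0.0,
) -> InteractionModel:
    """Least-squares fit of each gene's expression on its candidate REs'
    accessibility across the panel samples.

    ``panel_access`` is REs x samples, aligned with ``panel_expr`` columns.
    A ridge penalty (``ridge_lambda``) is required when samples are fewer
    than parameters and is applied automatically (tiny lambda) on
    rank-deficient designs.
    """
    n_samples = panel_access.shape[1]
    if n_samples != len(panel_expr.samples):
        raise ValidationError("accessibility and expression sample counts differ")
    weights: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    cand_map = {tg: list(k) for tg, k in candidates.items()}
    for tg, k_idx in cand_map.items():
        y = panel_expr.subset([tg])[0]
        if not k_idx:
            weights[tg] = np.empty(0)
            intercepts[tg] = float(y.mean())
            continue
        X = np.column_stack([np.ones(n_samples), panel_access[k_idx, :].T])
        p = X.shape[1]
        lam = ridge_lambda
        if n_samples < p and lam <= 0:
            raise ValidationError(
                f"gene {tg!r}: {n_samples} samples for {p} parameters; "
                "set ridge_lambda > 0"
            )
        if lam <= 0 and np.linalg.matrix_rank(X) < p:
            lam = 1e-8  # rank-deficient design: minimal stabilization
        if lam > 0:
            penalty = lam * np.eye(p)
            penalty[0, 0] = 0.0  # intercept unpenalized
            beta = np.linalg.solve(X.T @ X + penalty, X.T @ y)
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercepts[tg] = float(beta[0])
        weights[tg] = beta[1:]
    return InteractionModel(cand_map, weights, intercepts)


def expression_correlation(
    panel_expr: ExpressionMatrix, tfs: Sequence[str], tgs: Sequence[str]
) -> np.ndarray:
    """Pearson correlation R[i, j] of TF i with TG j across panel samples.

    Constant series correlate 0 by convention.
    """
    if len(panel_expr.samples) < 3:
        raise ValidationError("need >= 3 panel samples for correlation")
    X = panel_expr.subset(tfs)
    Y = panel_expr.subset(tgs)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    denom = np.outer(xn, yn)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(denom > 0, (Xc @ Yc.T) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(R, -1.0, 1.0)


# ---------------------------------------------------------------------------
# TF activity
# ---------------------------------------------------------------------------


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving exact dinucleotide counts.

    Altschul-Erickson style: treat the sequence as an Eulerian walk on the
    base graph, pick random last-out edges forming an in-tree to the final
    base (rejection sampled), permute the remaining out-edges.
    """
    if len(seq) <= 2:
        return seq
    vertices = sorted(set(seq))
    out_edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        out_edges[a].append(b)
    last = seq[-1]
    non_terminal = [v for v in vertices if v != last and out_edges[v]]
    for _ in range(10_000):
        last_edge = {v: out_edges[v][rng.integers(len(out_edges[v]))]
                     for v in non_terminal}
        # check every non-terminal vertex reaches `last` via last-edges
        ok = True
        for v in non_terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection sampling virtually always succeeds
        return seq
    shuffled_out: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(out_edges[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        rng.shuffle(edges)
        if v in last_edge:
            edges.append(last_edge[v])
        shuffled_out[v] = edges
    out: list[str] = [seq[0]]
    counters = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_out[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def motif_enrichment(
    pwm: PWM,
    open_res: Sequence[RegulatoryElement],
    shuffles: int,
    rng: np.random.Generator,
    floor: float = 1e-3,
) -> float:
    """Hit density in open elements over the mean density in
    dinucleotide-shuffled copies, floored at ``floor``."""
    seqs = [re_.sequence for re_ in open_res]
    if any(s is None for s in seqs):
        raise ValidationError("open REs must carry sequences")
    positions = sum(max(len(s) - pwm.width + 1, 0) for s in seqs) * 2
    if positions == 0:
        return floor
    observed = sum(count_hits(s, pwm) for s in seqs) / positions
    null_density = []
    for _ in range(shuffles):
        hits = sum(count_hits(dinucleotide_shuffle(s, rng), pwm) for s in seqs)
        null_density.append(hits / positions)
    baseline = float(np.mean(null_density))
    if baseline == 0.0:
        baseline = 1.0 / positions  # as if a single background hit
    return max(observed / baseline, floor)


def tf_activity(
    expr: Mapping[str, float],
    pwms: Sequence[PWM],
    tf_ids: Sequence[str],
    open_res: Sequence[RegulatoryElement],
    shuffles: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """TFA_i = sqrt(TF_i * E_i): geometric mean of expression and motif
    enrichment on open elements.  Zero exactly when the TF is unexpressed."""
    if shuffles < 1:
        raise ValidationError("shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = [re_.sequence for re_ in open_res]
    if any(s is None for s in seqs):
        raise ValidationError("open REs must carry sequences")
    # one background set shared by every PWM: shuffle each sequence once
    # per round, score all motifs against the same copies
    shuffled_sets = [
        [dinucleotide_shuffle(s, rng) for s in seqs] for _ in range(shuffles)
    ]
    tfa = np.zeros(len(tf_ids))
    for i, (tf, pwm) in enumerate(zip(tf_ids, pwms)):
        level = float(expr[tf])
        if level < 0:
            raise ValidationError(f"TF {tf!r}: negative expression")
        if level == 0.0:
            continue
        positions = sum(max(len(s) - pwm.width + 1, 0) for s in seqs) * 2
        if positions == 0:
            enrichment = 1e-3
        else:
            observed = sum(count_hits(s, pwm) for s in seqs) / positions
            null = [
                sum(count_hits(s, pwm) for s in batch) / positions
                for batch in shuffled_sets
            ]
            baseline = float(np.mean(null))
            if baseline == 0.0:
                baseline = 1.0 / positions
            enrichment = max(observed / baseline, 1e-3)
        tfa[i] = np.sqrt(level * enrichment)
    return tfa


# ---------------------------------------------------------------------------
# Trans-regulation scores and network assembly
# ---------------------------------------------------------------------------


def trans_regulation_scores(
    B: np.ndarray,
    accessibility: np.ndarray,
    model: InteractionModel,
    R: np.ndarray,
    tfa: np.ndarray,
    tg_expr: np.ndarray,
    tg_ids: Sequence[str],
) -> np.ndarray:
    """S[i, j] per the trans-regulation formula; inner sums clamped at 0.

    The panel regression is sign-unconstrained, so the RE-weighted inner
    sum can go negative; those entries are clamped to keep S >= 0.
    """
    n_tfs, n_res = B.shape
    if accessibility.shape != (n_res,):
        raise ValidationError("accessibility length does not match B columns")
    if (np.asarray(tg_expr) < 0).any():
        raise ValidationError("tg_expr must be >= 0")
    I = np.column_stack(
        [model.weight_vector(tg, n_res) for tg in tg_ids]
    )  # RE x TG
    if R.shape != (n_tfs, len(tg_ids)) or tfa.shape != (n_tfs,):
        raise ValidationError("dimension mismatch among B, R, tfa, tg_ids")
    inner = B @ (accessibility[:, None] * I)
    inner = np.clip(inner, 0.0, None)
    S = inner * np.power(2.0, np.abs(R)) * np.sqrt(np.outer(tfa, tg_expr))
    return S


def candidate_res_by_window(
    res: Sequence[RegulatoryElement],
    tss: Mapping[str, tuple[str, int]],
    window: int = 200_000,
) -> dict[str, list[int]]:
    """D_j: candidate RE indices within ``window`` bases of each gene's TSS."""
    out: dict[str, list[int]] = {}
    for tg, (chrom, pos) in tss.items():
        out[tg] = [
            k
            for k, re_ in enumerate(res)
            if re_.interval.chrom == chrom
            and re_.interval.start < pos + window
            and re_.interval.end > pos - window
        ]
    return out


@dataclass
class BuildConfig:
    """Tunables for single-replicate network construction."""

    window_kb: float = 200.0
    pwm_threshold_frac: float = 0.6
    s_quantile: float = 0.5
    ridge_lambda: float = 0.0
    enrichment_shuffles: int = 10
    seed: int = 0


def build_replicate_network(
    replicate_id: str,
    sample: PairedSample,
    pwms: Sequence[PWM],
    tf_ids: Sequence[str],
    tg_ids: Sequence[str],
    model: InteractionModel,
    R: np.ndarray,
    weight: float = 1.0,
    s_quantile: float = 0.5,
    enrichment_shuffles: int = 10,
    seed: int = 0,
) -> ReplicateNetwork:
    """Run the full per-replicate pipeline and keep the strongest edges.

    Edges with S at or above the ``s_quantile`` quantile of positive scores
    are retained; each retained (i, j) edge's CRM is the merged set of
    candidate REs (D_j) the TF actually binds (B_ik > 0).
    """
    res = sample.res
    B = motif_binding_matrix(res, pwms)
    accessibility = np.array([re_.accessibility for re_ in res])
    open_res = [re_ for re_ in res if re_.accessibility > 0]
    tfa = tf_activity(
        sample.expression, pwms, tf_ids, open_res, enrichment_shuffles, seed
    )
    tg_expr = np.array([float(sample.expression[tg]) for tg in tg_ids])
    S = trans_regulation_scores(B, accessibility, model, R, tfa, tg_expr, tg_ids)
    if S.max() > 0:
        # regression round-off can leave scores at machine-epsilon scale;
        # they are numerically zero, not regulations
        S[S < 1e-9 * S.max()] = 0.0

    positive = S[S > 0]
    triplets: list[Triplet] = []
    if positive.size:
        cutoff = float(np.quantile(positive, s_quantile))
        for i, tf in enumerate(tf_ids):
            for j, tg in enumerate(tg_ids):
                if S[i, j] <= 0 or S[i, j] < cutoff:
                    continue
                crm = [
                    res[k].interval
                    for k in model.candidates.get(tg, [])
                    if B[i, k] > 0
                ]
                if not crm:
                    continue
                triplets.append(Triplet(tf, tg, float(S[i, j]), tuple(crm)))
    else:
        import logging

        logging.getLogger(__name__).warning(
            "replicate %s: no positive trans-regulation scores; empty network",
            replicate_id,
        )
    return ReplicateNetwork(
        replicate_id, triplets, weight, n_tfs=len(tf_ids), n_tgs=len(tg_ids)
    )
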