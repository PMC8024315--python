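"""Regulatory architecture: TF modules, the dense TF subnetwork, and roles.

The dense subnetwork of a non-negative TF-TF strength matrix S0 is the
rank-one importance decomposition

    max_{u, v >= 0, ||u|| = ||v|| = 1}  sum_ij S0_ij u_i v_j

solved by alternating projected power iteration.  u_i measures a TF's
out-going importance, v_i its in-coming importance; with cutoffs mu_c
and v_c a TF is upstream (high u, low v), core (high both), downstream
(low u, high v), or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats

from .io import ValidationError


@dataclass
class DenseSubnetResult:
    matrix: np.ndarray
    u: np.ndarray
    v: np.ndarray
    objective: float
    trace: list[float]

    def __post_init__(self) -> None:
        for vec in (self.u, self.v):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-9 or (vec < -1e-12).any():
                raise ValidationError("importance vectors must be unit-norm, >= 0")


def cluster_tf_modules(
    S: np.ndarray,
    tf_ids: list[str],
    k: int = 2,
    metric: str = "euclidean",
    method: str = "complete",
) -> dict[str, int]:
    """Agglomerative clustering of TF row vectors, cut at k modules.

    Labels are renumbered so module 1 has the largest mean row sum, i.e.
    contains the broadest regulators.
    """
    S = np.asarray(S, dtype=float)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > S.shape[0]:
        raise ValidationError(f"k={k} exceeds number of TFs {S.shape[0]}")
    if k == S.shape[0]:
        raw = np.arange(1, k + 1)
    else:
        Z = linkage(S, method=method, metric=metric)
        raw = fcluster(Z, t=k, criterion="maxclust")
    row_sums = S.sum(axis=1)
    order = sorted(
        set(raw), key=lambda lab: -float(row_sums[raw == lab].mean())
    )
    relabel = {lab: rank + 1 for rank, lab in enumerate(order)}
    return {tf: relabel[lab] for tf, lab in zip(tf_ids, raw)}


def dense_subnetwork(
    S0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    restarts: int = 5,
    seed: int = 0,
) -> DenseSubnetResult:
    """Maximize u' S0 v over non-negative unit vectors.

    Alternating updates u <- [S0 v]_+ / ||.||, v <- [S0' u]_+ / ||.|| from
    several seeded random starts; for S0 >= 0 the optimum equals the
    leading singular pair, which is attainable with non-negative vectors.
    """
    S0 = np.asarray(S0, dtype=float)
    if S0.ndim != 2 or S0.shape[0] != S0.shape[1]:
        raise ValidationError("S0 must be square")
    if (S0 < 0).any():
        raise ValidationError("S0 must be elementwise non-negative")
    if not S0.any():
        raise ValidationError("S0 is all-zero")
    n = S0.shape[0]
    rng = np.random.default_rng(seed)
    best: DenseSubnetResult | None = None
    for restart in range(restarts):
        if restart == 0:
            v = np.ones(n) / np.sqrt(n)
        else:
            v = rng.random(n)
            v /= np.linalg.norm(v)
        trace: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            u = np.clip(S0 @ v, 0.0, None)
            norm_u = np.linalg.norm(u)
            if norm_u == 0:
                u = np.ones(n) / np.sqrt(n)
            else:
                u /= norm_u
            v = np.clip(S0.T @ u, 0.0, None)
            norm_v = np.linalg.norm(v)
            if norm_v == 0:
                v = np.ones(n) / np.sqrt(n)
            else:
                v /= norm_v
            objective = float(u @ S0 @ v)
            trace.append(objective)
            if objective - prev < tol:
                break
            prev = objective
        candidate = DenseSubnetResult(S0, u, v, objective, trace)
        if best is None or candidate.objective > best.objective:
            best = candidate
    return best


def classify_tf_roles(
    result: DenseSubnetResult,
    tf_ids: list[str],
    mu_c: float = 0.1,
    v_c: float = 0.05,
) -> dict[str, str]:
    """Role per TF from the importance vectors with cutoffs (mu_c, v_c)."""
    roles = {}
    for tf, ui, vi in zip(tf_ids, result.u, result.v):
        if ui >= mu_c and vi < v_c:
            roles[tf] = "upstream"
        elif ui >= mu_c and vi >= v_c:
            roles[tf] = "core"
        elif ui < mu_c and vi >= v_c:
            roles[tf] = "downstream"
        else:
            roles[tf] = "none"
    return roles


def subnetwork_density_pvalue(
    S: np.ndarray,
    selected: np.ndarray,
    draws: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Is the selected TF set denser than same-size random sets?

    Density is the mean off-diagonal edge weight within a node set; the
    null is ``draws`` uniform same-size node subsets.  Returns the
    one-tailed t-test p-value of the null densities against the observed
    density, plus the empirical exceedance fraction.
    """
    S = np.asarray(S, dtype=float)
    selected = np.asarray(selected, dtype=int)
    n = S.shape[0]
    m = selected.size
    if m > n:
        raise ValidationError("selected set larger than TF count")
    if draws < 30:
        raise ValidationError("draws must be >= 30")

    def density(nodes: np.ndarray) -> float:
        sub = S[np.ix_(nodes, nodes)]
        if m < 2:
            return float(sub.sum())
        return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))

    observed = density(selected)
    rng = np.random.default_rng(seed)
    null = np.array(
        [density(rng.choice(n, size=m, replace=False)) for _ in range(draws)]
    )
    if np.allclose(null, null[0]) and np.isclose(observed, null[0]):
        p_t = 0.5  # degenerate null identical to the observation
    else:
        t, p_two = stats.ttest_1samp(null, observed)
        p_t = p_two / 2 if t < 0 else 1 - p_two / 2
    exceedance = float((null >= observed).mean())
    return {
        "observed_density": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "p_ttest": float(p_t),
        "exceedance_fraction": exceedance,
    }
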