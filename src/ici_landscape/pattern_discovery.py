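"""Consensus clustering of per-sample infiltration profiles.

Subsampled PAM (k-medoids, Euclidean) runs are aggregated into a consensus
matrix of co-clustering frequencies; the final partition cuts an
average-linkage tree of (1 - consensus) at k; the number of clusters is
chosen from the growth of the area under the consensus CDF (delta-area
elbow). PAM uses a deterministic greedy build step plus swap phase, so the
only randomness is the per-repetition subsample draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ConsensusResult:
    k: int
    consensus_matrix: pd.DataFrame  # samples x samples in [0, 1]
    assignments: pd.Series  # sample -> {1..k}
    cdf_x: np.ndarray  # CDF support (upper-triangle consensus values)
    cdf_y: np.ndarray
    area_under_cdf: float
    never_cosampled: int  # pairs with consensus undefined (set to 0)


@dataclass
class KSelection:
    k_range: list[int]
    delta_area: dict[int, float]
    chosen_k: int


def pam(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic: greedy build (first medoid minimizes total distance, each
    next maximizes cost reduction) followed by the swap phase; ties break on
    the lower index. Returns 0-based cluster labels.
    """
    n = dist.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    # Build phase.
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    d_near = dist[medoids[0]].copy()
    while len(medoids) < k:
        # Gain of adding candidate h: sum of max(0, d_near - d(:, h)).
        gain = np.maximum(0.0, d_near[:, None] - dist).sum(axis=0)
        gain[medoids] = -np.inf
        h = int(np.argmax(gain))
        medoids.append(h)
        d_near = np.minimum(d_near, dist[h])
    medoids = np.array(medoids)

    # Swap phase: try replacing each medoid with each non-medoid.
    for _ in range(max_iter):
        dm = dist[medoids]  # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        nearest = order[0]
        d1 = dm[nearest, np.arange(n)]
        d2 = dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        cand = np.where(~is_medoid)[0]
        if cand.size == 0:
            break
        for mi in range(k):
            # Distance to the nearest medoid excluding medoid mi.
            d_wo = np.where(nearest == mi, d2, d1)
            costs = np.minimum(d_wo[:, None], dist[:, cand]).sum(axis=0)
            deltas = d1.sum() - costs
            j = int(np.argmax(deltas))
            if deltas[j] > best_delta:
                best_delta, best_swap = deltas[j], (mi, cand[j])
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    dm = dist[medoids]
    return np.argmin(dm, axis=0)


def _cdf_and_area(values: np.ndarray, n_bins: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical CDF of consensus values on a fixed [0, 1] grid and its area."""
    grid = np.linspace(0.0, 1.0, n_bins + 1)
    cdf = np.searchsorted(np.sort(values), grid, side="right") / max(len(values), 1)
    area = float(np.trapezoid(cdf, grid))
    return grid, cdf, area


def consensus_cluster(
    features: pd.DataFrame,
    k: int,
    reps: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus matrix over subsampled PAM runs and the resulting partition.

    For each repetition, ceil(p_item * n) samples are drawn without
    replacement and PAM (Euclidean) is run at k; consensus(i, j) is the
    co-cluster count over the co-sample count (0, flagged, for pairs never
    drawn together). Final assignments cut an average-linkage tree of
    1 - consensus at k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 < p_item <= 1.0:
        raise ValueError("p_item must lie in (0, 1]")
    n = len(features)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples {n}")

    X = features.to_numpy(dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    rng = np.random.default_rng(seed)
    m = int(np.ceil(p_item * n))

    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        labels = pam(dist[np.ix_(idx, idx)], k)
        co_sample[np.ix_(idx, idx)] += 1.0
        for c in range(k):
            members = idx[labels == c]
            co_cluster[np.ix_(members, members)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    never = int((co_sample[np.triu_indices(n, 1)] == 0).sum())
    consensus = (consensus + consensus.T) / 2.0
    np.fill_diagonal(consensus, 1.0)

    condensed = squareform(1.0 - consensus, checks=False)
    Z = linkage(condensed, method="average")
    assignments = pd.Series(
        fcluster(Z, t=k, criterion="maxclust"), index=features.index, name="cluster"
    )
    upper = consensus[np.triu_indices(n, 1)]
    cdf_x, cdf_y, area = _cdf_and_area(upper)
    return ConsensusResult(
        k=k,
        consensus_matrix=pd.DataFrame(
            consensus, index=features.index, columns=features.index
        ),
        assignments=assignments,
        cdf_x=cdf_x,
        cdf_y=cdf_y,
        area_under_cdf=area,
        never_cosampled=never,
    )


def consensus_sweep(
    features: pd.DataFrame,
    k_range,
    reps: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
) -> dict[int, ConsensusResult]:
    """Run :func:`consensus_cluster` for each k; one child seed per k."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(len(list(k_range)))]
    return {
        k: consensus_cluster(features, k, reps=reps, p_item=p_item, seed=s)
        for k, s in zip(k_range, seeds)
    }


def select_k(results: dict[int, ConsensusResult], elbow: float = 0.1) -> KSelection:
    """Delta-area elbow over the consensus-CDF areas.

    delta_area(k) is the relative increase of the area under the consensus
    CDF versus k-1 (the area itself for the smallest k); the chosen k is the
    smallest k after which delta_area drops below ``elbow`` (ties toward the
    smaller k); if the gain never drops below the threshold the largest k is
    returned.
    """
    ks = sorted(results)
    if len(ks) < 2:
        raise ValueError("select_k needs results for at least two values of k")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k_range must be consecutive")
    areas = {k: results[k].area_under_cdf for k in ks}
    delta = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        base = areas[prev] if areas[prev] > 0 else 1e-12
        delta[k] = (areas[k] - areas[prev]) / base
    chosen = ks[-1]
    for k in ks[:-1]:
        if delta[k + 1] < elbow:
            chosen = k
            break
    return KSelection(k_range=ks, delta_area=delta, chosen_k=chosen)
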