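"""Resampling consensus clustering for subtype discovery.

Monti-style consensus clustering: repeatedly subsample the cohort (and
optionally the feature set), cluster each subsample by Ward-linkage
agglomeration on 1 − Pearson correlation distance, and record for every
sample pair the fraction of co-sampled resamples in which the pair
co-clusters. The consensus matrix is scanned over k (2..15 by default);
final labels come from Ward clustering of 1 − consensus. Cluster-stability
diagnostics follow the consensus CDF: the area under the empirical CDF of
off-diagonal consensus entries per k, and its relative increase (delta
area) from k−1 to k.

A single root seed derives independent per-resample substreams, so any
resample can be replayed by index for auditing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, check_annotation

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, final labels, and CDF diagnostics."""

    sample_ids: list[str]
    k_values: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]  # 1-based cluster index per sample
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    params: dict

    def labels_series(self, k: int) -> pd.Series:
        return pd.Series(self.labels[k], index=self.sample_ids)


def pairwise_pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between columns over shared non-missing rows.

    Pairs with fewer than 2 shared features or zero variance on the shared
    features get correlation 0 (distance 1). Computed via masked matrix
    products, so missing values cost no explicit pair loop.
    """
    M = ~np.isnan(X)
    Xf = np.where(M, X, 0.0)
    Mf = M.astype(float)
    n = Mf.T @ Mf
    sx = Xf.T @ Mf  # sum of column i over rows shared with column j
    sxx = (Xf**2).T @ Mf
    sxy = Xf.T @ Xf
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        r = cov / np.sqrt(varx * varx.T)
    r[~np.isfinite(r)] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    return dist


def _ward_labels(dist: np.ndarray, k: int) -> np.ndarray:
    """Ward agglomeration of a square dissimilarity, cut into k clusters."""
    if k > dist.shape[0]:
        raise ValueError(f"k={k} exceeds {dist.shape[0]} samples")
    if k == 1:
        return np.ones(dist.shape[0], dtype=int)
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    Z = linkage(condensed, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def _draw_resample(
    n_samples: int, n_features: int, p_item: float, p_feature: float, rng: np.random.Generator, k: int
) -> tuple[np.ndarray, np.ndarray]:
    m = int(round(p_item * n_samples))
    if m < k:
        raise ValueError(f"resample of {m} samples cannot hold k={k} clusters")
    items = np.sort(rng.choice(n_samples, size=m, replace=False))
    f = int(round(p_feature * n_features))
    feats = np.sort(rng.choice(n_features, size=max(f, 1), replace=False))
    return items, feats


def resample_once(
    matrix: ExpressionMatrix,
    k: int,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], np.ndarray]:
    """One resampling step: subsample, cluster, return (sampled ids, labels)."""
    if k < 2:
        raise ValueError("k must be ≥ 2")
    rng = rng or np.random.default_rng()
    X = matrix.values.to_numpy()
    items, feats = _draw_resample(X.shape[1], X.shape[0], p_item, p_feature, rng, k)
    dist = pairwise_pearson_distance(X[np.ix_(feats, items)])
    labels = _ward_labels(dist, k)
    ids = [matrix.sample_ids[i] for i in items]
    return ids, labels


def consensus_scan(
    matrix: ExpressionMatrix,
    k_values: Sequence[int],
    reps: int = 500,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int = 0,
    return_resamples: bool = False,
):
    """Consensus matrices for every k in ``k_values`` from shared resamples.

    Each resample's distance matrix and Ward tree are computed once and cut at
    every k (the resampling scheme is identical across k, so sharing the tree
    only removes redundant work). Returns ``{k: consensus}`` and, when
    ``return_resamples`` is set, the per-resample (item indices, {k: labels})
    log for oracle replay.
    """
    X = matrix.values.to_numpy()
    n = X.shape[1]
    k_values = sorted(set(int(k) for k in k_values))
    if any(k < 2 for k in k_values):
        raise ValueError("all k must be ≥ 2")
    both = np.zeros((n, n))
    together = {k: np.zeros((n, n)) for k in k_values}
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).generate_state(reps)]
    resample_log = []
    for rep in range(reps):
        rng = streams[rep]
        items, feats = _draw_resample(n, X.shape[0], p_item, p_feature, rng, max(k_values))
        dist = pairwise_pearson_distance(X[np.ix_(feats, items)])
        condensed = squareform(np.maximum(dist, 0.0), checks=False)
        Z = linkage(condensed, method="ward")
        ix = np.ix_(items, items)
        both[ix] += 1.0
        rep_labels = {}
        for k in k_values:
            labels = fcluster(Z, t=k, criterion="maxclust")
            together[k][ix] += (labels[:, None] == labels[None, :]).astype(float)
            rep_labels[k] = labels
        if return_resamples:
            resample_log.append((items, rep_labels))
    consensus = {}
    never = (both == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning("%d sample pairs never co-sampled; consensus set to 0", int(never.sum() / 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_values:
            M = np.where(both > 0, together[k] / np.maximum(both, 1e-300), 0.0)
            np.fill_diagonal(M, 1.0)
            consensus[k] = M
    if return_resamples:
        return consensus, resample_log
    return consensus


def build_consensus(
    matrix: ExpressionMatrix,
    k: int,
    reps: int = 500,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Consensus matrix at a single k: co-cluster count / co-sampled count."""
    if reps < 1:
        raise ValueError("reps must be ≥ 1")
    return consensus_scan(matrix, [k], reps, p_item, p_feature, seed)[k]


def final_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cluster the consensus matrix (Ward on 1 − M) into k final clusters.

    Clusters are renumbered 1..k by decreasing size, ties broken by the
    smallest member index.
    """
    n = consensus.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if k == 1:
        return np.ones(n, dtype=int)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    raw = _ward_labels(dist, k)
    return renumber_by_size(raw)


def renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..K by decreasing size (ties: first member)."""
    labels = np.asarray(labels)
    info = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        info.append((-len(members), members[0], c))
    out = np.zeros_like(labels)
    for new, (_, _, old) in enumerate(sorted(info), start=1):
        out[labels == old] = new
    return out


def cdf_area_of(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries on [0, 1]."""
    n = consensus.shape[0]
    vals = np.sort(consensus[np.triu_indices(n, k=1)])
    if vals.size == 0:
        return 0.0
    # exact integral of the right-continuous step CDF over [0, 1];
    # the CDF is 0 below the smallest value, so that segment contributes 0
    steps = np.arange(1, vals.size + 1) / vals.size
    return float(np.sum(steps * np.diff(np.concatenate([vals, [1.0]]))))


def cdf_and_delta(consensus: dict[int, np.ndarray]) -> tuple[dict[int, float], dict[int, float]]:
    """Per-k CDF areas and the relative area increase from k−1 to k.

    delta_area at the smallest k equals that k's area; later ks report
    (A(k) − A(k−1)) / A(k−1), the conventional stability diagnostic.
    """
    ks = sorted(consensus)
    areas = {k: cdf_area_of(consensus[k]) for k in ks}
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else float("inf")
    return areas, delta


def select_k_elbow(delta_area: dict[int, float]) -> int:
    """Elbow rule: the k at which the relative delta area collapses.

    At the true cluster count the consensus is maximally stable, so the
    marginal CDF-area gain over k−1 is smallest; past it, inconsistent
    over-segmentation re-introduces area gains. The elbow is therefore the
    argmin of delta_area over the interior of the scanned range (the
    smallest k is excluded — its delta equals the raw area). Assumes the
    scan extends beyond the true count; ties break to the smaller k.
    """
    ks = sorted(delta_area)
    if len(ks) < 2:
        return ks[0]
    interior = ks[1:]
    return min(interior, key=lambda k: (delta_area[k], k))


def discover_subtypes(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    k_range: Iterable[int] = range(2, 16),
    chosen_k: int = 10,
    reps: int = 500,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int = 0,
    auto_k: bool = False,
) -> tuple[ConsensusResult, pd.DataFrame]:
    """Full consensus scan plus final subtype labels at the chosen k.

    Scans k over ``k_range`` (default 2..15), computes per-k consensus
    matrices, final labels and CDF diagnostics, and writes subtype names
    ``k1..kK`` (ordered by decreasing size) into the annotation at
    ``chosen_k`` (default 10) — or at the elbow-selected k when ``auto_k``.
    """
    k_values = sorted(set(int(k) for k in k_range))
    if chosen_k not in k_values:
        raise ValueError(f"chosen_k={chosen_k} outside k_range {k_values[0]}..{k_values[-1]}")
    consensus = consensus_scan(matrix, k_values, reps, p_item, p_feature, seed)
    labels = {k: final_labels(consensus[k], k) for k in k_values}
    areas, delta = cdf_and_delta(consensus)
    result = ConsensusResult(
        sample_ids=matrix.sample_ids,
        k_values=k_values,
        consensus=consensus,
        labels=labels,
        cdf_area=areas,
        delta_area=delta,
        params={
            "reps": reps,
            "p_item": p_item,
            "p_feature": p_feature,
            "distance": "pearson",
            "linkage": "ward",
            "seed": seed,
        },
    )
    k_final = select_k_elbow(delta) if auto_k else chosen_k
    result.params["chosen_k"] = k_final
    ann = check_annotation(annotation).set_index("sample_id")
    named = pd.Series(labels[k_final], index=matrix.sample_ids).map(lambda c: f"k{c}")
    ann.loc[named.index, "subtype"] = named
    return result, ann.reset_index()
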