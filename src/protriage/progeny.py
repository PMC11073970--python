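"""Progeny clustering: stability-based choice of the number of clusters.

For each candidate k, the data are clustered, then artificial "progeny"
observations are built per cluster by resampling each feature independently
(with replacement) from that cluster's members — preserving marginals while
destroying within-cluster feature covariance.  Reclustering the progeny and
scoring how often progeny of the same origin cluster land together (minus
how often progeny of different origins do), normalized against the same
quantity on label-shuffled progeny, yields a stability score; the k with the
highest average score wins.

k-means (k-means++ init, 10 restarts) is the default base clusterer; Ward
agglomerative clustering is available via ``base="ward"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans

logger = logging.getLogger(__name__)


@dataclass
class ProgenyConfig:
    n_iterations: int = 50
    m_per_cluster: int = 20
    base: str = "kmeans"  # or "ward"
    seed: int = 0


@dataclass
class ProgenyResult:
    chosen_k: int
    stability_scores: dict[int, float]
    assignments: np.ndarray = field(repr=False)
    n_iterations: int = 0
    seed: int = 0


def base_cluster(matrix, k: int, seed: int, base: str = "kmeans") -> np.ndarray:
    """Cluster rows into k groups; the building block of progeny scoring."""
    X = np.asarray(matrix, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of observations ({X.shape[0]})")
    if k < 2:
        raise ValueError("k must be at least 2")
    if base == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        return km.fit_predict(X)
    if base == "ward":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    raise ValueError(f"unknown base clusterer: {base!r}")


def make_progeny(
    matrix, labels, m_per_cluster: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Resample features within clusters to build progeny observations."""
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    # iterate clusters by first-member position, not label value, so that
    # relabeling clusters leaves the resampling stream (and score) unchanged
    uniq = sorted(np.unique(labels),
                  key=lambda c: int(np.argmax(labels == c)))
    chunks, truth = [], []
    for c in uniq:
        members = X[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"empty cluster {c}")
        idx = rng.integers(0, members.shape[0], size=(m_per_cluster, X.shape[1]))
        chunks.append(members[idx, np.arange(X.shape[1])])
        truth.append(np.full(m_per_cluster, c))
    return np.vstack(chunks), np.concatenate(truth)


def _coassignment_score(relabels: np.ndarray, truth: np.ndarray) -> float:
    co = relabels[:, None] == relabels[None, :]
    same = truth[:, None] == truth[None, :]
    off = ~np.eye(truth.size, dtype=bool)
    return co[same & off].mean() - co[~same].mean()


def stability_score(
    matrix, k: int, n_iterations: int, m_per_cluster: int, seed: int,
    base: str = "kmeans", labels: np.ndarray | None = None,
    fine_k: int | None = None,
) -> float:
    """Average progeny co-assignment score for candidate k, null-referenced.

    Each iteration reclusters a fresh progeny draw at k and scores
    same-origin minus different-origin co-assignment, with the same score
    on label-shuffled progeny subtracted as the null reference.  This term
    alone penalizes over-clustering but saturates for every k at or below
    the true cluster count (coarse clusterings of separated groups are
    perfectly stable), so a chimera-homogeneity term is added: the progeny
    are also reclustered at a finer resolution ``fine_k``; progeny of a
    homogeneous cluster stay together, while progeny of a merged cluster
    are feature-wise chimeras of its sub-populations and scatter.  The
    reported score is the sum of the two terms.
    """
    X = np.asarray(matrix, dtype=float)
    if labels is None:
        labels = base_cluster(X, k, seed, base)
    if fine_k is None:
        fine_k = min(max(k + 2, 7), X.shape[0])
    rng = np.random.default_rng(seed)
    scores = np.empty(n_iterations)
    for it in range(n_iterations):
        progeny, truth = make_progeny(X, labels, m_per_cluster, rng)
        sub_seed = int(rng.integers(2**31 - 1))
        relabels = base_cluster(progeny, k, sub_seed, base)
        observed = _coassignment_score(relabels, truth)
        null = _coassignment_score(relabels, rng.permutation(truth))
        fine = base_cluster(progeny, min(fine_k, progeny.shape[0]), sub_seed, base)
        homogeneity = _coassignment_score(fine, truth)
        scores[it] = (observed - null) + homogeneity
    return float(scores.mean())


def progeny_cluster(
    matrix, k_candidates=(2, 3, 4, 5, 6), config: ProgenyConfig | None = None
) -> ProgenyResult:
    """Evaluate the stability score per candidate k and keep the best.

    Ties (and flat score curves) resolve to the smallest candidate k.  A
    single-element ``k_candidates`` forces that k without a sweep.
    """
    config = config or ProgenyConfig()
    X = np.asarray(matrix, dtype=float)
    k_candidates = sorted(k_candidates)
    if not k_candidates:
        raise ValueError("no candidate k values")
    if any(k < 2 or k > 8 for k in k_candidates):
        raise ValueError("candidate k values must lie in 2..8")

    scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_candidates:
        labels_by_k[k] = base_cluster(X, k, config.seed, config.base)
        if len(k_candidates) == 1:
            scores[k] = float("nan")
            continue
        scores[k] = stability_score(
            X, k, config.n_iterations, config.m_per_cluster, config.seed,
            config.base, labels=labels_by_k[k],
            fine_k=max(k_candidates) + 1,
        )
    if len(k_candidates) == 1:
        chosen = k_candidates[0]
    else:
        chosen = max(k_candidates, key=lambda k: (scores[k], -k))
    logger.info("progeny clustering chose k=%d (scores: %s)", chosen,
                {k: round(s, 4) for k, s in scores.items()})
    return ProgenyResult(
        chosen_k=chosen,
        stability_scores=scores,
        assignments=labels_by_k[chosen],
        n_iterations=config.n_iterations,
        seed=config.seed,
    )
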