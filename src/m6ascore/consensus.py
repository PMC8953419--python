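"""Resampling-based consensus clustering with PAC-driven choice of k.

Each resample draws a sample subset without replacement, clusters it with
Ward agglomerative linkage on the z-scored feature subspace, and accumulates
co-clustering counts.  The consensus entry (i, j) is the fraction of runs
co-sampling i and j in which they landed in the same cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger("m6ascore")


@dataclass
class ConsensusResult:
    k: int
    consensus_matrix: pd.DataFrame  # sample x sample in [0, 1]
    assignments: pd.Series  # sample -> cluster label 1..k
    co_sample_counts: pd.DataFrame  # sample x sample integer
    pac: float
    low_confidence: bool = False


def _ward_labels(x: np.ndarray, k: int) -> np.ndarray:
    z = linkage(x, method="ward")
    return fcluster(z, t=k, criterion="maxclust")


def _pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    off = consensus[~np.eye(consensus.shape[0], dtype=bool)]
    return float(((off > lower) & (off < upper)).mean())


def consensus_cluster(
    z_matrix,
    features,
    k: int,
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
    severity=None,
) -> ConsensusResult:
    """Consensus clustering of samples on a feature subspace.

    Parameters
    ----------
    z_matrix:
        :class:`~m6ascore.io.ExpressionMatrix` (any scale; z-scored expected)
        or a genes-x-samples DataFrame.
    features:
        Gene symbols defining the clustering subspace (case-insensitive);
        ``None`` uses every row.
    severity:
        Optional per-sample score; cluster labels are renumbered so label 1
        has the lowest mean severity, making "cluster 1 < cluster k" a
        reproducible convention.
    """
    data = z_matrix.data if hasattr(z_matrix, "data") else z_matrix
    if features is not None:
        wanted = [str(f).upper() for f in features]
        present = [f for f in wanted if f in data.index]
        if not present:
            raise ValueError("no clustering features present in matrix")
        if len(present) < len(wanted):
            logger.warning("consensus_cluster: %d of %d features absent", len(wanted) - len(present), len(wanted))
        data = data.loc[present]
    samples = list(data.columns)
    n = len(samples)
    x = data.to_numpy(dtype=float).T  # samples x features
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(np.unique(x, axis=0)):
        raise ValueError(f"k={k} exceeds number of distinct samples")

    rng = np.random.default_rng(seed)
    m = math.ceil(subsample_fraction * n)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    full = np.arange(n)
    for _ in range(n_resamples):
        idx = full if m >= n else np.sort(rng.choice(n, size=m, replace=False))
        labels = _ward_labels(x[idx], k)
        same = (labels[:, None] == labels[None, :]).astype(float)
        co_cluster[np.ix_(idx, idx)] += same
        co_sample[np.ix_(idx, idx)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    # final partition: agglomerative (average linkage) on 1 - consensus
    from scipy.spatial.distance import squareform

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    assignments = fcluster(linkage(condensed, method="average"), t=k, criterion="maxclust")

    assignments = _order_labels(assignments, severity, x)
    pac = _pac(consensus)
    return ConsensusResult(
        k=k,
        consensus_matrix=pd.DataFrame(consensus, index=samples, columns=samples),
        assignments=pd.Series(assignments, index=samples, name="cluster"),
        co_sample_counts=pd.DataFrame(co_sample.astype(int), index=samples, columns=samples),
        pac=pac,
    )


def _order_labels(labels: np.ndarray, severity, x: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k by ascending mean severity (default: feature mean)."""
    sev = np.asarray(severity, dtype=float) if severity is not None else x.mean(axis=1)
    uniq = np.unique(labels)
    means = [(sev[labels == lab].mean(), lab) for lab in uniq]
    order = [lab for _, lab in sorted(means, key=lambda t: (t[0], t[1]))]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[lab] for lab in labels])


def select_k(results: dict[int, ConsensusResult], low_confidence_pac: float = 0.5) -> int:
    """Pick k by minimum PAC (ties toward smaller k); warn when all PACs are high."""
    if len(results) < 2:
        raise ValueError("select_k needs >= 2 candidate k values")
    best_k = min(sorted(results), key=lambda k: (results[k].pac, k))
    if results[best_k].pac > low_confidence_pac:
        logger.warning("select_k: min PAC %.3f > %.2f; weak cluster structure", results[best_k].pac, low_confidence_pac)
        results[best_k].low_confidence = True
    return best_k
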