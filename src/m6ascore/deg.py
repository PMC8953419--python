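"""Pairwise differential expression, core-gene extraction and overlap testing.

The per-gene test is a two-sided Wilcoxon rank-sum on log2-normalized values
with a linear-scale fold change (pseudocount 1) and Benjamini-Hochberg
adjustment.  A count-model strategy can be plugged in via ``test_func``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger("m6ascore")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforced."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class DEGTable:
    """Per-gene statistics for one pairwise contrast (direction is relative to group B)."""

    contrast: str
    table: pd.DataFrame  # index gene; columns log2_fc, fc, p, q, significant, direction

    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values (normal approximation with tie correction)."""
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
    return np.asarray(res.pvalue)


def pairwise_deg(
    expr: ExpressionMatrix,
    labels,
    group_a,
    group_b,
    fdr_max: float = 0.05,
    fc_min: float = 2.0,
    test_func=None,
) -> DEGTable:
    """Call differential genes between two sample groups.

    Significance requires q < ``fdr_max`` and max(FC, 1/FC) > ``fc_min`` where
    FC is the ratio of linear-scale group means with pseudocount 1.  Direction
    ``up``/``down`` describes group B relative to group A.
    """
    if expr.scale not in ("log2", "normalized"):
        raise ValueError(f"pairwise_deg expects log2/normalized input, got {expr.scale!r}")
    labels = pd.Series(np.asarray(labels), index=expr.sample_ids)
    mask_a = (labels == group_a).to_numpy()
    mask_b = (labels == group_b).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs >= 3 samples")
    values = expr.data.to_numpy(dtype=float)
    a = values[:, mask_a]
    b = values[:, mask_b]
    if expr.scale == "log2":
        lin_a, lin_b = np.exp2(a) - 1.0, np.exp2(b) - 1.0
    else:
        lin_a, lin_b = a, b
    fc = (lin_b.mean(axis=1) + 1.0) / (lin_a.mean(axis=1) + 1.0)
    log2_fc = np.log2(fc)
    p = test_func(a, b) if test_func is not None else _wilcoxon_p(a, b)
    q = bh_fdr(p)
    sig = (q < fdr_max) & (np.maximum(fc, 1.0 / fc) > fc_min)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "fc": fc,
            "p": p,
            "q": q,
            "significant": sig,
            "direction": np.where(fc >= 1.0, "up", "down"),
        },
        index=expr.data.index,
    )
    return DEGTable(f"{group_b}_vs_{group_a}", table)


@dataclass
class CoreDEGSet:
    genes: list[str]
    counts: pd.Series  # gene -> number of contrasts in which significant

    def __len__(self) -> int:
        return len(self.genes)


def core_degs(deg_tables, min_contrasts: int = 2) -> CoreDEGSet:
    """Genes significant in at least ``min_contrasts`` of the supplied contrasts."""
    tables = list(deg_tables)
    if len(tables) < 3:
        raise ValueError("core_degs expects the three pairwise contrasts")
    counter: dict[str, int] = {}
    for t in tables:
        for g in t.significant_genes():
            counter[g] = counter.get(g, 0) + 1
    counts = pd.Series(counter, dtype=int).sort_index()
    core = counts[counts >= min_contrasts]
    return CoreDEGSet(list(core.index), core)


def hypergeometric_overlap(query_set, target_set, universe_size: int) -> dict:
    """Upper-tail hypergeometric test of overlap between two gene sets.

    Returns ``{"overlap": k, "p": P(X >= k)}`` under
    Hypergeom(universe_size, |target|, |query|).
    """
    query = {str(g).upper() for g in query_set}
    target = {str(g).upper() for g in target_set}
    if len(query) > universe_size or len(target) > universe_size:
        raise ValueError("set larger than universe")
    k = len(query & target)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(target), len(query)))
    return {"overlap": k, "p": min(p, 1.0)}


def evidence_filter(evidence_counts: pd.Series, min_evidence: int = 2) -> list[str]:
    """Generic per-gene evidence-count filter (keep genes supported >= min_evidence times)."""
    keep = evidence_counts[evidence_counts >= min_evidence]
    return sorted(str(g).upper() for g in keep.index)
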