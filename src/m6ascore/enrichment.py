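"""Single-sample rank-weighted enrichment scores and group-wise signature tests.

The per-sample statistic is the running-sum enrichment score
``ES = sum_i [P_in(i) - P_out(i)]`` over genes ordered by decreasing
expression, with in-set mass weighted by rank^alpha and out-of-set mass
uniform.  Scores depend only on within-sample ranks, so any strictly
monotone transform of a sample's expression leaves them unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_fdr
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("m6ascore")


def ssgsea_score(values, gene_ids, gene_set, alpha: float = 0.25, tie_rng=None) -> float | None:
    """Enrichment score of ``gene_set`` in one sample.

    ``values`` is the sample's expression vector aligned with ``gene_ids``.
    Returns ``None`` (with a warning) when fewer than 2 set members are
    present.  Rank ties are broken by a seeded shuffle of gene order so the
    statistic is well defined; pass ``tie_rng`` to control it.
    """
    values = np.asarray(values, dtype=float)
    gene_ids = np.asarray([str(g).upper() for g in gene_ids])
    members = {str(g).upper() for g in gene_set}
    in_set = np.isin(gene_ids, list(members))
    n_in = int(in_set.sum())
    n = len(values)
    if n_in < 2:
        logger.warning("ssgsea_score: only %d set members present; score undefined", n_in)
        return None
    if n_in == n:
        raise ValueError("gene set covers the whole matrix; out-of-set mass undefined")
    if tie_rng is None:
        tie_rng = np.random.default_rng(0)
    perm = tie_rng.permutation(n)
    order = perm[np.argsort(-values[perm], kind="stable")]
    in_ordered = in_set[order]
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank n
    w = np.where(in_ordered, ranks**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_ordered) / (n - n_in)
    return float(np.sum(p_in - p_out))


@dataclass
class EnrichmentMatrix:
    scores: pd.DataFrame  # signatures x samples
    alpha: float
    row_zscored: bool


def enrich_collection(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    zscore_rows: bool = True,
    tie_seed: int = 0,
) -> EnrichmentMatrix:
    """Score every signature in ``collection`` for every sample.

    Signatures with fewer than 2 members present are skipped with a warning.
    Optional row z-scoring (population sd) eases cross-signature display.
    """
    if expr.scale not in ("normalized", "log2", "zscore"):
        raise ValueError(f"enrich_collection expects normalized/log2 input, got {expr.scale!r}")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    values = expr.data.to_numpy(dtype=float)
    gene_ids = np.asarray(expr.gene_ids)
    rows = {}
    for name, members in collection.items():
        col_scores = []
        ok = True
        for j in range(values.shape[1]):
            s = ssgsea_score(values[:, j], gene_ids, members, alpha=alpha, tie_rng=np.random.default_rng(tie_seed))
            if s is None:
                ok = False
                break
            col_scores.append(s)
        if ok:
            rows[name] = col_scores
        else:
            logger.warning("enrich_collection: signature %r skipped", name)
    scores = pd.DataFrame(rows, index=expr.sample_ids).T
    if zscore_rows and not scores.empty:
        sd = scores.std(axis=1, ddof=0).replace(0.0, np.nan)
        scores = scores.sub(scores.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    return EnrichmentMatrix(scores, alpha=alpha, row_zscored=zscore_rows)


def til_abundance(expr: ExpressionMatrix, til_collection: GeneSetCollection, alpha: float = 0.25) -> EnrichmentMatrix:
    """Relative abundance of TIL subpopulations: plain enrichment of the 28 sets."""
    return enrich_collection(expr, til_collection, alpha=alpha, zscore_rows=False)


def immunity_cycle_scores(expr: ExpressionMatrix, step_collection: GeneSetCollection, alpha: float = 0.25) -> EnrichmentMatrix:
    """Per-sample activity of the seven sequential anticancer-immunity steps."""
    if len(step_collection) != 7:
        logger.warning("immunity_cycle_scores: expected 7 step sets, got %d", len(step_collection))
    return enrich_collection(expr, step_collection, alpha=alpha, zscore_rows=False)


@dataclass
class TMEScores:
    scores: pd.DataFrame  # rows ImmuneScore, StromaScore


def tme_scores(expr: ExpressionMatrix, immune_set, stromal_set, alpha: float = 0.25) -> TMEScores:
    """ImmuneScore/StromaScore as enrichment of the supplied immune and stromal sets."""
    coll = GeneSetCollection({"ImmuneScore": [str(g).upper() for g in immune_set], "StromaScore": [str(g).upper() for g in stromal_set]})
    em = enrich_collection(expr, coll, alpha=alpha, zscore_rows=False)
    missing = {"ImmuneScore", "StromaScore"} - set(em.scores.index)
    if missing:
        raise ValueError(f"could not score {sorted(missing)}: too few genes present")
    return TMEScores(em.scores.loc[["ImmuneScore", "StromaScore"]])


def groupwise_signature_test(enrichment: EnrichmentMatrix, labels) -> pd.DataFrame:
    """Per-signature Kruskal-Wallis (>2 groups) or Wilcoxon rank-sum (2 groups) with BH."""
    labels = pd.Series(np.asarray(labels), index=enrichment.scores.columns)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("groupwise_signature_test requires >= 2 groups")
    for g in groups:
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g!r} empty")
    ps = []
    for _, row in enrichment.scores.iterrows():
        parts = [row[labels == g].to_numpy() for g in groups]
        if len(groups) == 2:
            p = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided", method="asymptotic").pvalue
        else:
            p = stats.kruskal(*parts).pvalue
        ps.append(float(p))
    q = bh_fdr(ps)
    return pd.DataFrame({"p": ps, "q": q}, index=enrichment.scores.index)
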