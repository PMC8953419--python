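"""Count filtering, library-size normalization and per-gene standardization."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("m6ascore")


def filter_low_count(counts: ExpressionMatrix, min_count: int = 3, min_fraction: float = 1.0 / 3.0) -> ExpressionMatrix:
    """Keep genes detected (count >= ``min_count``) in more than ``min_fraction`` of samples.

    The threshold is strict: a gene detected in exactly ``min_fraction * n``
    samples is dropped.  Idempotent.
    """
    if counts.scale != "counts":
        raise ValueError(f"filter_low_count requires counts scale, got {counts.scale!r}")
    values = counts.data.to_numpy()
    n = values.shape[1]
    detected = (values >= min_count).sum(axis=1)
    keep = detected > min_fraction * n
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_count: dropped %d of %d genes", dropped, len(keep))
    return ExpressionMatrix(counts.data.loc[keep], "counts")


def normalize_log(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million per sample followed by log2(x+1)."""
    if counts.scale != "counts":
        raise ValueError(f"normalize_log requires counts scale, got {counts.scale!r}")
    values = counts.data.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"sample {counts.sample_ids[zero[0]]!r} has zero total counts")
    cpm = values / lib * 1e6
    out = pd.DataFrame(np.log2(cpm + 1.0), index=counts.data.index, columns=counts.data.columns)
    return ExpressionMatrix(out, "log2")


def gene_zscore(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise z-scores using the sample (n-1) standard deviation.

    Genes with zero variance are dropped with a warning; requires >= 2 samples.
    """
    if expr.scale not in ("normalized", "log2"):
        raise ValueError(f"gene_zscore expects normalized or log2 input, got {expr.scale!r}")
    if expr.shape[1] < 2:
        raise ValueError("gene_zscore requires at least 2 samples")
    values = expr.data.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.warning("gene_zscore: dropped %d constant genes", n_const)
    z = (values[keep] - mean[keep]) / sd[keep]
    out = pd.DataFrame(z, index=expr.data.index[keep], columns=expr.data.columns)
    return ExpressionMatrix(out, "zscore")
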