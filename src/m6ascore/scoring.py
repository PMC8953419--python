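"""Regulator-panel signature and the signed prognostic gene score.

Both scores are linear combinations of per-gene z-scores: the panel
signature sums positively weighted regulators minus negatively weighted
ones, and the prognostic score sums risk genes (HR > 1) minus protective
genes (HR < 1) selected from cluster-associated core differential genes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .deg import core_degs, pairwise_deg
from .io import DrugResponseTable, ExpressionMatrix
from .preprocess import gene_zscore
from .survival import cox_fit, km_logrank, maxstat_cutpoint, roc_auc, univariate_screen

logger = logging.getLogger("m6ascore")


def load_regulator_panel(path=None) -> pd.DataFrame:
    """Load the regulator panel (columns gene, role, weight_sign); default ships with the package."""
    if path is None:
        with resources.files("m6ascore.data").joinpath("regulators.tsv").open() as fh:
            panel = pd.read_csv(fh, sep="\t")
    else:
        panel = pd.read_csv(path, sep="\t")
    required = {"gene", "role", "weight_sign"}
    if missing := required - set(panel.columns):
        raise ValueError(f"regulator panel missing columns {sorted(missing)}")
    panel["gene"] = panel["gene"].astype(str).str.upper()
    if not panel["weight_sign"].isin([1, -1]).all():
        raise ValueError("weight_sign must be +1 or -1")
    if panel["gene"].duplicated().any():
        raise ValueError("duplicate genes in regulator panel")
    return panel


def weighted_regulator_signature(zscores: ExpressionMatrix, panel: pd.DataFrame) -> pd.Series:
    """Per-sample panel score: sum of z over +1 genes minus sum over -1 genes."""
    if zscores.scale != "zscore":
        raise ValueError("weighted_regulator_signature expects z-scored input")
    data = zscores.data
    present = panel[panel["gene"].isin(data.index)]
    if present.empty:
        raise ValueError("no panel genes present in matrix")
    dropped = len(panel) - len(present)
    if dropped:
        logger.warning("weighted_regulator_signature: %d panel genes absent, dropped", dropped)
    weights = present.set_index("gene")["weight_sign"].astype(float)
    score = data.loc[weights.index].T @ weights
    score.name = "regulator_signature"
    return score


@dataclass
class M6AvalueModel:
    """Signed gene lists defining the per-sample prognostic score."""

    risk_genes: list[str]
    protective_genes: list[str]
    screen_table: pd.DataFrame
    core_gene_counts: pd.Series
    n_all_degs: int
    train_means: pd.Series | None = None
    train_sds: pd.Series | None = None
    contrast_tables: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if set(self.risk_genes) & set(self.protective_genes):
            raise ValueError("risk and protective gene lists overlap")

    @property
    def genes(self) -> list[str]:
        return list(self.risk_genes) + list(self.protective_genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, 1) for g in self.risk_genes] + [(g, -1) for g in self.protective_genes]
        df = pd.DataFrame(rows, columns=["gene", "weight_sign"]).set_index("gene")
        for col in ("hr", "p"):
            if col in self.screen_table.columns:
                df[col] = self.screen_table.reindex(df.index)[col]
            else:
                df[col] = np.nan
        return df.reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "M6AvalueModel":
        df = df.copy()
        df["gene"] = df["gene"].astype(str).str.upper()
        risk = sorted(df.loc[df["weight_sign"] == 1, "gene"])
        prot = sorted(df.loc[df["weight_sign"] == -1, "gene"])
        screen = df.set_index("gene")[[c for c in ("hr", "p") if c in df.columns]]
        return cls(risk, prot, screen, pd.Series(dtype=int), n_all_degs=0)


def build_m6avalue_model(
    expr: ExpressionMatrix,
    cluster_labels,
    time,
    event,
    fdr_max: float = 0.05,
    fc_min: float = 2.0,
    p_max: float = 0.05,
) -> M6AvalueModel:
    """Build the prognostic model from cluster contrasts and a univariate Cox screen.

    Pipeline: pairwise differential tests over every cluster pair, core genes
    significant in >= 2 contrasts, per-gene Cox screen at ``p_max`` on
    z-scored expression, partition by HR sign.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=expr.sample_ids)
    clusters = sorted(labels.unique())
    if len(clusters) < 3:
        raise ValueError("build_m6avalue_model requires >= 3 clusters")
    tables = [
        pairwise_deg(expr, labels, a, b, fdr_max=fdr_max, fc_min=fc_min)
        for a, b in itertools.combinations(clusters, 2)
    ]
    n_all = len(set().union(*[set(t.significant_genes()) for t in tables]))
    core = core_degs(tables)
    if len(core) == 0:
        raise ValueError("no core differential genes; cannot build model")
    logger.info("build_m6avalue_model: %d all / %d core differential genes", n_all, len(core))
    z = gene_zscore(expr)
    risk, protective, screen = univariate_screen(z, core.genes, time, event, p_max=p_max)
    if not risk and not protective:
        raise ValueError("prognostic screen retained no genes; model is empty")
    model_genes = risk + protective
    return M6AvalueModel(
        risk_genes=risk,
        protective_genes=protective,
        screen_table=screen,
        core_gene_counts=core.counts,
        n_all_degs=n_all,
        train_means=expr.data.loc[model_genes].mean(axis=1),
        train_sds=expr.data.loc[model_genes].std(axis=1, ddof=1),
        contrast_tables=tables,
    )


def apply_m6avalue(model: M6AvalueModel, expr: ExpressionMatrix, standardization: str = "refit") -> pd.DataFrame:
    """Score samples: sum of risk-gene z-scores minus sum of protective-gene z-scores.

    ``refit`` recomputes per-gene mean/sd on this cohort; ``frozen`` reuses the
    training moments stored in the model.  Model genes absent from the matrix
    are dropped with a warning.
    """
    if standardization not in ("refit", "frozen"):
        raise ValueError("standardization must be 'refit' or 'frozen'")
    data = expr.data
    present = [g for g in model.genes if g in data.index]
    if not present:
        raise ValueError("no model genes present in matrix")
    if len(present) < len(model.genes):
        logger.warning("apply_m6avalue: %d model genes absent, dropped", len(model.genes) - len(present))
    sub = data.loc[present]
    if standardization == "refit":
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
    else:
        if model.train_means is None or model.train_sds is None:
            raise ValueError("model lacks training moments; frozen standardization unavailable")
        mean = model.train_means.loc[present]
        sd = model.train_sds.loc[present]
    ok = sd > 0
    if (~ok).any():
        logger.warning("apply_m6avalue: %d constant model genes dropped", int((~ok).sum()))
        sub, mean, sd = sub.loc[ok], mean[ok], sd[ok]
        if sub.empty:
            raise ValueError("all model genes constant; score undefined")
    z = sub.sub(mean, axis=0).div(sd, axis=0)
    signs = pd.Series([1.0 if g in set(model.risk_genes) else -1.0 for g in sub.index], index=sub.index)
    score = z.T @ signs
    return pd.DataFrame({"m6avalue": score})


@dataclass
class StratificationResult:
    scores: pd.DataFrame  # columns m6avalue, group
    cutoff: float
    km: object
    logrank_p: float
    auc: float
    multivariate: object | None = None


def stratify_by_cutpoint(
    score_table: pd.DataFrame,
    time,
    event,
    covariates: pd.DataFrame | None = None,
    min_group_fraction: float = 0.1,
) -> StratificationResult:
    """Split samples at the maximally selected rank-statistic cutoff.

    Reports KM curves with log-rank p, AUC of the score against the event
    indicator, and (when grade/stage covariates are supplied) a multivariate
    Cox fit of group + covariates.
    """
    score = score_table["m6avalue"].to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cut = maxstat_cutpoint(score, time, event, min_group_fraction=min_group_fraction)
    group = np.where(score > cut.cutoff, "high", "low")
    out = score_table.copy()
    out["group"] = group
    km = km_logrank(group, time, event)
    auc = roc_auc(score, event)
    multi = None
    if covariates is not None:
        design = covariates.copy()
        design.insert(0, "m6avalue_high", (group == "high").astype(float))
        multi = cox_fit(design, time, event)
    return StratificationResult(out, cut.cutoff, km, km.p, auc, multi)


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p for n <= 8, else asymptotic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 8:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def drug_sensitivity_screen(
    scores: pd.Series,
    drug_table: DrugResponseTable,
    r_min: float = 0.1,
    p_max: float = 0.05,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Correlate per-line scores with IC50 per compound and label retained hits.

    A compound is retained when |Spearman r| > ``r_min`` and p < ``p_max`` on
    pairwise-complete data; positive correlations are labeled ``resistant``
    and negative ones ``sensitive``.  Compounds with fewer than ``min_pairs``
    complete pairs are skipped with a log entry.
    """
    rows = []
    for compound in drug_table.compounds():
        pairs = drug_table.pairs_for(compound)
        common = pairs.index.intersection(scores.index)
        if len(common) < min_pairs:
            logger.warning("drug_sensitivity_screen: %r has %d complete pairs (<%d), skipped", compound, len(common), min_pairs)
            continue
        r, p = spearman_test(scores.loc[common].to_numpy(), pairs.loc[common, "ic50"].to_numpy())
        retained = (abs(r) > r_min) and (p < p_max) and math.isfinite(r)
        label = "resistant" if r > 0 else "sensitive"
        rows.append((compound, len(common), r, p, retained, label if retained else ""))
    return pd.DataFrame(rows, columns=["compound", "n", "spearman_r", "p", "retained", "label"]).set_index("compound")
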