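"""Survival statistics implemented from the partial-likelihood level up.

Cox proportional-hazards fitting (Newton-Raphson, Efron tie handling),
Kaplan-Meier curves, the log-rank test with hypergeometric variance, the
maximally selected rank-statistic cutpoint, and rank-based ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("m6ascore")

_BETA_CAP = 20.0


@dataclass
class CoxFit:
    """Wald summary of a Cox proportional-hazards fit."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    converged: bool
    separation: bool = False

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def ci(self, level: float = 0.95) -> np.ndarray:
        q = stats.norm.ppf(0.5 + level / 2.0)
        return np.exp(np.column_stack([self.beta - q * self.se, self.beta + q * self.se]))

    def summary(self) -> pd.DataFrame:
        ci = self.ci()
        return pd.DataFrame(
            {
                "beta": self.beta,
                "hr": self.hr,
                "se": self.se,
                "p": self.p,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "n": self.n,
                "n_events": self.n_events,
            },
            index=self.names,
        )


def _untied_quantities(beta, x, time, event):
    """Vectorized partial-likelihood quantities valid when no two times tie.

    With distinct event times the Efron and Breslow constructions coincide,
    so everything reduces to suffix cumulative sums.
    """
    order = np.argsort(time, kind="stable")
    x = x[order]
    event = event[order]
    eta = x @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    s2 = np.cumsum(np.einsum("i,ij,ik->ijk", w, x, x)[::-1], axis=0)[::-1]
    ev = event == 1
    r0 = s0[ev]
    r1 = s1[ev]
    r2 = s2[ev]
    loglik = float(eta[ev].sum() - np.log(r0).sum())
    mean1 = r1 / r0[:, None]
    score = (x[ev] - mean1).sum(axis=0)
    info = (r2 / r0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", mean1, mean1)
    return loglik, score, info


def _efron_quantities(beta, x, time, event):
    """Log partial likelihood, score vector and information matrix (Efron ties)."""
    n, p = x.shape
    if len(np.unique(time)) == n:
        return _untied_quantities(beta, x, time, event)
    order = np.argsort(time, kind="stable")
    x = x[order]
    time = time[order]
    event = event[order]
    eta = x @ beta
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = np.einsum("i,ij,ik->ijk", w, x, x)
    # suffix sums: risk set at t = all with time >= t
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = np.flatnonzero(event[i:j]) + i
        d = len(deaths)
        if d > 0:
            sum_w_d = w[deaths].sum()
            sum_wx_d = wx[deaths].sum(axis=0)
            sum_wxx_d = wxx[deaths].sum(axis=0)
            loglik += eta[deaths].sum()
            for r in range(d):
                frac = r / d
                denom = s0[i] - frac * sum_w_d
                num1 = s1[i] - frac * sum_wx_d
                num2 = s2[i] - frac * sum_wxx_d
                loglik -= np.log(denom)
                score -= num1 / denom
                info += num2 / denom - np.outer(num1, num1) / denom**2
            score += x[deaths].sum(axis=0)
        i = j
    return loglik, score, info


def cox_fit(covariates, time, event, max_iter: int = 50, tol: float = 1e-8) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the Efron partial likelihood.

    ``covariates`` may be a DataFrame, Series, or array (n or n x p).
    Raises on constant covariates; monotone-likelihood divergence is flagged
    and the coefficient capped rather than left to run away.
    """
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        x = covariates.to_numpy(dtype=float)
    elif isinstance(covariates, pd.Series):
        names = [str(covariates.name or "x")]
        x = covariates.to_numpy(dtype=float)[:, None]
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.isfinite(x).all():
        raise ValueError("covariates must be finite")
    if event.sum() < 2:
        raise ValueError("cox_fit requires at least 2 events")
    if (x.std(axis=0) == 0).any():
        raise ValueError("constant covariate")

    # center for numerical stability; beta is unaffected
    center = x.mean(axis=0)
    xc = x - center

    beta = np.zeros(x.shape[1])
    converged = False
    separation = False
    for _ in range(max_iter):
        _, score, info = _efron_quantities(beta, xc, time, event)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > _BETA_CAP:
            separation = True
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            logger.warning("cox_fit: monotone likelihood suspected; beta capped at ±%g", _BETA_CAP)
            break
    _, _, info = _efron_quantities(beta, xc, time, event)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(x.shape[1], np.nan)
    return CoxFit(names, beta, se, n=len(time), n_events=int(event.sum()), converged=converged, separation=separation)


def univariate_screen(zscores, genes, time, event, p_max: float = 0.05):
    """Per-gene univariate Cox fits on z-scored expression.

    Returns ``(risk_genes, protective_genes, table)``; genes with p < ``p_max``
    are partitioned by HR > 1 versus HR < 1 (HR exactly 1 joins neither list).
    Fit failures are excluded and logged.
    """
    data = zscores.data if hasattr(zscores, "data") else zscores
    genes = [str(g).upper() for g in genes]
    present = [g for g in genes if g in data.index]
    if len(present) < len(genes):
        logger.warning("univariate_screen: %d genes absent from matrix", len(genes) - len(present))
    rows = []
    for g in present:
        x = data.loc[g].to_numpy(dtype=float)
        try:
            fit = cox_fit(x[:, None], time, event)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("univariate_screen: fit failed for %s (%s)", g, exc)
            continue
        rows.append((g, fit.beta[0], fit.hr[0], fit.se[0], fit.p[0]))
    table = pd.DataFrame(rows, columns=["gene", "beta", "hr", "se", "p"]).set_index("gene")
    sig = table[table["p"] < p_max]
    risk = sorted(sig.index[sig["hr"] > 1.0])
    protective = sorted(sig.index[sig["hr"] < 1.0])
    n_boundary = int((sig["hr"] == 1.0).sum())
    if n_boundary:
        logger.info("univariate_screen: %d significant genes with HR exactly 1 assigned to neither list", n_boundary)
    return risk, protective, table


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival
    chi2: float
    p: float
    df: int


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, survival) step table."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    out_t, out_s = [0.0], [1.0]
    s = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1.0 - d / at_risk
        out_t.append(float(t))
        out_s.append(s)
    return pd.DataFrame({"time": out_t, "survival": out_s})


def _logrank_oe(groups, time, event):
    """Observed, expected and covariance of event counts per group."""
    labels = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq = sorted(pd.unique(labels))
    g = len(uniq)
    idx = {lab: i for i, lab in enumerate(uniq)}
    gi = np.array([idx[lab] for lab in labels])
    observed = np.zeros(g)
    expected = np.zeros(g)
    cov = np.zeros((g, g))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = ((time == t) & (event == 1)).sum()
        n_g = np.bincount(gi[at_risk], minlength=g).astype(float)
        d_g = np.bincount(gi[(time == t) & (event == 1)], minlength=g).astype(float)
        observed += d_g
        expected += d_t * n_g / n_t
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1)
            p_g = n_g / n_t
            cov += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    return uniq, observed, expected, cov


def km_logrank(groups, time, event) -> KMResult:
    """Kaplan-Meier curves per group plus the k-group log-rank test."""
    labels = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("km_logrank requires >= 2 groups")
    for lab in uniq:
        if (labels == lab).sum() == 0:
            raise ValueError(f"group {lab!r} empty")
    if event.sum() < 1:
        raise ValueError("no events observed")
    curves = {str(lab): km_curve(time[labels == lab], event[labels == lab]) for lab in uniq}
    uniq, observed, expected, cov = _logrank_oe(labels, time, event)
    g = len(uniq)
    diff = (observed - expected)[: g - 1]
    sub = cov[: g - 1, : g - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(sub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(sub) @ diff)
    df = g - 1
    p = float(stats.chi2.sf(chi2, df))
    return KMResult(curves, chi2, p, df)


def logrank_z(mask, time, event) -> float:
    """Standardized two-group log-rank statistic (O - E)/sqrt(V) for group ``mask``.

    Fully vectorized (hypergeometric variance with tie correction); used in the
    inner loop of :func:`maxstat_cutpoint`.
    """
    mask = np.asarray(mask, dtype=bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    ev = event == 1
    uniq_t, inv = np.unique(time[ev], return_inverse=True)
    d_t = np.bincount(inv).astype(float)
    d_a = np.bincount(inv, weights=mask[ev].astype(float))
    sorted_all = np.sort(time)
    n_t = n - np.searchsorted(sorted_all, uniq_t, side="left")
    sorted_a = np.sort(time[mask])
    na_t = mask.sum() - np.searchsorted(sorted_a, uniq_t, side="left")
    p_a = na_t / n_t
    expected = float((d_t * p_a).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = np.where(n_t > 1, d_t * (n_t - d_t) / np.maximum(n_t - 1, 1) * p_a * (1 - p_a), 0.0)
    v = float(var_t.sum())
    if v <= 0:
        return 0.0
    return float((d_a.sum() - expected) / np.sqrt(v))


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float  # |standardized log-rank| at the cutoff
    n_low: int
    n_high: int


def maxstat_cutpoint(score, time, event, min_group_fraction: float = 0.1) -> CutpointResult:
    """Maximally selected rank-statistic cutpoint.

    Scans every midpoint of consecutive distinct score values whose induced
    split leaves both groups with at least ``min_group_fraction`` of the
    samples, and returns the cutoff maximizing the absolute standardized
    log-rank statistic (ties resolved toward the lower cutoff).
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(score)
    if n < 10:
        raise ValueError("maxstat_cutpoint requires >= 10 samples")
    distinct = np.unique(score)
    if len(distinct) < 2:
        raise ValueError("score is constant; no cutpoint exists")
    min_n = min_group_fraction * n
    best: CutpointResult | None = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        high = score > cut
        n_high = int(high.sum())
        n_low = n - n_high
        if n_low < min_n or n_high < min_n:
            continue
        stat = abs(logrank_z(high, time, event))
        if best is None or stat > best.statistic + 1e-12:
            best = CutpointResult(cut, stat, n_low, n_high)
    if best is None:
        raise ValueError("no admissible cutpoint under the group-size constraint")
    return best


def roc_auc(score, outcome) -> float:
    """Area under the ROC curve via the rank formulation (ties count half)."""
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    pos = outcome == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(score)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
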