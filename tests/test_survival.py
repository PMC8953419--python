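import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from m6ascore.survival import (
    _efron_quantities,
    cox_fit,
    km_curve,
    km_logrank,
    logrank_z,
    maxstat_cutpoint,
    roc_auc,
    univariate_screen,
)


def grid_mle_1d(x, time, event, lo=-4.0, hi=4.0, steps=20001):
    """Independent 1-D brute-force maximization of the partial likelihood."""
    xc = (x - x.mean())[:, None]
    grid = np.linspace(lo, hi, steps)
    lls = [_efron_quantities(np.array([b]), xc, time, event)[0] for b in grid]
    return grid[int(np.argmax(lls))]


class TestCoxFit:
    def test_toy_matches_grid_oracle(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        fit = cox_fit(x, t, e)
        oracle = grid_mle_1d(x, t, e)
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-3)
        assert fit.beta[0] == pytest.approx(0.94, abs=0.01)
        assert fit.hr[0] == pytest.approx(2.56, abs=0.01)

    @pytest.mark.parametrize("seed", range(8))
    def test_small_no_ties_instances_match_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        x = rng.normal(size=n)
        t = rng.exponential(size=n)
        e = rng.integers(0, 2, n)
        if e.sum() < 2:
            e[:2] = 1
        fit = cox_fit(x, t, e)
        if fit.separation or abs(fit.beta[0]) > 10:
            pytest.skip("monotone/quasi-monotone likelihood instance")
        oracle = grid_mle_1d(x, t, e, lo=fit.beta[0] - 1, hi=fit.beta[0] + 1)
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-3)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(size=(n, 2))
        t = np.ceil(rng.exponential(np.exp(-(0.8 * x[:, 0] - 0.5 * x[:, 1]))) * 5)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        df = pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e")
        fit = cox_fit(pd.DataFrame(x, columns=["x0", "x1"]), t, e)
        np.testing.assert_allclose(fit.beta, ref.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-6)

    def test_matches_lifelines_no_ties(self):
        rng = np.random.default_rng(4)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.7 * x))
        e = np.ones(n, dtype=int)
        ref = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        fit = cox_fit(x, t, e)
        assert fit.beta[0] == pytest.approx(ref.params_.iloc[0], abs=1e-6)

    def test_covariate_rescaling(self):
        rng = np.random.default_rng(5)
        n = 50
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(n, dtype=int)
        f1 = cox_fit(x, t, e)
        f2 = cox_fit(10.0 * x, t, e)
        assert f2.beta[0] == pytest.approx(f1.beta[0] / 10.0, rel=1e-6)
        assert f2.p[0] == pytest.approx(f1.p[0], rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones(10), np.arange(1.0, 11.0), np.ones(10, dtype=int))

    def test_separation_flagged_and_capped(self, caplog):
        # perfect separation: all deaths at low x, all censored at high x
        x = np.array([0.0, 0.1, 0.2, 0.3, 5.0, 5.1, 5.2, 5.3])
        t = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        fit = cox_fit(x, t, e)
        assert fit.separation
        assert abs(fit.beta[0]) <= 20.0
        assert any("monotone" in r.message for r in caplog.records)

    def test_summary_invariants(self):
        rng = np.random.default_rng(6)
        n = 40
        x = rng.normal(size=n)
        t = rng.exponential(size=n)
        e = np.ones(n, dtype=int)
        s = cox_fit(x, t, e).summary()
        assert (s["hr"] > 0).all()
        assert (s["ci_low"] <= s["ci_high"]).all()
        assert s["p"].between(0, 1).all()


class TestUnivariateScreen:
    def test_null_retention_near_alpha(self):
        rng = np.random.default_rng(0)
        n, n_genes = 150, 300
        data = pd.DataFrame(
            rng.normal(size=(n_genes, n)),
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n)],
        )
        t = rng.exponential(size=n)
        e = rng.integers(0, 2, n)
        risk, prot, table = univariate_screen(data, list(data.index), t, e)
        frac = (len(risk) + len(prot)) / n_genes
        assert 0.01 < frac < 0.10

    def test_planted_sign_recovery(self):
        rng = np.random.default_rng(1)
        n = 200
        risk_x = rng.normal(size=(5, n))
        prot_x = rng.normal(size=(5, n))
        lin = risk_x.sum(axis=0) - prot_x.sum(axis=0)
        t = rng.exponential(np.exp(-0.5 * lin))
        e = np.ones(n, dtype=int)
        data = pd.DataFrame(
            np.vstack([risk_x, prot_x]),
            index=[f"R{i}" for i in range(5)] + [f"P{i}" for i in range(5)],
            columns=[f"S{j}" for j in range(n)],
        )
        risk, prot, _ = univariate_screen(data, list(data.index), t, e)
        planted_risk = {f"R{i}" for i in range(5)}
        planted_prot = {f"P{i}" for i in range(5)}
        assert set(risk) <= planted_risk and set(prot) <= planted_prot  # no sign flips
        assert len(risk) + len(prot) >= 9  # at most one planted gene missed

    def test_absent_genes_logged(self, caplog):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(2, 30)), index=["A", "B"], columns=[f"S{j}" for j in range(30)])
        univariate_screen(data, ["A", "B", "MISSING"], rng.exponential(size=30), np.ones(30, dtype=int))
        assert any("absent" in r.message for r in caplog.records)


class TestKMLogrank:
    def test_hand_case(self):
        res = km_logrank(["A", "A", "B", "B"], [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert res.chi2 == pytest.approx(2.882, abs=1e-3)
        assert res.p == pytest.approx(0.0896, abs=1e-3)

    def test_identical_groups(self):
        t = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        e = np.ones(10, dtype=int)
        res = km_logrank(["a"] * 5 + ["b"] * 5, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(7)
        n = 60
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.exp(-0.8 * g))
        e = rng.integers(0, 2, n)
        e[:4] = 1
        res = km_logrank(g, t, e)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        n = 40
        g = np.array(["x"] * 20 + ["y"] * 20)
        t = rng.exponential(size=n)
        e = np.ones(n, dtype=int)
        r1 = km_logrank(g, t, e)
        g2 = np.where(g == "x", "y", "x")
        r2 = km_logrank(g2, t, e)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_km_no_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(size=25)
        curve = km_curve(t, np.ones(25, dtype=int))
        for _, row in curve.iloc[1:].iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean(), abs=1e-12)

    def test_km_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(size=40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        curve = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in curve.iterrows():
            assert row["survival"] == pytest.approx(kmf.predict(row["time"]), abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(["a", "a"], [1.0, 2.0], [1, 1])


def naive_maxstat(score, time, event, min_group_fraction=0.1):
    """Independent exhaustive scan re-deriving the cutpoint with naive loops."""
    distinct = sorted(set(score))
    n = len(score)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        high = np.asarray(score) > cut
        if high.sum() < min_group_fraction * n or (n - high.sum()) < min_group_fraction * n:
            continue
        # two-group log-rank from first principles
        o = e_exp = v = 0.0
        for t in sorted({time[i] for i in range(n) if event[i] == 1}):
            at = [i for i in range(n) if time[i] >= t]
            d = sum(1 for i in at if time[i] == t and event[i] == 1)
            n1 = sum(1 for i in at if high[i])
            nt = len(at)
            o += sum(1 for i in at if high[i] and time[i] == t and event[i] == 1)
            e_exp += d * n1 / nt
            if nt > 1:
                v += d * (nt - d) / (nt - 1) * (n1 / nt) * (1 - n1 / nt)
        stat = abs((o - e_exp) / np.sqrt(v)) if v > 0 else 0.0
        if best is None or stat > best[1] + 1e-12:
            best = (cut, stat)
    return best


class TestMaxstatCutpoint:
    def test_perfect_separation_midpoint(self):
        score = np.array([1.0, 2.0, 3.0, 4.0] * 3)
        time = np.where(score > 2, 1.0, 100.0) + np.arange(12) * 0.01
        event = np.where(score > 2, 1, 0)
        res = maxstat_cutpoint(score, time, event, min_group_fraction=0.1)
        assert res.cutoff == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        score = np.round(rng.normal(size=n), 2)
        time = rng.exponential(np.exp(-0.4 * score))
        event = rng.integers(0, 2, n)
        event[:5] = 1
        res = maxstat_cutpoint(score, time, event)
        cut, stat = naive_maxstat(score, time, event)
        assert res.cutoff == pytest.approx(cut, abs=1e-12)
        assert res.statistic == pytest.approx(stat, abs=1e-9)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            maxstat_cutpoint(np.ones(20), np.arange(1.0, 21.0), np.ones(20, dtype=int))

    def test_group_size_constraint(self):
        score = np.array([1.0] * 19 + [2.0])
        time = np.arange(1.0, 21.0)
        event = np.ones(20, dtype=int)
        with pytest.raises(ValueError, match="admissible"):
            maxstat_cutpoint(score, time, event, min_group_fraction=0.1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == pytest.approx(1.0)

    def test_hand_case(self):
        # positives {2,4}, negatives {1,3}: 3 of 4 pairs concordant
        assert roc_auc([2, 4, 1, 3], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        assert roc_auc(s, y) == pytest.approx(1.0 - roc_auc(s, 1 - y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        s = rng.normal(size=100)
        y = (rng.uniform(size=100) < stats.norm.cdf(s)).astype(int)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_logrank_z_consistent_with_chi2():
    rng = np.random.default_rng(11)
    n = 50
    g = rng.integers(0, 2, n).astype(bool)
    t = rng.exponential(size=n)
    e = rng.integers(0, 2, n)
    e[:3] = 1
    z = logrank_z(g, t, e)
    res = km_logrank(g.astype(int), t, e)
    assert z**2 == pytest.approx(res.chi2, rel=1e-9)
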