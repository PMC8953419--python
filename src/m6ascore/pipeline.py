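"""End-to-end orchestration: simulate -> preprocess -> cluster -> model -> score
-> survival -> enrich -> drugs, from a single config, with a hashed manifest.

A single global seed is fanned out to per-stage sub-seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))`` so adding a
stage never perturbs the randomness of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import consensus_cluster, select_k
from .enrichment import enrich_collection
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    RunConfig,
    read_clinical,
    read_drug_table,
    read_expression,
    read_gmt,
    setup_logging,
    write_clinical,
    write_drug_table,
    write_expression,
    write_gmt,
)
from .preprocess import filter_low_count, gene_zscore, normalize_log
from .scoring import (
    apply_m6avalue,
    build_m6avalue_model,
    drug_sensitivity_screen,
    load_regulator_panel,
    stratify_by_cutpoint,
    weighted_regulator_signature,
)
from .simulate import SimulationParams, fixture_gene_sets, simulate_cell_lines, simulate_cohort

logger = logging.getLogger("m6ascore")

_STAGE_INDEX = {
    "simulate": 0,
    "preprocess": 1,
    "cluster": 2,
    "model": 3,
    "score": 4,
    "survival": 5,
    "enrich": 6,
    "drugs": 7,
}


def stage_seed(seed: int, stage: str) -> int:
    """Counter-based per-stage sub-seed derived from the global seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0])


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str = __version__
    files: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[path.name] = digest

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "files": self.files,
            "timings": self.timings,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _config_snapshot(config: RunConfig) -> dict:
    snap = {}
    for name in RunConfig.__dataclass_fields__:
        value = getattr(config, name)
        snap[name] = value
    return snap


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every configured stage, writing fixed-name outputs to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "run.log")
    manifest = RunManifest(seed=config.seed, config=_config_snapshot(config))

    def timed(stage, fn):
        t0 = _time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage label is the contract
            logger.error("stage %s failed: %s", stage, exc)
            raise StageError(stage, exc) from exc
        manifest.timings[stage] = _time.perf_counter() - t0
        return result

    # ---- simulate or load ------------------------------------------------
    fixture_sets = None
    cell_truth = None
    if config.simulate is not None:
        def _simulate():
            sim_cfg = dict(config.simulate or {})
            cell_cfg = sim_cfg.pop("cell_lines", None)
            params = SimulationParams(seed=stage_seed(config.seed, "simulate"), **sim_cfg)
            cohort = simulate_cohort(params)
            write_expression(cohort.counts, out / "expression.tsv")
            write_clinical(cohort.clinical, out / "clinical.tsv")
            cohort.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.10g")
            sets = fixture_gene_sets(cohort.gene_roles, seed=stage_seed(config.seed, "simulate"))
            write_gmt(sets, out / "fixture_sets.gmt")
            cells = None
            if cell_cfg:
                expr_cl, drug, truth_cl = simulate_cell_lines(
                    n_lines=cell_cfg.get("n_lines", 100),
                    n_compounds=cell_cfg.get("n_compounds", 10),
                    link_strengths=cell_cfg.get("link_strengths", [0.0] * cell_cfg.get("n_compounds", 10)),
                    seed=stage_seed(config.seed, "simulate") + 1,
                    params=params,
                )
                write_expression(expr_cl, out / "cell_line_expression.tsv")
                write_drug_table(drug, out / "drug_response.tsv")
                cells = (expr_cl, drug, truth_cl)
            return cohort, sets, cells

        cohort, fixture_sets, cells = timed("simulate", _simulate)
        counts, clinical = cohort.counts, cohort.clinical
        cell_expr, drug_table = (cells[0], cells[1]) if cells else (None, None)
        cell_truth = cells[2] if cells else None
        for name in ("expression.tsv", "clinical.tsv", "truth.tsv", "fixture_sets.gmt"):
            manifest.record(out / name)
        if cells:
            manifest.record(out / "cell_line_expression.tsv")
            manifest.record(out / "drug_response.tsv")
    else:
        if config.expression is None:
            raise StageError("load", ValueError("config.expression is required when simulate is disabled"))
        counts = read_expression(config.expression, "counts")
        clinical = read_clinical(config.clinical) if config.clinical else None
        cell_expr = read_expression(config.cell_line_expression, "counts") if config.cell_line_expression else None
        drug_table = read_drug_table(config.drug_table) if config.drug_table else None

    # ---- preprocess ------------------------------------------------------
    def _preprocess():
        filtered = filter_low_count(counts, config.min_count, config.min_fraction)
        normalized = normalize_log(filtered)
        return filtered, normalized, gene_zscore(normalized)

    filtered, normalized, zmat = timed("preprocess", _preprocess)

    # ---- consensus clustering on the regulator panel ---------------------
    panel = load_regulator_panel(config.regulator_panel)

    def _cluster():
        severity = weighted_regulator_signature(zmat, panel)
        results = {
            k: consensus_cluster(
                zmat,
                panel["gene"],
                k,
                n_resamples=config.n_resamples,
                subsample_fraction=config.subsample_fraction,
                seed=stage_seed(config.seed, "cluster") + k,
                severity=severity.to_numpy(),
            )
            for k in config.k_range
        }
        k_best = select_k(results)
        best = results[k_best]
        frame = pd.DataFrame({"cluster": best.assignments, "regulator_signature": severity})
        frame.index.name = "sample_id"
        frame.to_csv(out / "clusters.tsv", sep="\t", float_format="%.10g")
        cm = best.consensus_matrix.copy()
        cm.index.name = "sample_id"
        cm.to_csv(out / f"consensus_k{k_best}.tsv", sep="\t", float_format="%.10g")
        return best, k_best

    best, k_best = timed("cluster", _cluster)
    manifest.record(out / "clusters.tsv")
    manifest.record(out / f"consensus_k{k_best}.tsv")
    labels = best.assignments.map(lambda c: f"C{c}")

    # ---- survival-complete subset ---------------------------------------
    if clinical is None:
        raise StageError("model", ValueError("clinical table required for model construction"))
    surv = clinical.survival_subset()
    common = [s for s in normalized.sample_ids if s in surv.index]
    expr_surv = ExpressionMatrix(normalized.data[common], normalized.scale)
    time_v = surv.loc[common, "time_months"].to_numpy()
    event_v = surv.loc[common, "event"].to_numpy().astype(int)

    # ---- differential genes + prognostic model ---------------------------
    def _model():
        model = build_m6avalue_model(
            expr_surv,
            labels.loc[common].to_numpy(),
            time_v,
            event_v,
            fdr_max=config.deg_fdr,
            fc_min=config.deg_fc,
            p_max=config.cox_p,
        )
        degs = pd.concat(
            [t.table.assign(contrast=t.contrast) for t in model.contrast_tables],
            axis=0,
        )
        degs.index.name = "gene"
        degs.to_csv(out / "degs.tsv", sep="\t", float_format="%.10g")
        model.to_frame().to_csv(out / "model.tsv", sep="\t", index=False, float_format="%.10g")
        return model

    model = timed("model", _model)
    manifest.record(out / "degs.tsv")
    manifest.record(out / "model.tsv")

    # ---- scoring ---------------------------------------------------------
    def _score():
        scores = apply_m6avalue(model, normalized, standardization=config.standardization)
        scores["regulator_signature"] = weighted_regulator_signature(zmat, panel)
        scores["cluster"] = labels
        return scores

    scores = timed("score", _score)

    # ---- survival stratification ----------------------------------------
    def _survival():
        sc = scores.loc[common]
        covars = surv.loc[common, ["grade", "stage"]].astype(float)
        covars = covars.dropna(axis=1, how="any")
        covars = covars.loc[:, covars.std() > 0] if not covars.empty else None
        strat = stratify_by_cutpoint(sc, time_v, event_v, covariates=covars if covars is not None and not covars.empty else None)
        scores.loc[common, "group"] = strat.scores["group"]
        scores.fillna({"group": ""}, inplace=True)
        scores.index.name = "sample_id"
        scores.to_csv(out / "scores.tsv", sep="\t", float_format="%.10g")
        rows = [
            ("cutoff", strat.cutoff),
            ("logrank_chi2", strat.km.chi2),
            ("logrank_p", strat.logrank_p),
            ("auc", strat.auc),
        ]
        summary = pd.DataFrame(rows, columns=["quantity", "value"])
        if strat.multivariate is not None:
            multi = strat.multivariate.summary().reset_index(names="covariate")
            multi.insert(0, "quantity", "multivariate_cox")
            summary = pd.concat([summary, multi], axis=0)
        summary.to_csv(out / "survival.tsv", sep="\t", index=False, float_format="%.10g")
        km_rows = []
        for grp, curve in strat.km.curves.items():
            c = curve.copy()
            c.insert(0, "group", grp)
            km_rows.append(c)
        pd.concat(km_rows).to_csv(out / "km.tsv", sep="\t", index=False, float_format="%.10g")
        (out / "cutpoint.txt").write_text(f"{strat.cutoff:.10g}\n")
        return strat

    timed("survival", _survival)
    for name in ("scores.tsv", "survival.tsv", "km.tsv", "cutpoint.txt"):
        manifest.record(out / name)

    # ---- enrichment ------------------------------------------------------
    collections = {}
    if fixture_sets is not None:
        collections["fixture"] = fixture_sets
    for path in config.gene_sets:
        collections[Path(path).stem] = read_gmt(path)

    if collections:
        def _enrich():
            frames = []
            for cname, coll in collections.items():
                em = enrich_collection(normalized, coll, zscore_rows=False)
                block = em.scores.copy()
                block.insert(0, "collection", cname)
                frames.append(block)
            combined = pd.concat(frames)
            combined.index.name = "signature"
            combined.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.10g")

        timed("enrich", _enrich)
        manifest.record(out / "enrichment.tsv")

    # ---- drug screen -----------------------------------------------------
    if cell_expr is not None and drug_table is not None:
        def _drugs():
            filtered_cl = filter_low_count(cell_expr, config.min_count, config.min_fraction)
            norm_cl = normalize_log(filtered_cl)
            cl_scores = apply_m6avalue(model, norm_cl, standardization="refit")["m6avalue"]
            table = drug_sensitivity_screen(cl_scores, drug_table, r_min=config.drug_r, p_max=config.drug_p)
            table.to_csv(out / "drugs.tsv", sep="\t", float_format="%.10g")
            return table

        timed("drugs", _drugs)
        manifest.record(out / "drugs.tsv")

    manifest.write(out / "manifest.json")
    return manifest


def summarize(run_dir) -> str:
    """Deterministic plain-text report of the main outputs of a completed run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{manifest_path} not found; is this a completed run directory?")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"run summary (seed {manifest['seed']}, version {manifest['version']})", ""]

    clusters = pd.read_csv(run_dir / "clusters.tsv", sep="\t", index_col=0)
    sizes = clusters["cluster"].value_counts().sort_index()
    lines.append("cluster sizes: " + ", ".join(f"C{k}={v}" for k, v in sizes.items()))

    model = pd.read_csv(run_dir / "model.tsv", sep="\t")
    n_risk = int((model["weight_sign"] == 1).sum())
    n_prot = int((model["weight_sign"] == -1).sum())
    lines.append(f"model: {len(model)} genes ({n_risk} risk, {n_prot} protective)")

    degs = pd.read_csv(run_dir / "degs.tsv", sep="\t")
    lines.append(f"differential calls: {int(degs['significant'].sum())} across {degs['contrast'].nunique()} contrasts")

    survival = pd.read_csv(run_dir / "survival.tsv", sep="\t")
    for q in ("cutoff", "logrank_p", "auc"):
        row = survival[survival["quantity"] == q]
        if not row.empty:
            lines.append(f"{q}: {float(row['value'].iloc[0]):.6g}")

    drugs_path = run_dir / "drugs.tsv"
    if drugs_path.exists():
        drugs = pd.read_csv(drugs_path, sep="\t")
        retained = drugs[drugs["retained"]]
        lines.append(f"retained drugs: {len(retained)} of {len(drugs)}")
        for _, row in retained.iterrows():
            lines.append(f"  {row['compound']}: r={row['spearman_r']:.3f} ({row['label']})")
    else:
        lines.append("drug stage: skipped")

    report = "\n".join(lines) + "\n"
    (run_dir / "summary.txt").write_text(report)
    return report
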