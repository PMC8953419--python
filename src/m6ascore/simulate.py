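"""Synthetic cohort generator with planted cluster, survival and drug-response structure.

Counts are negative-binomial with cluster-shifted means for the regulator
panel and score-linked means for phenotype genes, so that every downstream
stage (clustering, DEG calling, Cox screening, scoring, enrichment, the drug
screen) has recoverable ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .scoring import load_regulator_panel

logger = logging.getLogger("m6ascore")

# fraction of phenotype genes allotted to each planted role
_ROLE_SPLIT = (("risk", 0.30), ("protective", 0.20), ("immune", 0.35), ("stroma", 0.15))


@dataclass
class SimulationParams:
    """Knobs of the cohort generator; defaults give a clearly recoverable cohort."""

    n_samples: int = 300
    cluster_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_regulators: int = 24
    n_phenotype_genes: int = 300
    n_noise_genes: int = 500
    regulator_effect: float = 1.0  # log2 shift per cluster step
    # own-signature strength of the middle cluster (x regulator_effect); the
    # default sqrt(3) places the three cluster centres at the vertices of an
    # equilateral triangle, so no 2-cluster merge is privileged
    middle_cluster_shift: float = 1.7320508075688772
    phenotype_effect: float = 1.0  # log2 shift per unit planted score
    dispersion: float = 0.2
    hazard_coefficient: float = 0.5
    baseline_hazard: float = 0.02  # events per month at score 0
    censoring_fraction: float = 0.5
    library_sigma: float = 0.3
    score_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must lie in [0,1)")
        n_clusters = len(self.cluster_proportions)
        if self.n_samples < 3 * n_clusters:
            raise ValueError(f"need at least {3 * n_clusters} samples for {n_clusters} clusters")


@dataclass
class SimulatedCohort:
    counts: ExpressionMatrix
    clinical: ClinicalTable
    sample_truth: pd.DataFrame  # columns cluster, score
    gene_roles: pd.Series  # gene -> role label

    def truth_frame(self) -> pd.DataFrame:
        """Long-form truth table (samples then genes) for truth.tsv."""
        samples = self.sample_truth.reset_index().rename(columns={"index": "id"})
        samples.insert(0, "kind", "sample")
        genes = self.gene_roles.rename("role").reset_index().rename(columns={"index": "id"})
        genes.insert(0, "kind", "gene")
        return pd.concat([samples, genes], ignore_index=True)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _phenotype_roles(n_genes: int) -> list[tuple[str, int]]:
    counts = []
    assigned = 0
    for role, frac in _ROLE_SPLIT[:-1]:
        k = int(round(frac * n_genes))
        counts.append((role, k))
        assigned += k
    counts.append((_ROLE_SPLIT[-1][0], n_genes - assigned))
    return counts


def _gene_table(params: SimulationParams) -> tuple[pd.Series, pd.Series]:
    """Gene roles and per-unit-score log2 directions; regulators use panel symbols."""
    panel = load_regulator_panel()
    if params.n_regulators > len(panel):
        raise ValueError(f"at most {len(panel)} panel regulators available")
    reg = panel.iloc[: params.n_regulators]
    names = list(reg["gene"])
    roles = [f"regulator-{'up' if s > 0 else 'down'}" for s in reg["weight_sign"]]
    directions = list(reg["weight_sign"].astype(float))
    for role, count in _phenotype_roles(params.n_phenotype_genes):
        for i in range(count):
            names.append(f"{role.upper()[:4]}{i + 1:04d}")
            roles.append(role)
            directions.append(1.0 if role == "risk" else -1.0)
    for i in range(params.n_noise_genes):
        names.append(f"NOIS{i + 1:04d}")
        roles.append("noise")
        directions.append(0.0)
    return pd.Series(roles, index=names, name="role"), pd.Series(directions, index=names)


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Draw a cohort with three latent clusters, planted score and linked survival.

    The planted aggressiveness score is the centred cluster index plus noise;
    regulator means shift along the cluster axis (positively weighted genes up,
    negatively weighted down), risk genes rise and protective/immune/stroma
    genes fall with the score, and survival is exponential with hazard
    proportional to ``exp(hazard_coefficient * score)``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    n_clusters = len(params.cluster_proportions)

    # deterministic per-cluster counts (largest-remainder rounding), shuffled
    # assignment: realized sizes honour the proportions exactly
    raw = np.asarray(params.cluster_proportions) * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    clusters = rng.permutation(np.repeat(np.arange(n_clusters), sizes))
    score = (clusters - (n_clusters - 1) / 2.0) + rng.normal(0.0, params.score_noise_sd, n)

    roles, directions = _gene_table(params)
    genes = roles.index
    n_genes = len(genes)

    base_mean = np.exp(rng.normal(np.log(50.0), 1.0, n_genes))
    is_reg = roles.str.startswith("regulator").to_numpy()
    # common base mean for the panel keeps per-gene noise scales comparable,
    # so the three cluster centres sit on a near-exact equilateral triangle
    base_mean[is_reg] = 100.0
    lib_factor = np.exp(rng.normal(0.0, params.library_sigma, n))

    axis = np.where(is_reg[:, None], (clusters - (n_clusters - 1) / 2.0)[None, :], score[None, :])
    effect = np.where(is_reg, params.regulator_effect, params.phenotype_effect)
    dirs = directions.to_numpy()
    log2_shift = dirs[:, None] * effect[:, None] * axis
    # the middle cluster carries its own signature along a +/- regulator
    # pattern chosen orthogonal to the weight-sign direction (balanced within
    # each sign group), so it is a genuine third mode rather than a point on
    # the C1-C3 segment
    if n_clusters == 3 and params.middle_cluster_shift != 0:
        orth = np.zeros(n_genes)
        for sign in (1.0, -1.0):
            idx = np.flatnonzero(is_reg & (dirs == sign))
            half = len(idx) // 2
            orth[idx[:half]] = 1.0
            orth[idx[half : 2 * half]] = -1.0
        in_middle = (clusters == 1).astype(float)
        log2_shift += params.regulator_effect * params.middle_cluster_shift * orth[:, None] * in_middle[None, :]
    mu = base_mean[:, None] * np.exp2(log2_shift) * lib_factor[None, :]

    counts = _nb_draw(rng, mu, params.dispersion)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids, dtype=float)

    hazard = params.baseline_hazard * np.exp(params.hazard_coefficient * score)
    latent = rng.exponential(1.0 / hazard)
    if params.censoring_fraction > 0:
        cut = np.quantile(latent, 1.0 - params.censoring_fraction)
        event = (latent <= cut).astype(int)
        time = np.minimum(latent, cut)
    else:
        event = np.ones(n, dtype=int)
        time = latent
    time = np.maximum(time, 1e-6)

    grade = np.clip(np.rint(6 + clusters + rng.normal(0, 1.0, n)), 6, 10).astype(int)
    stage = np.clip(np.rint(1 + 0.7 * clusters + rng.normal(0, 0.8, n)), 1, 4).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {"time_months": time, "event": event, "grade": grade, "stage": stage},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    sample_truth = pd.DataFrame(
        {"cluster": [f"C{c + 1}" for c in clusters], "score": score},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SimulatedCohort(ExpressionMatrix(counts_df, "counts"), clinical, sample_truth, roles)


def simulate_cell_lines(
    n_lines: int,
    n_compounds: int,
    link_strengths,
    seed: int = 0,
    params: SimulationParams | None = None,
):
    """Cell-line panel: expression tied to a planted score, IC50 linearly linked per compound.

    ``link_strengths`` holds one value in [-1, 1] per compound; the observed
    IC50 is ``ls * score + sqrt(1 - ls^2) * noise`` so the population
    correlation with the planted score is approximately ``ls``.
    """
    link_strengths = np.asarray(link_strengths, dtype=float)
    if link_strengths.shape != (n_compounds,):
        raise ValueError("need one link strength per compound")
    if (np.abs(link_strengths) > 1).any():
        raise ValueError("link strengths must lie in [-1, 1]")
    if params is None:
        params = SimulationParams()
    rng = np.random.default_rng(seed)

    score = rng.normal(0.0, 1.0, n_lines)
    roles, directions = _gene_table(params)
    genes = roles.index
    base_mean = np.exp(rng.normal(np.log(50.0), 1.0, len(genes)))
    lib_factor = np.exp(rng.normal(0.0, params.library_sigma, n_lines))
    effect = np.where(roles.str.startswith("regulator"), params.regulator_effect, params.phenotype_effect)
    log2_shift = directions.to_numpy()[:, None] * effect[:, None] * score[None, :]
    mu = base_mean[:, None] * np.exp2(log2_shift) * lib_factor[None, :]
    counts = _nb_draw(rng, mu, params.dispersion)
    line_ids = [f"CL{i + 1:04d}" for i in range(n_lines)]
    expr = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=line_ids, dtype=float), "counts")

    rows = []
    for j in range(n_compounds):
        ls = link_strengths[j]
        noise = rng.normal(0.0, 1.0, n_lines)
        ic50 = ls * score + np.sqrt(max(0.0, 1.0 - ls**2)) * noise
        for i, line in enumerate(line_ids):
            rows.append((line, f"DRUG{j + 1:02d}", ic50[i]))
    from .io import DrugResponseTable

    drug = DrugResponseTable(pd.DataFrame(rows, columns=["cell_line", "compound", "ic50"]))
    truth = pd.DataFrame({"score": score}, index=pd.Index(line_ids, name="cell_line"))
    return expr, drug, truth


def fixture_gene_sets(
    gene_roles: pd.Series,
    n_til: int = 28,
    n_steps: int = 7,
    min_role_genes: int = 5,
    seed: int = 0,
) -> GeneSetCollection:
    """Stand-in signature collections built from the planted gene roles.

    One set per role (omitted below ``min_role_genes`` members), ``n_til``
    disjoint pseudo-TIL sets partitioning a subset of the immune genes, and
    ``n_steps`` pseudo-immunity-step sets sampled from the immune genes.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for role in sorted(gene_roles.unique()):
        members = sorted(gene_roles.index[gene_roles == role])
        if len(members) < min_role_genes:
            logger.warning("fixture_gene_sets: role %r has %d genes (<%d), set omitted", role, len(members), min_role_genes)
            continue
        name = f"ROLE_{role.upper().replace('-', '_')}"
        sets[name] = members
        descriptions[name] = f"planted {role} genes"

    immune = sorted(gene_roles.index[gene_roles == "immune"])
    if not immune:
        logger.warning("fixture_gene_sets: no immune-role genes; TIL and step sets omitted")
    else:
        shuffled = list(immune)
        rng.shuffle(shuffled)
        per_set = max(1, len(shuffled) // n_til)
        if per_set * n_til > len(shuffled):
            logger.warning("fixture_gene_sets: only %d immune genes for %d TIL sets", len(shuffled), n_til)
        for i in range(n_til):
            chunk = shuffled[i * per_set : (i + 1) * per_set]
            if not chunk:
                break
            name = f"TIL{i + 1:02d}"
            sets[name] = sorted(chunk)
            descriptions[name] = "pseudo TIL subpopulation"
        step_size = max(2, len(immune) // 10)
        for s in range(n_steps):
            members = sorted(rng.choice(immune, size=min(step_size, len(immune)), replace=False))
            name = f"STEP{s + 1}"
            sets[name] = [str(m) for m in members]
            descriptions[name] = "pseudo immunity-cycle step"
    return GeneSetCollection(sets, descriptions)
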