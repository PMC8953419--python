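"""Readers/writers for the external artifacts of a run.

Expression tables, clinical tables, GMT gene-set collections, long-format
drug-response tables and the YAML run configuration.  All gene symbols are
uppercased on load so downstream matching is case-insensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("m6ascore")

VALID_SCALES = ("counts", "normalized", "log2", "zscore")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into a typed table."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with a declared measurement scale.

    Parameters
    ----------
    data:
        DataFrame indexed by unique gene symbols with unique sample columns.
    scale:
        One of ``counts``, ``normalized``, ``log2``, ``zscore``.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.scale == "counts" and (values < 0).any():
            raise ValueError("counts-scale matrix contains negative entries")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Case-insensitive gene subset; absent genes dropped with a log entry."""
        wanted = [str(g).upper() for g in genes]
        present = [g for g in wanted if g in self.data.index]
        missing = len(wanted) - len(present)
        if missing:
            logger.warning("subset_genes: %d of %d requested genes absent from matrix", missing, len(wanted))
        return ExpressionMatrix(self.data.loc[present], self.scale)


def read_expression(path, scale: str) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column = gene symbol).

    Duplicate gene symbols are collapsed to the row with the highest mean
    expression; the number collapsed is logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty expression file") from exc
    if df.empty:
        raise ParseError(f"{path}: empty expression file")
    df.index = df.index.astype(str).str.upper()
    # locate non-numeric cells before coercion so the error names them
    coerced = df.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().to_numpy().any() and not df.isna().to_numpy().any():
        bad = np.argwhere(coerced.isna().to_numpy() & ~df.isna().to_numpy())
        r, c = bad[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if coerced.isna().to_numpy().any():
        bad = np.argwhere(coerced.isna().to_numpy())
        r, c = bad[0]
        raise ParseError(f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    df = coerced
    if df.index.duplicated().any():
        n_before = len(df)
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        # restore original relative gene order
        df = df.loc[[g for g in coerced.index.unique() if g in df.index]]
        logger.warning("read_expression: collapsed %d duplicate gene rows (kept max-mean row)", n_before - len(df))
    return ExpressionMatrix(df, scale)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates with survival time in months."""

    data: pd.DataFrame  # index sample_id; columns time_months, event, grade, stage

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        t = self.data["time_months"]
        if (t.dropna() <= 0).any():
            raise ValueError("survival time must be > 0")
        ev = self.data["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def survival_subset(self) -> pd.DataFrame:
        """Rows usable for survival analysis (time and event present)."""
        ok = self.data["time_months"].notna() & self.data["event"].notna()
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("survival_subset: excluded %d samples lacking time/event", n_dropped)
        return self.data.loc[ok]


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: clinical table missing columns {sorted(missing)}")
    for col in ("grade", "stage"):
        if col not in df.columns:
            df[col] = np.nan
    df = df.set_index("sample_id")
    return ClinicalTable(df[["time_months", "event", "grade", "stage"]])


def write_clinical(table: ClinicalTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions; symbols uppercased."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3")
            name, desc, *members = fields
            seen: list[str] = []
            for m in members:
                m = m.strip().upper()
                if m and m not in seen:
                    seen.append(m)
            sets[name] = seen
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


@dataclass
class DrugResponseTable:
    """Long-format (cell line, compound, IC50) table; missing IC50 permitted."""

    data: pd.DataFrame  # columns cell_line, compound, ic50

    def __post_init__(self) -> None:
        if self.data.duplicated(subset=["cell_line", "compound"]).any():
            raise ValueError("duplicate (cell_line, compound) pairs in drug table")

    def compounds(self) -> list[str]:
        return sorted(self.data["compound"].unique())

    def pairs_for(self, compound: str) -> pd.DataFrame:
        sub = self.data[self.data["compound"] == compound]
        return sub.dropna(subset=["ic50"]).set_index("cell_line")


def read_drug_table(path) -> DrugResponseTable:
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "compound": str})
    required = {"cell_line", "compound", "ic50"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: drug table missing columns {sorted(missing)}")
    df["ic50"] = pd.to_numeric(df["ic50"], errors="coerce")
    return DrugResponseTable(df[["cell_line", "compound", "ic50"]].reset_index(drop=True))


def write_drug_table(table: DrugResponseTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Run-wide configuration: paths, thresholds, clustering parameters, seed."""

    seed: int = 0
    out_dir: str = "run"
    expression: str | None = None
    clinical: str | None = None
    drug_table: str | None = None
    cell_line_expression: str | None = None
    regulator_panel: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    deg_fdr: float = 0.05
    deg_fc: float = 2.0
    cox_p: float = 0.05
    drug_r: float = 0.1
    drug_p: float = 0.05
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    min_count: int = 3
    min_fraction: float = 1.0 / 3.0
    standardization: str = "refit"
    simulate: dict | None = None

    def __post_init__(self) -> None:
        for name in ("deg_fdr", "cox_p", "drug_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0,1]")
        if self.standardization not in ("refit", "frozen"):
            raise ValueError("standardization must be 'refit' or 'frozen'")


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def setup_logging(log_path=None, level=logging.INFO) -> logging.Logger:
    """Attach a stream handler (and optional file handler) to the package logger."""
    logger.setLevel(level)
    if log_path is not None:
        for h in list(logger.handlers):
            if isinstance(h, logging.FileHandler):
                logger.removeHandler(h)
                h.close()
        handler = logging.FileHandler(log_path)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    return logger
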