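"""Tabular readers/writers, configuration and run logging shared by all stages.

All pipeline tables are plain :class:`pandas.DataFrame` objects with fixed
column sets, validated on read:

* trait table   — ``genotype, trait, condition, timepoint, replicate, value``
* DE table      — ``contrast, gene, log2fc, fdr``
* expression    — wide gene x sample FPKM matrix plus a sample->group map

Writers emit deterministic CSV/TSV: fixed column order, floats at 6
significant digits, and a comment header carrying the seed and config hash so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRAIT_COLUMNS = ["genotype", "trait", "condition", "timepoint", "replicate", "value"]
DE_COLUMNS = ["contrast", "gene", "log2fc", "fdr"]
CONDITIONS = ("control", "salt")


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ValidationError(ValueError):
    """Table content violates an invariant (duplicates, out-of-range values)."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Thresholds and toggles for every pipeline stage.

    Defaults are the study-stated construction choices: DEG calling at
    FDR <= 0.05 and |log2FC| >= 1 (2-fold), the rule-3/4 gap delta = 0.6,
    expression floor FPKM 5, soft power 12, minimum module size 30,
    eigengene merge cutoff 0.25, module-group screening at |r| > 0.6 and
    p < 0.05, and an 80% cumulative-variance target for component selection.
    """

    fdr_max: float = 0.05
    min_abs_log2fc: float = 1.0
    delta_log2fc: float = 0.6
    fpkm_min: float = 5.0
    soft_power: int = 12
    min_module_size: int = 30
    merge_cutoff: float = 0.25
    module_r_min: float = 0.6
    module_p_max: float = 0.05
    variance_target: float = 0.80
    membership_level: str = "component"  # or "trait"
    linkage: str = "ward"  # genotype grading linkage
    rules: tuple = (1, 2, 3, 4)
    clip: bool = False
    allow_missing: bool = False
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.fdr_max <= 1:
            raise ValidationError("fdr_max must be in (0, 1]")
        if not 0 < self.variance_target <= 1:
            raise ValidationError("variance_target must be in (0, 1]")
        if self.min_abs_log2fc < 0 or self.delta_log2fc < 0:
            raise ValidationError("log2fc thresholds must be nonnegative")
        if self.membership_level not in ("component", "trait"):
            raise ValidationError("membership_level must be 'component' or 'trait'")
        if self.linkage not in ("ward", "average", "complete"):
            raise ValidationError("linkage must be ward|average|complete")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "rules" in data:
            data["rules"] = tuple(data["rules"])
        return cls(**data)

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# delimiter handling


def _sep_for(path, sep=None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


# ---------------------------------------------------------------------------
# readers


def read_trait_table(path, schema: dict | None = None, sep: str | None = None,
                     allow_missing: bool = False) -> pd.DataFrame:
    """Read and validate a genotype x trait measurement table.

    ``schema`` maps file column names to the canonical names; identity
    mapping by default.  Enforces uniqueness of
    (genotype, trait, condition, timepoint, replicate), finite values, and
    that every (genotype, trait, timepoint) seen under salt also exists
    under control (the salt-tolerance ratio is undefined otherwise).
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep), comment="#")
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trait table missing column(s): {missing}")
    df = df[TRAIT_COLUMNS].copy()
    return validate_trait_table(df, allow_missing=allow_missing)


def validate_trait_table(df: pd.DataFrame, allow_missing: bool = False) -> pd.DataFrame:
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValidationError(f"unknown condition label(s): {sorted(bad_cond)}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna()
    if bad.any():
        raise ValidationError(
            f"non-numeric trait value at row index {int(df.index[bad][0])}")
    if df["value"].isna().any():
        if not allow_missing:
            raise ValidationError("missing trait values (enable allow_missing to average over present replicates)")
        df = df.dropna(subset=["value"])
    df = df.assign(value=vals[df.index].astype(float),
                   replicate=df["replicate"].astype(int))
    if not np.isfinite(df["value"]).all():
        raise ValidationError("non-finite trait value")
    key = ["genotype", "trait", "condition", "timepoint", "replicate"]
    dup = df.duplicated(key)
    if dup.any():
        raise ValidationError(
            f"duplicate measurement key: {df.loc[dup, key].iloc[0].tolist()}")
    # every salt cell must have a control counterpart
    cells = df.groupby(["genotype", "trait", "timepoint", "condition"]).size().unstack(
        "condition", fill_value=0)
    if "salt" in cells and ((cells["salt"] > 0) & (cells.get("control", 0) == 0)).any():
        orphan = cells[(cells["salt"] > 0) & (cells.get("control", 0) == 0)].index[0]
        raise ValidationError(f"salt measurement without control counterpart: {orphan}")
    return df.reset_index(drop=True)


def read_de_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a differential-expression table (one row per
    contrast x gene, with log2 fold change and FDR)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), comment="#")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"DE table missing column(s): {missing}")
    df = df[DE_COLUMNS].copy()
    return validate_de_table(df)


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.assign(log2fc=df["log2fc"].astype(float), fdr=df["fdr"].astype(float))
    if not np.isfinite(df["log2fc"]).all():
        raise ValidationError("non-finite log2fc")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any() or df["fdr"].isna().any():
        raise ValidationError("fdr outside [0, 1]")
    dup = df.duplicated(["contrast", "gene"])
    if dup.any():
        raise ValidationError(
            f"duplicate (contrast, gene): {df.loc[dup, ['contrast', 'gene']].iloc[0].tolist()}")
    return df.reset_index(drop=True)


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with one group label per sample."""

    fpkm: pd.DataFrame           # index = genes, columns = samples
    groups: pd.Series            # index = samples, values = group labels

    def __post_init__(self):
        self.fpkm = self.fpkm.astype(float)
        if (self.fpkm.values < 0).any():
            raise ValidationError("negative FPKM")
        missing = set(self.fpkm.columns) - set(self.groups.index)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.fpkm.columns)]

    def __eq__(self, other):
        return (isinstance(other, ExpressionMatrix)
                and self.fpkm.equals(other.fpkm)
                and self.groups.equals(other.groups))


def read_expression(matrix_path, sample_sheet_path, sep: str | None = None) -> ExpressionMatrix:
    """Read a gene x sample FPKM CSV (first column = gene id) and a sample
    sheet with columns ``sample, group``."""
    fpkm = pd.read_csv(matrix_path, sep=_sep_for(matrix_path, sep), comment="#",
                       index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep=_sep_for(sample_sheet_path, sep),
                        comment="#")
    if not {"sample", "group"} <= set(sheet.columns):
        raise SchemaError("sample sheet needs columns: sample, group")
    groups = sheet.set_index("sample")["group"]
    return ExpressionMatrix(fpkm=fpkm, groups=groups)


# ---------------------------------------------------------------------------
# writers


def _format_float(x) -> str:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return ""
        return f"{x:.6g}"
    return str(x)


def write_table(df: pd.DataFrame, path, *, seed: int | None = None,
                config_hash: str | None = None, sep: str | None = None,
                index: bool = False) -> Path:
    """Write a tabular result deterministically.

    Column order is preserved as given; floats are rendered at 6 significant
    digits; a ``#`` comment header records the seed and config hash so the
    provenance of every artifact is in the file itself.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = _sep_for(path, sep)
    buf = _io.StringIO()
    if config_hash is not None:
        buf.write(f"# config={config_hash}\n")
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    out = df.copy()
    if index:
        out = out.reset_index()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_format_float)
    out.to_csv(buf, sep=sep, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())
    return path


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class RunLog:
    """JSON-lines run log: one record per stage with params and counts."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text("")

    def record(self, stage: str, **fields):
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"stage": stage, **fields}, sort_keys=True) + "\n")
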