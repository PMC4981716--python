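"""Tabular I/O, unit handling and pipeline configuration.

The canonical tabular dialect is TSV with an optional leading comment line
``#units: col=unit col=unit ...`` declaring per-column units; CSV is
accepted.  Schemas map column names to expected dtypes; unit-tagged
quantities (currently kLa) are normalized to the package's canonical units
on load, with the conversion recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .reactor_kinetics import GasLiquidParams


class TableError(ValueError):
    """Structured table validation failure listing each offending cell."""

    def __init__(self, path, problems):
        self.path = str(path)
        self.problems = list(problems)
        lines = "\n".join(f"  - {p}" for p in self.problems)
        super().__init__(f"invalid table {path}:\n{lines}")


#: column dtype schemas for the pipeline's input tables
SCHEMAS = {
    "steady_state": {"organism": str, "Ii": float, "D": float, "mu": float,
                     "OD730": float, "x": float, "O2_uM": float, "pH": float},
    "trace": {"time_s": float, "F": float, "phase": str},
    "rlc": {"PAR": float, "F": float, "Fm_prime": float},
    "annotation": {"gene": str, "level": str, "category": str},
    "cells": {"cell_id": str, "a_um": float, "b_um": float,
              "condition": float},
}


def _read_units_header(path: Path) -> dict:
    units = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#units:"):
        for tok in first[len("#units:"):].split():
            if "=" in tok:
                col, unit = tok.split("=", 1)
                units[col] = unit
    return units


def read_table(path, schema=None, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV table, validating against a schema if given.

    ``schema`` is either a key of :data:`SCHEMAS` or a column->dtype dict.
    Missing columns and non-numeric cells are reported together in a
    :class:`TableError`, with 1-based data line numbers.  Declared units are
    attached as ``df.attrs["units"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    units = _read_units_header(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    problems = []
    if schema:
        missing = [c for c in schema if c not in df.columns]
        problems += [f"missing column {c!r}" for c in missing]
        for col, dtype in schema.items():
            if col in missing or dtype is str:
                continue
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            problems += [f"non-numeric value {df.at[i, col]!r} in column "
                         f"{col!r} at data line {i + 1}" for i in bad]
            if len(bad) == 0:
                df[col] = coerced.astype(float)
    if problems:
        raise TableError(path, problems)
    df.attrs["units"] = units
    return df


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x conditions RPKM matrix: first column gene id, remaining
    columns condition labels.  Duplicate gene ids are an error."""
    df = read_table(path)
    gene_col = df.columns[0]
    dup = df[gene_col][df[gene_col].duplicated()].unique().tolist()
    if dup:
        raise TableError(path, [f"duplicate gene id {g!r}" for g in dup])
    out = df.set_index(gene_col)
    out.index.name = "gene"
    bad = [c for c in out.columns
           if not pd.api.types.is_numeric_dtype(out[c])]
    if bad:
        raise TableError(path, [f"non-numeric expression column {c!r}"
                                for c in bad])
    if (out.values < 0).any():
        raise TableError(path, ["negative RPKM values present"])
    return out


def write_table(df: pd.DataFrame, path, units: dict | None = None) -> None:
    """Write a TSV with an optional ``#units:`` header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        if units:
            fh.write("#units: " + " ".join(f"{c}={u}"
                                           for c, u in units.items()) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def load_gas_params(source) -> GasLiquidParams:
    """Gas-liquid parameters from a YAML/JSON file path or a dict.

    Accepts ``kla_unit: per_minute`` to tag a per-minute kLa; stored
    internally in h^-1.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = (json.loads(text) if str(source).endswith(".json")
                else yaml.safe_load(text))
    else:
        data = dict(source)
    allowed = {"kla", "kH", "pO2_in", "O2_in", "kla_unit"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown gas parameter(s): {sorted(unknown)}")
    return GasLiquidParams(**data)


@dataclass
class PipelineConfig:
    """Paths and options for a full pipeline run."""

    outdir: str = "photoacclim_out"
    seed: int = 0
    steady_state_table: str | None = None
    gas_params: dict = field(default_factory=lambda: {
        "kla": 0.83, "kla_unit": "per_minute", "kH": 1.08,
        "pO2_in": 0.0, "O2_in": 0.0})
    trace_table: str | None = None
    rlc_table: str | None = None
    expression_table: str | None = None
    annotation_table: str | None = None
    cell_table: str | None = None
    fit_model: str = "auto"
    regime_delta: float = 0.25
    cluster_k: int = 6
    n_major: int = 4
    filter_quantile: float = 0.20
    filter_policy: str = "all"
    pseudocount: float = 1.0
    enrichment_alpha: float = 0.05
    enrichment_universe: str = "expressed"  # or "annotation"
    rcef_window_s: float = 10.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in
                               cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
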