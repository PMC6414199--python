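"""Schema-validated CSV readers/writers for the pipeline's table formats.

All on-disk formats are plain CSV (inspectable, diffable); fit results and
run reports are JSON.  Each table schema lists required columns, a coercible
dtype per column, and row-level invariants; :func:`validate_table` reports
every violation with its row index so a bad export fails loudly before any
analysis runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchemaError
from .synthgen import DecayHistogram

__all__ = ["SCHEMAS", "ValidationReport", "validate_table", "validate_dataframe",
           "read_roi_table", "read_decay_histograms", "write_json", "read_json"]


def _nonneg(s):
    return s >= 0


def _positive(s):
    return s > 0


def _unit_interval(s):
    return (s >= 0) & (s <= 1)


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict          # column -> dtype kind ("num", "int", "str")
    invariants: dict       # column -> (description, vectorized predicate)


SCHEMAS: dict[str, TableSchema] = {
    "roi": TableSchema(
        "roi",
        columns={
            "donor_intensity": "num",
            "acceptor_intensity": "num",
            "mean_lifetime_ns": "num",
            "photon_count": "int",
            "condition": "str",
            "replicate_id": "str",
        },
        invariants={
            "donor_intensity": (">= 0", _nonneg),
            "acceptor_intensity": (">= 0", _nonneg),
            "mean_lifetime_ns": ("> 0", _positive),
            "photon_count": (">= 0", _nonneg),
        },
    ),
    "decay": TableSchema(
        "decay",
        columns={"t_low_ns": "num", "t_high_ns": "num", "counts": "int"},
        invariants={"counts": (">= 0", _nonneg)},
    ),
    "titration": TableSchema(
        "titration",
        columns={"conc_nM": "num", "response": "num", "replicate_id": "str"},
        invariants={"conc_nM": (">= 0", _nonneg)},
    ),
    "quench": TableSchema(
        "quench",
        columns={"quencher_M": "num", "fluorescence": "num", "condition": "str"},
        invariants={"quencher_M": (">= 0", _nonneg), "fluorescence": ("> 0", _positive)},
    ),
    "cells": TableSchema(
        "cells",
        columns={
            "tmre_total": "num",
            "nuclear_area": "num",
            "nuclear_roundness": "num",
            "cell_area": "num",
            "cell_roundness": "num",
            "venus_mean": "num",
            "venus_median": "num",
            "mito_mean": "num",
            "well_id": "str",
            "replicate_id": "str",
            "control_label": "str",
        },
        invariants={
            "nuclear_area": ("> 0", _positive),
            "cell_area": ("> 0", _positive),
            "nuclear_roundness": ("in [0, 1]", _unit_interval),
            "cell_roundness": ("in [0, 1]", _unit_interval),
        },
    ),
    "pixels": TableSchema(
        "pixels",
        columns={
            "object_id": "str",
            "replicate_id": "str",
            "channel_a": "num",
            "channel_b": "num",
            "bg_a": "num",
            "bg_b": "num",
        },
        invariants={},
    ),
}


@dataclass
class ValidationReport:
    schema: str
    path: str
    issues: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_dict(self) -> dict:
        return {"schema": self.schema, "path": self.path,
                "n_issues": len(self.issues), "issues": self.issues}


def validate_dataframe(df: pd.DataFrame, schema_name: str, path: str = "<memory>") -> ValidationReport:
    """Check a DataFrame against a named schema; never raises for data issues."""
    if schema_name not in SCHEMAS:
        raise ConfigurationError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    report = ValidationReport(schema=schema_name, path=str(path))

    for col, kind in schema.columns.items():
        if col not in df.columns:
            report.issues.append({"type": "missing_column", "column": col})
            continue
        if kind in ("num", "int"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            for idx in df.index[bad][:50]:
                report.issues.append(
                    {"type": "type_violation", "column": col, "row": int(idx),
                     "value": repr(df.loc[idx, col])}
                )

    for col, (desc, pred) in schema.invariants.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        ok = pred(vals) | vals.isna()
        for idx in df.index[~ok][:50]:
            report.issues.append(
                {"type": "invariant_violation", "column": col, "row": int(idx),
                 "constraint": desc, "value": float(vals.loc[idx])}
            )
    return report


def validate_table(path: str | Path, schema_name: str) -> ValidationReport:
    """Read a CSV and validate it against a named schema."""
    path = Path(path)
    df = pd.read_csv(path)
    return validate_dataframe(df, schema_name, path=str(path))


def read_roi_table(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if validate:
        report = validate_dataframe(df, "roi", path=str(path))
        if not report.ok:
            first = report.issues[0]
            raise SchemaError(f"ROI table {path} failed validation ({len(report.issues)} issues); "
                              f"first: {first}")
    return df


def read_decay_histograms(path: str | Path) -> list[DecayHistogram]:
    """Read a (possibly multi-pixel) decay-histogram CSV."""
    df = pd.read_csv(path)
    report = validate_dataframe(df, "decay", path=str(path))
    if not report.ok:
        raise SchemaError(f"decay table {path} failed validation; first issue: {report.issues[0]}")
    groups = df.groupby("pixel_id", sort=True) if "pixel_id" in df.columns else [(None, df)]
    out = []
    for pid, grp in groups:
        grp = grp.sort_values("t_low_ns")
        edges = np.append(grp["t_low_ns"].to_numpy(float), grp["t_high_ns"].to_numpy(float)[-1])
        out.append(DecayHistogram(bin_edges=edges, counts=grp["counts"].to_numpy(int),
                                  pixel_id=None if pid is None else int(pid)))
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
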