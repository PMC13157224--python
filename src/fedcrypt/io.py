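"""Cohort-table readers and structured result writers.

CSV/TSV tables with a header row; the delimiter is sniffed. Result records
are JSON with a provenance block (seed, parameter fingerprint, backend) so
every run is reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("fedcrypt")

__all__ = [
    "SchemaError",
    "read_cohort_csv",
    "write_results",
    "write_forest_data",
    "provenance_block",
]


class SchemaError(ValueError):
    """Input table missing required columns or empty."""


PHENOTYPE_COLUMNS = {"id", "sex", "sbp", "dbp", "htn_history"}


def detect_separator(path) -> str:
    """Comma/tab detection from the header line (the csv sniffer cannot
    handle single-column or empty files)."""
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise SchemaError(f"{path} is empty")
    return "\t" if "\t" in header else ","


def _required_columns(kind: str, columns) -> set[str]:
    if kind == "phenotype":
        return set(PHENOTYPE_COLUMNS)
    if kind == "genomic":
        pgs = {c for c in columns if str(c).startswith("pgs_")}
        if not pgs:
            raise SchemaError("genomic table needs at least one pgs_* column")
        return {"id"} | pgs
    raise ValueError(f"unknown table kind: {kind}")


def read_cohort_csv(path, kind: str = "phenotype") -> pd.DataFrame:
    """Read a cohort table (comma or tab separated, sniffed).

    Malformed rows (unparseable numerics, missing required fields) are
    dropped with a logged count, available as ``df.attrs['n_dropped']``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=detect_separator(path))
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty") from exc
    if df.empty and df.columns.empty:
        raise SchemaError(f"{path} has no header row")
    required = _required_columns(kind, df.columns)
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path} missing required columns: {sorted(missing)}")

    n_before = len(df)
    if kind == "phenotype":
        for col in ("sbp", "dbp"):
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        df["htn_history"] = df["htn_history"].map(
            {
                True: True, False: False, "True": True, "False": False,
                "true": True, "false": False, 1: True, 0: False, "1": True,
                "0": False,
            }
        )
        df["sex"] = df["sex"].where(df["sex"].isin(["male", "female"]))
    else:
        for col in (c for c in required if c.startswith("pgs_")):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=sorted(required)).reset_index(drop=True)
    if df["id"].duplicated().any():
        raise SchemaError(f"{path} has duplicate participant ids")
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d malformed row(s)", path, n_dropped)
    df.attrs["n_dropped"] = n_dropped
    return df


def provenance_block(seed, backend: str = "reference", **params) -> dict:
    fp = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {
        "seed": seed,
        "backend": backend,
        "params": params,
        "params_fingerprint": fp,
    }


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(result, path, provenance: dict | None = None) -> dict:
    """Write a statistic/result record as JSON (with provenance)."""
    record = {"result": _jsonable(result)}
    if provenance is not None:
        record["provenance"] = _jsonable(provenance)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2) + "\n")
    return record


def write_forest_data(meta, studies, path, provenance: dict | None = None) -> dict:
    """Forest-plot data export (JSON only, no plotting): pooled effects,
    CIs, heterogeneity, and per-study rows with weights standardized to
    sum to 100%."""
    meta_d = _jsonable(meta)
    wf = meta_d.get("weights_fixed") or []
    wr = meta_d.get("weights_random") or []
    rows = []
    for i, study in enumerate(studies):
        row = dict(_jsonable(study))
        if i < len(wf):
            row["weight_fixed_pct"] = 100.0 * wf[i]
        if i < len(wr):
            row["weight_random_pct"] = 100.0 * wr[i]
        rows.append(row)
    record = {"pooled": meta_d, "studies": rows}
    if provenance is not None:
        record["provenance"] = _jsonable(provenance)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2) + "\n")
    return record
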