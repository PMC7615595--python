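"""Cohort/config readers and writers and report serialization.

All tabular I/O is CSV (UTF-8, header row, one row per participant, missing
values as empty fields); reports are JSON.  Numeric columns are coerced on
read: unparseable entries become missing with a logged count (or raise in
strict mode).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schema import MANDATORY_COLS, RAW_NUMERIC_COLS

logger = logging.getLogger(__name__)


def write_cohort(df: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_cohort(path, strict=False) -> pd.DataFrame:
    """Read a cohort CSV into typed columns.

    Unknown extra columns are kept with a warning; missing mandatory columns
    raise; unparseable numerics become missing (counted) unless ``strict``.
    """
    df = pd.read_csv(path, dtype=object)
    missing = [c for c in MANDATORY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing mandatory columns: {missing}")
    extra = [c for c in df.columns if c not in MANDATORY_COLS]
    if extra:
        logger.warning("cohort file has unrecognized columns (kept as-is): %s", extra)
    numeric_cols = ["age", "mid_year", "weight_sample"] + RAW_NUMERIC_COLS
    n_bad = 0
    for col in numeric_cols:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        n_bad += int(bad.sum())
        df[col] = coerced
    if n_bad:
        msg = f"{n_bad} unparseable numeric values set to missing"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    for col in ("med_antihypertensive", "med_statin", "med_oral_hypoglycemic",
                "med_insulin", "hist_mi", "hist_stroke", "hist_chf"):
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    df["age"] = df["age"].astype(float)
    return df


def write_json(obj, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
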