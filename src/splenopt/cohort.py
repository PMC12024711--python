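"""Cohort table schema and I/O.

A cohort is a flat :class:`pandas.DataFrame` with one row per patient:
admission covariates, a three-level ``treatment`` column and a binary
``death`` (in-hospital mortality) outcome.  Synthetic cohorts additionally
carry oracle risk columns (``p_obs``, ``p_ae``, ``p_splen``) holding the
true per-arm mortality probabilities; these are excluded from every model
feature list by name.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError

#: Treatment arms in fixed column order. OBS = observation (non-operative
#: management), AE = splenic angioembolization, SPLENECTOMY = surgical removal.
ARMS: tuple[str, ...] = ("OBS", "AE", "SPLENECTOMY")

TREATMENT_COL = "treatment"
DEATH_COL = "death"

#: True per-arm mortality risks, written by the synthetic generator only.
ORACLE_RISK_COLS: tuple[str, ...] = ("p_obs", "p_ae", "p_splen")

#: Columns never offered to nuisance or policy models.
NON_FEATURE_COLS: tuple[str, ...] = (TREATMENT_COL, DEATH_COL) + ORACLE_RISK_COLS

SCHEMA_VERSION = "splenopt-cohort-v1"


def validate_cohort(df: pd.DataFrame, require_outcome: bool = True) -> None:
    """Check the minimal analysis contract: treatment / death present and complete.

    Raises :class:`SchemaError` naming the offending column.
    """
    if TREATMENT_COL not in df.columns:
        raise SchemaError(f"cohort is missing required column '{TREATMENT_COL}'")
    bad = set(df[TREATMENT_COL].dropna()) - set(ARMS)
    if bad:
        raise SchemaError(f"unknown treatment levels {sorted(bad)}; expected {ARMS}")
    if df[TREATMENT_COL].isna().any():
        raise SchemaError(f"column '{TREATMENT_COL}' contains missing values")
    if require_outcome:
        if DEATH_COL not in df.columns:
            raise SchemaError(f"cohort is missing required column '{DEATH_COL}'")
        if df[DEATH_COL].isna().any():
            raise SchemaError(f"column '{DEATH_COL}' contains missing values")
        vals = set(pd.unique(df[DEATH_COL]))
        if not vals <= {0, 1}:
            raise SchemaError(f"column '{DEATH_COL}' must be binary 0/1, found {sorted(vals)}")
    if "spleen_grade" in df.columns:
        g = df["spleen_grade"].dropna()
        if len(g) and not g.isin([1, 2, 3, 4, 5]).all():
            raise SchemaError("column 'spleen_grade' must be an integer in 1..5")


def feature_names(df: pd.DataFrame, exclude: tuple[str, ...] = ()) -> list[str]:
    """Numeric columns usable as model features (oracle/outcome columns dropped)."""
    drop = set(NON_FEATURE_COLS) | set(exclude)
    return [
        c for c in df.columns
        if c not in drop and pd.api.types.is_numeric_dtype(df[c])
    ]


def write_cohort_csv(df: pd.DataFrame, path: str | Path, data_dictionary: dict | None = None) -> None:
    """Write a cohort CSV with a versioned header comment and a sidecar data dictionary."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)
    if data_dictionary is not None:
        sidecar = path.with_suffix(path.suffix + ".dict.json")
        sidecar.write_text(json.dumps(data_dictionary, indent=2, sort_keys=True))


def read_cohort_csv(path: str | Path, require_outcome: bool = True) -> pd.DataFrame:
    """Read a cohort CSV (versioned comment header tolerated) and validate it."""
    df = pd.read_csv(path, comment="#")
    validate_cohort(df, require_outcome=require_outcome)
    return df
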