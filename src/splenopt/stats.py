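"""Descriptive cohort statistics and derived features.

Implements the registry-style "Table 1" summaries: per-arm counts and
percentages for binary/categorical variables, median (IQR) for continuous
ones, the shock index (heart rate / systolic blood pressure), and the
hemodynamic stratification at SBP 70 mmHg used to define the two modelling
cohorts.

Quartiles everywhere use linear interpolation on the inclusive empirical
distribution (numpy's default ``linear`` method); group percentages use the
variable's non-missing denominator within each group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ARMS, DEATH_COL, TREATMENT_COL
from .errors import SchemaError, UndefinedValueError


def shock_index(hr, sbp):
    """Shock index = heart rate / systolic blood pressure.

    Accepts scalars or aligned arrays. SBP must be strictly positive;
    non-positive SBP raises :class:`UndefinedValueError` rather than
    returning an infinity. Values above ~1 indicate hemodynamic compromise.
    """
    hr_a = np.asarray(hr, dtype=float)
    sbp_a = np.asarray(sbp, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(sbp_a[~np.isnan(sbp_a)] <= 0):
            raise UndefinedValueError("shock index undefined for sbp <= 0")
    out = hr_a / sbp_a
    if np.isscalar(hr) and np.isscalar(sbp):
        return float(out)
    return out


def add_shock_index(df: pd.DataFrame, out_col: str = "shock_index") -> pd.DataFrame:
    """Return a copy of *df* with a shock-index column (NaN where sbp missing)."""
    for col in ("hr", "sbp"):
        if col not in df.columns:
            raise SchemaError(f"cannot derive shock index: missing column '{col}'")
    df = df.copy()
    df[out_col] = shock_index(df["hr"].to_numpy(), df["sbp"].to_numpy())
    return df


@dataclass(frozen=True)
class StratumDefinition:
    """A two-way stratification on one numeric variable.

    Rows with ``variable < threshold`` form the low stratum, ``>= threshold``
    the high stratum; rows missing the variable belong to neither.
    """

    variable: str = "sbp"
    threshold: float = 70.0
    low_label: str = "SBP < 70 mmHg"
    high_label: str = "SBP >= 70 mmHg"


SBP70 = StratumDefinition()


def stratify(df: pd.DataFrame, strat: StratumDefinition = SBP70) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into (low, high) strata; missing values fall in neither."""
    if strat.variable not in df.columns:
        raise SchemaError(f"stratification variable '{strat.variable}' not in cohort")
    v = df[strat.variable]
    low = df[v < strat.threshold]
    high = df[v >= strat.threshold]
    return low, high


def treatment_distribution(df: pd.DataFrame) -> pd.DataFrame:
    """Per-arm counts and percentages (1 d.p.), counts summing to n."""
    if len(df) == 0:
        raise UndefinedValueError("treatment distribution undefined for an empty cohort")
    if TREATMENT_COL not in df.columns or df[TREATMENT_COL].isna().any():
        raise SchemaError(f"'{TREATMENT_COL}' column must be present and complete")
    counts = df[TREATMENT_COL].value_counts().reindex(ARMS, fill_value=0)
    pct = (100.0 * counts / counts.sum()).round(1)
    return pd.DataFrame({"n": counts.astype(int), "percent": pct})


def observed_mortality(df: pd.DataFrame) -> float:
    """Crude in-hospital mortality: deaths / rows."""
    if len(df) == 0:
        raise UndefinedValueError("observed mortality undefined for an empty cohort")
    if DEATH_COL not in df.columns or df[DEATH_COL].isna().any():
        raise SchemaError(f"'{DEATH_COL}' column must be present and complete")
    return float(df[DEATH_COL].mean())


def _is_binary(s: pd.Series) -> bool:
    vals = set(pd.unique(s.dropna()))
    return vals <= {0, 1}


def _median_iqr(s: pd.Series) -> str:
    x = s.dropna().to_numpy(dtype=float)
    if x.size == 0:
        return "NA"
    med, q1, q3 = np.percentile(x, [50, 25, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def _count_pct(s: pd.Series, level=None) -> str:
    x = s.dropna()
    if len(x) == 0:
        return "NA"
    k = int((x == 1).sum()) if level is None else int((x == level).sum())
    return f"{k} ({100.0 * k / len(x):.1f}%)"


def describe(df: pd.DataFrame, variables: list[str], by_arm: bool = True) -> pd.DataFrame:
    """Table-1-shaped summary: count (%) for binary/categorical, median (IQR) for continuous.

    Categorical variables (more than two levels, few distinct integer values,
    e.g. splenic AAST grade) expand to one row per level. Percentages use the
    group's non-missing denominator for each variable.
    """
    for v in variables:
        if v not in df.columns:
            raise SchemaError(f"unknown variable '{v}'")
    groups: dict[str, pd.DataFrame] = {"Total": df}
    if by_arm and TREATMENT_COL in df.columns:
        for arm in ARMS:
            groups[arm] = df[df[TREATMENT_COL] == arm]
    rows = {}
    for v in variables:
        s = df[v]
        if _is_binary(s):
            rows[v] = {g: _count_pct(gdf[v]) for g, gdf in groups.items()}
        elif (s.dropna().nunique() <= 6
              and pd.api.types.is_integer_dtype(s.dropna().infer_objects())
              and s.max() - s.min() <= 6):
            for level in sorted(s.dropna().unique()):
                rows[f"{v}={level:g}"] = {
                    g: _count_pct(gdf[v], level) for g, gdf in groups.items()
                }
        else:
            rows[v] = {g: _median_iqr(gdf[v]) for g, gdf in groups.items()}
    return pd.DataFrame(rows).T[list(groups)]
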