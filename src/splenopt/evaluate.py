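"""Policy evaluation and paper-style reporting.

The headline quantity is the held-out doubly-robust policy value: the mean,
over test-half rows, of the AIPW mortality score of the arm the policy
prescribes. It is compared with the observed mortality of the same rows
(current practice) and broken down per leaf: for each terminal leaf, the
number of patients who actually received each arm and their crude observed
death rate — plain ratios of in-leaf events, no modelling. An empty
leaf-arm cell is reported as NA, never 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import ARMS, DEATH_COL, TREATMENT_COL
from .errors import AlignmentError
from .rewards import NuisanceModels, RewardMatrix
from .stats import observed_mortality  # re-exported: part of this module's surface
from .tree import PolicyTree

__all__ = [
    "policy_value_dr",
    "observed_mortality",
    "leaf_report",
    "PolicyValueReport",
    "build_report",
]


def _prescribed_arm_idx(policy: PolicyTree, rows: pd.DataFrame) -> np.ndarray:
    pres = policy.prescribe(rows)
    return pres.map({a: i for i, a in enumerate(ARMS)}).to_numpy(dtype=int)


def policy_value_dr(policy: PolicyTree, rewards: RewardMatrix,
                    cohort: Optional[pd.DataFrame] = None,
                    return_se: bool = False):
    """Mean doubly-robust mortality score of the policy's prescriptions.

    ``cohort`` supplies the covariates for routing; it defaults to the
    cohort the reward matrix was computed on and must align row-for-row.
    """
    if cohort is None:
        cohort = rewards.cohort
    if cohort is None:
        raise AlignmentError("no cohort attached to rewards; pass one explicitly")
    if len(cohort) != len(rewards) or not pd.Index(cohort.index).equals(rewards.index):
        raise AlignmentError("cohort rows do not align with the reward matrix")
    arm = _prescribed_arm_idx(policy, cohort)
    vals = rewards.gamma[np.arange(len(rewards)), arm]
    if return_se:
        return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(len(vals)))
    return float(vals.mean())


def argmin_value(rewards: RewardMatrix) -> float:
    """Value of the unconstrained row-wise argmin prescription.

    Lower-bounds the DR value of every tree policy on the same rewards.
    """
    return float(rewards.gamma.min(axis=1).mean())


def plugin_policy_value(policy: PolicyTree, nuisances: NuisanceModels,
                        cohort: pd.DataFrame) -> float:
    """Naive outcome-model (plug-in) policy value, for diagnostics only."""
    arm = _prescribed_arm_idx(policy, cohort)
    return float(nuisances.mu[np.arange(len(cohort)), arm].mean())


def leaf_report(policy: PolicyTree, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-leaf observed mortality by treatment actually received.

    One row per terminal leaf: routing path, prescribed arm, total n, and
    for each arm the count of patients who received it with their observed
    death rate (NaN when no patient in the leaf received the arm). The
    ``best_observed`` column flags the arm with the lowest observed rate
    among non-empty cells.
    """
    ids = policy.leaf_ids(cohort)
    leaves = policy.leaves()
    rows = []
    for i, (path, leaf) in enumerate(leaves):
        sub = cohort[ids == i]
        rec: dict = {"leaf": i + 1, "path": path, "prescribed": leaf.treatment,
                     "n": int(len(sub))}
        best_arm, best_rate = None, np.inf
        for arm in ARMS:
            got = sub[sub[TREATMENT_COL] == arm]
            rec[f"n_{arm}"] = int(len(got))
            rate = float(got[DEATH_COL].mean()) if len(got) else np.nan
            rec[f"mortality_{arm}"] = rate
            if len(got) and rate < best_rate:
                best_arm, best_rate = arm, rate
        rec["best_observed"] = best_arm
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class PolicyValueReport:
    """Prescribed-vs-observed mortality with per-leaf breakdowns."""

    stratum: str
    estimated_policy_mortality: float
    estimated_se: float
    observed_mortality_test: float
    observed_mortality_stratum: Optional[float]
    plugin_policy_mortality: Optional[float]
    argmin_lower_bound: float
    prescription_counts: dict
    leaf_table: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "leaf_table"}
        d["leaf_table"] = json.loads(self.leaf_table.to_json(orient="records"))
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    def to_text(self) -> str:
        lines = [
            f"Stratum: {self.stratum}",
            f"Estimated mortality under prescribed policy: "
            f"{100 * self.estimated_policy_mortality:.2f}% "
            f"(SE {100 * self.estimated_se:.2f} pp)",
            f"Observed mortality (test half):              "
            f"{100 * self.observed_mortality_test:.2f}%",
        ]
        if self.observed_mortality_stratum is not None:
            lines.append(f"Observed mortality (full stratum):           "
                         f"{100 * self.observed_mortality_stratum:.2f}%")
        if self.plugin_policy_mortality is not None:
            lines.append(f"Plug-in (outcome-model only) policy value:   "
                         f"{100 * self.plugin_policy_mortality:.2f}%  [diagnostic]")
        lines.append(f"Unconstrained argmin lower bound:            "
                     f"{100 * self.argmin_lower_bound:.2f}%")
        lines.append("Prescriptions: " + ", ".join(
            f"{a}={self.prescription_counts.get(a, 0)}" for a in ARMS))
        lines.append("")
        lines.append(self.leaf_table.to_string(index=False,
                                               float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def build_report(policy: PolicyTree, rewards_test: RewardMatrix,
                 cohort_test: pd.DataFrame,
                 full_stratum: Optional[pd.DataFrame] = None,
                 nuisances_test: Optional[NuisanceModels] = None,
                 stratum_label: str = "") -> PolicyValueReport:
    """Assemble the full prescribed-vs-observed report for one stratum.

    The estimated policy mortality is the held-out DR value; the observed
    baseline is reported both for the test half and (when given) the full
    stratum, since either convention is defensible.
    """
    value, se = policy_value_dr(policy, rewards_test, cohort_test, return_se=True)
    pres = policy.prescribe(cohort_test)
    counts = pres.value_counts().reindex(ARMS, fill_value=0).astype(int).to_dict()
    plug = (plugin_policy_value(policy, nuisances_test, cohort_test)
            if nuisances_test is not None else None)
    return PolicyValueReport(
        stratum=stratum_label,
        estimated_policy_mortality=value,
        estimated_se=se,
        observed_mortality_test=observed_mortality(cohort_test),
        observed_mortality_stratum=(observed_mortality(full_stratum)
                                    if full_stratum is not None else None),
        plugin_policy_mortality=plug,
        argmin_lower_bound=argmin_value(rewards_test),
        prescription_counts=counts,
        leaf_table=leaf_report(policy, cohort_test),
    )
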