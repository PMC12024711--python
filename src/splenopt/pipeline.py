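"""End-to-end prescriptive pipeline.

Protocol, per hemodynamic stratum (SBP < 70 vs >= 70 mmHg by default):

1. load a cohort CSV or simulate the synthetic preset;
2. 50/50 train/test split, stratified jointly on (treatment, outcome);
3. fit cross-fitted nuisances independently within each half (the test
   half's rewards never see training rows);
4. doubly-robust reward matrices per half;
5. grid-tune (max depth 3-8, complexity penalty) on an internal validation
   split of the training half; refit the winner on the full training half;
6. evaluate on the test half: DR policy value vs observed mortality,
   per-leaf observed-rate tables;
7. write trees (JSON + DOT), reports, the tuning table and a provenance
   block; a fixed seed makes the whole run byte-reproducible.

A stratum too small to support the nuisance cross-fitting or the leaf
constraint is skipped with an explicit warning rather than fit badly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import ARMS, TREATMENT_COL, feature_names, read_cohort_csv, write_cohort_csv
from .errors import ConfigurationError
from .evaluate import build_report
from .rewards import DEFAULT_CLIP, doubly_robust_rewards, fit_nuisances, split_cohort
from .stats import SBP70, StratumDefinition, add_shock_index, stratify
from .synthetic import default_preset, generate_cohort
from .tree import tune

log = logging.getLogger("splenopt")

__all__ = ["RunConfig", "run_pipeline"]

_PRESETS = {"default": default_preset}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; echoed verbatim to the output dir."""

    input_csv: Optional[str] = None
    preset: str = "default"
    n_patients: int = 20_000
    seed: int = 1
    train_fraction: float = 0.5
    stratify_sbp: bool = True
    sbp_threshold: float = 70.0
    min_leaf: int = 20
    depth_grid: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    cp_grid: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    k_folds: int = 5
    clip_bounds: tuple[float, float] = DEFAULT_CLIP
    model_family: str = "forest"
    n_estimators: int = 100
    n_restarts: int = 3
    features: Optional[tuple[str, ...]] = None
    outdir: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        for key in ("depth_grid", "cp_grid", "clip_bounds", "features"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        for key in ("depth_grid", "cp_grid", "clip_bounds", "features"):
            if d[key] is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _load_cohort(config: RunConfig, seed: int) -> pd.DataFrame:
    if config.input_csv is not None:
        df = read_cohort_csv(config.input_csv)
        if "shock_index" not in df.columns:
            df = add_shock_index(df)
        return df
    if config.preset not in _PRESETS:
        raise ConfigurationError(f"unknown preset '{config.preset}'")
    spec = _PRESETS[config.preset](n_patients=config.n_patients, seed=seed)
    return generate_cohort(spec)


def _stratum_feasible(df: pd.DataFrame, config: RunConfig) -> Optional[str]:
    """Reason the stratum cannot be fit, or None when it can."""
    if len(df) < 4 * config.min_leaf:
        return f"n={len(df)} < 4 x min_leaf={config.min_leaf}"
    counts = df[TREATMENT_COL].value_counts()
    need = 4 * config.k_folds
    for arm in ARMS:
        if counts.get(arm, 0) < need:
            return (f"arm '{arm}' has {counts.get(arm, 0)} rows; "
                    f"needs >= {need} for per-half cross-fitting")
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Run the full protocol; returns per-stratum results, writing
    ``config.outdir`` when set."""
    rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(rng.integers(2 ** 31))  # noqa: E731 - one seed stream

    cohort = _load_cohort(config, stage_seed())
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    strata: list[tuple[str, pd.DataFrame]]
    if config.stratify_sbp:
        sd = StratumDefinition(threshold=config.sbp_threshold,
                               low_label=f"SBP < {config.sbp_threshold:g} mmHg",
                               high_label=f"SBP >= {config.sbp_threshold:g} mmHg")
        low, high = stratify(cohort, sd)
        strata = [(sd.low_label, low), (sd.high_label, high)]
    else:
        strata = [("all patients", cohort)]

    results: dict = {"config": config.to_dict(), "strata": {}, "skipped": {},
                     "n_total": int(len(cohort))}
    provenance: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed, "strata": {},
    }
    import sklearn
    provenance["scikit_learn"] = sklearn.__version__

    for label, df_s in strata:
        reason = _stratum_feasible(df_s, config)
        if reason is not None:
            log.warning("skipping stratum '%s': %s", label, reason)
            results["skipped"][label] = reason
            provenance["strata"][label] = {"skipped": reason}
            continue
        s_split, s_nu_itr, s_nu_ival, s_nu_te, s_inner, s_tune = (
            stage_seed() for _ in range(6))
        train, test = split_cohort(df_s, config.train_fraction, seed=s_split)
        feats = list(config.features) if config.features else feature_names(df_s)
        nus_test = fit_nuisances(test, feats, config.k_folds, s_nu_te,
                                 config.model_family, config.clip_bounds,
                                 config.n_estimators)
        r_test = doubly_robust_rewards(test, nus_test)
        # tune on an internal validation split of the training half. The
        # nuisances for the two inner halves are fit independently — the
        # same device the outer protocol uses for the test half — so local
        # outcome-model bias cannot be endorsed by the validation value.
        # The winner is refit on the full training half inside tune().
        inner_tr, inner_val = split_cohort(train, 0.5, seed=s_inner)
        nus_itr = fit_nuisances(inner_tr, feats, config.k_folds, s_nu_itr,
                                config.model_family, config.clip_bounds,
                                config.n_estimators)
        nus_ival = fit_nuisances(inner_val, feats, config.k_folds, s_nu_ival,
                                 config.model_family, config.clip_bounds,
                                 config.n_estimators)
        tree, grid = tune(doubly_robust_rewards(inner_tr, nus_itr), inner_tr[feats],
                          doubly_robust_rewards(inner_val, nus_ival), inner_val[feats],
                          depth_grid=config.depth_grid, cp_grid=config.cp_grid,
                          min_leaf=config.min_leaf, seed=s_tune,
                          n_restarts=config.n_restarts)
        report = build_report(tree, r_test, test, full_stratum=df_s,
                              nuisances_test=nus_test, stratum_label=label)
        results["strata"][label] = {
            "tree": tree, "report": report, "tuning": grid,
            "train_index": train.index, "test_index": test.index,
            "rewards_test": r_test,
        }
        provenance["strata"][label] = {
            "n": int(len(df_s)), "n_train": int(len(train)), "n_test": int(len(test)),
            "train_test_disjoint": bool(len(train.index.intersection(test.index)) == 0),
            "nuisance_clipped": {"inner_train": nus_itr.n_clipped,
                                 "inner_val": nus_ival.n_clipped,
                                 "test": nus_test.n_clipped},
            "cross_fitted": {"train": nus_itr.is_cross_fitted and nus_ival.is_cross_fitted,
                             "test": nus_test.is_cross_fitted},
            "tree_warnings": tree.metadata.get("warnings", []),
            "tuned": {"depth": int(tree.metadata.get("tuned_depth", -1)),
                      "cp": float(tree.metadata.get("tuned_cp", -1.0))},
        }
        if outdir:
            safe = label.replace(" ", "_").replace("<", "lt").replace(">=", "ge")
            tree.to_json(outdir / f"tree_{safe}.json")
            (outdir / f"tree_{safe}.dot").write_text(tree.to_dot(title=label) + "\n")
            report.to_json(outdir / f"report_{safe}.json")
            (outdir / f"report_{safe}.txt").write_text(report.to_text() + "\n")
            grid.to_csv(outdir / f"tuning_{safe}.csv", index=False)
        log.info("stratum '%s': policy value %.4f vs observed %.4f", label,
                 report.estimated_policy_mortality, report.observed_mortality_test)

    if outdir:
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n")
        if config.input_csv is None:
            write_cohort_csv(cohort.head(0), outdir / "cohort_schema.csv")
    results["provenance"] = provenance
    return results
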