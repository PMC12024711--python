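"""Doubly-robust (AIPW) counterfactual reward estimation.

For each patient i and arm t the reward is the augmented
inverse-propensity-weighted mortality score

    Gamma_i(t) = mu_t(x_i) + 1{T_i = t} * (Y_i - mu_t(x_i)) / e_t(x_i),

where mu_t is the outcome model (mortality risk under arm t) and e_t the
propensity model (probability of receiving arm t). The score is consistent
for the counterfactual mortality if either nuisance model is correct.
Rewards are mortality scores to be MINIMIZED, package-wide.

Both nuisances are cross-fitted: every row is predicted by models trained on
the other folds, so no row is scored by a model trained on itself. Scores
may fall outside [0, 1] because of the correction term; they are left
unclamped. Propensities are clipped into ``clip_bounds`` before weighting to
bound the variance on rare arms (angioembolization is ~3% of the cohort);
the number of clipped entries is reported in the provenance metadata.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import ARMS, DEATH_COL, TREATMENT_COL, feature_names, validate_cohort
from .errors import AlignmentError, ConfigurationError, EstimationError, SchemaError

__all__ = [
    "NuisanceModels",
    "RewardMatrix",
    "fit_nuisances",
    "doubly_robust_rewards",
    "split_cohort",
    "oracle_nuisances",
]

DEFAULT_CLIP = (0.01, 0.99)


@dataclass
class NuisanceModels:
    """Cross-fitted out-of-fold nuisance predictions for one cohort.

    ``mu``: n x 3 outcome-model mortality risks mu_t(x) in [0,1].
    ``e``: n x 3 clipped propensities; ``e_raw`` the pre-clip softmax-valid
    probabilities (rows sum to 1). ``fold``: per-row fold id (-1 marks
    oracle/externally supplied predictions, which need no cross-fitting).
    """

    mu: np.ndarray
    e: np.ndarray
    e_raw: np.ndarray
    fold: np.ndarray
    index: pd.Index
    clip_bounds: tuple[float, float] = DEFAULT_CLIP
    n_clipped: int = 0
    model_family: str = "forest"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu.shape != self.e.shape or self.mu.shape[1] != len(ARMS):
            raise SchemaError("nuisance arrays must be n x 3 and aligned")
        lo, hi = self.clip_bounds
        if not ((self.e >= lo - 1e-12) & (self.e <= hi + 1e-12)).all():
            raise SchemaError("clipped propensities fall outside clip_bounds")
        rowsum = self.e_raw.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            raise SchemaError("pre-clip propensity rows must sum to 1")

    @property
    def is_cross_fitted(self) -> bool:
        """True when every row has an out-of-fold prediction (or is oracle)."""
        return bool(((self.fold >= 0).all() and len(np.unique(self.fold)) >= 2)
                    or (self.fold == -1).all())

    @staticmethod
    def from_arrays(mu, e_raw, index, clip_bounds=DEFAULT_CLIP, model_family="supplied",
                    meta=None) -> "NuisanceModels":
        """Wrap externally computed (e.g. oracle or misspecified) nuisances."""
        mu = np.asarray(mu, dtype=float)
        e_raw = np.asarray(e_raw, dtype=float)
        lo, hi = clip_bounds
        e = np.clip(e_raw, lo, hi)
        n_clipped = int(((e_raw < lo) | (e_raw > hi)).sum())
        return NuisanceModels(mu=mu, e=e, e_raw=e_raw,
                              fold=np.full(len(mu), -1), index=pd.Index(index),
                              clip_bounds=clip_bounds, n_clipped=n_clipped,
                              model_family=model_family, meta=meta or {})


@dataclass
class RewardMatrix:
    """n x 3 doubly-robust mortality scores, columns in fixed ARMS order."""

    gamma: np.ndarray
    index: pd.Index
    cohort: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim != 2 or self.gamma.shape[1] != len(ARMS):
            raise SchemaError(f"reward matrix must be n x {len(ARMS)}")
        if not np.isfinite(self.gamma).all():
            raise SchemaError("reward matrix contains non-finite entries")

    def __len__(self) -> int:
        return len(self.gamma)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gamma, index=self.index, columns=list(ARMS))

    def loc(self, index: pd.Index) -> "RewardMatrix":
        """Row-subset by cohort index, preserving alignment."""
        pos = self.index.get_indexer(index)
        if (pos < 0).any():
            raise AlignmentError("requested rows are not in this reward matrix")
        sub_cohort = self.cohort.loc[index] if self.cohort is not None else None
        return RewardMatrix(self.gamma[pos], pd.Index(index), sub_cohort, dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index_label="row")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.meta, indent=2, sort_keys=True, default=str))

    @staticmethod
    def read_csv(path: str | Path) -> "RewardMatrix":
        df = pd.read_csv(path, index_col="row")
        missing = [a for a in ARMS if a not in df.columns]
        if missing:
            raise SchemaError(f"reward CSV missing arm columns {missing}")
        meta = {}
        sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return RewardMatrix(df[list(ARMS)].to_numpy(), df.index, meta=meta)


# ---------------------------------------------------------------------------
# Nuisance fitting
# ---------------------------------------------------------------------------

def _make_model(model_family: str, seed: int, n_estimators: int,
                role: str = "outcome"):
    # probability forests need large leaves for calibrated class fractions,
    # especially on the rare angioembolization arm
    if model_family == "forest":
        msl = 50 if role == "propensity" else 25
        return RandomForestClassifier(n_estimators=n_estimators, min_samples_leaf=msl,
                                      random_state=seed, n_jobs=1)
    if model_family == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000, random_state=seed))
    raise ConfigurationError(f"unknown model_family '{model_family}'")


def _predict_proba_binary(model, X: np.ndarray) -> np.ndarray:
    """P(death=1); robust to a single-class training subset."""
    p = model.predict_proba(X)
    classes = list(model.classes_) if hasattr(model, "classes_") else list(model[-1].classes_)
    if 1 not in classes:
        return np.zeros(len(X))
    return p[:, classes.index(1)]


def fit_nuisances(cohort: pd.DataFrame, features: Optional[Sequence[str]] = None,
                  k_folds: int = 5, seed: int = 0, model_family: str = "forest",
                  clip_bounds: tuple[float, float] = DEFAULT_CLIP,
                  n_estimators: int = 100) -> NuisanceModels:
    """Fit cross-fitted outcome and propensity models on one cohort (half).

    The outcome model is one probabilistic classifier per arm (fit on the
    rows that received that arm); the propensity model is a single
    three-class classifier. Folds are stratified on treatment; every row's
    predictions come from models trained on the other folds. The default
    family is an ensemble of randomized trees (random forest); a logistic
    family is available for tests and diagnostics.
    """
    validate_cohort(cohort)
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    if features is None:
        features = feature_names(cohort)
    for f in features:
        if f not in cohort.columns:
            raise SchemaError(f"unknown feature '{f}'")
        if not pd.api.types.is_numeric_dtype(cohort[f]):
            raise SchemaError(f"feature '{f}' is not numeric")
    X = cohort[list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [f for f in features if cohort[f].isna().any()]
        raise SchemaError(f"features contain missing values: {bad}")
    y = cohort[DEATH_COL].to_numpy(dtype=int)
    t = cohort[TREATMENT_COL].to_numpy()
    n = len(cohort)
    counts = pd.Series(t).value_counts()
    for arm in ARMS:
        if counts.get(arm, 0) < 2 * k_folds:
            raise EstimationError(
                f"arm '{arm}' has {counts.get(arm, 0)} rows; needs at least "
                f"2 x k_folds = {2 * k_folds} for cross-fitting")

    mu = np.full((n, len(ARMS)), np.nan)
    e_raw = np.full((n, len(ARMS)), np.nan)
    fold_id = np.full(n, -1)
    arm_onehot = pd.get_dummies(
        pd.Categorical(t, categories=ARMS)).to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed & 0x7FFFFFFF)
    for k, (tr, te) in enumerate(skf.split(X, pd.Categorical(t, categories=ARMS).codes)):
        fold_id[te] = k
        prop = _make_model(model_family, seed + 1000 + k, n_estimators, "propensity")
        prop.fit(X[tr], t[tr])
        classes = list(prop.classes_) if hasattr(prop, "classes_") else list(prop[-1].classes_)
        pp = prop.predict_proba(X[te])
        for i, arm in enumerate(ARMS):
            e_raw[te, i] = pp[:, classes.index(arm)] if arm in classes else 0.0
        if model_family == "forest":
            # single outcome forest over covariates + treatment indicators:
            # the mortality-risk structure is largely shared across arms, and
            # per-arm fits starve on the ~3% angioembolization arm
            out = _make_model(model_family, seed + 2000 + k, n_estimators)
            out.fit(np.hstack([X[tr], arm_onehot[tr]]), y[tr])
            for i in range(len(ARMS)):
                ind = np.zeros((len(te), len(ARMS)))
                ind[:, i] = 1.0
                mu[te, i] = _predict_proba_binary(out, np.hstack([X[te], ind]))
        else:
            for i, arm in enumerate(ARMS):
                rows = tr[t[tr] == arm]
                if np.unique(y[rows]).size == 1:
                    mu[te, i] = float(y[rows][0])  # single-class training subset
                    continue
                out = _make_model(model_family, seed + 2000 + 10 * k + i, n_estimators)
                out.fit(X[rows], y[rows])
                mu[te, i] = _predict_proba_binary(out, X[te])
    # guard against numerical drift in predict_proba rows
    e_raw /= e_raw.sum(axis=1, keepdims=True)
    lo, hi = clip_bounds
    n_clipped = int(((e_raw < lo) | (e_raw > hi)).sum())
    e = np.clip(e_raw, lo, hi)
    return NuisanceModels(mu=mu, e=e, e_raw=e_raw, fold=fold_id, index=cohort.index,
                          clip_bounds=clip_bounds, n_clipped=n_clipped,
                          model_family=model_family,
                          meta={"k_folds": k_folds, "seed": int(seed),
                                "features": list(features),
                                "n_estimators": n_estimators})


def oracle_nuisances(cohort: pd.DataFrame, spec, clip_bounds=DEFAULT_CLIP) -> NuisanceModels:
    """Nuisances computed from the synthetic generator's true models."""
    from .synthetic import true_propensities, true_risks

    mu = true_risks(spec, cohort)
    e_raw = true_propensities(spec, cohort)
    return NuisanceModels.from_arrays(mu, e_raw, cohort.index, clip_bounds,
                                      model_family="oracle")


# ---------------------------------------------------------------------------
# AIPW rewards
# ---------------------------------------------------------------------------

def doubly_robust_rewards(cohort: pd.DataFrame, nuisances: NuisanceModels) -> RewardMatrix:
    """Combine nuisances into the n x 3 AIPW reward matrix.

    The column of each row's observed arm carries the inverse-propensity
    correction; the other columns equal the outcome-model prediction.
    """
    validate_cohort(cohort)
    if not cohort.index.equals(nuisances.index):
        raise AlignmentError("nuisances were not fit on this cohort (index mismatch)")
    if not nuisances.is_cross_fitted:
        raise EstimationError("nuisances must be cross-fitted (or oracle) before use")
    n = len(cohort)
    y = cohort[DEATH_COL].to_numpy(dtype=float)
    arm_idx = pd.Categorical(cohort[TREATMENT_COL], categories=ARMS).codes
    gamma = nuisances.mu.copy()
    rows = np.arange(n)
    gamma[rows, arm_idx] += (y - nuisances.mu[rows, arm_idx]) / nuisances.e[rows, arm_idx]
    return RewardMatrix(gamma, cohort.index, cohort=cohort,
                        meta={"n_clipped": nuisances.n_clipped,
                              "clip_bounds": list(nuisances.clip_bounds),
                              "model_family": nuisances.model_family,
                              **nuisances.meta})


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def split_cohort(cohort: pd.DataFrame, train_fraction: float = 0.5,
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition, stratified on (arm, outcome).

    Every (treatment, death) cell is split close to ``train_fraction`` so all
    arms and both outcomes appear in both halves whenever counts permit; a
    singleton cell is assigned to training with a warning. Largest-remainder
    apportionment makes the overall training size exactly
    round(train_fraction * n).
    """
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    validate_cohort(cohort)
    n = len(cohort)
    rng = np.random.default_rng(seed)
    cells = list(cohort.groupby([TREATMENT_COL, DEATH_COL], sort=True).groups.items())
    target_total = int(round(train_fraction * n))
    base, frac_part, forced = [], [], []
    for key, idx in cells:
        m = len(idx)
        if m == 1:
            _warnings.warn(f"(treatment, death) cell {key} has a single row; "
                           "assigned to training", stacklevel=2)
            base.append(1)
            frac_part.append(-1.0)  # never gets an extra
            forced.append(True)
        else:
            tgt = train_fraction * m
            base.append(int(np.floor(tgt)))
            frac_part.append(tgt - np.floor(tgt))
            forced.append(False)
    remaining = target_total - sum(base)
    order = np.argsort([-f for f in frac_part], kind="stable")
    for j in order:
        if remaining <= 0:
            break
        m = len(cells[j][1])
        if not forced[j] and base[j] < m - 1:
            base[j] += 1
            remaining -= 1
    train_idx = []
    for (key, idx), k in zip(cells, base):
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:k]])
    train_mask = cohort.index.isin(train_idx)
    return cohort.loc[train_mask], cohort.loc[~train_mask]
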