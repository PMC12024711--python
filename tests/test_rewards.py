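import dataclasses

import numpy as np
import pandas as pd
import pytest

from splenopt.cohort import ARMS, ORACLE_RISK_COLS
from splenopt.errors import AlignmentError, ConfigurationError, EstimationError
from splenopt.rewards import (
    NuisanceModels,
    RewardMatrix,
    doubly_robust_rewards,
    fit_nuisances,
    oracle_nuisances,
    split_cohort,
)
from splenopt.synthetic import (
    CovariateSpec,
    LinearModel,
    SyntheticSpec,
    generate_cohort,
)


def _marginal_spec(n, probs=(0.5, 0.3, 0.2), seed=0):
    """Treatment independent of the single covariate, fixed marginals."""
    prop = {a: LinearModel(float(np.log(p)), {})
            for a, p in zip(ARMS, probs)}
    return SyntheticSpec(
        n_patients=n,
        covariates=(CovariateSpec("x", "continuous", {"mean": 0.0, "sd": 1.0}),),
        propensity=prop,
        outcome_base=LinearModel(-2.0, {"x": 0.5}),
        seed=seed,
    )


def _logistic_outcome_spec(n, seed=0):
    """Per-arm mortality logits linear in x: a logistic family can match it."""
    return SyntheticSpec(
        n_patients=n,
        covariates=(CovariateSpec("x", "continuous", {"mean": 0.0, "sd": 1.0}),),
        propensity={a: LinearModel(0.0, {}) for a in ARMS},
        outcome_base=LinearModel(-2.0, {"x": 0.8}),
        outcome_arm={"AE": LinearModel(-0.5, {"x": 0.3}),
                     "SPLENECTOMY": LinearModel(0.5, {})},
        seed=seed,
    )


class TestFitNuisances:
    def test_marginal_propensity_recovery_under_independence(self):
        probs = (0.5, 0.3, 0.2)
        df = generate_cohort(_marginal_spec(10_000, probs, seed=4))
        nus = fit_nuisances(df, ["x"], k_folds=5, seed=1, model_family="logistic")
        for i, p in enumerate(probs):
            se = np.sqrt(p * (1 - p) / len(df))
            assert nus.e_raw[:, i].mean() == pytest.approx(p, abs=3 * se)

    def test_logistic_outcome_model_recovers_true_risks(self):
        df = generate_cohort(_logistic_outcome_spec(20_000, seed=5))
        nus = fit_nuisances(df, ["x"], k_folds=5, seed=2, model_family="logistic")
        mae = np.abs(nus.mu - df[list(ORACLE_RISK_COLS)].to_numpy()).mean()
        assert mae < 0.05

    def test_sparse_arm_raises_estimation_error_naming_it(self):
        df = generate_cohort(_marginal_spec(300, seed=6))
        df = pd.concat([df[df.treatment != "AE"], df[df.treatment == "AE"].head(3)])
        with pytest.raises(EstimationError, match="AE"):
            fit_nuisances(df, ["x"], k_folds=2, seed=0)

    def test_cross_fitting_bookkeeping(self):
        df = generate_cohort(_marginal_spec(600, seed=7))
        nus = fit_nuisances(df, ["x"], k_folds=3, seed=0, model_family="logistic")
        assert nus.is_cross_fitted
        assert (nus.fold >= 0).all() and len(np.unique(nus.fold)) == 3
        assert np.isfinite(nus.mu).all() and np.isfinite(nus.e).all()
        assert np.allclose(nus.e_raw.sum(axis=1), 1.0, atol=1e-6)

    def test_k_folds_below_two_rejected(self, cohort20k):
        with pytest.raises(ConfigurationError):
            fit_nuisances(cohort20k.head(100), ["age"], k_folds=1, seed=0)


class TestDoublyRobustRewards:
    def test_aipw_hand_example(self):
        # T=AE, Y=1, mu=0.5 everywhere, e=0.5: Gamma(AE) = 0.5 + (1-0.5)/0.5
        df = pd.DataFrame({"x": [0.0, 1.0], "treatment": ["AE", "OBS"],
                           "death": [1, 0]})
        mu = np.full((2, 3), 0.5)
        e = np.full((2, 3), 1 / 3)
        e[0] = [0.25, 0.5, 0.25]
        nus = NuisanceModels.from_arrays(mu, e, df.index)
        R = doubly_robust_rewards(df, nus)
        assert R.gamma[0, 1] == pytest.approx(0.5 + (1 - 0.5) / 0.5)
        assert R.gamma[0, 0] == pytest.approx(0.5)  # unobserved arms keep mu
        assert R.gamma[0, 2] == pytest.approx(0.5)

    def test_perfect_outcome_model_reproduces_observed_outcomes(self, cohort20k):
        sub = cohort20k.head(2000)
        mu = np.zeros((len(sub), 3))
        arm_idx = sub.treatment.map({a: i for i, a in enumerate(ARMS)}).to_numpy()
        mu[np.arange(len(sub)), arm_idx] = sub.death.to_numpy()
        e = np.full((len(sub), 3), 1 / 3)
        nus = NuisanceModels.from_arrays(mu, e, sub.index)
        R = doubly_robust_rewards(sub, nus)
        np.testing.assert_allclose(
            R.gamma[np.arange(len(sub)), arm_idx], sub.death.to_numpy())

    def test_oracle_nuisances_recover_per_arm_mean_risk(self, spec20k, cohort20k):
        nus = oracle_nuisances(cohort20k, spec20k)
        R = doubly_robust_rewards(cohort20k, nus)
        risks = cohort20k[list(ORACLE_RISK_COLS)].to_numpy()
        for i in range(3):
            truth = risks[:, i].mean()
            se = R.gamma[:, i].std(ddof=1) / np.sqrt(len(cohort20k))
            assert R.gamma[:, i].mean() == pytest.approx(truth, abs=2 * se)

    def test_clipping_bounds_the_correction_magnitude(self, spec20k, cohort20k):
        nus = oracle_nuisances(cohort20k, spec20k, clip_bounds=(0.01, 0.99))
        R = doubly_robust_rewards(cohort20k, nus)
        assert np.abs(R.gamma - nus.mu).max() <= 1 / 0.01 + 1e-9

    def test_misaligned_nuisances_rejected(self, spec20k, cohort20k):
        nus = oracle_nuisances(cohort20k.head(100), spec20k)
        with pytest.raises(AlignmentError):
            doubly_robust_rewards(cohort20k.head(50), nus)

    def test_reward_matrix_csv_round_trip(self, tmp_path, spec20k, cohort20k):
        sub = cohort20k.head(50)
        R = doubly_robust_rewards(sub, oracle_nuisances(sub, spec20k))
        path = tmp_path / "rewards.csv"
        R.to_csv(path)
        back = RewardMatrix.read_csv(path)
        np.testing.assert_allclose(back.gamma, R.gamma)
        assert back.meta["model_family"] == "oracle"


class TestSplitCohort:
    def test_exact_halving(self, cohort20k):
        tr, te = split_cohort(cohort20k.head(100), 0.5, seed=3)
        assert len(tr) == 50 and len(te) == 50
        assert len(tr.index.intersection(te.index)) == 0

    def test_same_seed_identical_partition(self, cohort20k):
        a1, _ = split_cohort(cohort20k, 0.5, seed=9)
        a2, _ = split_cohort(cohort20k, 0.5, seed=9)
        assert a1.index.equals(a2.index)

    def test_stratification_balances_arm_frequencies(self, cohort20k):
        tr, te = split_cohort(cohort20k, 0.5, seed=5)
        for arm in ARMS:
            diff = abs((tr.treatment == arm).mean() - (te.treatment == arm).mean())
            assert diff <= 0.02

    def test_both_outcomes_in_both_halves_per_arm(self, cohort20k):
        tr, te = split_cohort(cohort20k, 0.5, seed=5)
        for half in (tr, te):
            for arm in ARMS:
                assert half.loc[half.treatment == arm, "death"].nunique() == 2

    def test_singleton_cell_goes_to_training_with_warning(self):
        df = pd.DataFrame({
            "treatment": ["OBS"] * 10 + ["AE"],
            "death": [0] * 5 + [1] * 5 + [1],
        })
        with pytest.warns(UserWarning, match="single row"):
            tr, te = split_cohort(df, 0.5, seed=0)
        assert (tr.treatment == "AE").sum() == 1
        assert (te.treatment == "AE").sum() == 0

    def test_invalid_fraction_rejected(self, cohort20k):
        with pytest.raises(ConfigurationError):
            split_cohort(cohort20k, 1.0, seed=0)
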