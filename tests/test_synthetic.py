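import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from splenopt.cohort import ARMS, ORACLE_RISK_COLS
from splenopt.errors import ConfigurationError
from splenopt.synthetic import (
    CovariateSpec,
    LinearModel,
    SyntheticSpec,
    default_preset,
    generate_cohort,
    true_policy_value,
    true_propensities,
    true_risks,
)
from splenopt.tree import Node, PolicyTree


def _uniform_propensity():
    return {a: LinearModel(0.0, {}) for a in ARMS}


def _flat_spec(n, p_death=0.1, seed=0):
    """Minimal spec: one covariate, uniform assignment, constant risk."""
    return SyntheticSpec(
        n_patients=n,
        covariates=(CovariateSpec("x", "continuous", {"mean": 0.0, "sd": 1.0}),),
        propensity=_uniform_propensity(),
        outcome_base=LinearModel(float(np.log(p_death / (1 - p_death))), {}),
        seed=seed,
    )


class TestGenerateCohort:
    def test_zero_patients_gives_empty_table_with_full_header(self):
        df = generate_cohort(default_preset(n_patients=0, seed=1))
        assert len(df) == 0
        for col in ("age", "sbp", "treatment", "death") + ORACLE_RISK_COLS:
            assert col in df.columns

    def test_zero_propensity_coefficients_give_uniform_arms(self):
        spec = dataclasses.replace(default_preset(30_000, seed=3),
                                   propensity=_uniform_propensity())
        df = generate_cohort(spec)
        se = np.sqrt((1 / 3) * (2 / 3) / len(df))
        for arm in ARMS:
            assert (df.treatment == arm).mean() == pytest.approx(1 / 3, abs=3 * se)

    def test_death_rate_matches_mean_assigned_oracle_risk(self, spec20k, cohort20k):
        risks = cohort20k[list(ORACLE_RISK_COLS)].to_numpy()
        arm_idx = cohort20k.treatment.map(
            {a: i for i, a in enumerate(ARMS)}).to_numpy()
        p_assigned = risks[np.arange(len(cohort20k)), arm_idx]
        expected = p_assigned.mean()
        mc_se = np.sqrt((p_assigned * (1 - p_assigned)).mean() / len(cohort20k))
        assert cohort20k.death.mean() == pytest.approx(expected, abs=3 * mc_se)

    def test_same_seed_same_spec_is_bit_identical(self):
        spec = default_preset(500, seed=11)
        pd.testing.assert_frame_equal(generate_cohort(spec), generate_cohort(spec))

    def test_assignment_frequencies_match_softmax_propensities(self, spec20k, cohort20k):
        e = true_propensities(spec20k, cohort20k)
        for i, arm in enumerate(ARMS):
            target = e[:, i].mean()
            se = np.sqrt(target * (1 - target) / len(cohort20k))
            assert (cohort20k.treatment == arm).mean() == pytest.approx(
                target, abs=3 * se)

    def test_invalid_distribution_parameters_name_the_covariate(self):
        bad = dataclasses.replace(
            _flat_spec(10),
            covariates=(CovariateSpec("sbp", "binary", {"p": 1.7}),))
        with pytest.raises(ConfigurationError, match="sbp"):
            generate_cohort(bad)


class TestPlantedPolicy:
    def test_planted_policy_is_argmin_of_oracle_risks(self, spec20k):
        df = generate_cohort(dataclasses.replace(spec20k, n_patients=10_000))
        risks = df[list(ORACLE_RISK_COLS)].to_numpy()
        planted = spec20k.planted_policy.prescribe(df).map(
            {a: i for i, a in enumerate(ARMS)}).to_numpy()
        agree = risks[np.arange(len(df)), planted] <= risks.min(axis=1) + 1e-12
        assert agree.mean() >= 0.999

    def test_preset_validates(self, spec20k):
        spec20k.validate()

    def test_preset_grade45_and_treatment_mix_marginals(self, cohort20k):
        assert (cohort20k.spleen_grade >= 4).mean() == pytest.approx(0.25, abs=0.03)
        mix = cohort20k.treatment.value_counts(normalize=True)
        assert mix["OBS"] == pytest.approx(0.838, abs=0.03)
        assert mix["SPLENECTOMY"] == pytest.approx(0.131, abs=0.03)
        assert mix["AE"] == pytest.approx(0.031, abs=0.015)

    def test_preset_planted_policy_is_valid_tree(self, spec20k):
        t = spec20k.planted_policy
        assert t.depth == 2
        assert set(t.split_features()) == {"shock_index", "spleen_grade", "prbc_1h"}
        json_round = PolicyTree.from_json(t.to_json())
        df = generate_cohort(dataclasses.replace(spec20k, n_patients=500))
        assert (json_round.prescribe(df) == t.prescribe(df)).all()


class TestTruePolicyValue:
    def test_constant_risk_constant_policy(self):
        spec = _flat_spec(10, p_death=0.1)
        policy = PolicyTree(root=Node(treatment="OBS"))
        v = true_policy_value(spec, policy, n_mc=20_000, seed=5)
        assert v.value == pytest.approx(0.1, abs=3 * max(v.se, 1e-9) + 1e-12)

    def test_planted_policy_beats_every_constant_policy(self, spec20k):
        planted = true_policy_value(spec20k, spec20k.planted_policy, 50_000, 17)
        for arm in ARMS:
            const = true_policy_value(
                spec20k, PolicyTree(root=Node(treatment=arm)), 50_000, 17)
            assert planted.value <= const.value + 1e-12

    def test_matches_grid_integration_on_reduced_spec(self):
        # two continuous vitals + one binary flag; quadrature over the grid
        # is the independent oracle for the Monte-Carlo policy value
        planted = PolicyTree(root=Node(
            feature="shock_index", threshold=1.0,
            left=Node(treatment="OBS"),
            right=Node(
                feature="prbc_1h", threshold=0.5,
                left=Node(treatment="AE"),
                right=Node(treatment="SPLENECTOMY"),
            ),
        ), max_depth=2)
        offsets = {0: {"OBS": 0.0, "AE": 0.5, "SPLENECTOMY": 1.0},
                   1: {"OBS": 0.6, "AE": 0.0, "SPLENECTOMY": 0.4},
                   2: {"OBS": 1.0, "AE": 0.5, "SPLENECTOMY": 0.0}}
        spec = SyntheticSpec(
            n_patients=10,
            covariates=(
                CovariateSpec("hr", "continuous", {"mean": 95.0, "sd": 15.0}),
                CovariateSpec("sbp", "continuous", {"mean": 110.0, "sd": 20.0}),
                CovariateSpec("prbc_1h", "binary", {"p": 0.3}),
            ),
            propensity=_uniform_propensity(),
            outcome_base=LinearModel(-3.0, {"shock_index": 1.0}),
            planted_policy=planted,
            leaf_offsets=offsets,
            seed=2,
        )
        mc = true_policy_value(spec, planted, n_mc=200_000, seed=9)

        # quadrature: tensor grid over (hr, sbp) normal densities x prbc
        zs, step = np.linspace(-5, 5, 801, retstep=True)
        w = norm.pdf(zs) * step
        hr = (95.0 + 15.0 * zs)[:, None]
        sbp = np.clip(110.0 + 20.0 * zs, 1e-6, None)[None, :]
        si = hr / sbp
        wgrid = w[:, None] * w[None, :]
        total = 0.0
        for prbc, wp in ((0, 0.7), (1, 0.3)):
            base = -3.0 + si
            # route through the planted tree analytically
            leaf0 = si < 1.0
            leaf1 = (~leaf0) & (prbc == 0)
            leaf2 = (~leaf0) & (prbc == 1)
            off = {"OBS": 0, "AE": 1, "SPLENECTOMY": 2}
            p = np.where(leaf0, expit(base + offsets[0]["OBS"]),
                         np.where(leaf1, expit(base + offsets[1]["AE"]),
                                  expit(base + offsets[2]["SPLENECTOMY"])))
            total += wp * (p * wgrid).sum()
        assert mc.value == pytest.approx(total, abs=2 * mc.se + 1e-4)

    def test_policy_on_unknown_covariate_raises_schema_error(self):
        spec = _flat_spec(10)
        policy = PolicyTree(root=Node(
            feature="nonexistent", threshold=0.0,
            left=Node(treatment="OBS"), right=Node(treatment="AE")))
        from splenopt.errors import SchemaError
        with pytest.raises(SchemaError):
            true_policy_value(spec, policy, n_mc=100, seed=1)

    def test_n_mc_must_be_positive(self, spec20k):
        with pytest.raises(ConfigurationError):
            true_policy_value(spec20k, spec20k.planted_policy, n_mc=0, seed=1)
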