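import io

import numpy as np
import pandas as pd
import pytest

import ptsd_phenotyper as pp
from ptsd_phenotyper.effects import glass_delta
from ptsd_phenotyper.preprocess import resolve_transforms, transformed_frame
from ptsd_phenotyper.simulate import (
    Marginal,
    SimulationError,
    default_simulation_config,
    null_simulation_config,
    simulate_cohort,
)


class TestConfigDefaults:
    def test_study_scale(self):
        cfg = default_simulation_config()
        assert cfg.n_exposed_per_sex * 2 == 84
        assert cfg.n_control_per_sex * 2 == 38
        assert cfg.susceptible_fraction == 0.30

    def test_subtype_probs_sum_to_one_per_sex(self):
        cfg = default_simulation_config()
        for probs in cfg.resilient_subtype_probs.values():
            assert sum(probs.values()) == pytest.approx(1.0)

    def test_marginal_families_match_declared_transforms(self):
        cfg = default_simulation_config()
        cat = pp.default_catalog()
        family_to_transform = {
            "normal": "identity", "lognormal": "log",
            "sqrt-normal": "sqrt", "bernoulli": "identity",
        }
        for p in cat.all_parameters:
            fam = cfg.control_marginals[p.name].family
            assert family_to_transform[fam] == p.transform, p.name

    def test_config_json_round_trip(self):
        cfg = default_simulation_config(seed=5)
        again = pp.SimulationConfig.from_json(cfg.to_json())
        assert again.control_marginals == cfg.control_marginals
        assert again.susceptible_shift == cfg.susceptible_shift
        assert again.seed == 5


class TestConfigValidation:
    def test_subtype_probs_must_sum_to_one(self):
        cfg = default_simulation_config()
        cfg.resilient_subtype_probs["female"]["both"] = 0.9
        with pytest.raises(SimulationError, match="sum to 1"):
            simulate_cohort(cfg)

    def test_negative_scale_rejected(self):
        with pytest.raises(SimulationError, match="scale"):
            Marginal("normal", 1.0, -2.0)

    def test_bad_failure_probability_rejected(self):
        cfg = default_simulation_config()
        cfg.barnes_fail_prob["susceptible"] = 1.4
        with pytest.raises(SimulationError, match="barnes"):
            simulate_cohort(cfg)

    def test_validation_happens_before_sampling(self):
        cfg = default_simulation_config()
        cfg.susceptible_fraction = -0.1
        with pytest.raises(SimulationError):
            simulate_cohort(cfg)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = default_simulation_config(seed=42)
        c1, t1 = simulate_cohort(cfg)
        c2, t2 = simulate_cohort(default_simulation_config(seed=42))
        b1, b2 = io.StringIO(), io.StringIO()
        c1.write_csv(b1)
        c2.write_csv(b2)
        assert b1.getvalue() == b2.getvalue()
        assert t1.frame.equals(t2.frame)

    def test_different_seeds_differ(self):
        c1, _ = simulate_cohort(default_simulation_config(seed=1))
        c2, _ = simulate_cohort(default_simulation_config(seed=2))
        assert not c1.frame["ld_dark_duration"].equals(c2.frame["ld_dark_duration"])

    def test_draws_keyed_by_mouse_and_parameter(self):
        """Adding a parameter must not reshuffle other columns' draws."""
        cfg = default_simulation_config(seed=9)
        c1, _ = simulate_cohort(cfg)
        cfg2 = default_simulation_config(seed=9)
        cfg2.control_marginals["extra_param"] = Marginal("normal", 0.0, 1.0)
        c2, _ = simulate_cohort(cfg2)
        for col in ("ld_dark_duration", "cs_pre_inactivity_pct", "barnes_probe"):
            assert c1.frame[col].equals(c2.frame[col])

    def test_truth_consistent_with_groups(self):
        _, truth = simulate_cohort(default_simulation_config(seed=3))
        t = truth.frame
        assert (t[t["group"] == "control"]["true_class"] == "control").all()
        assert set(t[t["group"] == "exposed"]["true_class"]) <= {
            "susceptible", "resilient",
        }
        resilient = t[t["true_class"] == "resilient"]
        assert (resilient["true_subtype"] != "").all()


class TestPlantedEffects:
    def test_null_configuration_has_no_group_difference(self):
        cfg = null_simulation_config(seed=21)
        cfg.n_control_per_sex = 500
        cfg.n_exposed_per_sex = 500
        cohort, _ = simulate_cohort(cfg)
        plan = resolve_transforms(cohort)
        tx = transformed_frame(cohort, plan)
        f = tx[tx["sex"] == "female"]
        for name in cohort.catalog.continuous_names:
            d = glass_delta(
                f[f["group"] == "exposed"][name], f[f["group"] == "control"][name]
            )
            assert abs(d) < 0.2, name

    def test_planted_shift_recovered_as_glass_delta(self):
        """All-susceptible exposed arm shifted +2.0 SD on one parameter:
        the sample Glass delta lands within 2.0 +/- 0.3."""
        cfg = null_simulation_config(seed=13)
        cfg.n_control_per_sex = 200
        cfg.n_exposed_per_sex = 200
        cfg.susceptible_fraction = 1.0
        cfg.susceptible_shift = {"ld_dark_duration": 2.0}
        cohort, _ = simulate_cohort(cfg)
        plan = resolve_transforms(cohort)
        tx = transformed_frame(cohort, plan)
        for sex in ("female", "male"):
            s = tx[tx["sex"] == sex]
            d = glass_delta(
                s[s["group"] == "exposed"]["ld_dark_duration"],
                s[s["group"] == "control"]["ld_dark_duration"],
            )
            assert d == pytest.approx(2.0, abs=0.3)

    def test_shift_on_transformed_scale_for_lognormal(self):
        cfg = null_simulation_config(seed=17)
        cfg.n_control_per_sex = 300
        cfg.n_exposed_per_sex = 300
        cfg.susceptible_fraction = 1.0
        cfg.susceptible_shift = {"cs_pre_inactivity_pct": 1.5}
        cohort, _ = simulate_cohort(cfg)
        plan = resolve_transforms(cohort)
        tx = transformed_frame(cohort, plan)
        f = tx[tx["sex"] == "female"]
        d = glass_delta(
            f[f["group"] == "exposed"]["cs_pre_inactivity_pct"],
            f[f["group"] == "control"]["cs_pre_inactivity_pct"],
        )
        assert d == pytest.approx(1.5, abs=0.3)

    def test_barnes_failures_follow_class_probabilities(self):
        cfg = default_simulation_config(seed=29)
        cfg.n_exposed_per_sex = 600
        cfg.n_control_per_sex = 600
        cohort, truth = simulate_cohort(cfg)
        df = cohort.frame.merge(truth.frame[["mouse_id", "true_class"]], on="mouse_id")
        for cls, p in cfg.barnes_fail_prob.items():
            sub = df[df["true_class"] == cls]
            rate = (sub["barnes_probe"] == "fail").mean()
            se = np.sqrt(p * (1 - p) / len(sub))
            assert abs(rate - p) < 4 * se + 1e-9, cls

    def test_body_weights_positive_and_sex_specific(self):
        cohort, _ = simulate_cohort(default_simulation_config(seed=8))
        w = cohort.frame
        assert (w["body_weight"] > 0).all()
        assert (
            w[w["sex"] == "male"]["body_weight"].mean()
            > w[w["sex"] == "female"]["body_weight"].mean()
        )

    def test_equicorrelation_induces_dependence(self):
        cfg = null_simulation_config(seed=31)
        cfg.n_control_per_sex = 400
        cfg.n_exposed_per_sex = 2
        cfg.equicorrelation = 0.6
        cohort, _ = simulate_cohort(cfg)
        ctrl = cohort.frame[cohort.frame["group"] == "control"]
        r = np.corrcoef(
            ctrl["ld_dark_duration"], ctrl["water_consumed_48h"]
        )[0, 1]
        assert r > 0.35  # rho=0.6 target, sampling noise allowed
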