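import math

import numpy as np
import pandas as pd
import pytest

import ptsd_phenotyper as pp
from ptsd_phenotyper.classify import (
    ClassifyError,
    binary_exceedance,
    classify_cohort,
    control_stats,
    critical_z,
    score_criteria,
    zscore,
)
from ptsd_phenotyper.effects import GroupStats, SelectionResult
from ptsd_phenotyper.preprocess import resolve_transforms

from conftest import build_cohort, toy_catalog
from oracles import brute_force_scorecards


class TestCriticalZ:
    def test_85_coverage_rounds_to_1_44(self):
        assert round(critical_z(0.85), 2) == 1.44
        assert critical_z(0.85) == pytest.approx(1.4395, abs=5e-4)

    def test_95_coverage_is_1_96(self):
        assert round(critical_z(0.95), 2) == 1.96

    def test_monotone_and_vanishing(self):
        grid = [0.05, 0.3, 0.6, 0.85, 0.99]
        vals = [critical_z(c) for c in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert critical_z(1e-9) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_coverage_domain(self, bad):
        with pytest.raises(ClassifyError):
            critical_z(bad)


def _stats(mean=0.0, sd=1.0):
    return GroupStats(
        sex="female", parameter="p", scale="transformed",
        control_mean=mean, control_sd=sd, exposed_mean=float("nan"),
        n_control=10, n_exposed=0,
    )


class TestZScore:
    def test_center_scores_zero(self):
        r = zscore(4.0, _stats(mean=4.0, sd=2.0))
        assert r.z_abs == 0.0 and not r.exceeds

    def test_exact_tie_with_cutoff_does_not_exceed(self):
        # "above" the 85% bound is strict: z = 1.44 exactly scores nothing
        r = zscore(1.44, _stats(), cutoff=1.44)
        assert r.z_abs == 1.44 and not r.exceeds

    def test_symmetric_below_mean_exceeds(self):
        r = zscore(-2.0, _stats(), cutoff=1.44)
        assert r.z_signed == -2.0 and r.z_abs == 2.0 and r.exceeds

    def test_missing_value_yields_missing_record(self):
        assert zscore(float("nan"), _stats()) is None


class TestBinaryExceedance:
    def test_rare_failure_exceeds(self):
        flag, warn = binary_exceedance("fail", 0.05)
        assert flag and warn is None

    def test_pass_never_exceeds(self):
        flag, _ = binary_exceedance("pass", 0.01)
        assert not flag

    def test_common_failure_uninformative(self):
        flag, warn = binary_exceedance("fail", 0.40)
        assert not flag
        assert warn and "uninformative" in warn


def _five_criterion_cohort():
    """Five criteria, one identity parameter each (p0..p4, criterion order
    B,C,D,E,G); controls at mean 0, sd 1 by construction."""
    cat = toy_catalog(n_continuous=5, n_criteria=5)
    ctrl_vals = [-1.0, 0.0, 1.0]  # mean 0, sd 1
    rows = [
        {"mouse_id": f"c{i}", "sex": "female", "group": "control",
         **{f"p{j}": v for j in range(5)}}
        for i, v in enumerate(ctrl_vals)
    ]
    return cat, rows


def _mk(cohort):
    plan = resolve_transforms(cohort)
    sel = SelectionResult.from_catalog(cohort.catalog, cohort.sexes)
    return plan, sel


class TestScoreCriteria:
    def test_one_exceedance_per_criterion_is_susceptible(self):
        cat, rows = _five_criterion_cohort()
        rows.append(
            {"mouse_id": "e1", "sex": "female", "group": "exposed",
             **{f"p{j}": 2.0 for j in range(5)}}
        )
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        card = score_criteria(cohort, "e1", sel, plan)
        assert card["total_points"] == 5 and card["label"] == "susceptible"

    def test_all_exceedances_on_one_criterion_score_one_point(self):
        cat, rows = _five_criterion_cohort()
        rows.append(
            {"mouse_id": "e1", "sex": "female", "group": "exposed",
             "p0": 5.0, **{f"p{j}": 0.0 for j in range(1, 5)}}
        )
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        card = score_criteria(cohort, "e1", sel, plan)
        assert card["total_points"] == 1 and card["label"] == "resilient"

    def test_shared_parameter_scores_both_criteria(self):
        """A parameter listed under two criteria (like the EPM ratio under
        avoidance and arousal) contributes a point to each."""
        shared = pp.ParameterSpec(
            name="shared", assay="toy", criteria=frozenset({"C", "E"})
        )
        other = pp.ParameterSpec(name="other", assay="toy", criteria=frozenset({"B"}))
        cat = pp.CriterionCatalog(
            parameters=(shared, other), measurable_criteria=("B", "C", "E")
        )
        rows = [
            {"mouse_id": f"c{i}", "sex": "female", "group": "control",
             "shared": v, "other": v}
            for i, v in enumerate([-1.0, 0.0, 1.0])
        ]
        rows.append(
            {"mouse_id": "e1", "sex": "female", "group": "exposed",
             "shared": 3.0, "other": 0.0}
        )
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        card = score_criteria(cohort, "e1", sel, plan)
        assert card["points_C"] == 1 and card["points_E"] == 1
        assert card["points_B"] == 0
        assert card["total_points"] == 2 and card["label"] == "resilient"


class TestControlStats:
    def test_closed_form_mean_and_sd(self):
        cat = toy_catalog(n_continuous=1)
        rows = [
            {"mouse_id": "c1", "sex": "male", "group": "control", "p0": 2.0},
            {"mouse_id": "c2", "sex": "male", "group": "control", "p0": 4.0},
            {"mouse_id": "c3", "sex": "male", "group": "control", "p0": 6.0},
            {"mouse_id": "e1", "sex": "male", "group": "exposed", "p0": 5.0},
        ]
        cohort = build_cohort(cat, rows)
        plan = resolve_transforms(cohort)
        st = control_stats(cohort, plan)[("male", "p0")]
        assert st.control_mean == 4.0 and st.control_sd == 2.0

    def test_binary_failure_prevalence(self):
        cat = toy_catalog(n_continuous=1, binary=True)
        rows = [
            {"mouse_id": f"c{i}", "sex": "male", "group": "control",
             "p0": float(i), "probe": o}
            for i, o in enumerate(["pass", "pass", "fail", "pass"])
        ]
        rows.append(
            {"mouse_id": "e1", "sex": "male", "group": "exposed",
             "p0": 1.0, "probe": "fail"}
        )
        cohort = build_cohort(cat, rows)
        st = control_stats(cohort, resolve_transforms(cohort))[("male", "probe")]
        assert st.failure_prevalence == 0.25

    def test_stats_stratified_by_sex(self, default_cohort):
        cohort, _ = default_cohort
        stats = control_stats(cohort, resolve_transforms(cohort))
        f = stats[("female", "ld_dark_duration")]
        m = stats[("male", "ld_dark_duration")]
        assert f.control_mean != m.control_mean

    def test_zero_control_sd_rejected(self):
        cat = toy_catalog(n_continuous=1)
        rows = [
            {"mouse_id": "c1", "sex": "male", "group": "control", "p0": 3.0},
            {"mouse_id": "c2", "sex": "male", "group": "control", "p0": 3.0},
            {"mouse_id": "e1", "sex": "male", "group": "exposed", "p0": 5.0},
        ]
        cohort = build_cohort(cat, rows)
        with pytest.raises(ClassifyError, match="zero control SD"):
            control_stats(cohort, resolve_transforms(cohort))


class TestClassifyCohort:
    def test_null_cohort_has_zero_incidence(self):
        cat, rows = _five_criterion_cohort()
        for i in range(4):
            rows.append(
                {"mouse_id": f"e{i}", "sex": "female", "group": "exposed",
                 **{f"p{j}": 0.0 for j in range(5)}}
            )
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        res = classify_cohort(cohort, sel, plan)
        assert res.incidence() == 0.0

    def test_label_partition_of_classifiable_exposed(self, fitted):
        c = fitted.classification.counts()
        assert c["n_susceptible"] + c["n_resilient"] == c["n_exposed"]

    def test_controls_never_enter_incidence(self, fitted):
        labels = fitted.labels
        exposed_ids = set(labels[labels["group"] == "exposed"]["mouse_id"])
        c = fitted.classification.counts()
        assert c["n_exposed"] <= len(exposed_ids)
        assert set(labels[labels["label"] == "susceptible"]["mouse_id"]) <= exposed_ids

    def test_monotone_in_cutoff(self, default_cohort):
        cohort, _ = default_cohort
        plan, sel = _mk(cohort)
        prev_points = None
        prev_inc = None
        for cutoff in [1.0, 1.44, 2.0, 2.5]:
            res = classify_cohort(cohort, sel, plan, cutoff=cutoff)
            pts = res.scorecards.set_index("mouse_id")["total_points"]
            inc = res.incidence()
            if prev_points is not None:
                assert (pts <= prev_points).all()
                assert inc <= prev_inc
            prev_points, prev_inc = pts, inc

    def test_exact_vs_rounded_cutoff_differ_only_in_sliver(self):
        """Only |z| inside (1.4395…, 1.44] can flip between the conventional
        1.44 cutoff and the exact quantile."""
        cat, rows = _five_criterion_cohort()
        sliver = 1.4397  # between the exact quantile and 1.44
        rows.append(
            {"mouse_id": "e1", "sex": "female", "group": "exposed",
             "p0": sliver, **{f"p{j}": 2.0 for j in range(1, 5)}}
        )
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        rounded = classify_cohort(cohort, sel, plan, use_exact_quantile=False)
        exact = classify_cohort(cohort, sel, plan, use_exact_quantile=True)
        get = lambda r: r.scorecards.set_index("mouse_id").loc["e1", "total_points"]
        assert get(rounded) == 4 and get(exact) == 5

    def test_control_with_full_points_is_flagged_not_susceptible(self):
        cat, rows = _five_criterion_cohort()
        rows.append(
            {"mouse_id": "cx", "sex": "female", "group": "control",
             **{f"p{j}": 50.0 for j in range(5)}}
        )
        rows.append(
            {"mouse_id": "e1", "sex": "female", "group": "exposed",
             **{f"p{j}": 0.0 for j in range(5)}}
        )
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        res = classify_cohort(cohort, sel, plan)
        labels = res.labels.set_index("mouse_id")["label"]
        assert labels["cx"] == "control_flagged"
        assert res.counts()["n_control_flagged"] == 1
        assert res.incidence() == 0.0  # the flagged control is not in the numerator

    def test_missing_all_parameters_of_criterion_unclassifiable(self):
        cat, rows = _five_criterion_cohort()
        nan = float("nan")
        rows.append(
            {"mouse_id": "e1", "sex": "female", "group": "exposed",
             "p0": nan, **{f"p{j}": 2.0 for j in range(1, 5)}}
        )
        rows.append(
            {"mouse_id": "e2", "sex": "female", "group": "exposed",
             **{f"p{j}": 2.0 for j in range(5)}}
        )
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        res = classify_cohort(cohort, sel, plan)
        labels = res.labels.set_index("mouse_id")["label"]
        assert labels["e1"] == "unclassifiable"
        assert res.counts()["n_unclassifiable"] == 1
        assert res.incidence() == 1.0  # denominator excludes the unclassifiable

    def test_missing_one_of_two_parameters_scores_on_remainder(self):
        cat = toy_catalog(n_continuous=2, n_criteria=1)
        rows = [
            {"mouse_id": f"c{i}", "sex": "female", "group": "control",
             "p0": v, "p1": v}
            for i, v in enumerate([-1.0, 0.0, 1.0])
        ]
        rows.append(
            {"mouse_id": "e1", "sex": "female", "group": "exposed",
             "p0": float("nan"), "p1": 3.0}
        )
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        card = score_criteria(cohort, "e1", sel, plan)
        assert card["label"] == "susceptible"  # one criterion, point earned


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_small_cohorts_match_direct_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        cat = toy_catalog(n_continuous=8, n_criteria=4, binary=True)
        rows = []
        for i in range(12):
            group = "control" if i < 5 else "exposed"
            row = {"mouse_id": f"m{i}", "sex": "female", "group": group}
            for j in range(8):
                row[f"p{j}"] = float(rng.normal(0, 1)) if rng.random() > 0.1 else float("nan")
            row["probe"] = rng.choice(["pass", "fail"], p=[0.8, 0.2])
            rows.append(row)
        cohort = build_cohort(cat, rows)
        plan, sel = _mk(cohort)
        res = classify_cohort(cohort, sel, plan)
        oracle = brute_force_scorecards(cohort, sel, plan, cutoff=res.cutoff)
        for _, card in res.scorecards.iterrows():
            pts, total, label = oracle[card["mouse_id"]]
            for crit, pt in pts.items():
                assert card[f"points_{crit}"] == pt, card["mouse_id"]
            assert card["total_points"] == total
            assert card["label"] == label
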