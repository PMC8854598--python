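"""Direct-effect classification: enumeration, decisions, iteration,
reduction to the plain screen, order invariance, the joint model."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ceranet.netcoupler import (class_totals, classify_direct_effect,
                                enumerate_adjustment_sets, joint_model,
                                netcoupler_iterate)
from ceranet.network import Skeleton, pc_skeleton
from ceranet.preprocess import StandardizedPanel, log_z_transform
from ceranet.survival import CoxSpec, fit_prentice_cox, single_lipid_screen
from ceranet.synth_cohort import draw_case_cohort, simulate_cohort


def _skeleton(nodes, edges, alpha=0.05):
    return Skeleton(nodes=tuple(nodes),
                    edges=frozenset(frozenset(e) for e in edges),
                    sepsets={}, alpha=alpha)


class TestEnumeration:
    def test_power_set_of_neighbors(self):
        skel = _skeleton("abc", [("a", "b"), ("a", "c")])
        subsets = enumerate_adjustment_sets(skel, "a")
        assert subsets == [(), ("b",), ("c",), ("b", "c")]

    def test_isolated_node_single_empty_set(self):
        skel = _skeleton("abc", [("b", "c")])
        assert enumerate_adjustment_sets(skel, "a") == [()]

    def test_fixed_set_excluded(self):
        skel = _skeleton("abcd", [("a", "b"), ("a", "c"), ("a", "d")])
        subsets = enumerate_adjustment_sets(skel, "a", fixed_set={"c"})
        assert subsets == [(), ("b",), ("d",), ("b", "d")]

    def test_cap_enforced(self):
        nodes = [f"n{i}" for i in range(12)]
        skel = _skeleton(nodes, [("n0", x) for x in nodes[1:]])
        with pytest.raises(ValueError, match="cap"):
            enumerate_adjustment_sets(skel, "n0", cap=2 ** 10)


class TestClassTotals:
    def test_totals_standardized_by_prefix(self, effect_cohort):
        raw = effect_cohort.data[list(effect_cohort.metabolites)]
        totals = class_totals(raw)
        assert set(totals.columns) == {"total_cer", "total_dhcer"}
        assert np.abs(totals.mean()).max() < 1e-10
        assert np.abs(totals.std(ddof=1) - 1).max() < 1e-10
        # total is the log-z of the raw-scale class sum
        cer_cols = [c for c in raw.columns if not c.startswith("dh")]
        s = np.log(raw[cer_cols].sum(axis=1))
        expect = (s - s.mean()) / s.std(ddof=1)
        assert np.allclose(totals["total_cer"], expect)


class TestClassification:
    def test_true_effector_direct_nulls_not(self, effect_sample, effect_panel,
                                            effect_cohort):
        # class totals are left out of the adjustment here: with only three
        # metabolites per class the total is nearly collinear with the
        # exposure itself (they are used at study scale in the pipeline)
        skel = pc_skeleton(effect_panel, alpha=0.05)
        extra = effect_panel.transform(
            effect_sample.data[list(effect_panel.metabolites)])
        base = CoxSpec(exposures=(), confounders=("sex", "adiposity"))
        dec = classify_direct_effect(effect_sample, "Cer16:0", skel, base,
                                     extra_columns=extra)
        assert dec.classification == "direct"
        assert dec.submodel_count == 2 ** len(
            [e for e in skel.edges if "Cer16:0" in e])
        for null_node in ("Cer14:0", "Cer18:0"):
            d = classify_direct_effect(effect_sample, null_node, skel, base,
                                       extra_columns=extra)
            assert d.classification in ("none", "ambiguous")

    def test_isolated_node_single_model(self, effect_sample, effect_panel):
        skel = _skeleton(effect_panel.metabolites, [])
        z = effect_panel.transform(effect_sample.data[list(effect_panel.metabolites)])
        base = CoxSpec(exposures=(), confounders=("sex", "adiposity"))
        dec = classify_direct_effect(effect_sample, "Cer16:0", skel, base,
                                     extra_columns=z)
        assert dec.submodel_count == 1
        assert dec.classification == "direct"
        assert dec.log_hr_range[0] == dec.log_hr_range[1] > 0


class TestIteration:
    def test_empty_skeleton_reduces_to_screen(self, effect_sample, effect_panel):
        skel = _skeleton(effect_panel.metabolites, [])
        z = effect_panel.transform(effect_sample.data[list(effect_panel.metabolites)])
        base = CoxSpec(exposures=(), confounders=("sex", "adiposity"))
        res = netcoupler_iterate(effect_sample, skel, base, extra_columns=z)
        screen = single_lipid_screen(
            effect_sample, effect_panel,
            {"full": base}).set_index("metabolite")
        for dec in res.decisions:
            if dec.iteration == 1:
                assert dec.max_p == pytest.approx(
                    screen.loc[dec.metabolite, "p"], abs=1e-10)
                assert (dec.classification == "direct") == \
                    (screen.loc[dec.metabolite, "p"] < 0.05)

    def test_metabolite_order_invariance(self, effect_sample, effect_panel):
        skel = pc_skeleton(effect_panel, alpha=0.05)
        z = effect_panel.transform(effect_sample.data[list(effect_panel.metabolites)])
        base = CoxSpec(exposures=(), confounders=("sex", "adiposity"))
        res = netcoupler_iterate(effect_sample, skel, base, extra_columns=z)
        rng = np.random.default_rng(0)
        cols = list(effect_panel.data.columns)
        rng.shuffle(cols)
        shuffled_panel = StandardizedPanel(
            data=effect_panel.data[cols],
            transform_params=effect_panel.transform_params.loc[cols],
            excluded_subjects=[])
        skel2 = pc_skeleton(shuffled_panel, alpha=0.05)
        res2 = netcoupler_iterate(effect_sample, skel2, base,
                                  extra_columns=z[cols])
        assert res.selected == res2.selected
        assert res.iterations <= len(effect_panel.metabolites)

    def test_null_panel_selects_nothing(self, null_truth):
        cohort = simulate_cohort(null_truth, 2000, seed=23, case_fraction=0.12)
        sample = draw_case_cohort(cohort, 0.3, "t2d", seed=24)
        panel = log_z_transform(cohort.data[list(cohort.metabolites)])
        skel = pc_skeleton(panel)
        z = panel.transform(sample.data[list(panel.metabolites)])
        base = CoxSpec(exposures=(), confounders=("sex", "adiposity"))
        res = netcoupler_iterate(sample, skel, base, extra_columns=z)
        assert len(res.selected) <= 1          # chance hits only
        if not res.selected:
            assert res.joint_fit is None


class TestJointModel:
    def test_single_selected_equals_classify_fit(self, effect_sample,
                                                 effect_panel):
        z = effect_panel.transform(effect_sample.data[list(effect_panel.metabolites)])
        base = CoxSpec(exposures=(), confounders=("sex", "adiposity"))
        joint = joint_model(effect_sample, ("Cer16:0",), base, extra_columns=z)
        solo = fit_prentice_cox(
            effect_sample,
            CoxSpec(exposures=("Cer16:0",), confounders=("sex", "adiposity")),
            extra_columns=z)
        assert joint.log_hr["Cer16:0"] == pytest.approx(
            solo.log_hr["Cer16:0"], abs=1e-12)

    def test_opposite_sign_effectors_preserved(self):
        from ceranet.synth_cohort import generate_ground_truth
        truth = generate_ground_truth(
            3, 3, "elongation_chain", edge_weight_range=(0.4, 0.6),
            effect_spec={"direct_log_hr":
                         {"t2d": {"Cer16:0": 0.5, "Cer18:0": -0.5}}}, seed=5)
        cohort = simulate_cohort(truth, 4000, seed=6, case_fraction=0.15)
        sample = draw_case_cohort(cohort, 0.3, "t2d", seed=7)
        panel = log_z_transform(cohort.data[list(cohort.metabolites)])
        z = panel.transform(sample.data[list(panel.metabolites)])
        base = CoxSpec(exposures=(), confounders=("sex", "adiposity"))
        fit = joint_model(sample, ("Cer16:0", "Cer18:0"), base, extra_columns=z)
        assert fit.log_hr["Cer16:0"] > 0 > fit.log_hr["Cer18:0"]

    def test_empty_selection_rejected(self, effect_sample):
        with pytest.raises(ValueError):
            joint_model(effect_sample, (),
                        CoxSpec(exposures=(), confounders=("sex",)))
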