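"""Fisher-z test and stable-PC skeleton: correctness, oracle recovery,
order invariance, determinism."""

import numpy as np
import pandas as pd
import pytest

from ceranet.network import (fisher_z_ci_test, neighbors, pc_skeleton,
                             pc_skeleton_from_corr)
from ceranet.preprocess import StandardizedPanel, log_z_transform
from ceranet.synth_cohort import implied_log_covariance, simulate_cohort


def _panel_from(data: np.ndarray, cols) -> StandardizedPanel:
    df = pd.DataFrame(data, columns=cols)
    z = (df - df.mean()) / df.std(ddof=1)
    return StandardizedPanel(data=z, transform_params=pd.DataFrame(
        {"mean": df.mean(), "sd": df.std(ddof=1)}), excluded_subjects=[])


class TestFisherZ:
    def test_zero_correlation_independent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 2))
        x[:, 1] -= np.polyval(np.polyfit(x[:, 0], x[:, 1], 1), x[:, 0])  # exact r=0
        panel = _panel_from(x, ["a", "b"])
        stat, p, indep = fisher_z_ci_test(panel, "a", "b")
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)
        assert indep

    def test_printed_example_n51_r03(self):
        # r = 0.3 at n = 51, |S| = 0: z = atanh(0.3) = 0.30952,
        # statistic = sqrt(48) * z = 2.1445, two-sided p = 0.0320
        from ceranet.network import _fisher_z_from_r
        stat, p, indep = _fisher_z_from_r(0.3, 51, 0, 0.05)
        assert stat == pytest.approx(2.1445, abs=1e-4)
        assert p == pytest.approx(0.0320, abs=2e-4)
        assert not indep

    def test_permutation_cross_check(self):
        # the Fisher-z p agrees with a permutation null at moderate n
        rng = np.random.default_rng(1)
        n = 51
        x = rng.normal(size=n)
        y = 0.35 * x + rng.normal(size=n)
        r_obs = np.corrcoef(x, y)[0, 1]
        perms = np.array([
            abs(np.corrcoef(x, rng.permutation(y))[0, 1]) for _ in range(10000)])
        p_perm = float(np.mean(perms >= abs(r_obs)))
        from ceranet.network import _fisher_z_from_r
        _, p_z, _ = _fisher_z_from_r(r_obs, n, 0, 0.05)
        assert p_z == pytest.approx(p_perm, abs=0.02)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(2)
        panel = _panel_from(rng.normal(size=(80, 3)), ["a", "b", "c"])
        s1 = fisher_z_ci_test(panel, "a", "b", ("c",))
        s2 = fisher_z_ci_test(panel, "b", "a", ("c",))
        assert s1[0] == pytest.approx(s2[0], abs=1e-12)

    def test_preconditions(self):
        rng = np.random.default_rng(3)
        panel = _panel_from(rng.normal(size=(4, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError):
            fisher_z_ci_test(panel, "a", "a")
        with pytest.raises(ValueError):
            fisher_z_ci_test(panel, "a", "b", ("a",))
        with pytest.raises(ValueError):
            fisher_z_ci_test(panel, "a", "b", ("c",))  # n - |S| - 3 = 0


class TestOracleSkeletons:
    def test_chain_d_separation(self):
        cov = pd.DataFrame(
            [[1.0, 0.8, 0.64], [0.8, 1.0, 0.8], [0.64, 0.8, 1.0]],
            index=list("ABC"), columns=list("ABC"))
        skel = pc_skeleton_from_corr(cov, n=None)
        assert skel.edge_list() == [("A", "B"), ("B", "C")]
        assert skel.sepsets[frozenset("AC")] == frozenset("B")

    def test_collider_parents_unlinked(self):
        # A -> C <- B with A independent of B
        cov = pd.DataFrame(
            [[1.0, 0.0, 0.6], [0.0, 1.0, 0.6], [0.6, 0.6, 1.0]],
            index=list("ABC"), columns=list("ABC"))
        skel = pc_skeleton_from_corr(cov, n=None)
        assert skel.edge_list() == [("A", "C"), ("B", "C")]
        assert skel.sepsets[frozenset("AB")] == frozenset()


class TestSampleSkeleton:
    def test_recovers_true_skeleton(self, study_truth):
        cohort = simulate_cohort(study_truth, 5000, seed=21)
        panel = log_z_transform(cohort.data[list(cohort.metabolites)])
        skel = pc_skeleton(panel, alpha=0.05)
        truth_adj = study_truth.adjacency()
        found = skel.adjacency().loc[truth_adj.index, truth_adj.columns]
        true_edges = truth_adj.to_numpy()[np.triu_indices(len(truth_adj), 1)]
        found_edges = found.to_numpy()[np.triu_indices(len(found), 1)]
        # all true edges found; false-positive edges bounded by the alpha level
        assert (found_edges[true_edges == 1] == 1).all()
        n_false = int(((true_edges == 0) & (found_edges == 1)).sum())
        assert n_false <= 0.05 * (true_edges == 0).sum() + 3

    def test_order_invariance(self, effect_panel):
        base = pc_skeleton(effect_panel, alpha=0.05)
        rng = np.random.default_rng(9)
        for _ in range(20):
            cols = list(effect_panel.data.columns)
            rng.shuffle(cols)
            shuffled = StandardizedPanel(
                data=effect_panel.data[cols],
                transform_params=effect_panel.transform_params.loc[cols],
                excluded_subjects=[])
            assert pc_skeleton(shuffled, alpha=0.05).edges == base.edges

    def test_determinism(self, effect_panel):
        a = pc_skeleton(effect_panel)
        b = pc_skeleton(effect_panel)
        assert a.edges == b.edges and a.sepsets == b.sepsets

    def test_insufficient_n_rejected(self):
        rng = np.random.default_rng(10)
        panel = _panel_from(rng.normal(size=(6, 4)), list("abcd"))
        with pytest.raises(ValueError):
            pc_skeleton(panel)


class TestNeighbors:
    def test_adjacency_sets(self):
        cov = pd.DataFrame(
            [[1.0, 0.8, 0.64], [0.8, 1.0, 0.8], [0.64, 0.8, 1.0]],
            index=list("ABC"), columns=list("ABC"))
        skel = pc_skeleton_from_corr(cov, n=None)
        assert neighbors(skel, "B") == {"A", "C"}
        assert neighbors(skel, "A") == {"B"}
        with pytest.raises(KeyError):
            neighbors(skel, "Z")

    def test_interior_chain_degree(self, study_truth):
        # population oracle on the structural covariance (shared confounder
        # loadings are latent common causes and would densify the skeleton)
        cov = implied_log_covariance(study_truth, structural_only=True)
        skel = pc_skeleton_from_corr(cov, n=None)
        assert skel.edges == frozenset(
            frozenset((u, v)) for u, v, w in study_truth.dag_edges if w != 0)
        # interior nodes of the elongation chain have degree >= 2
        assert len(neighbors(skel, "Cer20:0")) >= 2
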