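"""Cox solver correctness (vs external oracles), Prentice construction,
screen mechanics and sensitivity filters."""

import numpy as np
import pandas as pd
import pytest

from ceranet.preprocess import log_z_transform
from ceranet.survival import (CoxSpec, apply_sensitivity_filters, coxph,
                              fit_prentice_cox, single_lipid_screen)
from ceranet.synth_cohort import CaseCohortSample, draw_case_cohort, simulate_cohort


def _oracle_fixture():
    """Seeded left-truncated survival data; R survival::coxph reference values
    are frozen below (coef / robust SE / naive SE printed by R 4.3)."""
    rng = np.random.default_rng(1)
    n = 2000
    X = rng.normal(size=(n, 4))
    entry = rng.uniform(35, 65, n)
    lp = X @ np.array([0.5, -0.3, 0.2, 0.0])
    T = entry + rng.exponential(5 * np.exp(-lp))
    censor = entry + rng.uniform(2, 10, n)
    exit_ = np.minimum(T, censor)
    event = (T <= censor).astype(int)
    return X, entry, exit_, event


R_COEF = [0.512010891, -0.333608399, 0.191646000, -0.008967794]
R_ROBUST = [0.02859754, 0.02832512, 0.02733005, 0.02693157]
R_NAIVE = [0.02928176, 0.02916040, 0.02810039, 0.02813806]
R_COEF_TIED = [0.51230243, -0.33451489, 0.19351800, -0.01084986]
R_ROBUST_TIED = [0.02876273, 0.02844470, 0.02745888, 0.02701526]


class TestCoxSolver:
    def test_matches_r_survival(self):
        X, entry, exit_, event = _oracle_fixture()
        beta, naive, robust, _, conv = coxph(X, entry, exit_, event)
        assert conv
        assert np.allclose(beta, R_COEF, atol=5e-8)
        assert np.allclose(np.sqrt(np.diag(robust)), R_ROBUST, atol=5e-8)
        assert np.allclose(np.sqrt(np.diag(naive)), R_NAIVE, atol=5e-8)

    def test_efron_ties_match_r_survival(self):
        X, entry, exit_, event = _oracle_fixture()
        exit_t = np.maximum(np.round(exit_, 1), entry + 1e-3)
        beta, _, robust, _, conv = coxph(X, entry, exit_t, event)
        assert conv
        assert np.allclose(beta, R_COEF_TIED, atol=5e-8)
        assert np.allclose(np.sqrt(np.diag(robust)), R_ROBUST_TIED, atol=5e-8)

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter
        X, entry, exit_, event = _oracle_fixture()
        df = pd.DataFrame(X, columns=list("abcd"))
        df["entry"], df["exit"], df["event"] = entry, exit_, event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="exit", event_col="event", entry_col="entry")
        beta, *_ = coxph(X, entry, exit_, event)
        assert np.allclose(beta, cph.params_.to_numpy(), atol=1e-5)

    def test_rank_deficiency_rejected(self):
        X, entry, exit_, event = _oracle_fixture()
        Xdup = np.column_stack([X[:, 0], X[:, 0]])
        with pytest.raises(np.linalg.LinAlgError):
            coxph(Xdup, entry, exit_, event)


class TestPrentice:
    def test_full_subcohort_equals_standard_cox(self, effect_cohort, effect_panel):
        sample = draw_case_cohort(effect_cohort, 1.0, "t2d", seed=0)
        z = effect_panel.transform(sample.data[list(effect_panel.metabolites)])
        spec = CoxSpec(exposures=("Cer16:0",), confounders=("sex", "adiposity"))
        fit = fit_prentice_cox(sample, spec, extra_columns=z)
        X = np.column_stack([
            z["Cer16:0"], sample.data["sex"], sample.data["adiposity"]])
        beta, *_ = coxph(X, sample.data["entry_age"].to_numpy(),
                         sample.data["exit_age"].to_numpy(),
                         sample.data["event"].to_numpy())
        assert fit.log_hr["Cer16:0"] == pytest.approx(beta[0], abs=1e-8)

    def test_case_cohort_estimate_near_full_cohort(self, effect_cohort,
                                                   effect_panel, effect_sample):
        spec = CoxSpec(exposures=("Cer16:0",), confounders=("sex", "adiposity"))
        full = draw_case_cohort(effect_cohort, 1.0, "t2d", seed=0)
        zf = effect_panel.transform(full.data[list(effect_panel.metabolites)])
        zs = effect_panel.transform(effect_sample.data[list(effect_panel.metabolites)])
        fit_full = fit_prentice_cox(full, spec, extra_columns=zf)
        fit_cc = fit_prentice_cox(effect_sample, spec, extra_columns=zs)
        # single-replicate check: estimates agree within joint uncertainty
        diff = abs(fit_full.log_hr["Cer16:0"] - fit_cc.log_hr["Cer16:0"])
        assert diff < 3 * fit_cc.se["Cer16:0"]

    def test_row_permutation_invariance(self, effect_sample, effect_panel):
        spec = CoxSpec(exposures=("Cer16:0",), confounders=("sex", "adiposity"))
        z = effect_panel.transform(effect_sample.data[list(effect_panel.metabolites)])
        fit = fit_prentice_cox(effect_sample, spec, extra_columns=z)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(effect_sample.data))
        from dataclasses import replace
        shuffled = replace(effect_sample, data=effect_sample.data.iloc[perm])
        fit2 = fit_prentice_cox(shuffled, spec, extra_columns=z.iloc[perm])
        assert fit.log_hr["Cer16:0"] == pytest.approx(
            fit2.log_hr["Cer16:0"], abs=1e-8)
        assert fit.se["Cer16:0"] == pytest.approx(fit2.se["Cer16:0"], abs=1e-8)

    def test_confounder_rescaling_invariance(self, effect_sample, effect_panel):
        spec = CoxSpec(exposures=("Cer16:0",), confounders=("sex", "adiposity"))
        z = effect_panel.transform(effect_sample.data[list(effect_panel.metabolites)])
        fit = fit_prentice_cox(effect_sample, spec, extra_columns=z)
        from dataclasses import replace
        data = effect_sample.data.copy()
        data["adiposity"] = 10.0 * data["adiposity"] + 3.0
        fit2 = fit_prentice_cox(replace(effect_sample, data=data),
                                spec, extra_columns=z)
        assert fit.log_hr["Cer16:0"] == pytest.approx(
            fit2.log_hr["Cer16:0"], abs=1e-8)

    def test_no_events_rejected(self, effect_sample):
        from dataclasses import replace
        data = effect_sample.data.copy()
        data["event"] = 0
        with pytest.raises(ValueError):
            fit_prentice_cox(replace(effect_sample, data=data),
                             CoxSpec(exposures=("sex",)))


class TestScreen:
    def test_bh_hand_computed(self):
        from statsmodels.stats.multitest import multipletests
        _, q, *_ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_true_effect_flagged_nulls_mostly_not(self, effect_sample,
                                                  effect_panel):
        specs = {"full": CoxSpec(exposures=(), confounders=("sex", "adiposity"))}
        table = single_lipid_screen(effect_sample, effect_panel, specs)
        row = table.set_index("metabolite")
        assert row.loc["Cer16:0", "fdr_significant"]
        assert row.loc["Cer16:0", "logHR"] > 0

    def test_null_panel_no_fdr_hits(self, null_truth):
        cohort = simulate_cohort(null_truth, 3000, seed=17, case_fraction=0.12)
        sample = draw_case_cohort(cohort, 0.3, "t2d", seed=18)
        panel = log_z_transform(cohort.data[list(cohort.metabolites)])
        specs = {"full": CoxSpec(exposures=(), confounders=("sex", "adiposity"))}
        table = single_lipid_screen(sample, panel, specs)
        assert table["fdr_significant"].sum() <= 1


class TestSensitivityFilters:
    def test_no_medication_users_unchanged(self, effect_sample):
        from dataclasses import replace
        data = effect_sample.data.copy()
        data["lipid_lowering"] = 0.0
        s = replace(effect_sample, data=data)
        out = apply_sensitivity_filters(s, "drop_lipid_lowering_users")
        assert out.n == s.n

    def test_early_event_count(self, effect_sample):
        d = effect_sample.data
        early = int(((d["event"] == 1)
                     & (d["exit_age"] - d["entry_age"] < 2.0)).sum())
        out = apply_sensitivity_filters(effect_sample, "drop_events_first_2y")
        assert effect_sample.n_events - out.n_events == early

    def test_all_cases_early_rejected(self, effect_sample):
        from dataclasses import replace
        data = effect_sample.data.copy()
        data.loc[data["event"] == 1, "exit_age"] = \
            data.loc[data["event"] == 1, "entry_age"] + 1.0
        with pytest.raises(ValueError, match="removed all cases"):
            apply_sensitivity_filters(replace(effect_sample, data=data),
                                      "drop_events_first_2y")

    def test_unknown_filter_rejected(self, effect_sample):
        with pytest.raises(ValueError):
            apply_sensitivity_filters(effect_sample, "nope")
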