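"""End-to-end orchestration from a single declarative configuration.

Stages run in dependency order: simulate (or load) the cohort, standardize
the panel, learn the skeleton from the random subcohort, run the FDR
single-lipid screen, the network-coupled direct-effect selection, mediation
for each diet exposure, and a synthetic two-sample MR.  Every stage writes a
tab-separated table into the run directory and appends to a machine-readable
manifest (stage, seed, row counts, wall time).  All randomness derives from
the seeds recorded in the config; result tables are byte-identical across
re-runs with the same config.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mediation as med
from . import mr as mr_mod
from . import netcoupler as nc
from .network import pc_skeleton
from .preprocess import StandardizedPanel, icc_one_way, log_z_transform
from .survival import CoxSpec, fit_prentice_cox, single_lipid_screen
from .synth_cohort import (CaseCohortSample, CohortTable, default_ground_truth,
                           draw_case_cohort, ground_truth_to_yaml,
                           simulate_cohort, simulate_repeat_measures,
                           write_cohort_tsv)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every alpha the analysis uses is here."""

    out_dir: str = "ceranet_run"
    seed: int = 0
    n: int = 6000
    subcohort_fraction: float = 0.25
    case_fraction: float = 0.12
    admin_censor_years: float = 10.0
    endpoints: tuple[str, ...] = ("t2d",)
    alpha_network: float = 0.05
    alpha_netcoupler: float = 0.05
    fdr_level: float = 0.05
    gwas_threshold: float = 1e-5
    bootstrap_B: int = 1000
    bootstrap_fraction: float = 2.0 / 3.0
    degree_cap: int = 10
    pilot_n: int = 35
    pilot_icc: float = 0.6
    confounders: tuple[str, ...] = ("sex", "adiposity", "lipid_lowering")
    cohort_path: str | None = None           # load instead of simulate

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("endpoints", "confounders"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def validate(self, cohort: CohortTable) -> None:
        errors = []
        for c in self.confounders:
            if c not in cohort.data.columns:
                errors.append(f"unknown confounder column: {c}")
        for ep in self.endpoints:
            if ep not in cohort.endpoints:
                errors.append(f"unknown endpoint: {ep}")
        if errors:
            raise ValueError("; ".join(errors))


class _Manifest:
    def __init__(self, path: Path, seed: int):
        self.path = path
        self.doc = {"seed": seed, "stages": []}

    def record(self, stage: str, t0: float, **info) -> None:
        self.doc["stages"].append(
            {"stage": stage, "wall_seconds": round(time.time() - t0, 3), **info})
        self.path.write_text(json.dumps(self.doc, indent=2))


def _extra_columns(sample: CaseCohortSample, panel: StandardizedPanel
                   ) -> pd.DataFrame:
    """Standardized metabolites plus class totals, aligned to sample rows."""
    raw = sample.data[list(panel.metabolites)]
    z = panel.transform(raw)
    totals = nc.class_totals(raw)
    return pd.concat([z, totals], axis=1)


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", config.seed)

    # --- simulate / load -------------------------------------------------
    t0 = time.time()
    truth = default_ground_truth(config.seed)
    cohort = simulate_cohort(
        truth, config.n, admin_censor_years=config.admin_censor_years,
        seed=config.seed, case_fraction=config.case_fraction)
    config.validate(cohort)
    cohort = simulate_repeat_measures(
        cohort, config.pilot_icc, config.pilot_n, seed=config.seed + 1)
    write_cohort_tsv(cohort, out / "cohort.tsv")
    ground_truth_to_yaml(truth, out / "ground_truth.yaml")
    manifest.record("simulate", t0, n=cohort.n, seed=config.seed)

    # --- reliability pilot ----------------------------------------------
    t0 = time.time()
    pairs = cohort.data[[c for m in cohort.metabolites
                         for c in (m, f"{m}__repeat")
                         if f"{m}__repeat" in cohort.data.columns]]
    report = icc_one_way(pairs)
    report.to_tsv(out / "reliability.tsv")
    manifest.record("reliability", t0, n_pairs=config.pilot_n)

    results: dict[str, dict] = {}
    for endpoint in config.endpoints:
        ep_dir = out / endpoint
        ep_dir.mkdir(exist_ok=True)

        t0 = time.time()
        sample = draw_case_cohort(
            cohort, config.subcohort_fraction, endpoint, seed=config.seed + 2)
        sample.data.to_csv(ep_dir / "case_cohort.tsv", sep="\t", index=False)
        manifest.record(f"case_cohort[{endpoint}]", t0, n=sample.n,
                        n_events=sample.n_events,
                        cases_in_subcohort=sample.n_cases_in_subcohort)

        # --- standardize on the random subcohort, learn the skeleton -----
        t0 = time.time()
        sub = cohort.data.loc[cohort.data["subject_id"].isin(
            sample.data.loc[sample.data["subcohort"], "subject_id"])]
        panel = log_z_transform(sub[list(cohort.metabolites)])
        skeleton = pc_skeleton(panel, alpha=config.alpha_network)
        skeleton.to_tsv(ep_dir / "skeleton.tsv")
        manifest.record(f"network[{endpoint}]", t0,
                        n=panel.n, n_edges=len(skeleton.edges))

        extra = _extra_columns(sample, panel)
        base_conf = tuple((*config.confounders, "total_cer", "total_dhcer"))

        # --- single-lipid FDR screen -------------------------------------
        t0 = time.time()
        specs = {
            "minimal": CoxSpec(exposures=(), confounders=("sex",),
                               endpoint=endpoint),
            "full": CoxSpec(exposures=(), confounders=base_conf,
                            endpoint=endpoint),
        }
        screen = single_lipid_screen(sample, panel, specs,
                                     fdr_level=config.fdr_level,
                                     extra_columns=extra)
        screen.to_csv(ep_dir / "screening.tsv", sep="\t", index=False)
        manifest.record(f"screen[{endpoint}]", t0, n_models=len(screen))

        # --- network-coupled direct-effect selection ----------------------
        t0 = time.time()
        base_spec = CoxSpec(exposures=(), confounders=base_conf,
                            endpoint=endpoint)
        result = nc.netcoupler_iterate(
            sample, skeleton, base_spec, alpha=config.alpha_netcoupler,
            extra_columns=extra, cap=2 ** config.degree_cap)
        result.decision_table().to_csv(ep_dir / "decisions.tsv",
                                       sep="\t", index=False)
        result.joint_table().to_csv(ep_dir / "joint_model.tsv",
                                    sep="\t", index=False)
        manifest.record(f"netcoupler[{endpoint}]", t0,
                        selected=list(result.selected),
                        iterations=result.iterations)
        results[endpoint] = {"sample": sample, "panel": panel,
                             "extra": extra, "netcoupler": result}

        # --- mediation (diet exposures; needs joint-model signs) ---------
        t0 = time.time()
        med_rows = []
        if result.joint_fit is not None:
            signs = {m: result.joint_fit.log_hr[m] for m in result.selected}
            for exposure in cohort.diet:
                confs = tuple((*config.confounders,
                               *(d for d in cohort.diet if d != exposure)))
                r = med.run_mediation(
                    sample, exposure, signs, confs,
                    extra_columns=extra, B=config.bootstrap_B,
                    sampling_fraction=config.bootstrap_fraction,
                    seed=config.seed + 3)
                if r is not None:
                    med_rows.append(r.row())
        pd.DataFrame(med_rows).to_csv(ep_dir / "mediation.tsv",
                                      sep="\t", index=False)
        manifest.record(f"mediation[{endpoint}]", t0, n_exposures=len(med_rows))

    # --- synthetic two-sample MR -----------------------------------------
    t0 = time.time()
    mr_table = _synthetic_mr(truth, config)
    mr_table.to_csv(out / "mr.tsv", sep="\t", index=False)
    manifest.record("mr", t0, n_rows=len(mr_table))
    return out


def _synthetic_mr(truth, config: RunConfig) -> pd.DataFrame:
    """Two-sample MR on independently simulated exposure and outcome cohorts."""
    inst = truth.instrument_spec
    if inst is None:
        return pd.DataFrame()
    endpoint = config.endpoints[0]
    exp_cohort = simulate_cohort(truth, max(config.n, 2000),
                                 seed=config.seed + 11,
                                 case_fraction=config.case_fraction)
    out_cohort = simulate_cohort(truth, max(config.n, 2000),
                                 seed=config.seed + 12,
                                 case_fraction=config.case_fraction)
    zpanel = log_z_transform(exp_cohort.data[list(exp_cohort.metabolites)])
    exp_assoc = mr_mod.snp_association(
        exp_cohort.data["dosage"].to_numpy(),
        zpanel.data[inst.target].to_numpy(),
        covariates=exp_cohort.data[["sex"]],
        snp=inst.snp_id, effect_allele=inst.effect_allele,
        other_allele=inst.other_allele)
    out_assoc = mr_mod.snp_association(
        out_cohort.data["dosage"].to_numpy(),
        out_cohort.data[f"event_{endpoint}"].to_numpy(),
        covariates=out_cohort.data[["sex"]],
        snp=inst.snp_id, effect_allele=inst.effect_allele,
        other_allele=inst.other_allele, binary=True)
    res = mr_mod.wald_ratio(mr_mod.harmonize(exp_assoc, out_assoc))
    return pd.DataFrame([{
        "snp": res.snp, "endpoint": endpoint,
        "beta_exposure": exp_assoc.beta, "se_exposure": exp_assoc.se,
        "beta_outcome": out_assoc.beta, "se_outcome": out_assoc.se,
        "WR": res.wr, "SE": res.se, "p": res.p,
    }])
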