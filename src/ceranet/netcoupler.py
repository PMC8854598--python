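"""Direct-effect classification of network metabolites against disease risk.

For each metabolite, one Cox model is fitted per subset of its conditional-
independence-network neighbors (on top of a fixed confounder set and the two
lipid-class totals).  A metabolite is a *direct effector* when its association
with the endpoint is significant (p < alpha) with a consistent sign across
every such sub-model; it is *none* when no sub-model is significant, and
*ambiguous* otherwise.  Because established direct effectors can only act as
confounders of the remaining candidates (not mediators), each round's new
effectors join a fixed adjustment set and the scan repeats until a round adds
none; all selected metabolites then enter one joint, mutually adjusted model.

The fixed set grows monotonically, so the loop terminates in at most p rounds.
New effectors are batch-added at round end, which (together with canonical
node ordering) makes the selection invariant to metabolite input order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Skeleton, neighbors
from .preprocess import StandardizedPanel, log_z_transform
from .survival import CoxFit, CoxSpec, fit_prentice_cox
from .synth_cohort import CaseCohortSample

__all__ = [
    "EffectDecision",
    "NetCouplerResult",
    "class_totals",
    "enumerate_adjustment_sets",
    "classify_direct_effect",
    "netcoupler_iterate",
    "joint_model",
]

DEFAULT_SUBMODEL_CAP = 2 ** 10


@dataclass
class EffectDecision:
    """Outcome of the all-neighbor-subset scan for one metabolite."""

    metabolite: str
    endpoint: str
    classification: str                  # direct | ambiguous | none | unresolved
    submodel_count: int
    log_hr_range: tuple[float, float]
    max_p: float
    sign_consistent: bool
    iteration: int

    def row(self) -> dict:
        return {
            "metabolite": self.metabolite, "endpoint": self.endpoint,
            "classification": self.classification,
            "n_submodels": self.submodel_count,
            "logHR_min": self.log_hr_range[0], "logHR_max": self.log_hr_range[1],
            "p_max": self.max_p, "iteration": self.iteration,
        }


@dataclass
class NetCouplerResult:
    """Selection trace, final selected set and the joint mutually adjusted model."""

    decisions: list[EffectDecision]
    selected: tuple[str, ...]
    joint_fit: CoxFit | None
    iterations: int
    endpoint: str

    def decision_table(self) -> pd.DataFrame:
        return pd.DataFrame([d.row() for d in self.decisions])

    def joint_table(self) -> pd.DataFrame:
        if self.joint_fit is None:
            return pd.DataFrame()
        return pd.DataFrame([self.joint_fit.row(m) for m in self.selected])


def class_totals(raw_panel: pd.DataFrame, classes: dict[str, list[str]] | None = None
                 ) -> pd.DataFrame:
    """Total per-class concentrations as adjustment covariates.

    Sums are taken on the raw nM scale and then log-z transformed, mirroring
    their role as "total ceramide" / "total dihydroceramide" adjustments.
    Class membership defaults to the dhCer/Cer name prefixes.
    """
    if classes is None:
        classes = {
            "total_dhcer": [c for c in raw_panel.columns if c.startswith("dhCer")],
            "total_cer": [c for c in raw_panel.columns
                          if c.startswith("Cer") and not c.startswith("dhCer")],
        }
    sums = pd.DataFrame({name: raw_panel[cols].sum(axis=1)
                         for name, cols in classes.items() if cols})
    return log_z_transform(sums).data


def enumerate_adjustment_sets(
    skeleton: Skeleton,
    node: str,
    fixed_set: frozenset | set = frozenset(),
    cap: int = DEFAULT_SUBMODEL_CAP,
) -> list[tuple[str, ...]]:
    """All subsets of neighbors(node) excluding the fixed set, in a
    deterministic (size, then lexicographic) order; includes the empty and
    the full set."""
    nb = sorted(neighbors(skeleton, node) - set(fixed_set))
    if 2 ** len(nb) > cap:
        raise ValueError(
            f"{node} has {len(nb)} free neighbors -> 2^{len(nb)} submodels "
            f"exceeds the cap of {cap}")
    out: list[tuple[str, ...]] = []
    for size in range(len(nb) + 1):
        out.extend(itertools.combinations(nb, size))
    return out


def classify_direct_effect(
    sample: CaseCohortSample,
    node: str,
    skeleton: Skeleton,
    base_spec: CoxSpec,
    fixed_set: frozenset | set = frozenset(),
    alpha: float = 0.05,
    extra_columns: pd.DataFrame | None = None,
    iteration: int = 0,
    cap: int = DEFAULT_SUBMODEL_CAP,
) -> EffectDecision:
    """Scan all neighbor-subset Cox models for one metabolite.

    Each sub-model adjusts for the base confounders plus the fixed set plus
    one neighbor subset.  ``extra_columns`` supplies the standardized
    metabolite values (and class totals) aligned to the sample rows.
    """
    subsets = enumerate_adjustment_sets(skeleton, node, fixed_set, cap=cap)
    betas, pvals = [], []
    for subset in subsets:
        confs = tuple(dict.fromkeys(
            (*base_spec.confounders, *sorted(fixed_set), *subset)))
        spec = CoxSpec(
            exposures=(node,), confounders=confs, endpoint=base_spec.endpoint,
            stratify_by_age_band=base_spec.stratify_by_age_band,
            age_band_years=base_spec.age_band_years)
        try:
            fit = fit_prentice_cox(sample, spec, extra_columns=extra_columns)
        except Exception:
            return EffectDecision(
                metabolite=node, endpoint=base_spec.endpoint,
                classification="unresolved", submodel_count=len(subsets),
                log_hr_range=(float("nan"), float("nan")), max_p=float("nan"),
                sign_consistent=False, iteration=iteration)
        betas.append(fit.log_hr[node])
        pvals.append(fit.p[node])
    betas_a, pvals_a = np.array(betas), np.array(pvals)
    sign_consistent = bool(np.all(betas_a > 0) or np.all(betas_a < 0))
    max_p = float(pvals_a.max())
    if sign_consistent and max_p < alpha:
        cls = "direct"
    elif bool(np.all(pvals_a >= alpha)):
        cls = "none"
    else:
        cls = "ambiguous"
    return EffectDecision(
        metabolite=node, endpoint=base_spec.endpoint, classification=cls,
        submodel_count=len(subsets),
        log_hr_range=(float(betas_a.min()), float(betas_a.max())),
        max_p=max_p, sign_consistent=sign_consistent, iteration=iteration)


def netcoupler_iterate(
    sample: CaseCohortSample,
    skeleton: Skeleton,
    base_spec: CoxSpec,
    alpha: float = 0.05,
    extra_columns: pd.DataFrame | None = None,
    cap: int = DEFAULT_SUBMODEL_CAP,
) -> NetCouplerResult:
    """Round-based direct-effector selection with a growing fixed set."""
    metabolites = sorted(skeleton.nodes)
    selected: list[str] = []
    decisions: list[EffectDecision] = []
    iteration = 0
    while True:
        iteration += 1
        fixed = frozenset(selected)
        newly: list[str] = []
        for node in metabolites:
            if node in selected:
                continue
            dec = classify_direct_effect(
                sample, node, skeleton, base_spec, fixed_set=fixed,
                alpha=alpha, extra_columns=extra_columns, iteration=iteration,
                cap=cap)
            decisions.append(dec)
            if dec.classification == "direct":
                newly.append(node)
        if not newly:
            break
        selected.extend(sorted(newly))       # batch update at round end
        if iteration >= len(metabolites):
            break
    fit = None
    if selected:
        fit = joint_model(sample, tuple(sorted(selected)), base_spec,
                          extra_columns=extra_columns)
    return NetCouplerResult(
        decisions=decisions, selected=tuple(sorted(selected)),
        joint_fit=fit, iterations=iteration, endpoint=base_spec.endpoint)


def joint_model(
    sample: CaseCohortSample,
    selected: tuple[str, ...],
    base_spec: CoxSpec,
    extra_columns: pd.DataFrame | None = None,
) -> CoxFit:
    """One Prentice-weighted Cox fit with all selected metabolites as
    simultaneous exposures (mutually adjusted hazard ratios)."""
    if not selected:
        raise ValueError("selected set is empty")
    spec = CoxSpec(
        exposures=tuple(selected), confounders=base_spec.confounders,
        endpoint=base_spec.endpoint,
        stratify_by_age_band=base_spec.stratify_by_age_band,
        age_band_years=base_spec.age_band_years)
    return fit_prentice_cox(sample, spec, extra_columns=extra_columns)
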