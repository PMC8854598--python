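"""Synthetic case-cohort generator for (dihydro)ceramide–disease analyses.

Emulates the statistical structure the downstream pipeline assumes: a sparse
linear-Gaussian network of log-scale metabolite concentrations (exponentiated
to right-tailed nM values), observed confounders loading on both metabolites
and hazard, proportional-hazards event generation with age as the time scale
(left truncation at the recruitment age, administrative censoring), diet
exposures acting partly through designated mediator metabolites, a single
genetic instrument acting on one metabolite, and case-cohort sampling
(random subcohort plus all incident cases).

Every draw is reproducible from the integer seed carried by the spec objects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfounderSpec",
    "MediationSpec",
    "InstrumentSpec",
    "GroundTruth",
    "CohortTable",
    "CaseCohortSample",
    "generate_ground_truth",
    "default_ground_truth",
    "mediation_benchmark_truth",
    "implied_log_covariance",
    "simulate_cohort",
    "draw_case_cohort",
    "simulate_repeat_measures",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "ground_truth_to_yaml",
    "ground_truth_from_yaml",
]


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfounderSpec:
    """An observed confounder: loads on metabolites and on the hazard."""

    loadings: Mapping[str, float]          # metabolite -> linear loading (log scale)
    log_hr: Mapping[str, float]            # endpoint -> log-HR per unit


@dataclass(frozen=True)
class MediationSpec:
    """A diet exposure acting on mediator metabolites plus a direct hazard path."""

    mediators: Mapping[str, float]         # metabolite -> exposure->metabolite coefficient
    direct_log_hr: Mapping[str, float]     # endpoint -> non-mediated log-HR per unit


@dataclass(frozen=True)
class InstrumentSpec:
    """A biallelic SNP instrument with an additive effect on one metabolite."""

    snp_id: str
    maf: float                             # minor-allele frequency, in [0.05, 0.5]
    target: str                            # instrumented metabolite
    beta_per_allele: float                 # effect in SD units of the target
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not (0.05 <= self.maf <= 0.5):
            raise ValueError(f"MAF {self.maf} outside [0.05, 0.5]")


@dataclass(frozen=True)
class GroundTruth:
    """The generating model: weighted DAG, hazards, mediation, instrument."""

    metabolite_names: tuple[str, ...]
    dag_edges: tuple[tuple[str, str, float], ...]
    confounders: Mapping[str, ConfounderSpec]
    direct_log_hr: Mapping[str, Mapping[str, float]]   # endpoint -> metabolite -> log-HR per SD
    mediation_spec: Mapping[str, MediationSpec]        # exposure -> spec
    instrument_spec: InstrumentSpec | None
    log_means: Mapping[str, float]                     # per-metabolite log-nM intercept
    seed: int

    def __post_init__(self) -> None:
        names = self.metabolite_names
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_weighted_edges_from(self.dag_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("dag_edges contain a cycle")
        unknown = {u for e in self.dag_edges for u in e[:2]} - set(names)
        if unknown:
            raise ValueError(f"edge endpoints not in metabolite_names: {sorted(unknown)}")

    @property
    def endpoints(self) -> tuple[str, ...]:
        return tuple(self.direct_log_hr)

    def adjacency(self) -> pd.DataFrame:
        """True undirected skeleton as a 0/1 adjacency matrix (nonzero weights only)."""
        p = len(self.metabolite_names)
        a = pd.DataFrame(np.zeros((p, p), dtype=int),
                         index=self.metabolite_names, columns=self.metabolite_names)
        for u, v, w in self.dag_edges:
            if w != 0.0:
                a.loc[u, v] = a.loc[v, u] = 1
        return a


def _chain_names(prefix: str, p: int) -> list[str]:
    # acyl chains 14, 16, ... carbons, fully saturated
    return [f"{prefix}{14 + 2 * i}:0" for i in range(p)]


def generate_ground_truth(
    p_cer: int,
    p_dhcer: int,
    topology: str = "elongation_chain",
    edge_weight_range: tuple[float, float] = (0.3, 0.6),
    effect_spec: Mapping | None = None,
    seed: int = 0,
    density: float = 0.2,
) -> GroundTruth:
    """Build a generating network over a ceramide + dihydroceramide panel.

    ``elongation_chain`` links consecutive chain lengths within each lipid
    class (fatty-acid elongation) and same-chain-length dihydroceramide ->
    ceramide pairs (desaturation).  ``random_sparse`` draws a random DAG in
    the listed node order with the given expected edge density.

    ``effect_spec`` may carry any of the keys ``direct_log_hr``,
    ``confounders``, ``mediation``, ``instrument`` and ``log_means`` to
    override the (null) defaults; values use the same shapes as the
    corresponding :class:`GroundTruth` fields.
    """
    if p_cer < 1 or p_dhcer < 1:
        raise ValueError("p_cer and p_dhcer must each be >= 1")
    lo, hi = edge_weight_range
    rng = np.random.default_rng(seed)
    cer = _chain_names("Cer", p_cer)
    dhcer = _chain_names("dhCer", p_dhcer)
    names = tuple(dhcer + cer)

    edges: list[tuple[str, str, float]] = []

    def w() -> float:
        return float(rng.uniform(lo, hi))

    if topology == "elongation_chain":
        for cls in (dhcer, cer):
            for a, b in zip(cls, cls[1:]):          # elongation steps
                edges.append((a, b, w()))
        for d in dhcer:                              # desaturation dhCerX:0 -> CerX:0
            partner = "Cer" + d[len("dhCer"):]
            if partner in cer:
                edges.append((d, partner, w()))
    elif topology == "random_sparse":
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if rng.uniform() < density:
                    edges.append((names[i], names[j], w()))
    else:
        raise ValueError(f"unknown topology {topology!r}")

    spec = dict(effect_spec or {})
    confounders = spec.get("confounders")
    if confounders is None:
        confounders = {
            "adiposity": ConfounderSpec(
                loadings={m: 0.2 for m in names},
                log_hr={ep: 0.3 for ep in spec.get("direct_log_hr", {"t2d": {}})},
            )
        }
    direct = {ep: {m: float(d.get(m, 0.0)) for m in names}
              for ep, d in spec.get("direct_log_hr", {"t2d": {}}).items()}
    log_means = spec.get("log_means")
    if log_means is None:
        # median concentrations spread over ~0.2 .. 40 nM across the panel
        log_means = {m: float(v) for m, v in
                     zip(names, np.linspace(np.log(0.2), np.log(40.0), len(names)))}
    return GroundTruth(
        metabolite_names=names,
        dag_edges=tuple(edges),
        confounders=confounders,
        direct_log_hr=direct,
        mediation_spec=spec.get("mediation", {}),
        instrument_spec=spec.get("instrument"),
        log_means=log_means,
        seed=seed,
    )


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """The reference study conditions: 13 dihydroceramides + 12 ceramides on an
    elongation/desaturation chain, six true direct T2D effectors of mixed sign,
    red-meat and coffee exposures acting partly through designated mediators,
    and one SNP instrument on a very-long-chain ceramide."""
    direct = {
        "t2d": {
            "Cer18:0": 0.40, "Cer22:0": 0.40, "dhCer20:0": 0.30,
            "dhCer22:0": 0.30, "Cer20:0": -0.30, "dhCer26:0": -0.30,
        },
        "cvd": {"Cer16:0": 0.35, "dhCer22:0": 0.35},
    }
    mediation = {
        "red_meat": MediationSpec(
            mediators={"Cer18:0": 0.15, "dhCer20:0": 0.15,
                       "Cer20:0": -0.15, "dhCer26:0": -0.15},
            direct_log_hr={"t2d": 0.05, "cvd": 0.0},
        ),
        "coffee": MediationSpec(
            mediators={"dhCer22:0": -0.15},
            direct_log_hr={"t2d": -0.04, "cvd": 0.0},
        ),
    }
    instrument = InstrumentSpec(
        snp_id="rs_synth_1", maf=0.3, target="Cer22:0", beta_per_allele=0.2,
    )
    return generate_ground_truth(
        p_cer=12, p_dhcer=13, topology="elongation_chain",
        edge_weight_range=(0.3, 0.6),
        effect_spec={
            "direct_log_hr": direct,
            "mediation": mediation,
            "instrument": instrument,
        },
        seed=seed,
    )


def mediation_benchmark_truth(
    pe_target: float = 0.5,
    mediator_log_hr: float = 0.4,
    direct_exposure_log_hr: float = 0.15,
    seed: int = 0,
) -> GroundTruth:
    """A two-metabolite design whose true mediated proportion is known.

    One diet exposure acts on the endpoint directly (log-HR ``d`` per unit)
    and through a single root mediator whose per-SD hazard effect is ``b``.
    The exposure->mediator coefficient ``a`` is chosen so the mediated path
    contributes d * pe/(1-pe): with the mediator's log-scale variance
    1 + l^2 + a^2 (unit noise plus confounder loading l plus the exposure),
    a*b/sd = d*pe/(1-pe) solves in closed form.  The designed proportion
    explainable is therefore ``pe_target`` exactly on the log-HR scale.
    """
    d, b = direct_exposure_log_hr, mediator_log_hr
    ratio = pe_target / (1.0 - pe_target)
    m = d * ratio                                   # mediated contribution
    l2 = 1.0 + 0.2**2                               # noise + confounder loading
    if b**2 <= m**2:
        raise ValueError("mediator hazard effect too weak for the target")
    a = m * np.sqrt(l2) / np.sqrt(b**2 - m**2)
    mediator = "dhCer14:0"
    return generate_ground_truth(
        p_cer=1, p_dhcer=1, topology="elongation_chain",
        edge_weight_range=(0.4, 0.4),
        effect_spec={
            "direct_log_hr": {"t2d": {mediator: b}},
            "mediation": {"diet_x": MediationSpec(
                mediators={mediator: a},
                direct_log_hr={"t2d": d})},
        },
        seed=seed)


def implied_log_covariance(truth: GroundTruth,
                           structural_only: bool = False) -> pd.DataFrame:
    """Model-implied covariance of the log-scale metabolites, in closed form.

    With structural weights W (W[i, j] = coefficient of parent i on child j),
    unit-variance noise, unit-variance confounder/diet exposures and a
    binomial(2, maf) dosage, the metabolite vector is a linear map of the
    exogenous variables and its covariance is B S B' with B = (I - W')^-1.

    ``structural_only`` drops the shared exogenous contributions (confounders,
    diet, dosage), leaving the pure DAG-plus-noise covariance.  Shared
    loadings act as latent common causes among the metabolites, so only the
    structural covariance has the DAG's d-separation structure; use it for
    population-oracle conditional-independence checks.
    """
    names = list(truth.metabolite_names)
    p = len(names)
    ix = {m: i for i, m in enumerate(names)}
    W = np.zeros((p, p))
    for u, v, wgt in truth.dag_edges:
        W[ix[u], ix[v]] = wgt
    B = np.linalg.inv(np.eye(p) - W.T)
    S = np.eye(p)                                   # unit noise variances
    if structural_only:
        return pd.DataFrame(B @ S @ B.T, index=names, columns=names)
    for conf in truth.confounders.values():
        l = np.zeros(p)
        for m, v in conf.loadings.items():
            l[ix[m]] = v
        S += np.outer(l, l)
    for med in truth.mediation_spec.values():
        l = np.zeros(p)
        for m, v in med.mediators.items():
            l[ix[m]] = v
        S += np.outer(l, l)
    inst = truth.instrument_spec
    if inst is not None:
        # the per-allele effect is expressed in SD units of the target
        # metabolite; on the log scale it is scaled by the target's
        # instrument-free SD (see _instrument_log_effect)
        base = B @ S @ B.T
        sd0 = np.sqrt(base[ix[inst.target], ix[inst.target]])
        l = np.zeros(p)
        l[ix[inst.target]] = inst.beta_per_allele * sd0
        S += 2.0 * inst.maf * (1.0 - inst.maf) * np.outer(l, l)
    cov = B @ S @ B.T
    return pd.DataFrame(cov, index=names, columns=names)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Subject-level cohort data: one row per subject.

    ``data`` holds entry_age, per-endpoint exit_age_<ep> / event_<ep> columns,
    covariates, raw metabolite concentrations (nM, strictly positive where
    observed), diet exposures and the genotype dosage.
    """

    data: pd.DataFrame
    metabolites: tuple[str, ...]
    covariates: tuple[str, ...]
    diet: tuple[str, ...]
    endpoints: tuple[str, ...]
    truth: GroundTruth | None = None
    repeat_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for ep in self.endpoints:
            bad = self.data[f"exit_age_{ep}"] <= self.data["entry_age"]
            if bad.any():
                raise ValueError(f"exit_age_{ep} <= entry_age for {int(bad.sum())} subjects")
            ev = self.data[f"event_{ep}"]
            if not ev.isin((0, 1)).all():
                raise ValueError("event indicators must be 0/1")
        raw = self.data[list(self.metabolites)]
        if (raw.le(0)).any().any():
            raise ValueError("raw concentrations must be positive where observed")

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass
class CaseCohortSample:
    """Rows of a cohort restricted to (random subcohort) union (all cases)."""

    data: pd.DataFrame                      # includes entry_age, exit_age, event,
    endpoint: str                           # subcohort (bool), case (bool)
    metabolites: tuple[str, ...]
    covariates: tuple[str, ...]
    diet: tuple[str, ...] = ()
    n_cases_in_subcohort: int = 0

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())


def _weibull_event_times(
    entry: np.ndarray, lp: np.ndarray, exp_draws: np.ndarray,
    shape: float, scale: float,
) -> np.ndarray:
    """Event ages under a Weibull baseline hazard on the age axis, conditional
    on being event-free at the entry age (left truncation by inversion)."""
    h_entry = (entry / scale) ** shape
    return scale * (h_entry + exp_draws * np.exp(-lp)) ** (1.0 / shape)


def _calibrate_scale(
    entry: np.ndarray, censor: np.ndarray, lp: np.ndarray, exp_draws: np.ndarray,
    shape: float, target_fraction: float,
) -> float:
    """Bisect the Weibull scale so the realized case fraction hits the target."""
    lo, hi = 40.0, 2000.0

    def frac(scale: float) -> float:
        t = _weibull_event_times(entry, lp, exp_draws, shape, scale)
        return float(np.mean(t <= censor))

    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _instrument_log_effect(truth: GroundTruth) -> float:
    """Per-allele effect on the target's log concentration such that the
    effect equals ``beta_per_allele`` in (instrument-free) SD units."""
    inst = truth.instrument_spec
    base = implied_log_covariance(dataclasses.replace(truth, instrument_spec=None))
    sd0 = float(np.sqrt(base.loc[inst.target, inst.target]))
    return inst.beta_per_allele * sd0


def simulate_cohort(
    truth: GroundTruth,
    n: int,
    baseline_age_range: tuple[float, float] = (35.0, 65.0),
    admin_censor_years: float = 10.0,
    seed: int = 0,
    case_fraction: float = 0.12,
    weibull_shape: float = 5.0,
    missing_rate: float = 0.0,
) -> CohortTable:
    """Draw a full synthetic cohort from the generating model.

    Metabolites follow the linear-Gaussian structural model on the log scale
    and are exponentiated to nM concentrations.  Event ages per endpoint come
    from a proportional-hazards model with a Weibull baseline hazard on the
    age axis whose scale is calibrated to the requested case fraction; exits
    are administratively censored at entry + ``admin_censor_years``.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    rng = np.random.default_rng(seed)
    names = list(truth.metabolite_names)
    p = len(names)
    ix = {m: i for i, m in enumerate(names)}

    conf_names = list(truth.confounders)
    conf_vals = {c: rng.standard_normal(n) for c in conf_names}
    sex = rng.integers(0, 2, size=n).astype(float)
    diet_names = list(truth.mediation_spec)
    diet_vals = {d: rng.standard_normal(n) for d in diet_names}
    inst = truth.instrument_spec
    dosage = (rng.binomial(2, inst.maf, size=n).astype(float)
              if inst is not None else None)
    inst_coef = _instrument_log_effect(truth) if inst is not None else 0.0

    # structural model on the log scale, in topological order
    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_weighted_edges_from(truth.dag_edges)
    x = np.zeros((n, p))
    noise = rng.standard_normal((n, p))
    for node in nx.topological_sort(g):
        j = ix[node]
        v = noise[:, j].copy()
        for parent, _, w in g.in_edges(node, data="weight"):
            v += w * x[:, ix[parent]]
        for c in conf_names:
            v += truth.confounders[c].loadings.get(node, 0.0) * conf_vals[c]
        for d in diet_names:
            v += truth.mediation_spec[d].mediators.get(node, 0.0) * diet_vals[d]
        if inst is not None and node == inst.target:
            v += inst_coef * (dosage - 2.0 * inst.maf)
        x[:, j] = v

    implied_sd = np.sqrt(np.diag(implied_log_covariance(truth).to_numpy()))
    z = x / implied_sd                                  # true per-SD scale
    raw = np.exp(np.array([truth.log_means[m] for m in names]) + x)

    entry = rng.uniform(*baseline_age_range, size=n)
    censor = entry + admin_censor_years
    cols = {
        "subject_id": np.arange(n),
        "entry_age": entry,
        "sex": sex,
    }
    for c in conf_names:
        cols[c] = conf_vals[c]
    for d in diet_names:
        cols[d] = diet_vals[d]
    if dosage is not None:
        cols["dosage"] = dosage
    cols["lipid_lowering"] = rng.binomial(1, 0.1, size=n).astype(float)

    for ep in truth.endpoints:
        lp = z @ np.array([truth.direct_log_hr[ep].get(m, 0.0) for m in names])
        lp = lp + 0.2 * sex
        for c in conf_names:
            lp = lp + truth.confounders[c].log_hr.get(ep, 0.0) * conf_vals[c]
        for d in diet_names:
            lp = lp + truth.mediation_spec[d].direct_log_hr.get(ep, 0.0) * diet_vals[d]
        draws = rng.exponential(size=n)
        scale = _calibrate_scale(entry, censor, lp, draws, weibull_shape, case_fraction)
        t = _weibull_event_times(entry, lp, draws, weibull_shape, scale)
        event = (t <= censor).astype(int)
        exit_age = np.minimum(t, censor)
        exit_age = np.maximum(exit_age, entry + 1e-4)   # guard strict ordering
        cols[f"exit_age_{ep}"] = exit_age
        cols[f"event_{ep}"] = event

    df = pd.DataFrame(cols)
    raw_df = pd.DataFrame(raw, columns=names)
    if missing_rate > 0:
        mask = rng.uniform(size=raw_df.shape) < missing_rate
        raw_df = raw_df.mask(mask)
    df = pd.concat([df, raw_df], axis=1)

    return CohortTable(
        data=df,
        metabolites=tuple(names),
        covariates=("sex", *conf_names, "lipid_lowering"),
        diet=tuple(diet_names),
        endpoints=truth.endpoints,
        truth=truth,
    )


def draw_case_cohort(
    cohort: CohortTable,
    subcohort_fraction: float,
    endpoint: str,
    seed: int = 0,
) -> CaseCohortSample:
    """Random subcohort plus all incident cases for one endpoint."""
    if not (0 < subcohort_fraction <= 1):
        raise ValueError("subcohort_fraction must be in (0, 1]")
    if endpoint not in cohort.endpoints:
        raise KeyError(f"unknown endpoint {endpoint!r}")
    rng = np.random.default_rng(seed)
    n = cohort.n
    n_sub = int(round(subcohort_fraction * n))
    sub_idx = np.sort(rng.choice(n, size=n_sub, replace=False))
    in_sub = np.zeros(n, dtype=bool)
    in_sub[sub_idx] = True
    case = cohort.data[f"event_{endpoint}"].to_numpy().astype(bool)
    if not case.any():
        import warnings
        warnings.warn(f"endpoint {endpoint!r} has zero cases; returning subcohort only")
    keep = in_sub | case
    df = cohort.data.loc[keep].copy()
    df["subcohort"] = in_sub[keep]
    df["case"] = case[keep]
    df["exit_age"] = df[f"exit_age_{endpoint}"]
    df["event"] = df[f"event_{endpoint}"]
    return CaseCohortSample(
        data=df.reset_index(drop=True),
        endpoint=endpoint,
        metabolites=cohort.metabolites,
        covariates=cohort.covariates,
        diet=cohort.diet,
        n_cases_in_subcohort=int((in_sub & case).sum()),
    )


def simulate_repeat_measures(
    cohort: CohortTable,
    icc_target: float | Mapping[str, float],
    n_subjects: int,
    seed: int = 0,
) -> CohortTable:
    """Attach a second measurement for a random subset of subjects.

    The within-person (log-scale) variance is chosen so the expected one-way
    ICC of the resulting pairs equals the target: with the first measurement
    taken as the subject's level (empirical between-subject variance s2_b),
    adding noise of variance w = 2 s2_b (1 - icc) / icc to the duplicate gives
    E[MSB - MSW] / E[MSB + MSW] = icc.
    """
    names = list(cohort.metabolites)
    iccs = ({m: float(icc_target) for m in names}
            if np.isscalar(icc_target) else dict(icc_target))
    for m, v in iccs.items():
        if not (0 < v <= 1):
            raise ValueError(f"icc_target for {m} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(cohort.n, size=n_subjects, replace=False))
    df = cohort.data.copy()
    repeat_cols = []
    for m in names:
        icc = iccs.get(m)
        if icc is None:
            continue
        log_first = np.log(df[m].to_numpy(dtype=float)[chosen])
        s2_b = np.var(log_first, ddof=1)
        w = 2.0 * s2_b * (1.0 - icc) / icc
        log_second = log_first + np.sqrt(w) * rng.standard_normal(n_subjects)
        col = f"{m}__repeat"
        df[col] = np.nan
        df.loc[df.index[chosen], col] = np.exp(log_second)
        repeat_cols.append(col)
    return dataclasses.replace(cohort, data=df, repeat_columns=tuple(repeat_cols))


# --------------------------------------------------------------------------
# external interfaces
# --------------------------------------------------------------------------

def write_cohort_tsv(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_tsv(
    path,
    metabolites: Sequence[str],
    covariates: Sequence[str],
    diet: Sequence[str] = (),
    endpoints: Sequence[str] = ("t2d",),
) -> CohortTable:
    df = pd.read_csv(path, sep="\t")
    return CohortTable(
        data=df, metabolites=tuple(metabolites), covariates=tuple(covariates),
        diet=tuple(diet), endpoints=tuple(endpoints),
    )


def ground_truth_to_yaml(truth: GroundTruth, path) -> None:
    doc = {
        "metabolites": list(truth.metabolite_names),
        "edges": [{"source": u, "target": v, "weight": float(w)}
                  for u, v, w in truth.dag_edges],
        "confounders": {c: {"loadings": dict(s.loadings), "log_hr": dict(s.log_hr)}
                        for c, s in truth.confounders.items()},
        "direct_log_hr": {ep: dict(d) for ep, d in truth.direct_log_hr.items()},
        "mediation": {e: {"mediators": dict(s.mediators),
                          "direct_log_hr": dict(s.direct_log_hr)}
                      for e, s in truth.mediation_spec.items()},
        "instrument": (None if truth.instrument_spec is None else {
            "snp_id": truth.instrument_spec.snp_id,
            "maf": truth.instrument_spec.maf,
            "target": truth.instrument_spec.target,
            "beta_per_allele": truth.instrument_spec.beta_per_allele,
            "effect_allele": truth.instrument_spec.effect_allele,
            "other_allele": truth.instrument_spec.other_allele,
        }),
        "log_means": {m: float(v) for m, v in truth.log_means.items()},
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def ground_truth_from_yaml(path) -> GroundTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    inst = doc.get("instrument")
    return GroundTruth(
        metabolite_names=tuple(doc["metabolites"]),
        dag_edges=tuple((e["source"], e["target"], float(e["weight"]))
                        for e in doc["edges"]),
        confounders={c: ConfounderSpec(loadings=s["loadings"], log_hr=s["log_hr"])
                     for c, s in doc.get("confounders", {}).items()},
        direct_log_hr=doc["direct_log_hr"],
        mediation_spec={e: MediationSpec(mediators=s["mediators"],
                                         direct_log_hr=s["direct_log_hr"])
                        for e, s in doc.get("mediation", {}).items()},
        instrument_spec=None if inst is None else InstrumentSpec(**inst),
        log_means=doc["log_means"],
        seed=int(doc.get("seed", 0)),
    )
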