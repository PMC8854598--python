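"""Two-sample univariable Mendelian randomization via Wald ratios.

Includes a small-scale additive genetic association routine (for synthetic
instruments), instrument selection by lowest p among replicable SNPs, allele
harmonization between exposure and outcome summary statistics, and the Wald
ratio WR = beta_outcome / beta_exposure with the first-order standard error
SE = SE_outcome / |beta_exposure| (the exposure uncertainty is ignored; a
second-order SE is available behind a flag).  Summary statistics travel as
tab-separated text with columns snp, effect_allele, other_allele, beta, se,
p, n.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "InstrumentAssociation",
    "HarmonizedPair",
    "MRResult",
    "snp_association",
    "select_instrument",
    "harmonize",
    "wald_ratio",
    "read_summary_stats",
    "write_summary_stats",
]

PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class InstrumentAssociation:
    """Per-effect-allele association of one SNP with a phenotype or outcome."""

    snp: str
    effect_allele: str
    other_allele: str
    beta: float                  # exposure: per SD of phenotype; outcome: log-odds
    se: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("SE must be positive")
        if self.effect_allele == self.other_allele:
            raise ValueError("alleles must be distinct")


@dataclass(frozen=True)
class HarmonizedPair:
    exposure: InstrumentAssociation
    outcome: InstrumentAssociation
    flipped: bool
    palindromic: bool


@dataclass(frozen=True)
class MRResult:
    """Single-instrument Wald-ratio estimate (outcome units per SD exposure)."""

    snp: str
    wr: float
    se: float
    p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"snp": self.snp, "WR": self.wr,
                              "SE": self.se, "p": self.p}])


def snp_association(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    snp: str = "snp",
    effect_allele: str = "A",
    other_allele: str = "G",
    binary: bool = False,
) -> InstrumentAssociation:
    """Additive-dosage association: least squares for a continuous
    (standardized) phenotype, logistic regression (log-odds per allele) for a
    binary outcome.  The SNP must pass the MAF filter [0.05, 0.5]."""
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    freq = dosage.mean() / 2.0
    maf = min(freq, 1.0 - freq)
    if maf == 0:
        raise ValueError("monomorphic SNP")
    if not (0.05 <= maf <= 0.5):
        raise ValueError(f"MAF {maf:.4f} outside [0.05, 0.5]")
    cols = [dosage]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cols.append(cov if cov.ndim == 2 else cov[:, None])
    X = sm.add_constant(np.column_stack(cols))
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few observations for the covariate count")
    if binary:
        res = sm.Logit(y, X).fit(disp=False)
    else:
        res = sm.OLS(y, X).fit()
    return InstrumentAssociation(
        snp=snp, effect_allele=effect_allele, other_allele=other_allele,
        beta=float(res.params[1]), se=float(res.bse[1]),
        p=float(res.pvalues[1]), n=len(y))


def select_instrument(
    associations: list[InstrumentAssociation],
    threshold: float = 1e-5,
    availability: set[str] | None = None,
) -> tuple[str | None, str]:
    """The qualifying SNP (p < threshold, replicable) with the lowest p.

    ``availability`` restricts to SNPs present in the external replication
    data.  Ties break lexicographically by SNP id.  Returns (snp_id, reason);
    snp_id is None when nothing qualifies.
    """
    if not associations:
        raise ValueError("no associations supplied")
    pool = [a for a in associations if a.p < threshold]
    if not pool:
        return None, f"no association with p < {threshold:g}"
    if availability is not None:
        pool = [a for a in pool if a.snp in availability]
        if not pool:
            return None, "no suggestive SNP available for replication"
    best = min(pool, key=lambda a: (a.p, a.snp))
    return best.snp, "selected by lowest p among replicable SNPs"


def _is_palindromic(a: str, b: str) -> bool:
    return {a.upper(), b.upper()} in PALINDROMIC_PAIRS


def harmonize(
    exposure: InstrumentAssociation,
    outcome: InstrumentAssociation,
) -> HarmonizedPair:
    """Align the outcome's effect allele with the exposure's.

    If the outcome reports the exposure's *other* allele as its effect
    allele, its beta is negated.  Palindromic allele pairs (A/T, C/G) are
    flagged, not dropped.  Incompatible allele pairs are rejected.
    """
    if exposure.snp != outcome.snp:
        raise ValueError(f"snp mismatch: {exposure.snp} vs {outcome.snp}")
    e_pair = {exposure.effect_allele, exposure.other_allele}
    o_pair = {outcome.effect_allele, outcome.other_allele}
    if e_pair != o_pair:
        raise ValueError(f"incompatible allele pairs {e_pair} vs {o_pair}")
    palindromic = _is_palindromic(exposure.effect_allele, exposure.other_allele)
    if outcome.effect_allele == exposure.effect_allele:
        return HarmonizedPair(exposure, outcome, flipped=False,
                              palindromic=palindromic)
    flipped = replace(outcome, beta=-outcome.beta,
                      effect_allele=outcome.other_allele,
                      other_allele=outcome.effect_allele)
    return HarmonizedPair(exposure, flipped, flipped=True,
                          palindromic=palindromic)


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MRResult:
    """WR = beta_outcome / beta_exposure with first-order SE
    SE_outcome / |beta_exposure| (second order additionally propagates the
    exposure SE); two-sided normal p."""
    be, bo = pair.exposure.beta, pair.outcome.beta
    if be == 0:
        raise ValueError("exposure beta is zero: undefined instrument")
    wr = bo / be
    se = pair.outcome.se / abs(be)
    if second_order:
        se = float(np.sqrt(pair.outcome.se**2 / be**2
                           + bo**2 * pair.exposure.se**2 / be**4))
    p = float(2.0 * stats.norm.sf(abs(wr) / se))
    return MRResult(snp=pair.exposure.snp, wr=float(wr), se=float(se), p=p)


def implied_outcome_association(
    exposure: InstrumentAssociation,
    wr: float,
    wr_se: float,
    n: int = 0,
) -> InstrumentAssociation:
    """Invert a published Wald ratio to the SNP-outcome association it implies.

    In the exposure's allele coding: beta_outcome = WR x beta_exposure and
    (first order) se_outcome = SE(WR) x |beta_exposure|.  Used when an
    outcome GWAS beta is not published directly but a WR computed from it is.
    """
    bo = wr * exposure.beta
    so = wr_se * abs(exposure.beta)
    p = float(2.0 * stats.norm.sf(abs(bo) / so))
    return InstrumentAssociation(
        snp=exposure.snp, effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele, beta=float(bo), se=float(so),
        p=p, n=n)


def cross_cohort_wald_ratios(
    exposures: dict[str, InstrumentAssociation],
    outcome: InstrumentAssociation,
    second_order: bool = False,
) -> pd.DataFrame:
    """Wald ratios of one outcome association against several exposure
    cohorts, harmonizing alleles per cohort."""
    rows = []
    for cohort, exp in exposures.items():
        res = wald_ratio(harmonize(exp, outcome), second_order=second_order)
        rows.append({"cohort": cohort, "snp": res.snp, "WR": res.wr,
                     "SE": res.se, "p": res.p})
    return pd.DataFrame(rows)


def read_summary_stats(path) -> list[InstrumentAssociation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [InstrumentAssociation(
        snp=r.snp, effect_allele=r.effect_allele, other_allele=r.other_allele,
        beta=float(r.beta), se=float(r.se), p=float(r.p), n=int(r.n))
        for r in df.itertuples()]


def write_summary_stats(assocs: list[InstrumentAssociation], path) -> None:
    pd.DataFrame([{
        "snp": a.snp, "effect_allele": a.effect_allele,
        "other_allele": a.other_allele, "beta": a.beta, "se": a.se,
        "p": a.p, "n": a.n,
    } for a in assocs]).to_csv(path, sep="\t", index=False)
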