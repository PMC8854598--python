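"""Analysis-scale transformation, measurement reliability and correlation structure.

Raw (dh)ceramide concentrations are right-tailed; the analysis scale is the
natural log followed by per-column z-scaling (sample SD, denominator n-1), so
all downstream regression estimates are per 1 SD.  Subjects with missing or
non-positive values in any involved metabolite are excluded with a recorded
reason, mirroring per-analysis exclusion.

Reliability of repeat measurements is quantified by the one-way random-effects
intraclass correlation on the log scale, classified by Rosner's cutoffs
(< 0.40 poor, 0.40-0.75 fair to good, > 0.75 excellent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedPanel",
    "ReliabilityReport",
    "log_z_transform",
    "icc_one_way",
    "icc_class",
    "correlation_matrices",
]

ROSNER_POOR = 0.40
ROSNER_EXCELLENT = 0.75


@dataclass
class StandardizedPanel:
    """Log-transformed, z-scaled metabolite matrix with exclusion provenance."""

    data: pd.DataFrame                       # subjects x metabolites, mean 0 / SD 1
    transform_params: pd.DataFrame           # per-metabolite mean and SD of log values
    excluded_subjects: list[tuple[object, str]]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored log/standardization parameters to new raw values."""
        logged = np.log(raw[self.data.columns])
        return (logged - self.transform_params["mean"]) / self.transform_params["sd"]


def log_z_transform(raw_panel: pd.DataFrame) -> StandardizedPanel:
    """Natural log then per-column standardization with sample SD (ddof=1).

    Subjects with a missing or non-positive value in any column are excluded
    (with the offending column recorded); a constant column is rejected since
    its SD is undefined for standardization.
    """
    raw = raw_panel.copy()
    excluded: list[tuple[object, str]] = []
    missing = raw.isna()
    nonpos = raw.le(0) & ~missing
    bad = missing | nonpos
    for idx in raw.index[bad.any(axis=1)]:
        cols = list(raw.columns[bad.loc[idx]])
        reason = "missing" if missing.loc[idx].any() else "non-positive"
        excluded.append((idx, f"{reason} value in {', '.join(cols)}"))
    kept = raw.loc[~bad.any(axis=1)]
    if kept.empty:
        raise ValueError("no subjects left after exclusion")
    logged = np.log(kept.astype(float))
    sd = logged.std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        const = list(sd.index[(sd == 0) | sd.isna()])
        raise ValueError(f"constant column(s), SD undefined: {const}")
    mean = logged.mean()
    z = (logged - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return StandardizedPanel(data=z, transform_params=params, excluded_subjects=excluded)


def icc_class(icc: float) -> str:
    if icc < ROSNER_POOR:
        return "poor"
    if icc > ROSNER_EXCELLENT:
        return "excellent"
    return "fair_to_good"


@dataclass
class ReliabilityReport:
    """Per-metabolite one-way ICC with Rosner reliability class."""

    table: pd.DataFrame                      # columns: metabolite, icc, icc_class

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _icc_pairs(first: np.ndarray, second: np.ndarray) -> float:
    """One-way random-effects ICC for paired measurements (k = 2)."""
    y = np.column_stack([first, second])
    n, k = y.shape
    subj_mean = y.mean(axis=1)
    grand = y.mean()
    msb = k * np.sum((subj_mean - grand) ** 2) / (n - 1)
    msw = np.sum((y - subj_mean[:, None]) ** 2) / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


def icc_one_way(repeat_pairs: pd.DataFrame, log_scale: bool = True) -> ReliabilityReport:
    """ICC per metabolite from a table of measurement pairs.

    ``repeat_pairs`` has two columns per metabolite, named ``<m>`` and
    ``<m>__repeat``; rows without a second measurement are ignored.  At least
    3 complete pairs are required per metabolite.
    """
    mets = [c for c in repeat_pairs.columns if f"{c}__repeat" in repeat_pairs.columns]
    if not mets:
        raise ValueError("no <metabolite>/<metabolite>__repeat column pairs found")
    rows = []
    for m in mets:
        sub = repeat_pairs[[m, f"{m}__repeat"]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for {m}")
        a = sub[m].to_numpy(dtype=float)
        b = sub[f"{m}__repeat"].to_numpy(dtype=float)
        if log_scale:
            a, b = np.log(a), np.log(b)
        icc = _icc_pairs(a, b)
        rows.append({"metabolite": m, "icc": icc, "icc_class": icc_class(icc)})
    return ReliabilityReport(table=pd.DataFrame(rows))


def correlation_matrices(panel: StandardizedPanel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations and full-order partial correlations.

    Partial correlations condition on all remaining panel metabolites via the
    precision matrix: rho_ij.rest = -Omega_ij / sqrt(Omega_ii Omega_jj).
    """
    x = panel.data
    n, p = x.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    corr = x.corr()
    cov = x.cov().to_numpy()
    rank = np.linalg.matrix_rank(cov)
    if rank < p:
        raise ValueError(f"singular covariance: rank {rank} < {p} variables")
    omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    partial = pd.DataFrame(partial, index=x.columns, columns=x.columns)
    return corr, partial
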