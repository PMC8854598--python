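"""Conditional-independence skeleton of the metabolite panel.

The skeleton is learned with the order-independent (stable) variant of the
PC algorithm: starting from the complete undirected graph, edges are removed
whenever the two endpoints are conditionally independent given some subset of
their neighbors, testing conditioning sets of growing size with neighbor sets
frozen at the start of each size level and deletions applied only at level
end.  Independence is judged by the Fisher-z test of the sample partial
correlation at a fixed alpha (0.05 by default).  Only the undirected skeleton
is produced; edge orientation is deliberately out of scope because the
downstream direct-effect search consumes adjacency alone.

This module is fully deterministic: same panel in, same skeleton out,
regardless of column order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import StandardizedPanel

__all__ = [
    "Skeleton",
    "fisher_z_ci_test",
    "partial_correlation",
    "pc_skeleton",
    "pc_skeleton_from_corr",
    "neighbors",
]


@dataclass
class Skeleton:
    """Undirected conditional-independence graph with separation sets."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset]
    sepsets: Mapping[frozenset, frozenset]
    alpha: float

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def adjacency(self) -> pd.DataFrame:
        a = pd.DataFrame(0, index=list(self.nodes), columns=list(self.nodes), dtype=int)
        for e in self.edges:
            u, v = tuple(e)
            a.loc[u, v] = a.loc[v, u] = 1
        return a

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.edges)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.edge_list(), columns=["node_a", "node_b"]).to_csv(
            path, sep="\t", index=False)


def partial_correlation(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Partial correlation of variables i, j given S from a correlation matrix,
    via the precision of the {i, j} + S submatrix."""
    if not S:
        return float(corr[i, j])
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    omega = np.linalg.pinv(sub)
    return float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))


def fisher_z_ci_test(
    panel: StandardizedPanel,
    i: str,
    j: str,
    S: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Fisher-z test of partial correlation: returns (statistic, p, independent).

    statistic = sqrt(n - |S| - 3) * |atanh(r)|, two-sided normal p;
    independent iff p > alpha.  A perfect correlation is declared dependent
    with p = 0 rather than overflowing the transform.
    """
    if i == j:
        raise ValueError("i and j must differ")
    if i in S or j in S:
        raise ValueError("conditioning set must not contain i or j")
    n = panel.n
    if n - len(S) - 3 <= 0:
        raise ValueError(f"need n - |S| - 3 > 0 (n={n}, |S|={len(S)})")
    cols = list(panel.data.columns)
    corr = panel.data.corr().to_numpy()
    r = partial_correlation(corr, cols.index(i), cols.index(j),
                            tuple(cols.index(s) for s in S))
    return _fisher_z_from_r(r, n, len(S), alpha)


def _fisher_z_from_r(r: float, n: int, s_size: int, alpha: float
                     ) -> tuple[float, float, bool]:
    if abs(r) >= 1.0 - 1e-15:
        return float("inf"), 0.0, False
    z = np.arctanh(r)
    stat = float(np.sqrt(n - s_size - 3) * abs(z))
    p = float(2.0 * stats.norm.sf(stat))
    return stat, p, p > alpha


def _make_sample_test(corr: np.ndarray, n: int, alpha: float) -> Callable:
    def test(i: int, j: int, S: tuple[int, ...]) -> bool:
        if n - len(S) - 3 <= 0:
            return False                      # cannot reject dependence
        r = partial_correlation(corr, i, j, S)
        return _fisher_z_from_r(r, n, len(S), alpha)[2]
    return test


def _make_oracle_test(corr: np.ndarray, tol: float = 1e-8) -> Callable:
    """Population-oracle independence: true partial correlation is (near) zero."""
    def test(i: int, j: int, S: tuple[int, ...]) -> bool:
        return abs(partial_correlation(corr, i, j, S)) < tol
    return test


def _pc_stable(
    names: list[str],
    indep: Callable[[int, int, tuple[int, ...]], bool],
    alpha: float,
    max_cond_size: int | None,
) -> Skeleton:
    p = len(names)
    # work in a canonical (sorted) node order so column order cannot matter
    order = sorted(range(p), key=lambda k: names[k])
    adj: dict[int, set[int]] = {i: set(range(p)) - {i} for i in range(p)}
    sepsets: dict[frozenset, frozenset] = {}
    level = 0
    while True:
        snapshot = {i: sorted(adj[i], key=lambda k: names[k]) for i in range(p)}
        any_testable = False
        to_delete: list[tuple[int, int]] = []
        for i in order:
            for j in snapshot[i]:
                candidates = [k for k in snapshot[i] if k != j]
                if len(candidates) < level:
                    continue
                any_testable = True
                for S in itertools.combinations(candidates, level):
                    if indep(i, j, S):
                        key = frozenset((names[i], names[j]))
                        if key not in sepsets:
                            sepsets[key] = frozenset(names[k] for k in S)
                        to_delete.append((i, j))
                        break
        for i, j in to_delete:                # deletions applied at level end
            adj[i].discard(j)
            adj[j].discard(i)
        if not any_testable:
            break
        level += 1
        if max_cond_size is not None and level > max_cond_size:
            break
    edges = frozenset(frozenset((names[i], names[j]))
                      for i in range(p) for j in adj[i] if i < j)
    return Skeleton(nodes=tuple(names), edges=edges, sepsets=sepsets, alpha=alpha)


def pc_skeleton(
    panel: StandardizedPanel,
    alpha: float = 0.05,
    max_cond_size: int | None = None,
) -> Skeleton:
    """Stable-PC skeleton of the panel at the given significance level."""
    n, p = panel.data.shape
    if n <= p + 3:
        raise ValueError(f"need n > p + 3 (n={n}, p={p})")
    names = list(panel.data.columns)
    corr = panel.data.corr().to_numpy()
    return _pc_stable(names, _make_sample_test(corr, n, alpha), alpha, max_cond_size)


def pc_skeleton_from_corr(
    corr: pd.DataFrame,
    n: int | None,
    alpha: float = 0.05,
    max_cond_size: int | None = None,
) -> Skeleton:
    """Skeleton from a correlation (or covariance) matrix.

    With ``n=None`` the tests are population oracles: an edge is absent
    exactly when some partial correlation vanishes, so for a faithful
    linear-Gaussian model the output equals the true skeleton.
    """
    names = list(corr.columns)
    c = corr.to_numpy(dtype=float)
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)                   # accept covariance input
    if n is None:
        test = _make_oracle_test(c)
    else:
        test = _make_sample_test(c, n, alpha)
    return _pc_stable(names, test, alpha, max_cond_size)


def neighbors(skeleton: Skeleton, node: str) -> set[str]:
    """Adjacency set of a node in the skeleton (empty set allowed)."""
    if node not in skeleton.nodes:
        raise KeyError(f"unknown node {node!r}")
    out = set()
    for e in skeleton.edges:
        if node in e:
            (other,) = set(e) - {node}
            out.add(other)
    return out
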