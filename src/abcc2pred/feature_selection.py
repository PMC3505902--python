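"""Correlation-based feature-subset selection (CFS) with best-first search.

CFS scores a feature subset by the merit

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where ``k = |S|``, ``r_cf`` is the mean absolute feature-class correlation
and ``r_ff`` the mean absolute pairwise feature-feature correlation: a good
subset correlates with the class while its members are mutually
non-redundant.

The default correlation is Pearson (point-biserial against the binary
class), appropriate for continuous z-scored descriptors and parameter
free.  A symmetric-uncertainty mode over equal-frequency 10-bin
discretized features is available for fidelity experiments with
entropy-based implementations.

The search is forward best-first from the empty set: the open subset with
the highest merit is expanded by single-feature additions, and the search
stops after ``stale_limit`` consecutive expansions that fail to improve
the best merit found.  Deterministic throughout; ties break toward the
earlier descriptor in vocabulary order.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureSubset:
    names: tuple[str, ...]
    merit: float
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)


class CfsEvaluator:
    """Caches correlations so repeated merit evaluations are O(k^2)."""

    def __init__(self, X: pd.DataFrame, y, measure: str = "pearson", n_bins: int = 10):
        if measure not in {"pearson", "symunc"}:
            raise ValueError(f"unknown correlation measure {measure!r}")
        self.names = list(X.columns)
        self._index = {n: i for i, n in enumerate(self.names)}
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("class vector must contain both classes")
        Xv = X.to_numpy(dtype=float)
        if measure == "pearson":
            self._rcf, self._rff = self._pearson_tables(Xv, y)
        else:
            self._rcf, self._rff = self._symunc_tables(Xv, y, n_bins)

    @staticmethod
    def _pearson_tables(X: np.ndarray, y: np.ndarray):
        n, p = X.shape
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = math.sqrt(float((yc**2).sum()))
        # zero-variance features correlate with nothing by convention
        sx_safe = np.where(sx > 1e-12, sx, np.inf)
        rcf = np.abs(Xc.T @ yc) / (sx_safe * (sy if sy > 1e-12 else np.inf))
        denom = np.outer(sx_safe, sx_safe)
        rff = np.abs(Xc.T @ Xc) / denom
        np.fill_diagonal(rff, 1.0)
        return rcf, rff

    @staticmethod
    def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
        ranks = pd.Series(x)
        try:
            binned = pd.qcut(ranks, q=n_bins, labels=False, duplicates="drop")
        except ValueError:
            return np.zeros(len(x), dtype=int)
        return np.asarray(binned.fillna(0), dtype=int)

    @classmethod
    def _symunc_tables(cls, X: np.ndarray, y: np.ndarray, n_bins: int):
        n, p = X.shape
        cols = [cls._discretize(X[:, j], n_bins) for j in range(p)]
        ycat = y.astype(int)
        rcf = np.array([_symmetric_uncertainty(c, ycat) for c in cols])
        rff = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                su = _symmetric_uncertainty(cols[i], cols[j])
                rff[i, j] = rff[j, i] = su
        return rcf, rff

    def merit(self, features) -> float:
        """CFS merit of a named feature subset (0 for the empty set)."""
        idx = [self._index[f] for f in features]
        k = len(idx)
        if k == 0:
            return 0.0
        rcf = float(self._rcf[idx].mean())
        if k == 1:
            return rcf
        sub = self._rff[np.ix_(idx, idx)]
        rff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
        denom = math.sqrt(k + k * (k - 1) * rff)
        return k * rcf / denom if denom > 0 else 0.0


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    ab = a.astype(np.int64) * (int(b.max()) + 1) + b.astype(np.int64)
    ha = _entropy(np.bincount(a))
    hb = _entropy(np.bincount(b))
    hab = _entropy(np.bincount(ab))
    if ha + hb <= 1e-12:
        return 0.0
    return 2.0 * (ha + hb - hab) / (ha + hb)


def cfs_merit(features, X: pd.DataFrame, y, measure: str = "pearson") -> float:
    """One-shot merit of a feature subset (see :class:`CfsEvaluator`)."""
    if len(list(features)) < 1:
        raise ValueError("need at least one feature")
    return CfsEvaluator(X, y, measure=measure).merit(list(features))


def best_first_select(
    X: pd.DataFrame,
    y,
    stale_limit: int = 5,
    measure: str = "pearson",
    max_expansions: int | None = None,
) -> FeatureSubset:
    """Forward best-first CFS subset search.

    Returns the best subset found together with the search trace.  The
    result's merit is always at least the best single-feature merit, since
    every singleton is generated from the root.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    ev = CfsEvaluator(X, y, measure=measure)
    names = ev.names
    order = {n: i for i, n in enumerate(names)}

    start: tuple[str, ...] = ()
    best_set, best_merit = start, 0.0
    trace: list[tuple[tuple[str, ...], float]] = [(start, 0.0)]
    # heap entries: (-merit, insertion ordinal) -> deterministic tie-break
    counter = itertools.count()
    open_heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, next(counter), start)]
    visited: set[tuple[str, ...]] = {start}
    stale = 0
    expansions = 0
    while open_heap and stale <= stale_limit:
        if max_expansions is not None and expansions >= max_expansions:
            break
        _, _, subset = heapq.heappop(open_heap)
        expansions += 1
        improved = False
        present = set(subset)
        for name in names:  # vocabulary order fixes tie-breaking
            if name in present:
                continue
            child = tuple(sorted(subset + (name,), key=order.__getitem__))
            if child in visited:
                continue
            visited.add(child)
            m = ev.merit(child)
            trace.append((child, m))
            heapq.heappush(open_heap, (-m, next(counter), child))
            if m > best_merit + 1e-12:
                best_set, best_merit = child, m
                improved = True
        stale = 0 if improved else stale + 1
    return FeatureSubset(names=best_set, merit=best_merit, trace=trace)
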