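"""OLS-based comparator selectors: exhaustive best subsets, forward and
backward stepwise, and sequential replacement.

Each selector returns one model per subset size; the final choice among
those is made downstream on held-out validation error, never by an
information criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["ModelSequence", "exhaustive_best_subsets", "forward_stepwise",
           "backward_stepwise", "sequential_replacement"]

_ENUM_GUARD = 30   # refuse plain enumeration beyond this many candidates


@dataclass
class SizeModel:
    terms: tuple[int, ...]
    coef: np.ndarray          # aligned with terms
    rss: float


@dataclass
class ModelSequence:
    """Per-size selected models: entry k has exactly k terms (k = 0..k_max)."""

    models: list[SizeModel]
    method: str = ""

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)


def _ols(X: np.ndarray, y: np.ndarray, terms: tuple[int, ...]) -> tuple[np.ndarray, float] | None:
    """OLS via pivoted QR on the chosen columns; None if rank deficient."""
    if not terms:
        return np.zeros(0), float(y @ y)
    A = X[:, list(terms)]
    coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < len(terms):
        return None
    r = y - A @ coef
    return coef, float(r @ r)


def exhaustive_best_subsets(X: np.ndarray, y: np.ndarray, k_max: int) -> ModelSequence:
    """For each size k, the k-term subset minimizing training RSS.

    Plain enumeration is the reference implementation and is guarded to
    p <= 30 candidates; larger problems should be filtered first or handed
    to a heuristic selector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if k_max > min(n - 1, p):
        raise ValueError("k_max must not exceed min(n - 1, p)")
    if p > _ENUM_GUARD:
        raise ValueError(
            f"exhaustive enumeration refused for p={p} > {_ENUM_GUARD}; "
            "filter the design more aggressively or use a stepwise selector"
        )
    models = [SizeModel((), np.zeros(0), float(y @ y))]
    for k in range(1, k_max + 1):
        best = None
        for terms in combinations(range(p), k):
            fit = _ols(X, y, terms)
            if fit is None:
                continue
            coef, rss = fit
            if best is None or rss < best.rss - 1e-14:
                best = SizeModel(terms, coef, rss)
        if best is None:
            break
        models.append(best)
    return ModelSequence(models, "exhaustive")


def forward_stepwise(X: np.ndarray, y: np.ndarray, k_max: int) -> ModelSequence:
    """Greedy forward selection: add the RSS-minimizing next term at each size."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    k_max = min(k_max, n - 1, p)
    current: tuple[int, ...] = ()
    models = [SizeModel((), np.zeros(0), float(y @ y))]
    for _ in range(k_max):
        best = None
        for j in range(p):
            if j in current:
                continue
            fit = _ols(X, y, current + (j,))
            if fit is None:
                continue
            coef, rss = fit
            if best is None or rss < best.rss - 1e-14:
                best = SizeModel(current + (j,), coef, rss)
        if best is None:
            warnings.warn("no full-rank candidate to add; stopping early",
                          RuntimeWarning, stacklevel=2)
            break
        current = best.terms
        models.append(best)
    return ModelSequence(models, "forward")


def backward_stepwise(X: np.ndarray, y: np.ndarray) -> ModelSequence:
    """Greedy backward elimination from the full OLS model down to empty.

    Requires p <= n - 1 so the full model is estimable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p > n - 1:
        raise ValueError("backward selection requires p <= n - 1 (full model estimable)")
    current = tuple(range(p))
    fit = _ols(X, y, current)
    if fit is None:
        raise ValueError("full model is rank deficient; backward selection undefined")
    seq = [SizeModel(current, fit[0], fit[1])]
    while current:
        best = None
        for j in current:
            terms = tuple(t for t in current if t != j)
            f = _ols(X, y, terms)
            if f is None:
                continue
            coef, rss = f
            if best is None or rss < best.rss - 1e-14:
                best = SizeModel(terms, coef, rss)
        current = best.terms
        seq.append(best)
    seq.reverse()   # order by size 0..p
    return ModelSequence(seq, "backward")


def sequential_replacement(X: np.ndarray, y: np.ndarray, k_max: int) -> ModelSequence:
    """Forward step then swap passes to a fixed point at each size.

    After each forward addition, in-model terms are scanned in index order
    and the first swap with an out-of-model term that strictly decreases RSS
    is taken; passes repeat until no improving swap exists.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    k_max = min(k_max, n - 1, p)
    current: tuple[int, ...] = ()
    models = [SizeModel((), np.zeros(0), float(y @ y))]
    for _ in range(k_max):
        # forward addition
        best = None
        for j in range(p):
            if j in current:
                continue
            fit = _ols(X, y, current + (j,))
            if fit is None:
                continue
            coef, rss = fit
            if best is None or rss < best.rss - 1e-14:
                best = SizeModel(current + (j,), coef, rss)
        if best is None:
            warnings.warn("no full-rank candidate to add; stopping early",
                          RuntimeWarning, stacklevel=2)
            break
        current, rss_cur, coef_cur = best.terms, best.rss, best.coef
        # swap passes: first-improvement, scan in index order, to fixed point
        improved = True
        while improved:
            improved = False
            for pos, t_in in enumerate(sorted(current)):
                for t_out in range(p):
                    if t_out in current:
                        continue
                    terms = tuple(sorted(set(current) - {t_in} | {t_out}))
                    fit = _ols(X, y, terms)
                    if fit is None:
                        continue
                    coef, rss = fit
                    if rss < rss_cur - 1e-12:
                        current, rss_cur, coef_cur = terms, rss, coef
                        improved = True
                        break
                if improved:
                    break
        models.append(SizeModel(current, coef_cur, rss_cur))
    return ModelSequence(models, "sequential")
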