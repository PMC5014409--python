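"""Repeated-split selection and inverse-error weighted model averaging.

The engine draws a fixed number of unique train/validation partitions
(default 500 splits of 35 training and 25 validation observations), runs a
variable selector on each training set, picks the candidate along the
selector's model sequence that minimises the validation set element
prediction error (VSEPE) sum of squares, and combines the per-split selected
models with weights inversely proportional to those validation error sums of
squares,

    W_i = (1 / SSE_i) / sum_k (1 / SSE_k).

Summaries report the pooled distribution of |VSEPE| and the coefficient of
determination of the weighted model-averaged predictions against all
observations; selection frequencies tally how many selected models include
each term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TermedDesign, StandardizationTransform, filter_mccm, standardize_pair
from .lars import PenalizedFitSpec, lar_lasso_path, predict
from .subsets import (ModelSequence, backward_stepwise, exhaustive_best_subsets,
                      forward_stepwise, sequential_replacement)

__all__ = ["SplitPlan", "SplitResult", "Ensemble", "make_splits",
           "select_on_validation", "eq2_weights", "fit_ensemble",
           "model_average_predict", "vsepe_summary", "selection_frequencies",
           "run_method_comparison"]

_ZERO_SSE = 1e-12


@dataclass
class SplitPlan:
    n_total: int
    n_train: int
    n_splits: int
    seed: int
    train_indices: list[np.ndarray]   # sorted index arrays, one per split

    def validation_indices(self, i: int) -> np.ndarray:
        mask = np.ones(self.n_total, dtype=bool)
        mask[self.train_indices[i]] = False
        return np.where(mask)[0]

    def fingerprint(self) -> int:
        h = 0
        for tr in self.train_indices:
            h = hash((h, tuple(int(t) for t in tr)))
        return h


@dataclass
class SplitResult:
    split_id: int
    method: str
    terms: tuple[int, ...]            # selected term indices (nonzero coefs)
    coef: np.ndarray                  # full-length coefficient vector
    transform: StandardizationTransform
    val_errors: np.ndarray            # e_{i,j}, one per validation element
    sse: float


@dataclass
class Ensemble:
    """Per-split selected models plus their inverse-SSE weights."""

    results: list[SplitResult]
    weights: np.ndarray
    method: str
    plan: SplitPlan
    term_names: list[str] = field(default_factory=list)


def make_splits(n_total: int, n_train: int = 35, n_splits: int = 500,
                seed: int = 0) -> SplitPlan:
    """Draw unique uniform-random train/validation partitions.

    Uniqueness is enforced by rejection; deterministic given the seed.
    """
    if not (0 < n_train < n_total):
        raise ValueError("require 0 < n_train < n_total")
    n_possible = math.comb(n_total, n_train)
    if n_splits > n_possible:
        raise ValueError(
            f"{n_splits} unique splits requested but only {n_possible} exist"
        )
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    plans: list[np.ndarray] = []
    while len(plans) < n_splits:
        tr = np.sort(rng.choice(n_total, size=n_train, replace=False))
        key = tuple(int(t) for t in tr)
        if key in seen:
            continue
        seen.add(key)
        plans.append(tr)
    return SplitPlan(n_total, n_train, n_splits, seed, plans)


def _candidate_models(method: str, Xs: np.ndarray, ys: np.ndarray,
                      k_max: int) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Model sequence for one training set as (terms, full-coef-vector) pairs."""
    p = Xs.shape[1]
    out: list[tuple[tuple[int, ...], np.ndarray]] = []
    if method == "lar":
        path = lar_lasso_path(Xs, ys, PenalizedFitSpec())
        for st in path.steps:
            nz = tuple(int(j) for j in np.where(st.beta != 0)[0])
            out.append((nz, st.beta.copy()))
    else:
        if method == "exhaustive":
            seq = exhaustive_best_subsets(Xs, ys, k_max)
        elif method == "forward":
            seq = forward_stepwise(Xs, ys, k_max)
        elif method == "backward":
            seq = backward_stepwise(Xs, ys)
        elif method == "sequential":
            seq = sequential_replacement(Xs, ys, k_max)
        else:
            raise ValueError(f"unknown method {method!r}")
        for m in seq:
            beta = np.zeros(p)
            beta[list(m.terms)] = m.coef
            out.append((tuple(m.terms), beta))
    return out


def select_on_validation(candidates: list[tuple[tuple[int, ...], np.ndarray]],
                         val_Xs: np.ndarray, val_y: np.ndarray,
                         y_centre: float) -> tuple[int, np.ndarray, float]:
    """Pick the candidate minimising validation SSE.

    Ties go to the candidate with fewer terms, then to the earlier candidate.
    Returns (index, validation errors, SSE).
    """
    if not candidates:
        raise ValueError("empty candidate list")
    best = None
    for k, (terms, beta) in enumerate(candidates):
        pred = y_centre + val_Xs @ beta
        e = val_y - pred
        sse = float(e @ e)
        key = (sse, len(terms), k)
        if best is None or (key[0] < best[0][0] - 1e-14) or (
            abs(key[0] - best[0][0]) <= 1e-14 and key[1:] < best[0][1:]
        ):
            best = (key, e)
    (sse, _, k), e = best
    return k, e, sse


def eq2_weights(sse_per_split: np.ndarray) -> np.ndarray:
    """Inverse-SSE model-averaging weights, normalised to sum 1.

    Any split with SSE below epsilon (an exact fit) takes the limit of the
    inverse-SSE rule: the exact-fit splits share all the weight equally and
    every other split gets weight zero.
    """
    sse = np.asarray(sse_per_split, dtype=float)
    if (sse < 0).any():
        raise ValueError("negative SSE")
    zero = sse < _ZERO_SSE
    if zero.any():
        w = np.zeros_like(sse)
        w[zero] = 1.0 / zero.sum()
        return w
    inv = 1.0 / sse
    return inv / inv.sum()


def fit_ensemble(design: TermedDesign, y: np.ndarray, plan: SplitPlan,
                 method: str = "lar", k_max: int | None = None) -> Ensemble:
    """Fit one selector over every split of the plan and weight by Eq-2."""
    X = design.matrix
    y = np.asarray(y, dtype=float)
    if len(y) != plan.n_total or X.shape[0] != plan.n_total:
        raise ValueError("design/response size does not match the split plan")
    if k_max is None:
        k_max = min(plan.n_train - 1, design.p)
    results: list[SplitResult] = []
    for i, tr in enumerate(plan.train_indices):
        va = plan.validation_indices(i)
        Xs, ys, Xv, transform = standardize_pair(X[tr], y[tr], X[va])
        cands = _candidate_models(method, Xs, ys, k_max)
        k, e, sse = select_on_validation(cands, Xv, y[va], transform.response_centre)
        terms, beta = cands[k]
        results.append(SplitResult(i, method, terms, beta, transform, e, sse))
    weights = eq2_weights(np.array([r.sse for r in results]))
    return Ensemble(results, weights, method, plan, design.term_names)


def per_model_predictions(ensemble: Ensemble, X_new_raw: np.ndarray) -> np.ndarray:
    """(n_new, n_splits) matrix of per-split-model predictions."""
    X_new_raw = np.asarray(X_new_raw, dtype=float)
    if X_new_raw.shape[1] != len(ensemble.results[0].coef):
        raise ValueError("column count mismatch with the ensemble's design")
    cols = [predict(r.coef, r.transform, X_new_raw) for r in ensemble.results]
    return np.column_stack(cols)


def model_average_predict(ensemble: Ensemble, X_new_raw: np.ndarray) -> np.ndarray:
    """Weighted model-averaged prediction: sum_i W_i * yhat_i(x)."""
    return per_model_predictions(ensemble, X_new_raw) @ ensemble.weights


def vsepe_summary(ensemble: Ensemble, design: TermedDesign,
                  y: np.ndarray) -> pd.Series:
    """Pooled |VSEPE| summary plus the model-averaged prediction R^2.

    min, Q1, median, mean, Q3, max are over the absolute validation errors
    pooled across every split; R^2 = 1 - SS_res/SS_tot of the weighted
    model-averaged predictions against all observed responses.
    """
    y = np.asarray(y, dtype=float)
    abs_e = np.abs(np.concatenate([r.val_errors for r in ensemble.results]))
    map_pred = model_average_predict(ensemble, design.matrix)
    ss_res = float(np.sum((y - map_pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return pd.Series(
        {
            "min": float(abs_e.min()),
            "q1": float(np.quantile(abs_e, 0.25)),
            "median": float(np.median(abs_e)),
            "mean": float(abs_e.mean()),
            "q3": float(np.quantile(abs_e, 0.75)),
            "max": float(abs_e.max()),
            "map_r2": 1.0 - ss_res / ss_tot,
        }
    )


def selection_frequencies(ensemble: Ensemble) -> pd.DataFrame:
    """Per-term count of selected models including it, sorted descending."""
    names = ensemble.term_names
    counts = np.zeros(len(names), dtype=int)
    for r in ensemble.results:
        counts[list(r.terms)] += 1
    df = pd.DataFrame({"term": names, "count": counts})
    return df.sort_values(["count", "term"], ascending=[False, True],
                          ignore_index=True)


def plot_selection_frequencies(ensemble: Ensemble, path, top: int = 30) -> None:
    """Simple bar chart of the most frequently selected terms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = selection_frequencies(ensemble).head(top)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(df))))
    ax.barh(df["term"][::-1], df["count"][::-1])
    ax.set_xlabel(f"selections out of {ensemble.plan.n_splits} splits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_method_comparison(design: TermedDesign, y: np.ndarray, plan: SplitPlan,
                          methods: tuple[str, ...] = ("lar",),
                          mccm_levels: tuple[float, ...] = (0.95,),
                          filter_seed: int = 0,
                          ) -> tuple[pd.DataFrame, dict[tuple[str, float], Ensemble]]:
    """Run each (method, MCCM level) on the SAME split plan.

    Every method sees identical train/validation partitions so the
    comparison isolates selector behaviour from split noise.  OLS-based
    exhaustive/backward selection is refused when the filtered design is too
    wide to be feasible.  Returns a summary table (one row per combination:
    pooled |VSEPE| summary plus model-averaged R^2) and the ensembles.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    ensembles: dict[tuple[str, float], Ensemble] = {}
    for mccm in mccm_levels:
        filtered = filter_mccm(design, mccm, seed=filter_seed) if design.p > 1 else design
        for method in methods:
            if method == "exhaustive" and filtered.p > 30:
                raise ValueError(
                    f"exhaustive search infeasible on {filtered.p} filtered terms; "
                    "use a stricter MCCM level"
                )
            if method == "backward" and filtered.p > plan.n_train - 1:
                raise ValueError(
                    f"backward selection needs p <= n_train - 1 but the filtered "
                    f"design has {filtered.p} terms"
                )
            ens = fit_ensemble(filtered, y, plan, method=method)
            ensembles[(method, mccm)] = ens
            s = vsepe_summary(ens, filtered, y)
            rows.append({"method": method, "mccm": mccm, "p_filtered": filtered.p,
                         **s.to_dict()})
    return pd.DataFrame(rows), ensembles
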