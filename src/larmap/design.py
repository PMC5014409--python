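"""Design-matrix construction: polynomial/interaction expansion, collinearity
filtering by maximum correlation coefficient magnitude (MCCM), and train/
validation standardization.

Expansion takes p base covariates to ``p*max_order + C(p, 2)`` candidate
terms: powers 1..max_order of each covariate plus every pairwise product of
two distinct covariates (computed on the raw realigned values).  Filtering
greedily removes one member of the most correlated pair above the threshold
until all remaining pairwise |Pearson r| are at or below it, preferring the
term observed at finer spatial resolution, then the less derived term, then a
seeded random choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TermDescriptor",
    "TermedDesign",
    "StandardizationTransform",
    "expand_terms",
    "count_models",
    "filter_mccm",
    "standardize_pair",
]


@dataclass(frozen=True)
class TermDescriptor:
    """Provenance of one design-matrix column.

    kind : "polynomial" (one base, power >= 1) or "interaction"
           (two distinct bases, each to power 1).
    resolution : finest native resolution (metres) of the source data;
                 interactions inherit the coarser parent resolution.
    derivation_complexity : 0 for a directly observed linear term, growing
                 with each power or product applied.
    """

    kind: str
    bases: tuple[str, ...]
    powers: tuple[int, ...]
    resolution: float
    derivation_complexity: int

    def __post_init__(self) -> None:
        if self.kind == "polynomial":
            if len(self.bases) != 1 or len(self.powers) != 1 or self.powers[0] < 1:
                raise ValueError(f"invalid polynomial descriptor {self}")
        elif self.kind == "interaction":
            if len(self.bases) != 2 or self.bases[0] == self.bases[1] or self.powers != (1, 1):
                raise ValueError(f"invalid interaction descriptor {self}")
        else:
            raise ValueError(f"unknown term kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "polynomial":
            b, k = self.bases[0], self.powers[0]
            return b if k == 1 else f"{b}^{k}"
        return ":".join(self.bases)


@dataclass
class TermedDesign:
    """Design matrix whose columns carry term provenance."""

    matrix: np.ndarray                 # (n, p)
    terms: list[TermDescriptor]
    filter_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["dropped_term", "kept_term", "abs_r", "rule"]
        )
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.terms):
            raise ValueError("descriptor count must equal column count")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicated term descriptors")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def subset_columns(self, idx: np.ndarray) -> "TermedDesign":
        idx = np.asarray(idx)
        return TermedDesign(self.matrix[:, idx], [self.terms[i] for i in idx],
                           self.filter_log)

    def subset_rows(self, idx: np.ndarray) -> "TermedDesign":
        return TermedDesign(self.matrix[np.asarray(idx), :], list(self.terms),
                           self.filter_log)


@dataclass
class StandardizationTransform:
    """Training-set centring/scaling mirrored onto validation/prediction data.

    Columns are centred on the training mean and scaled to unit Euclidean
    norm of the centred training column (the LAR convention); the response is
    centred on its training mean.
    """

    centres: np.ndarray
    scales: np.ndarray
    response_centre: float
    valid: np.ndarray  # boolean mask of columns usable for selection

    def apply(self, X_raw: np.ndarray) -> np.ndarray:
        X = (np.asarray(X_raw, dtype=float) - self.centres) / self.scales
        return X


def expand_terms(base_table: pd.DataFrame, max_order: int = 4,
                 resolutions: dict[str, float] | None = None,
                 complexities: dict[str, int] | None = None) -> TermedDesign:
    """Expand base covariates into polynomial and pairwise-interaction terms.

    Products/powers are computed on the raw (realigned, unstandardized)
    values.  Term count is ``p*max_order + p*(p-1)/2``.
    """
    if not np.isfinite(base_table.to_numpy(dtype=float)).all():
        arr = base_table.to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite value in base covariate '{base_table.columns[bad[1]]}' "
            f"row {bad[0]}"
        )
    resolutions = resolutions or {}
    complexities = complexities or {}
    names = list(base_table.columns)
    cols: list[np.ndarray] = []
    terms: list[TermDescriptor] = []
    for name in names:
        x = base_table[name].to_numpy(dtype=float)
        res = resolutions.get(name, 25.0)
        cx = complexities.get(name, 0)
        for k in range(1, max_order + 1):
            cols.append(x ** k)
            terms.append(TermDescriptor("polynomial", (name,), (k,), res, cx + (k - 1)))
    for i, a in enumerate(names):
        xa = base_table[a].to_numpy(dtype=float)
        for b in names[i + 1:]:
            xb = base_table[b].to_numpy(dtype=float)
            res = max(resolutions.get(a, 25.0), resolutions.get(b, 25.0))
            cx = complexities.get(a, 0) + complexities.get(b, 0) + 1
            cols.append(xa * xb)
            terms.append(TermDescriptor("interaction", (a, b), (1, 1), res, cx))
    return TermedDesign(np.column_stack(cols), terms)


def count_models(n_candidates: int, max_size: int) -> int:
    """Exact number of distinct non-empty models of size <= max_size.

    Returns sum_{i=1..max_size} C(n_candidates, i) in arbitrary precision.
    """
    if not (1 <= max_size <= n_candidates):
        raise ValueError("require 1 <= max_size <= n_candidates")
    return sum(math.comb(n_candidates, i) for i in range(1, max_size + 1))


def filter_mccm(design: TermedDesign, threshold: float,
                seed: int | None = 0) -> TermedDesign:
    """Greedy collinearity filter enforcing max pairwise |Pearson r| <= threshold.

    Repeatedly finds the retained pair with the largest |r| above the
    threshold and drops one member by, in order: (1) keep the finer-resolution
    term; (2) keep the lower derivation complexity; (3) seeded random choice.
    Exact |r| ties between pairs are broken by lexicographic term name.
    Zero-variance columns are dropped up-front (correlation undefined).
    Returns the filtered design with a complete decision log.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if design.p < 2:
        raise ValueError("need at least 2 columns to filter")
    rng = np.random.default_rng(seed)
    X = design.matrix
    names = design.term_names
    log_rows: list[dict] = []

    sd = X.std(axis=0)
    keep = sd > 0
    for j in np.where(~keep)[0]:
        log_rows.append({"dropped_term": names[j], "kept_term": "",
                         "abs_r": np.nan, "rule": "zero_variance"})
    idx = np.where(keep)[0]

    # order-invariant pass: work on name-sorted columns so the greedy scan and
    # tie-breaks do not depend on input column order
    order = sorted(range(len(idx)), key=lambda k: names[idx[k]])
    idx = idx[order]
    if len(idx) < 2:
        out = design.subset_columns(np.sort(idx))
        out.filter_log = pd.DataFrame(
            log_rows, columns=["dropped_term", "kept_term", "abs_r", "rule"])
        return out
    sub = X[:, idx]
    C = np.corrcoef(sub, rowvar=False)
    np.fill_diagonal(C, 0.0)
    A = np.abs(C)

    m = len(idx)
    alive = np.ones(m, dtype=bool)
    # per-row running maxima so each drop only rescans the rows it invalidates
    rowmax = A.max(axis=1) if m else np.empty(0)
    rowarg = A.argmax(axis=1) if m else np.empty(0, dtype=int)

    def _rescan(i: int) -> None:
        masked = np.where(alive, A[i], -np.inf)
        masked[i] = -np.inf
        rowarg[i] = int(np.argmax(masked))
        rowmax[i] = masked[rowarg[i]]

    while m:
        masked_max = np.where(alive, rowmax, -np.inf)
        ii = int(np.argmax(masked_max))
        r = masked_max[ii]
        if r <= threshold:
            break
        jj = int(rowarg[ii])
        i, j = sorted((ii, jj), key=lambda k: names[idx[k]])
        ti, tj = design.terms[idx[i]], design.terms[idx[j]]
        if ti.resolution != tj.resolution:
            drop, keep_t, rule = (j, i, "finer_resolution") \
                if ti.resolution < tj.resolution else (i, j, "finer_resolution")
        elif ti.derivation_complexity != tj.derivation_complexity:
            drop, keep_t, rule = (j, i, "lower_complexity") \
                if ti.derivation_complexity < tj.derivation_complexity else (i, j, "lower_complexity")
        else:
            drop = i if rng.random() < 0.5 else j
            keep_t = j if drop == i else i
            rule = "random"
        log_rows.append({"dropped_term": names[idx[drop]],
                         "kept_term": names[idx[keep_t]],
                         "abs_r": float(r), "rule": rule})
        alive[drop] = False
        for k in np.where(alive & (rowarg == drop))[0]:
            _rescan(int(k))

    kept_idx = np.sort(idx[alive])
    out = design.subset_columns(kept_idx)
    out.filter_log = pd.DataFrame(log_rows,
                                  columns=["dropped_term", "kept_term", "abs_r", "rule"])
    return out


def standardize_pair(train_X: np.ndarray, train_y: np.ndarray,
                     val_X: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None,
                                StandardizationTransform]:
    """Centre/scale a training design and mirror the transform on validation data.

    Training columns are recentred to mean zero and rescaled to unit Euclidean
    norm; validation columns use the *training* centre and scale (and are
    therefore generally not mean-zero/unit-norm).  The response is centred on
    its training mean.  Zero-norm training columns are flagged invalid and
    left as zeros.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    centres = train_X.mean(axis=0)
    centred = train_X - centres
    scales = np.linalg.norm(centred, axis=0)
    valid = scales > 1e-12
    safe = np.where(valid, scales, 1.0)
    Xs = centred / safe
    Xs[:, ~valid] = 0.0
    y_centre = float(train_y.mean())
    ys = train_y - y_centre
    tr = StandardizationTransform(centres=centres, scales=safe,
                                  response_centre=y_centre, valid=valid)
    Xv = None
    if val_X is not None:
        Xv = tr.apply(val_X)
        Xv[:, ~valid] = 0.0
    return Xs, ys, Xv, tr
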