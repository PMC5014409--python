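"""Least Angle Regression with the LASSO modification, from scratch.

Traces the full L1-penalised least-squares solution path

    beta_hat = argmin_beta  sum_i (y_i - beta0 - sum_j x_ij beta_j)^2
                            + lambda * sum_j |beta_j|

for a standardized design (columns centred, unit Euclidean norm) and centred
response.  The algorithm moves the prediction vector equiangularly among the
active covariates — all of which share, at every breakpoint, the same
absolute correlation with the current residual, strictly larger than any
inactive covariate's — and adds the next covariate the moment its correlation
catches up.  The LASSO modification removes an active covariate the moment
its coefficient path crosses zero, after which the direction is recomputed
for the reduced active set.  Covariates are added and removed until the
available degrees of freedom are exhausted (n - 1 with an intercept) or the
maximal absolute correlation falls to a user-specified threshold.

The shrinkage parameter lambda is never materialised as a user input: each
breakpoint corresponds to lambda = 2 * (maximal absolute correlation), and
model choice along the path is made downstream by validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .design import StandardizationTransform

__all__ = ["PenalizedFitSpec", "LarStep", "LarPath", "lar_lasso_path",
           "coefficients_at_l1", "predict"]

_TIE_TOL = 1e-12      # correlations closer than this are treated as tied
_NORM_TOL = 1e-6      # permitted deviation of column norms from 1


@dataclass(frozen=True)
class PenalizedFitSpec:
    """Controls for one LAR-LASSO run.

    gamma is the penalty exponent of the underlying penalised least-squares
    problem and must be 1 (the L1 / LASSO case); the ridge case gamma=2 has
    a closed form and is deliberately unsupported here.
    """

    gamma: int = 1
    corr_threshold: float = 0.0
    max_steps: int | None = None   # max active-set size; default min(n - 1, p)

    def __post_init__(self) -> None:
        if self.gamma != 1:
            raise ValueError("only the L1 penalty (gamma=1) is supported")
        if self.corr_threshold < 0:
            raise ValueError("correlation threshold must be non-negative")


@dataclass
class LarStep:
    event: str                 # "init" | "add" | "drop" | "terminate"
    term: int                  # column index added or dropped (-1 otherwise)
    active: list[int]          # active set at this breakpoint
    beta: np.ndarray           # coefficients at this breakpoint
    l1_norm: float
    max_abs_corr: float


@dataclass
class LarPath:
    """Ordered LAR-LASSO breakpoints for one training set.

    steps[0] is the zero solution; each add/drop step changes the active set
    by exactly one covariate (a newly added covariate has coefficient zero at
    its entry breakpoint) and the maximal absolute correlation with the
    residual is non-increasing along the path.
    """

    steps: list[LarStep]
    intercept: float = 0.0     # training response mean on the raw scale
    termination: str = ""

    @property
    def n_steps(self) -> int:
        return len(self.steps) - 1

    def betas(self) -> np.ndarray:
        """(n_breakpoints, p) coefficient matrix."""
        return np.array([s.beta for s in self.steps])

    def to_frame(self) -> pd.DataFrame:
        """Path as a tidy table (step, event, term, l1_norm, max_abs_corr)."""
        return pd.DataFrame(
            {
                "step": range(len(self.steps)),
                "event": [s.event for s in self.steps],
                "term": [s.term for s in self.steps],
                "l1_norm": [s.l1_norm for s in self.steps],
                "max_abs_corr": [s.max_abs_corr for s in self.steps],
            }
        )


def _check_standardized(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=0)
    usable = norms > _NORM_TOL     # flagged-out all-zero columns are permitted
    bad = usable & (np.abs(norms - 1.0) > _NORM_TOL)
    if bad.any():
        raise ValueError(
            "design not standardized: column norms deviate from 1 at indices "
            f"{np.where(bad)[0][:5].tolist()}"
        )
    if abs(float(np.mean(y))) > 1e-6 * (1.0 + float(np.abs(y).max(initial=0.0))):
        raise ValueError("response must be centred")
    return usable


def _gram_ok(X: np.ndarray, active: list[int]) -> bool:
    G = X[:, active].T @ X[:, active]
    try:
        scipy.linalg.cho_factor(G)
    except scipy.linalg.LinAlgError:
        return False
    return np.linalg.cond(G) < 1e12


def lar_lasso_path(X: np.ndarray, y: np.ndarray,
                   spec: PenalizedFitSpec | None = None) -> LarPath:
    """Compute the full LAR-LASSO solution path.

    Parameters
    ----------
    X : (n, p) standardized design (centred columns of unit Euclidean norm;
        all-zero columns are treated as excluded up-front).
    y : (n,) centred response.
    spec : termination controls; the default runs to degrees-of-freedom
        exhaustion at min(n - 1, p) active covariates.
    """
    spec = spec or PenalizedFitSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    usable = _check_standardized(X, y)
    max_active = min(n - 1, p)
    if spec.max_steps is not None:
        max_active = min(max_active, spec.max_steps)

    beta = np.zeros(p)
    active: list[int] = []
    excluded = ~usable
    c = X.T @ y
    C = float(np.abs(np.where(excluded, 0.0, c)).max(initial=0.0))
    steps = [LarStep("init", -1, [], beta.copy(), 0.0, C)]
    path = LarPath(steps=steps)

    if C <= spec.corr_threshold + _TIE_TOL or max_active == 0:
        path.termination = "threshold" if C <= spec.corr_threshold + _TIE_TOL else "df_exhausted"
        return path

    # first entry: the covariate most correlated with y (smallest index on ties)
    cand = np.abs(np.where(excluded, -np.inf, c))
    first = int(np.where(cand >= cand.max() - _TIE_TOL)[0].min())
    active.append(first)
    steps.append(LarStep("add", first, list(active), beta.copy(), 0.0, C))

    for _ in range(50 * (p + 1) ** 2):  # safety bound; breaks below
        s = np.sign(c[active])
        s[s == 0] = 1.0
        Xa = X[:, active] * s
        G = Xa.T @ Xa
        try:
            cho = scipy.linalg.cho_factor(G)
        except scipy.linalg.LinAlgError:
            cho = scipy.linalg.cho_factor(G + 1e-12 * np.eye(len(active)))
        one = np.ones(len(active))
        Ginv1 = scipy.linalg.cho_solve(cho, one)
        A_norm = 1.0 / np.sqrt(float(one @ Ginv1))
        w = A_norm * Ginv1
        u = Xa @ w                    # equiangular unit vector
        a = X.T @ u

        gamma_full = C / A_norm       # distance to the active-set OLS fit
        inactive = [k for k in range(p) if k not in active and not excluded[k]]
        j_star = -1
        gamma_hat = gamma_full
        if inactive and len(active) < max_active:
            ck, ak = c[inactive], a[inactive]
            with np.errstate(divide="ignore", invalid="ignore"):
                g1 = (C - ck) / (A_norm - ak)
                g2 = (C + ck) / (A_norm + ak)
            g1 = np.where((g1 > _TIE_TOL) & np.isfinite(g1), g1, np.inf)
            g2 = np.where((g2 > _TIE_TOL) & np.isfinite(g2), g2, np.inf)
            per_k = np.minimum(g1, g2)
            kmin = int(np.argmin(per_k))
            if per_k[kmin] < gamma_full - _TIE_TOL:
                gamma_hat = float(per_k[kmin])
                # ties between entering candidates: smallest column index
                tied = np.where(per_k <= gamma_hat + _TIE_TOL)[0]
                j_star = int(min(inactive[t] for t in tied))

        # LASSO modification: a sign crossing inside the move triggers a drop
        d = s * w
        drop_j = -1
        with np.errstate(divide="ignore", invalid="ignore"):
            gmz = np.where(d != 0, -beta[active] / d, np.inf)
        crossing = [(g, k) for g, k in zip(gmz, active) if _TIE_TOL < g < gamma_hat - _TIE_TOL]
        if crossing:
            gmin = min(g for g, _ in crossing)
            # simultaneous zero hits: drop the lowest index first, re-evaluate
            drop_j = min(k for g, k in crossing if g <= gmin + _TIE_TOL)
            gamma = gmin
        else:
            gamma = gamma_hat

        beta[active] = beta[active] + gamma * d
        c = c - gamma * a
        C = max(C - gamma * A_norm, 0.0)

        if drop_j >= 0:
            beta[drop_j] = 0.0
            active.remove(drop_j)
            steps.append(LarStep("drop", drop_j, list(active), beta.copy(),
                                 float(np.abs(beta).sum()), C))
            if C <= spec.corr_threshold + _TIE_TOL or not active:
                path.termination = "threshold"
                break
            continue   # recompute direction for the reduced active set

        if j_star >= 0:
            if not _gram_ok(X, active + [j_star]):
                warnings.warn(
                    f"covariate {j_star} makes the active set rank deficient; skipped",
                    RuntimeWarning, stacklevel=2,
                )
                excluded[j_star] = True
                continue
            active.append(j_star)
            steps.append(LarStep("add", j_star, list(active), beta.copy(),
                                 float(np.abs(beta).sum()), C))
            if C <= spec.corr_threshold + _TIE_TOL:
                path.termination = "threshold"
                break
            continue

        # completed the jump to the active-set least-squares fit
        steps.append(LarStep("terminate", -1, list(active), beta.copy(),
                             float(np.abs(beta).sum()), C))
        path.termination = ("threshold" if C <= spec.corr_threshold + _TIE_TOL
                            else "df_exhausted")
        break
    else:  # pragma: no cover - safety bound
        raise RuntimeError("LAR-LASSO failed to terminate")
    return path


def coefficients_at_l1(path: LarPath, l1_norm: float) -> np.ndarray:
    """Coefficients at an arbitrary point of the piecewise-linear path.

    Interpolates linearly between the two adjacent breakpoints bracketing the
    requested L1 arc-length coordinate; at a breakpoint returns that
    breakpoint's coefficients exactly.
    """
    l1s = [s.l1_norm for s in path.steps]
    lo, hi = min(l1s), max(l1s)
    if not (lo - 1e-12 <= l1_norm <= hi + 1e-12):
        raise ValueError(f"l1_norm {l1_norm} outside path range [{lo}, {hi}]")
    for k in range(len(l1s) - 1):
        a, b = l1s[k], l1s[k + 1]
        if min(a, b) - 1e-12 <= l1_norm <= max(a, b) + 1e-12:
            if abs(b - a) < 1e-15:
                return path.steps[k + 1].beta.copy()
            t = (l1_norm - a) / (b - a)
            return (1 - t) * path.steps[k].beta + t * path.steps[k + 1].beta
    return path.steps[-1].beta.copy()


def predict(coefficients: np.ndarray, transform: StandardizationTransform,
            X_new_raw: np.ndarray) -> np.ndarray:
    """Predict on the raw response scale from standardized-scale coefficients."""
    coefficients = np.asarray(coefficients, dtype=float)
    X_new_raw = np.atleast_2d(np.asarray(X_new_raw, dtype=float))
    if X_new_raw.shape[1] != len(transform.centres) or len(coefficients) != len(transform.centres):
        raise ValueError("column count mismatch between design, transform and coefficients")
    Xs = transform.apply(X_new_raw)
    Xs[:, ~transform.valid] = 0.0
    return transform.response_centre + Xs @ coefficients
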