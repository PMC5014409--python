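"""Trend-surface modelling of first-stage residuals.

Spatial position serves as a proxy for unobserved spatial processes: the
residuals of the covariate-based model averaging are regressed on a design
of Easting/Northing polynomial terms (single powers up to order 12 and
two-factor products E^a * N^b with total order a + b capped at half the
maximum single order, to avoid confounding high-order interactions with
high-order single terms).  Fitting, per-split selection and inverse-SSE
model averaging reuse the LAR + ensemble machinery unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import TermDescriptor, TermedDesign
from .ensemble import Ensemble, SplitPlan, fit_ensemble, model_average_predict
from .grids import PointSet

__all__ = ["SpatialDesignSpec", "build_spatial_design", "fit_residual_stage",
           "spatial_design_matrix"]


@dataclass(frozen=True)
class SpatialDesignSpec:
    """Orders of the trend-surface design.

    max_single_order : highest power of E and of N taken singly.
    max_interaction_total_order : cap on a + b for product terms E^a * N^b;
        must not exceed half the single-term maximum (confounding guard).
    include_interactions : disable products entirely if False.
    """

    max_single_order: int = 12
    max_interaction_total_order: int = 6
    include_interactions: bool = True

    def __post_init__(self) -> None:
        if self.max_single_order < 1:
            raise ValueError("max_single_order must be >= 1")
        if self.include_interactions and (
            self.max_interaction_total_order > self.max_single_order / 2
        ):
            raise ValueError(
                "max_interaction_total_order must not exceed max_single_order / 2"
            )


@dataclass
class ScaledCoords:
    """Midrange/half-range affine map taking coordinates into [-1, 1]."""

    centre: np.ndarray
    half_range: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(coords) - self.centre) / self.half_range


def _coord_scaler(coords: np.ndarray) -> ScaledCoords:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if np.any(hi - lo == 0):
        raise ValueError("degenerate coordinates: zero spatial extent")
    return ScaledCoords(centre=(lo + hi) / 2.0, half_range=(hi - lo) / 2.0)


def _spatial_terms(spec: SpatialDesignSpec) -> list[tuple[str, int, int]]:
    """(name, a, b) with a = power of E, b = power of N."""
    terms = [(f"E^{k}" if k > 1 else "E", k, 0) for k in range(1, spec.max_single_order + 1)]
    terms += [(f"N^{k}" if k > 1 else "N", 0, k) for k in range(1, spec.max_single_order + 1)]
    if spec.include_interactions:
        for total in range(2, spec.max_interaction_total_order + 1):
            for a in range(1, total):
                b = total - a
                terms.append((f"E^{a}*N^{b}", a, b))
    return terms


def spatial_design_matrix(coords: np.ndarray, spec: SpatialDesignSpec,
                          scaler: ScaledCoords) -> np.ndarray:
    sc = scaler.apply(coords)
    E, N = sc[:, 0], sc[:, 1]
    return np.column_stack([E ** a * N ** b for _, a, b in _spatial_terms(spec)])


def build_spatial_design(coords: np.ndarray, spec: SpatialDesignSpec | None = None,
                         scaler: ScaledCoords | None = None
                         ) -> tuple[TermedDesign, ScaledCoords]:
    """Trend-surface design at the given coordinates.

    Coordinates are recentred to their midrange and rescaled to [-1, 1]
    before powering — essential for conditioning at order 12.  The default
    spec (12, 6) yields 24 single terms + 15 products = 39 columns.
    """
    spec = spec or SpatialDesignSpec()
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    scaler = scaler or _coord_scaler(coords)
    mat = spatial_design_matrix(coords, spec, scaler)
    descs = []
    for name, a, b in _spatial_terms(spec):
        if a and b:
            descs.append(TermDescriptor("interaction", (f"E^{a}" if a > 1 else "E",
                                                        f"N^{b}" if b > 1 else "N"),
                                        (1, 1), 0.0, a + b - 1))
        else:
            base = "E" if a else "N"
            k = a or b
            descs.append(TermDescriptor("polynomial", (base,), (k,), 0.0, k - 1))
    return TermedDesign(mat, descs), scaler


@dataclass
class ResidualStage:
    """Fitted second-stage trend surface bound to its coordinate scaling."""

    ensemble: Ensemble
    spec: SpatialDesignSpec
    scaler: ScaledCoords

    def predict(self, coords: np.ndarray) -> np.ndarray:
        X = spatial_design_matrix(coords, self.spec, self.scaler)
        return model_average_predict(self.ensemble, X)


def fit_residual_stage(stage1_residuals: np.ndarray, response: PointSet,
                       spec: SpatialDesignSpec | None = None,
                       plan: SplitPlan | None = None,
                       seed: int = 0, n_splits: int = 500,
                       n_train: int = 35) -> ResidualStage:
    """Fit the LAR + model-averaging machinery to stage-1 residuals.

    Residuals are taken against the stage-1 weighted model-averaged
    predictions at the observation locations.  By default a fresh seeded
    split plan is drawn; pass the stage-1 plan to reuse its partitions.
    """
    from .ensemble import make_splits   # local import avoids cycle at module load

    spec = spec or SpatialDesignSpec()
    r = np.asarray(stage1_residuals, dtype=float)
    if len(r) != len(response):
        raise ValueError("residual vector does not match the observation count")
    design, scaler = build_spatial_design(response.coords, spec)
    if plan is None:
        plan = make_splits(len(response), n_train=min(n_train, len(response) - 1),
                           n_splits=n_splits, seed=seed)
    if plan.n_total != len(response):
        raise ValueError("split plan size does not match the observation count")
    ens = fit_ensemble(design, r, plan, method="lar")
    return ResidualStage(ensemble=ens, spec=spec, scaler=scaler)
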