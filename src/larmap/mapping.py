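"""Full-cover prediction and empirical uncertainty rasters.

Every pixel of the common covariate grid receives one prediction per
selected split model; the map is the inverse-SSE weighted average of that
per-model stack plus the second-stage trend surface evaluated at the pixel
centre.  Prediction uncertainty is the width of the interval containing the
middle 95% of the (unweighted) per-model predictions at the pixel.
"""

from __future__ import annotations

import numpy as np

from .align import tps_fit, tps_predict
from .design import TermDescriptor
from .ensemble import Ensemble, per_model_predictions
from .grids import PointSet, RasterGrid

__all__ = ["term_matrix_from_rasters", "rasterize_point_survey",
           "predict_full_cover", "uncertainty_raster"]


def rasterize_point_survey(survey: PointSet, column: str,
                           template: RasterGrid) -> RasterGrid:
    """Thin-plate-spline interpolation of a point survey to a raster grid."""
    model = tps_fit(survey, column)
    ee, nn = template.pixel_centres()
    vals = tps_predict(model, np.column_stack([ee.ravel(), nn.ravel()]))
    return RasterGrid(vals.reshape(template.values.shape), template.x_origin,
                      template.y_origin, template.pixel_size, template.nodata)


def term_matrix_from_rasters(terms: list[TermDescriptor],
                             rasters: dict[str, RasterGrid]) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate design terms at every pixel of aligned covariate rasters.

    Returns (matrix of shape (n_pixels, n_terms), nodata mask of shape
    (n_pixels,)); pixel order is row-major from the north-west corner.
    """
    needed = sorted({b for t in terms for b in t.bases})
    missing = [b for b in needed if b not in rasters]
    if missing:
        raise ValueError(f"missing covariate raster(s) for term base(s): {missing}")
    ref = rasters[needed[0]] if needed else next(iter(rasters.values()))
    for nm in needed:
        if not rasters[nm].same_georeference(ref):
            raise ValueError(f"raster '{nm}' is not aligned with the common grid")
    flat = {nm: rasters[nm].values.ravel() for nm in needed}
    bad = np.zeros(ref.nrows * ref.ncols, dtype=bool)
    for nm in needed:
        bad |= rasters[nm].is_nodata(flat[nm])
    cols = []
    for t in terms:
        if t.kind == "polynomial":
            cols.append(flat[t.bases[0]] ** t.powers[0])
        else:
            cols.append(flat[t.bases[0]] * flat[t.bases[1]])
    return np.column_stack(cols), bad


def predict_full_cover(stage1: Ensemble, covariate_rasters: dict[str, RasterGrid],
                       terms: list[TermDescriptor],
                       stage2=None) -> tuple[RasterGrid, np.ndarray]:
    """Evaluate the ensemble at every pixel.

    Parameters
    ----------
    stage1 : fitted covariate-based ensemble (its coefficients index ``terms``).
    covariate_rasters : aligned rasters, one per base covariate any selected
        term needs (rasterize point surveys first).
    terms : descriptors of the stage-1 design columns, in column order.
    stage2 : optional fitted trend-surface stage whose model-averaged value
        at each pixel centre is added to the weighted stage-1 average.

    Returns the prediction raster and the per-model prediction stack of
    shape (nrows, ncols, n_splits) — the stack excludes the stage-2
    component.  Nodata pixels propagate nodata.
    """
    ref = next(iter(covariate_rasters.values()))
    X, bad = term_matrix_from_rasters(terms, covariate_rasters)
    stack_flat = per_model_predictions(stage1, X)
    pred = stack_flat @ stage1.weights
    if stage2 is not None:
        ee, nn = ref.pixel_centres()
        pred = pred + stage2.predict(np.column_stack([ee.ravel(), nn.ravel()]))
    pred[bad] = ref.nodata
    stack = stack_flat.reshape(ref.nrows, ref.ncols, -1)
    stack[bad.reshape(ref.nrows, ref.ncols), :] = np.nan
    raster = RasterGrid(pred.reshape(ref.nrows, ref.ncols), ref.x_origin,
                        ref.y_origin, ref.pixel_size, ref.nodata)
    return raster, stack


def uncertainty_raster(stack: np.ndarray, template: RasterGrid,
                       level: float = 0.95) -> RasterGrid:
    """Empirical central-interval width of the per-model predictions.

    Per pixel: (upper - lower) empirical percentile of the unweighted
    per-model predictions, with tail mass (1 - level)/2 on each side.
    Percentiles use the linear-interpolation convention of numpy's default
    quantile rule.  Nodata (NaN) pixels propagate nodata.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[2] < 2:
        raise ValueError("need a (nrows, ncols, >=2 models) prediction stack")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    tail = 100.0 * (1.0 - level) / 2.0
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(stack, tail, axis=2)
        hi = np.nanpercentile(stack, 100.0 - tail, axis=2)
    width = hi - lo
    bad = np.isnan(stack).all(axis=2)
    width[bad] = template.nodata
    return RasterGrid(width, template.x_origin, template.y_origin,
                      template.pixel_size, template.nodata)


def plot_map(raster: RasterGrid, path, observations: PointSet | None = None,
             title: str = "") -> None:
    """Grayscale rendering of a raster with optional observation overlay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.where(raster.is_nodata(raster.values), np.nan, raster.values)
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(vals, cmap="gray",
                   extent=(raster.x_origin, raster.x_max, raster.y_origin, raster.y_max))
    if observations is not None:
        ax.scatter(observations.easting, observations.northing,
                   c=observations.values.iloc[:, 0], cmap="gray",
                   edgecolors="red", s=30)
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    ax.set_xlabel("Easting (m)")
    ax.set_ylabel("Northing (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
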