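import numpy as np
import pandas as pd
import pytest

from larmap.grids import PointSet, RasterGrid
from larmap.synth import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_survey(rng):
    """A 40-point random survey on a 500 m square."""
    e = rng.uniform(0, 500, 40)
    n = rng.uniform(0, 500, 40)
    v = np.sin(e / 80.0) + 0.3 * np.cos(n / 60.0) + 0.1 * rng.standard_normal(40)
    return PointSet(ids=np.arange(40), easting=e, northing=n,
                    values=pd.DataFrame({"v": v}))


@pytest.fixture
def small_raster(rng):
    return RasterGrid(values=rng.standard_normal((12, 15)), x_origin=100.0,
                      y_origin=200.0, pixel_size=25.0)


@pytest.fixture(scope="session")
def tiny_scene():
    """A small, fast scene shared by several integration-level tests."""
    cfg = SceneConfig(grid_nrows=20, grid_ncols=20, n_response=30,
                      n_base_covariates=10, n_collinear_blocks=2,
                      n_point_covariates=2, n_survey_points=80,
                      n_true_terms=3, residual_amplitude=0.3, seed=7)
    return generate_scene(cfg)


def standardized_instance(seed, n, p, rho=0.0, k_signal=3, noise=0.3):
    """Random regression instance with centred unit-norm columns and centred y."""
    g = np.random.default_rng(seed)
    if rho > 0:
        L = np.linalg.cholesky(rho * np.ones((p, p)) + (1 - rho) * np.eye(p))
        X = g.standard_normal((n, p)) @ L.T
    else:
        X = g.standard_normal((n, p))
    X -= X.mean(axis=0)
    X /= np.linalg.norm(X, axis=0)
    beta = np.zeros(p)
    beta[:k_signal] = g.uniform(1, 3, k_signal) * g.choice([-1, 1], k_signal)
    y = X @ beta + noise * g.standard_normal(n)
    return X, y - y.mean()
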