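import numpy as np
import pytest

from shapemapper.morpho import LandmarkSample
from shapemapper.synthetic import (
    MapSpec,
    QtlSpec,
    SimTruth,
    beta_norm_for_h2,
    default_mean_shape,
    isotropic_error_cov,
    make_mesh,
    simulate_backcross,
    simulate_shapes,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def ellipsoid_mesh():
    return make_mesh("ellipsoid", (3.0, 2.0, 1.0), subdivisions=3)


@pytest.fixture(scope="session")
def sphere_mesh():
    return make_mesh("ellipsoid", (1.0, 1.0, 1.0), subdivisions=3)


@pytest.fixture(scope="session")
def mean_shape():
    return default_mean_shape(13, 3)


@pytest.fixture(scope="session")
def small_cross():
    """3-chromosome backcross, 2 planted QTL, modest noise: shared by tests."""
    map_spec = MapSpec([("1", 100.0), ("2", 100.0), ("3", 100.0)], 5.0)
    cross = simulate_backcross(map_spec, n=400, seed=101)
    mean = default_mean_shape(13, 3)
    sigma = 0.004
    nrm = beta_norm_for_h2(0.3, sigma)
    r = np.random.default_rng(55)
    from shapemapper.synthetic import shape_tangent_projector

    proj = shape_tangent_projector(mean)
    dirs = r.standard_normal((3, 39)) @ proj
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    truth = SimTruth(
        mean_shape=mean,
        qtls=[QtlSpec("1", 30.0, nrm * dirs[0]), QtlSpec("2", 70.0, nrm * dirs[1])],
        size_effect=dirs[2] * 0.02,
        error_cov=isotropic_error_cov(13, 3, sigma),
    )
    coords, covars = simulate_shapes(cross, truth, seed=202)
    cross.phenotypes = LandmarkSample(coords=coords, ids=cross.ids)
    cross.covariates = covars
    cross.sim_truth = truth
    return cross
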