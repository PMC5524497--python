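"""Shared fixtures: a small synthetic population and a Gaussian feature cloud."""

import numpy as np
import pytest

from camotype import synth, typicality
from camotype.features import FeatureVector, extract_features

# reduced geometry for fast tests: counts and contracts are size-invariant
SMALL_IMAGE = (640, 520)
SMALL_DIMS = (64, 128)  # patch (height, width)


@pytest.fixture(scope="session")
def small_params() -> synth.PopulationParams:
    return synth.PopulationParams(image_size=SMALL_IMAGE, seed=11)


@pytest.fixture(scope="session")
def small_population(small_params):
    return synth.generate_population(small_params, 12)


@pytest.fixture(scope="session")
def small_features(small_population):
    return extract_features(small_population, n_patches=5, dims=SMALL_DIMS, seed=4)


def gaussian_features(seed: int, n: int = 505) -> list[FeatureVector]:
    """A unimodal feature cloud mimicking pipeline output: 3-d colour
    (axis-aligned elliptical Gaussian) + 6-d texture simplex weights."""
    rng = np.random.default_rng(seed)
    colour_mean = np.array([0.30, 0.25, 0.18])
    colour_cov = np.diag([0.0025, 0.0020, 0.0015])
    texture_mean = np.array([0.26, 0.22, 0.18, 0.14, 0.11, 0.09])
    out = []
    for i in range(n):
        col = np.abs(rng.multivariate_normal(colour_mean, colour_cov))
        tex = np.abs(rng.normal(texture_mean, 0.03))
        tex = tex / tex.sum()
        out.append(FeatureVector(colour=col, texture=tex, tree_id=i // 5, patch_id=i % 5))
    return out


@pytest.fixture(scope="session")
def feature_cloud() -> list[FeatureVector]:
    return gaussian_features(seed=21)


@pytest.fixture(scope="session")
def cloud_selection(feature_cloud):
    """Fitted ranks + 2x2 treatment selection on the Gaussian cloud."""
    fit = typicality.fit_ml(feature_cloud)
    ranked = typicality.distances(fit, feature_cloud)
    selection = typicality.select_treatments(ranked, 12)
    return fit, ranked, selection
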