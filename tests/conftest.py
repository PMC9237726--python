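import numpy as np
import pytest

import specmap as sm


@pytest.fixture(scope="session")
def default_scene():
    return sm.make_default_scene(32, 32, seed=0)


@pytest.fixture(scope="session")
def rendered_scene(default_scene):
    return sm.render(default_scene)


@pytest.fixture(scope="session")
def qc_mask(rendered_scene):
    params = sm.PreprocessParams()
    return sm.detect_empty(rendered_scene, params) & sm.detect_scatter(rendered_scene, params)


@pytest.fixture(scope="session")
def pipeline_result(default_scene, rendered_scene, qc_mask):
    """Standard pipeline on the default scene: QC -> CO2 -> normalize ->
    second derivative -> PCA(15) -> kNN Leiden at package defaults."""
    params = sm.PreprocessParams()
    retained = sm.apply_mask(rendered_scene, qc_mask)
    x = sm.exclude_co2(retained, params)
    x = sm.vector_normalize(x)
    x = sm.second_derivative(x, params)
    pca = sm.fit_pca(x, 15)
    assignment = sm.cluster(pca.scores, n_neighbors=15, seed=0)
    return {
        "retained": retained,
        "pca": pca,
        "assignment": assignment,
        "truth": default_scene.region_map[qc_mask.keep],
    }


@pytest.fixture()
def simple_map():
    """4-pixel x 5-point map with an easy axis for window arithmetic."""
    axis = np.array([1000.0, 1010.0, 1020.0, 1030.0, 1040.0])
    data = np.arange(20, dtype=float).reshape(4, 5) + 1.0
    return sm.SpectralMap(data, axis)


def gaussian(axis, center, sigma, amplitude=1.0):
    return amplitude * np.exp(-0.5 * ((np.asarray(axis) - center) / sigma) ** 2)
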