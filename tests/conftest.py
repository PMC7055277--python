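import numpy as np
import pytest

from odflow import kernel, mobility, synthetic

NYC_R_KM = 1.8
NYC_BETA_PER_KM = 0.15


@pytest.fixture(scope="session")
def zone_layout_800():
    """800 zones uniform in a 14 km x 14 km plane (fixed seed)."""
    return synthetic.make_zone_layout("uniform-random", 800, (14.0, 14.0), seed=1)


@pytest.fixture(scope="session")
def exact_model_pairs_800(zone_layout_800):
    """Exact model transition matrix at the fitted taxi-kernel parameters,
    reduced to (log10 d, log10 w) pairs in the 0.1-11 km window."""
    D = zone_layout_800.distance_matrix_km()
    W = mobility.model_transition_matrix(D, NYC_R_KM, NYC_BETA_PER_KM)
    return kernel.kernel_pairs(W, D, d_min=0.1, d_max=11.0)


@pytest.fixture(scope="session")
def small_dense_chain():
    """5-zone geometry with mixed local/long-range structure; fast-mixing."""
    pos = np.array([[0.0, 0.0], [800.0, 0.0], [0.0, 900.0],
                    [5000.0, 0.0], [9000.0, 4000.0]])
    layout = synthetic.ZoneLayout(positions_m=pos)
    D = layout.distance_matrix_km()
    W = mobility.model_transition_matrix(D, NYC_R_KM, NYC_BETA_PER_KM)
    return D, W
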