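import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fishscreen.spots import PSFModel
from fishscreen.synthetic import NoiseModel, SimulationConfig

VOXEL_SIZE = (0.3, 0.1, 0.1)
PSF = PSFModel(sigma_lateral=0.13, sigma_axial=0.35)


@pytest.fixture
def psf():
    return PSF


@pytest.fixture
def sim_config():
    """Small, fast baseline config for image simulations."""

    def factory(**overrides):
        defaults = dict(
            image_shape=(24, 96, 96),
            voxel_size=VOXEL_SIZE,
            psf_sigma=(PSF.sigma_lateral, PSF.sigma_axial),
            n_single_spots=50,
            single_amplitude_mean=100.0,
            single_amplitude_cv=0.05,
            noise_model=NoiseModel(baseline=100.0, read_sd=2.0),
            min_separation_um=0.6,
            seed=0,
        )
        defaults.update(overrides)
        return SimulationConfig(**defaults)

    return factory


def scaled_coords(df, psf=PSF):
    """Anisotropy-aware coordinates (axial compressed to lateral units)."""
    return np.column_stack(
        [
            df["z_um"].to_numpy() * psf.sigma_lateral / psf.sigma_axial,
            df["y_um"].to_numpy(),
            df["x_um"].to_numpy(),
        ]
    )


def match_to_truth(detected_df, truth_df, radius, psf=PSF):
    """(recall, precision) with nearest-neighbour matching at ``radius``."""
    if len(detected_df) == 0:
        return 0.0, 1.0
    d = cdist(scaled_coords(truth_df, psf), scaled_coords(detected_df, psf))
    recall = float((d.min(axis=1) < radius).mean())
    precision = float((d.min(axis=0) < radius).mean())
    return recall, precision
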