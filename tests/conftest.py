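import numpy as np
import pytest

from holodm import background, drymass, holosim, phantom, recon

SMALL_SHAPE = (192, 256)


@pytest.fixture(scope="session")
def small_scene() -> phantom.Scene:
    return phantom.random_scene(
        1,
        n_cells=10,
        shape=SMALL_SHAPE,
        radius_range_um=(7.0, 10.0),
        thickness_range_um=(2.0, 3.5),
        margin_um=12.0,
    )


@pytest.fixture(scope="session")
def small_optical() -> holosim.OpticalConfig:
    return holosim.OpticalConfig(shape=SMALL_SHAPE, frames_per_timepoint=1)


@pytest.fixture(scope="session")
def recon_params() -> recon.ReconstructionParams:
    return recon.ReconstructionParams()


@pytest.fixture(scope="session")
def dm_params() -> drymass.DryMassParams:
    return drymass.DryMassParams()


@pytest.fixture(scope="session")
def bg_params() -> background.BackgroundParams:
    return background.BackgroundParams()


@pytest.fixture(scope="session")
def small_ground_truth(small_scene, small_optical) -> phantom.PhaseMap:
    return phantom.render_phase(small_scene, small_optical.wavelength_um)


@pytest.fixture(scope="session")
def small_reconstruction(small_scene, small_optical, recon_params) -> phantom.PhaseMap:
    """Noise-free single-frame reconstruction of the small scene."""
    holos = holosim.acquire_timepoint(small_scene, small_optical, 0.0, seed=1)
    return recon.reconstruct_stack(holos, recon_params, conjugate=True)


def rms(a: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(a))))


def piston_removed(delta: np.ndarray) -> np.ndarray:
    return delta - delta.mean()
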