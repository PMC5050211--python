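import numpy as np
import pytest

from biofilmcubes.image_io import BinaryMask, ImageStack
from biofilmcubes.synthetic import OpticsParams, SceneParams, generate_scene, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_stack(rng):
    """Random uint16 two-channel anisotropic stack."""
    voxels = rng.integers(0, 4096, size=(2, 8, 16, 16), dtype=np.uint16)
    return ImageStack(
        voxels=voxels, spacing_um=(1.0, 0.5, 0.5), channel_names=["constitutive", "curli"]
    )


@pytest.fixture
def slab_mask():
    """Flat biomass slab: z indices 0..19 foreground at 1 um spacing."""
    vox = np.zeros((30, 24, 24), dtype=bool)
    vox[:20] = True
    return BinaryMask(voxels=vox, spacing_um=1.0)


def tiny_scene_params(**overrides) -> SceneParams:
    """A fast-to-render scene for end-to-end unit tests."""
    defaults = dict(
        n_single=150,
        n_aggregates=2,
        cells_per_aggregate=60,
        aggregate_radius_um=4.0,
        aggregate_zmax_um=20.0,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)


@pytest.fixture
def tiny_rendered():
    """Small no-noise render of a two-aggregate scene with ground truth."""
    params = tiny_scene_params()
    scene = generate_scene(params, domain_size_um=(32.0, 32.0, 32.0), seed=7)
    optics = OpticsParams(
        psf_sigma_um=(0.0, 0.0, 0.0),
        poisson_noise=False,
        read_noise_sd=0.0,
        background_level=0.0,
        seed=7,
    )
    stack = render_scene(scene, optics, ("constitutive", "curli", "flagella"))
    return scene, optics, stack
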