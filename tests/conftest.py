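import numpy as np
import pytest

from acidox import phantom, pipeline


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom: full nested tumor on a grid small enough for fast fits."""
    return phantom.PhantomSpec(
        grid_shape=(32, 32, 12),
        voxel_size_mm=(2.0, 2.0, 4.0),
        net_radius_vox=8.0,
        cet_radius_vox=5.0,
        necrosis_radius_vox=2.0,
        boundary_jitter=0.12,
        b0_field_ppm=0.1,
        noise_sigma=0.005,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_analysis(small_spec):
    """One full pipeline run shared across tests (deterministic by seed)."""
    return pipeline.analyze_phantom_patient(small_spec)


@pytest.fixture(scope="session")
def noiseless_phantom(small_spec):
    import dataclasses

    spec = dataclasses.replace(small_spec, noise_sigma=0.0, b0_field_ppm=0.0)
    roi, pmaps, anat = phantom.make_phantom(spec)
    return spec, roi, pmaps, anat


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
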