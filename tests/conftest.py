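import numpy as np
import pytest

from mesovasc import phantom


@pytest.fixture
def iso_spec():
    """Small isotropic phantom volume (90^3 voxels at 10 um)."""
    return phantom.PhantomSpec(
        field_of_view_mm=(0.9, 0.9, 0.9),
        voxel_spacing_um=(10.0, 10.0, 10.0),
        epidermis_band_um=(60.0, 360.0),
        dermis_band_um=(360.0, 860.0))


@pytest.fixture
def recovery_params():
    """One line + one Y + one H per layer, in the exact-recovery regime
    (radius >= 2 voxels, clearance >= 4 voxels)."""
    p = phantom.LayerVesselParams(
        n_lines=1, n_y=1, n_h=1, radius_um=(20.0, 30.0),
        arm_length_um=(180.0, 280.0), clearance_um=40.0)
    return {"epi_svp": p, "dermal": p}


@pytest.fixture
def planar_spec():
    """Roomy (z, x) field for planar (2D) phantoms."""
    return phantom.PhantomSpec(
        field_of_view_mm=(1.6, 0.3, 1.1),
        voxel_spacing_um=(10.0, 10.0, 10.0),
        epidermis_band_um=(60.0, 500.0),
        dermis_band_um=(500.0, 1060.0))


@pytest.fixture
def planar_params():
    p = phantom.LayerVesselParams(
        n_lines=1, n_y=1, n_h=1, radius_um=(20.0, 30.0),
        arm_length_um=(160.0, 240.0), clearance_um=40.0, planar=True)
    return {"epi_svp": p, "dermal": p}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
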