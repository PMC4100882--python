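import numpy as np
import pytest

from soapct.phantom import PhantomSpec, default_cavity_params, generate_phantom
from soapct.volume_io import VoxelVolume


@pytest.fixture(scope="session")
def spindle_phantom():
    """Tilted tumbling-spindle phantom with fragments and streak artifacts."""
    params = default_cavity_params("tumbling_spindle", 240.0)
    params["tilt_deg"] = 6.0
    spec = PhantomSpec("tumbling_spindle", params,
                       block_shape_mm=(110.0, 110.0, 280.0),
                       n_fragments=4, streak_artifacts=True, seed=42)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Small noiseless axis-aligned cylinder cavity (fully analytic)."""
    params = {"length_mm": 60.0, "max_radius_mm": 10.0,
              "neck_radius_mm": 10.0, "tilt_deg": 0.0}
    spec = PhantomSpec("cylinder", params, block_shape_mm=(60.0, 60.0, 90.0),
                       noise_sd_hu=0.0, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_cylinder_phantom():
    params = {"length_mm": 60.0, "max_radius_mm": 10.0,
              "neck_radius_mm": 10.0, "tilt_deg": 0.0}
    spec = PhantomSpec("cylinder", params, block_shape_mm=(60.0, 60.0, 90.0),
                       noise_sd_hu=5.0, seed=2)
    return generate_phantom(spec)


@pytest.fixture()
def soap_box_volume():
    """Intact uniform soap block (no cavity), air margin around it."""
    arr = np.full((40, 40, 60), -1000.0, dtype=np.float32)
    arr[5:35, 5:35, 5:55] = 100.0
    return VoxelVolume(arr, np.ones(3))
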