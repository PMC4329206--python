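import numpy as np
import pytest

from ssbdual.forward import ProbeConfig, noise_sigma
from ssbdual.imaging import ScanPlan, acquire_magnetic_image
from ssbdual.spots import DetectionConfig
from ssbdual.synthetic import PhantomSpec, make_phantom_scene


@pytest.fixture(scope="session")
def probe() -> ProbeConfig:
    """Default probe with the cached display calibration."""
    return ProbeConfig()


@pytest.fixture(scope="session")
def phantom_scan(probe):
    """Default phantom (0.075 emu at 31 mm), its plan and noiseless image."""
    scene = make_phantom_scene(PhantomSpec())
    plan = ScanPlan.cover(scene)
    img = acquire_magnetic_image(scene, plan, probe)
    det = DetectionConfig(noise_sigma_estimate=noise_sigma(probe, plan.dwell_time))
    return scene, plan, img, det


def toy_image(data, spacing=5.0, origin=(0.0, 0.0)):
    """Small baseline-corrected image literal for hand-enumerated cases."""
    from ssbdual.imaging import MagneticImage

    return MagneticImage(
        np.asarray(data, dtype=float),
        pixel_spacing=spacing,
        origin=origin,
        baseline_corrected=True,
    )
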