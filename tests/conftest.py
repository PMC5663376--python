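import numpy as np
import pytest

from saxskit.materials_library import default_brain_materials
from saxskit.phantom import DetectorModel, ScanPlan, default_mouse_phantom
from saxskit.synthetic import (GroundTruth, TissueLayout, default_geometry,
                               generate_planar_scan)


@pytest.fixture(scope="session")
def materials20():
    return default_brain_materials(20.0)


@pytest.fixture(scope="session")
def mouse_phantom():
    return default_mouse_phantom()


@pytest.fixture(scope="session")
def detector():
    return DetectorModel()


@pytest.fixture(scope="session")
def full_plan():
    return ScanPlan()


@pytest.fixture(scope="session")
def test_geometry():
    """Compact wide-q camera: 128×128 binned pixels, q ≈ 0.06–9.8 nm⁻¹."""
    return default_geometry(binning=8, n_pixels=128)


@pytest.fixture(scope="session")
def synthetic_scan(test_geometry):
    """Default-noise synthetic planar scan + ground truth (seed 7)."""
    layout = TissueLayout.nested(9, 9)
    container, truth = generate_planar_scan(layout, GroundTruth(),
                                            test_geometry, seed=7)
    return layout, container, truth


@pytest.fixture(scope="session")
def reduced_scan(synthetic_scan, test_geometry):
    from saxskit.reduction import reduce_scan

    layout, container, truth = synthetic_scan
    scan = reduce_scan(container, test_geometry, n_radial_bins=256)
    return layout, scan, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
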