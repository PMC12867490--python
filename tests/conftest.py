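import numpy as np
import pytest

import pwspdt as pw
import pwspdt.geometry as geometry


@pytest.fixture(scope="session")
def coarse_model():
    """Default lesion geometry on the coarse (10 μm) grid."""
    return pw.build_tissue_model(pw.GeometryConfig(voxel_size=10.0, coarse_wall=True))


@pytest.fixture(scope="session")
def fine_model():
    """Default lesion geometry at 5 μm (1-voxel wall annulus)."""
    return pw.build_tissue_model(pw.GeometryConfig(voxel_size=5.0))


@pytest.fixture()
def dermis_column():
    """Homogeneous dermis column for 1D analytic comparisons."""

    def make(voxel_size=2.0, depth=3000.0):
        cfg = pw.GeometryConfig(
            domain_size=(2 * voxel_size, 2 * voxel_size, depth),
            voxel_size=voxel_size,
            count=0,
        )
        model = pw.build_tissue_model(cfg)
        model.labels[:] = geometry.REGION_CODES["reticular_dermis"]
        return model

    return make


@pytest.fixture(scope="session")
def small_vessel_model():
    """Tiny vessel-bearing domain for fast transport tests."""
    cfg = pw.GeometryConfig(
        domain_size=(200.0, 250.0, 610.0),
        voxel_size=10.0,
        center_depth=360.0,
        spacing=250.0,
        count=1,
        coarse_wall=True,
    )
    return pw.build_tissue_model(cfg)
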