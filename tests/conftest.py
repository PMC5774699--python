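"""Shared fixtures: small analytic basins and a stair-step toy coast."""

import numpy as np
import pytest

import seadrift as sd


@pytest.fixture
def uniform_basin():
    """All-wet box with a 0.1 m/s eastward current, no turbulence."""
    return sd.UniformFlow(u=0.1, bounds=(-1.0, 1.0, -1.0, 1.0),
                          water_depth=100.0)


@pytest.fixture
def rotation_basin():
    """Solid-body rotation (period one day) about the origin at the equator."""
    return sd.SolidBodyRotation(lon0=0.0, lat0=0.0,
                                omega=2.0 * np.pi / 86400.0,
                                bounds=(-1.0, 1.0, -1.0, 1.0),
                                water_depth=100.0)


@pytest.fixture
def parabolic_basin():
    """Quiescent 50 m water column with parabolic Kv (well-mixed test bed)."""
    return sd.ParabolicKvBasin(K0=1e-4, K1=4e-6, water_depth=50.0,
                               bounds=(-1.0, 1.0, -1.0, 1.0))


@pytest.fixture
def toy_coast():
    """3x3-cell basin with a land column over lon in [1, 2]."""
    mask = np.zeros((3, 3), bool)
    mask[:, 1] = True
    return sd.ToyCoastBasin(np.arange(4.0), np.arange(4.0), mask,
                            u=0.0, water_depth=100.0)
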