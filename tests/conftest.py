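import numpy as np
import pytest

import opaplan as op


@pytest.fixture(scope="session")
def coarse_thorax() -> op.StructureSet:
    """Default thorax phantom at 5 mm voxels (fast, for unit tests)."""
    return op.build_thorax_phantom(op.PhantomSpec(voxel_spacing_mm=5.0))


@pytest.fixture(scope="session")
def idealized_coarse() -> op.StructureSet:
    """Idealized circular-cylinder phantom at 4 mm voxels."""
    return op.build_idealized_cylinder_phantom(voxel_spacing_mm=4.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def sample_valid_geometry(rng: np.random.Generator,
                          expected_v5: float | None = None) -> op.GeometryInputs:
    """Random geometry guaranteed to have an interior arc-angle solution.

    Lengths span the clinically plausible ranges (tumor length 6.3-25.2 cm);
    V_W is back-computed so the required restricted volume is a uniform
    fraction of the available cylinder, which keeps the solution in (0, 360).
    """
    T = rng.uniform(24.0, 36.0)
    E = rng.uniform(3.0, min(9.0, T - 4.5))
    Lt = rng.uniform(6.3, 25.2)
    v5 = expected_v5 if expected_v5 is not None else rng.uniform(0.35, 0.75)
    R = (T - E - 4.0) / 2.0
    denom = np.pi * R * R * (Lt + 4.0)
    required = rng.uniform(0.02, 0.98) * denom
    V_OW = rng.uniform(0.0, 0.4) * required
    V_W = (required + V_OW) / (1.0 - v5)
    return op.GeometryInputs(T=T, E=E, Lt=Lt, V_W=V_W, V_OW=V_OW, expected_v5=v5)
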