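import numpy as np
import pytest

from perisurv.core import CTVolume
from perisurv.phantom import PhantomSpec, SimulationTruth, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A desk-size phantom spec: 48 mm cube, modest tumors."""
    return PhantomSpec(
        volume_shape=(48, 48, 48),
        tumor_radius_range_mm=(5.0, 10.0),
        rim_width_range_mm=(1.0, 3.0),
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """One fixed phantom (volume, mask, covariates) reused across tests."""
    return generate_phantom(small_spec, seed=7)


def make_ball_mask(radius_mm: float, spacing=(1.0, 1.0, 1.0), pad: int = 3) -> CTVolume:
    """Digital ball: voxel centres within radius_mm of the centre voxel."""
    half = [int(np.ceil(radius_mm / s)) + pad for s in spacing]
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij")
    mask = sum(g**2 for g in grids) <= radius_mm**2 + 1e-9
    return CTVolume(mask.astype(np.uint8), spacing)
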