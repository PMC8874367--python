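import numpy as np
import pytest

from ngc_elute.geometry import (
    FLUID,
    WALL,
    DomainGrid,
    GeometrySpec,
    ReleaseSystemSpec,
    build_relay_ngc,
    place_release_system,
)


@pytest.fixture(scope="session")
def default_spec() -> GeometrySpec:
    return GeometrySpec()


@pytest.fixture(scope="session")
def coarse_grid(default_spec) -> DomainGrid:
    """Empty relay conduit at h = 0.04 mm (cheap; 8.5 cells per channel)."""
    return build_relay_ngc(default_spec, 0.04)


@pytest.fixture(scope="session")
def coarse_single_layer(coarse_grid) -> DomainGrid:
    return place_release_system(coarse_grid, ReleaseSystemSpec.single_layer())


def duct_grid(n_across: int = 20, n_along: int = 60, h: float = 0.02) -> DomainGrid:
    """Straight open channel: fluid core with one-wall-cell margins."""
    ny = n_across + 4
    role = np.full((ny, n_along), WALL, dtype=np.uint8)
    role[2 : 2 + n_across, :] = FLUID
    return DomainGrid(h=h, nx=n_along, ny=ny, cell_role=role, spec=GeometrySpec())


@pytest.fixture
def duct() -> DomainGrid:
    return duct_grid()
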