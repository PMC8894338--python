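import numpy as np
import pytest

from stomamech import (HoleSpec, LoadCase, MaterialTable, PhantomSpec,
                       build_unit_cube, build_wall_phantom, solve_case)


@pytest.fixture(scope="session")
def abdominal_materials():
    return MaterialTable.abdominal_wall()


@pytest.fixture(scope="session")
def unit_cube():
    return build_unit_cube(0.25)


def coarse_spec(**overrides) -> PhantomSpec:
    """A small, coarse wall phantom for fast unit tests."""
    base = dict(width=160.0, height=200.0, layer_thicknesses=(3.0, 3.0, 3.0, 3.0),
                strip_width=20.0, curvature_radius=200.0, resolution=8.0,
                hole_segments=24)
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def coarse_phantom():
    return build_wall_phantom(coarse_spec())


@pytest.fixture(scope="session")
def coarse_phantom_with_hole():
    return build_wall_phantom(coarse_spec(hole=HoleSpec(position="s11")))


@pytest.fixture(scope="session")
def coarse_hole_solution(coarse_phantom_with_hole, abdominal_materials):
    return solve_case(coarse_phantom_with_hole, abdominal_materials,
                      LoadCase(pressure=0.02))
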