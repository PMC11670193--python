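import numpy as np
import pytest

from veinflow.flow import BoundaryConditions, FluidProperties, solve_steady_flow
from veinflow.synthetic import VesselParams, generate_vessel


@pytest.fixture(scope="session")
def straight_params() -> VesselParams:
    """Straight uniform cylinder: L=60 mm, R=2.5 mm."""
    return VesselParams(
        inlet_radius=2.5,
        outlet_inlet_area_ratio=1.0,
        target_actual_length=60.0,
        tortuosity_amplitude=0.0,
        inlet_velocity=0.113,
    )


@pytest.fixture(scope="session")
def straight_geometry(straight_params):
    return generate_vessel(straight_params)


@pytest.fixture(scope="session")
def tapered_params() -> VesselParams:
    """Strongly tapering straight tube (outlet/inlet area ratio 0.25)."""
    return VesselParams(
        inlet_radius=3.0,
        outlet_inlet_area_ratio=0.25,
        target_actual_length=60.0,
        tortuosity_amplitude=0.0,
        inlet_velocity=0.05,
    )


@pytest.fixture(scope="session")
def tapered_geometry(tapered_params):
    return generate_vessel(tapered_params)


@pytest.fixture(scope="session")
def straight_solution(straight_geometry):
    return solve_steady_flow(
        straight_geometry, BoundaryConditions(0.113), FluidProperties()
    )
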