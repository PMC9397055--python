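"""Shared fixtures: converged reference solves reused across test modules.

The expensive steady solves (analytic duct fixtures, the Case 1A
unit-cell velocity sweep and the coarse design-comparison runs) are
computed once per session; tests assert different properties of the
same fields.
"""

import warnings

import numpy as np
import pytest

from scaffoldflow import (
    FluidProperties,
    ScaffoldSpec,
    SolverConfig,
    build_graded_ring_scaffold,
    darcy_permeability,
    make_channel_fixture,
    pressure_drop,
    solve_steady_flow,
    unit_cell_domain,
    velocity_sweep,
    voxelize,
)

PLATE_GAP_MM = 0.3
PLATE_SPACING_MM = 0.015  # 20 voxels across the gap
TUBE_RADIUS_MM = 0.5
TUBE_SPACING_MM = 1.0 / 30.0
INLET_1MM_S = 1e-3  # m/s


@pytest.fixture(scope="session")
def blood() -> FluidProperties:
    return FluidProperties.blood()


@pytest.fixture(scope="session")
def plate_case(blood):
    """Converged plane-Poiseuille solve: (domain, solution)."""
    dom = make_channel_fixture("parallel_plate", PLATE_GAP_MM, length=2.0, spacing=PLATE_SPACING_MM)
    sol = solve_steady_flow(dom, blood, SolverConfig(inlet_velocity=INLET_1MM_S))
    assert sol.converged
    return dom, sol


@pytest.fixture(scope="session")
def tube_case(blood):
    """Converged Hagen-Poiseuille solve: (domain, solution)."""
    dom = make_channel_fixture(
        "circular_tube", TUBE_RADIUS_MM, length=1.2, spacing=TUBE_SPACING_MM,
        entry_length=0.7, exit_length=0.7,
    )
    sol = solve_steady_flow(dom, blood, SolverConfig(inlet_velocity=INLET_1MM_S))
    assert sol.converged
    return dom, sol


@pytest.fixture(scope="session")
def uc1a_sweep(blood):
    """Case 1A unit cell swept over the standard 1-9 mm/s grid."""
    spec = ScaffoldSpec.case_1a()
    dom = unit_cell_domain(spec, 0.055, entry_length=1.0, exit_length=1.0)
    reports = velocity_sweep(dom, blood, pore_sizes=spec.pore_sizes, scaffold_id="1A")
    return spec, dom, reports


@pytest.fixture(scope="session")
def design_comparison(blood):
    """dP and k0 at 1 mm/s for all four catalogue designs, solved at
    matched ~0.1 mm voxel resolution (unit cells for the rectangular
    designs, quarter footprint for the graded design)."""
    out = {}
    for name in ("1A", "1B", "1C"):
        spec = ScaffoldSpec.named(name)
        dom = unit_cell_domain(spec, 0.09, entry_length=0.5, exit_length=0.5)
        sol = solve_steady_flow(dom, blood, SolverConfig(inlet_velocity=INLET_1MM_S))
        dP = pressure_drop(sol)
        out[name] = {
            "dP": dP,
            "k0": darcy_permeability(INLET_1MM_S, blood.dynamic_viscosity, dom.L * 1e-3, dP),
            "converged": sol.converged,
        }
    dom2 = voxelize(
        build_graded_ring_scaffold(ScaffoldSpec.case_2()),
        spacing=0.1, entry_length=0.5, exit_length=0.5, quarter=True,
    )
    # coarse full-domain run: integral quantities are stable well before
    # the strict stationarity band used on the small domains
    cfg = SolverConfig(inlet_velocity=INLET_1MM_S, velocity_change_tolerance=5e-4, check_every=250)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol2 = solve_steady_flow(dom2, blood, cfg)
    dP2 = pressure_drop(sol2)
    out["2"] = {
        "dP": dP2,
        "k0": darcy_permeability(INLET_1MM_S, blood.dynamic_viscosity, dom2.L * 1e-3, dP2),
        "converged": sol2.converged,
    }
    return out


def developed_mask(field, domain, h):
    """Select wall elements strictly inside the central duct section."""
    k0, k1 = domain.scaffold_range
    z = field.positions[:, 2]
    return (z > k0 * h) & (z < k1 * h)
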