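"""Shared fixtures; expensive solver solutions are session-scoped."""

import numpy as np
import pytest

from neotrap import (
    ElectrolyteSpec,
    OrigamiModel,
    PoreGeometry,
    SolverOptions,
    build_domain,
    solve_coupled,
)


@pytest.fixture(scope="session")
def kcl_1m():
    return ElectrolyteSpec.kcl(1.0)


@pytest.fixture(scope="session")
def open_pore_solution(kcl_1m):
    """Open pore (no origami) at +100 mV, moderate mesh."""
    geo = PoreGeometry()
    mesh = build_domain(geo, None, fine_cell_nm=1.0, coarse_cell_nm=10)
    sol = solve_coupled(mesh, kcl_1m, 0.1, SolverOptions(tol=1e-6, max_outer=300))
    assert sol.converged
    return geo, sol


@pytest.fixture(scope="session")
def orientation_pair(kcl_1m):
    """Vertical and horizontal docked-sphere solutions at +100 mV with the
    documented default parameterization (production mesh)."""
    geo = PoreGeometry()
    opts = SolverOptions(tol=1e-6, max_outer=200)
    sols = {}
    for orient in ("vertical", "horizontal"):
        mesh = build_domain(geo, OrigamiModel(orientation=orient), fine_cell_nm=0.75)
        sols[orient] = solve_coupled(mesh, kcl_1m, 0.1, opts)
        assert sols[orient].converged
    return geo, sols


@pytest.fixture(scope="session")
def poiseuille_solution(kcl_1m):
    """Uncharged straight channel, pressure-driven, no electric field."""
    geo = PoreGeometry(
        pore_radius_nm=20.0, lipid_thickness_nm=0.0, membrane_thickness_nm=300.0,
        reservoir_radius_nm=50.0, reservoir_height_nm=10.0,
    )
    mesh = build_domain(geo, None, fine_cell_nm=1.0, coarse_cell_nm=6.0)
    sol = solve_coupled(
        mesh, kcl_1m, 0.0, SolverOptions(tol=1e-6, max_outer=50), pressure_drop=2e4
    )
    assert sol.converged
    return geo, mesh, sol


@pytest.fixture(scope="session")
def smoluchowski_solution():
    """Long charged channel in dilute KCl with a thin double layer."""
    elec = ElectrolyteSpec.kcl(0.01)
    geo = PoreGeometry(
        pore_radius_nm=30.0, lipid_thickness_nm=0.0, membrane_thickness_nm=200.0,
        reservoir_radius_nm=45.0, reservoir_height_nm=8.0,
    )
    mesh = build_domain(geo, None, fine_cell_nm=0.75, coarse_cell_nm=4.0,
                        wall_charge=-5e-3)
    sol = solve_coupled(mesh, elec, 0.2, SolverOptions(tol=1e-6, max_outer=300))
    assert sol.converged
    return elec, geo, mesh, sol
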