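"""Solver validation against analytic electrokinetic limits.

The expensive solutions (open pore, orientation pair, Poiseuille channel,
electro-osmotic channel) are session fixtures shared with the acceptance
tests; the quicker property checks (antisymmetry, linearity, charge
monotonicity) run on deliberately coarse meshes.
"""

import numpy as np
import pytest

from neotrap import (
    ElectrolyteSpec,
    OrigamiModel,
    PoreGeometry,
    SolverOptions,
    axial_velocity_profile,
    build_domain,
    flow_rate,
    ionic_current,
    solve_coupled,
)
from neotrap.constants import GAS_CONSTANT, FARADAY, VACUUM_PERMITTIVITY


def coarse_solve(origami=None, voltage=0.1, molar=1.0, rho_f=None, **opts):
    geo = PoreGeometry()
    if rho_f is not None:
        origami = OrigamiModel(orientation="vertical", fixed_charge_density=rho_f)
    mesh = build_domain(geo, origami, fine_cell_nm=1.5, coarse_cell_nm=10)
    sol = solve_coupled(
        mesh, ElectrolyteSpec.kcl(molar), voltage,
        SolverOptions(tol=1e-6, max_outer=300, **opts),
    )
    assert sol.converged
    return geo, sol


class TestTrivialLimits:
    def test_zero_bias_gives_zero_fields(self):
        geo, sol = coarse_solve(voltage=0.0)
        assert ionic_current(sol, -40.0) == pytest.approx(0.0, abs=1e-18)
        assert flow_rate(sol, -40.0) == pytest.approx(0.0, abs=1e-30)
        assert np.max(np.abs(sol.v_z)) < 1e-15
        prof = axial_velocity_profile(sol)
        assert np.max(np.abs(prof[:, 1])) < 1e-15

    def test_voltage_outside_validity_range_rejected(self):
        geo = PoreGeometry()
        mesh = build_domain(geo, None, fine_cell_nm=3.0)
        with pytest.raises(ValueError):
            solve_coupled(mesh, ElectrolyteSpec.kcl(1.0), 1.5)

    def test_plane_outside_domain_rejected(self):
        geo, sol = coarse_solve(voltage=0.0)
        with pytest.raises(ValueError):
            ionic_current(sol, 1e4)


class TestConservation:
    def test_current_plane_independent(self, open_pore_solution):
        geo, sol = open_pore_solution
        planes = [-80.0, -15.0, 5.0, 60.0]
        currents = [ionic_current(sol, z) for z in planes]
        ref = currents[0]
        assert all(abs(i - ref) / abs(ref) < 0.01 for i in currents)

    def test_flow_rate_plane_independent(self, orientation_pair):
        geo, sols = orientation_pair
        for sol in sols.values():
            qs = [flow_rate(sol, z) for z in (-80.0, -15.0, 50.0)]
            assert max(abs(q - qs[0]) for q in qs) / abs(qs[0]) < 0.01


class TestConductanceOracle:
    def test_open_pore_matches_access_resistance_formula(self, open_pore_solution):
        geo, sol = open_pore_solution
        elec = sol.electrolyte
        sigma = elec.conductivity
        t = geo.slab_thickness_nm * 1e-9
        d = 2 * geo.effective_pore_radius_nm * 1e-9
        G_model = sigma / (4 * t / (np.pi * d * d) + 1 / d)
        G_sim = ionic_current(sol, -15.0) / sol.voltage
        assert G_sim == pytest.approx(G_model, rel=0.15)


class TestPoiseuilleOracle:
    def test_flow_matches_hagen_poiseuille(self, poiseuille_solution):
        geo, mesh, sol = poiseuille_solution
        eta = sol.electrolyte.viscosity
        R = geo.effective_pore_radius_nm * 1e-9
        zc = mesh.z_centers
        # measured pressure drop between two in-channel axis positions
        j1 = int(np.argmin(np.abs(zc + 250.0)))
        j2 = int(np.argmin(np.abs(zc + 50.0)))
        dp = sol.pressure[j1, 0] - sol.pressure[j2, 0]
        L = (zc[j2] - zc[j1]) * 1e-9
        Q_analytic = np.pi * R**4 * dp / (8 * eta * L)
        Q_sim = flow_rate(sol, -150.0)
        assert Q_sim == pytest.approx(Q_analytic, rel=0.02)

    def test_velocity_profile_parabolic(self, poiseuille_solution):
        geo, mesh, sol = poiseuille_solution
        R = geo.effective_pore_radius_nm
        j = int(np.argmin(np.abs(mesh.z_centers + 150.0)))
        rc = mesh.r_centers
        inside = rc < R
        v = 0.5 * (sol.v_z[j] + sol.v_z[j + 1])[inside]
        shape = 1.0 - (rc[inside] / R) ** 2
        vmax = v[0] / shape[0]
        assert np.max(np.abs(v - vmax * shape)) / abs(vmax) < 0.02

    def test_no_electric_response_without_charge(self, poiseuille_solution):
        geo, mesh, sol = poiseuille_solution
        assert abs(ionic_current(sol, -150.0)) < 1e-15


class TestSmoluchowskiOracle:
    def test_plug_velocity_matches_helmholtz_smoluchowski(self, smoluchowski_solution):
        elec, geo, mesh, sol = smoluchowski_solution
        eta = elec.viscosity
        eps = elec.relative_permittivity * VACUUM_PERMITTIVITY
        RT = GAS_CONSTANT * elec.temperature
        c0 = elec.species[0].concentration
        # Grahame relation for the wall zeta potential
        sigma_w = -5e-3
        zeta = 2 * RT / FARADAY * np.arcsinh(sigma_w / np.sqrt(8 * eps * RT * c0))
        zc = mesh.z_centers
        j1 = int(np.argmin(np.abs(zc + 160.0)))
        j2 = int(np.argmin(np.abs(zc + 40.0)))
        E = -(sol.psi[j2, 0] - sol.psi[j1, 0]) / ((zc[j2] - zc[j1]) * 1e-9)
        v_hs = -eps * zeta * E / eta
        jm = int(np.argmin(np.abs(zc + 100.0)))
        v_axis = 0.5 * (sol.v_z[jm, 0] + sol.v_z[jm + 1, 0])
        assert v_axis == pytest.approx(v_hs, rel=0.10)


class TestOrientationContrast:
    def test_vertical_flow_exceeds_horizontal(self, orientation_pair):
        geo, sols = orientation_pair
        z_mid = -0.5 * geo.slab_thickness_nm
        q_v = flow_rate(sols["vertical"], z_mid)
        q_h = flow_rate(sols["horizontal"], z_mid)
        assert q_v > 0 and q_h > 0
        assert q_v / q_h > 1.0

    def test_axial_velocity_dominates_pointwise_in_pore(self, orientation_pair):
        geo, sols = orientation_pair
        pv = axial_velocity_profile(sols["vertical"])
        ph = axial_velocity_profile(sols["horizontal"])
        # pore region: distance 2..32 nm below the sphere bottom
        m = (pv[:, 0] > 2.0) & (pv[:, 0] < geo.slab_thickness_nm)
        assert np.all(np.abs(pv[m, 1]) > np.abs(ph[m, 1]))

    def test_profile_decays_into_far_field(self, orientation_pair):
        geo, sols = orientation_pair
        prof = axial_velocity_profile(sols["vertical"])
        peak = np.max(np.abs(prof[:, 1]))
        far = np.abs(prof[np.argmax(prof[:, 0]), 1])  # trans boundary
        assert far < 0.10 * peak


class TestFieldProperties:
    # The strongly charged origami plug (Donnan concentration above the
    # 1 M bulk) behaves as a cation-selective membrane docked on one side
    # of the pore, so the I-V curve rectifies by concentration
    # polarization; the asymmetry scales linearly with V (quadratic
    # nonlinearity) and the Ohmic window is |V| <~ 10 mV.

    def test_antisymmetry_under_bias_reversal(self):
        _, sp = coarse_solve(OrigamiModel(orientation="vertical"), voltage=0.005)
        _, sm = coarse_solve(OrigamiModel(orientation="vertical"), voltage=-0.005)
        Ip, Im = ionic_current(sp, -40.0), ionic_current(sm, -40.0)
        Qp, Qm = flow_rate(sp, -40.0), flow_rate(sm, -40.0)
        assert Im == pytest.approx(-Ip, rel=0.05)
        assert Qm == pytest.approx(-Qp, rel=0.05)

    def test_low_bias_linearity(self):
        _, s1 = coarse_solve(OrigamiModel(orientation="vertical"), voltage=0.005)
        _, s2 = coarse_solve(OrigamiModel(orientation="vertical"), voltage=0.01)
        assert ionic_current(s2, -40.0) / ionic_current(s1, -40.0) == pytest.approx(2.0, rel=0.05)
        assert flow_rate(s2, -40.0) / flow_rate(s1, -40.0) == pytest.approx(2.0, rel=0.05)

    def test_flow_increases_with_fixed_charge(self):
        _, weak = coarse_solve(rho_f=-1e8)
        _, strong = coarse_solve(rho_f=-2e8)
        assert abs(flow_rate(strong, -40.0)) > abs(flow_rate(weak, -40.0))

    def test_concentrations_stay_positive(self, orientation_pair):
        _, sols = orientation_pair
        for sol in sols.values():
            for c in sol.concentrations.values():
                assert np.all(c >= 0)

    def test_nonconvergence_is_flagged_not_silent(self):
        geo = PoreGeometry()
        mesh = build_domain(geo, OrigamiModel(), fine_cell_nm=2.0)
        sol = solve_coupled(
            mesh, ElectrolyteSpec.kcl(1.0), 0.1,
            SolverOptions(tol=1e-12, max_outer=3),
        )
        assert not sol.converged
        assert len(sol.residual_history) == 3
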