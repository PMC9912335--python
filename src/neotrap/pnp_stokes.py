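"""Coupled Poisson–Nernst–Planck–Stokes–Brinkman solver on the axisymmetric mesh.

The steady fields are computed by a Gummel-style fixed-point iteration:

* Poisson with space charge from the mobile ions plus the smeared DNA
  charge, solved with a Newton inner loop in which the ion densities are
  damped by local Boltzmann factors (the classic Gummel stabilization);
* Nernst–Planck per species with Scharfetter–Gummel (exponentially fitted)
  face fluxes that combine diffusion, migration and advection and keep the
  concentrations positive;
* creeping-flow (Stokes) momentum with the electric body force of the
  *mobile* space charge and a Brinkman drag -eta kappa^-1 v inside the
  porous origami, discretized on a staggered (MAC) grid and solved as one
  sparse saddle-point system (factorized once per mesh).

The electric force deliberately excludes the fixed DNA charge: the DNA
skeleton is rigid and anchored, so the field's pull on the backbone charge
is transmitted to the solid, not the fluid.  The mobile counter-charge that
screens it (given by the Donnan equilibrium inside the porous sphere) is
what drags the water and drives the electro-osmotic flow.

Creeping flow (zero Reynolds number) replaces the full Navier–Stokes
momentum balance; in a ~10 nm pore at mm/s velocities Re ~ 1e-5, so the
inertial terms are negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import FARADAY, GAS_CONSTANT, NM, VACUUM_PERMITTIVITY
from .continuum_model import (
    AxiMesh,
    ElectrolyteSpec,
    MATERIAL_MEMBRANE,
    MATERIAL_ORIGAMI,
)

__all__ = [
    "SolverOptions",
    "FieldSolution",
    "solve_coupled",
    "ionic_current",
    "flow_rate",
    "axial_velocity_profile",
]


@dataclass(frozen=True)
class SolverOptions:
    """Nonlinear iteration controls for the coupled solve.

    ``tol`` is the maximum relative field update (all blocks) accepted as
    converged; ``relax_*`` are the per-block under-relaxation factors of the
    Gummel outer loop.
    """

    tol: float = 1e-6
    max_outer: int = 200
    relax_psi: float = 0.3
    relax_c: float = 0.3
    relax_v: float = 0.3
    newton_max: int = 12
    newton_tol: float = 1e-10  # volts
    verbose: bool = False

    def __post_init__(self) -> None:
        for name in ("relax_psi", "relax_c", "relax_v"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FieldSolution:
    """Converged (or flagged) steady fields on the axisymmetric mesh.

    Scalars live at cell centres, shape (nz, nr); ``v_r`` at radial faces
    (nz, nr+1) and ``v_z`` at axial faces (nz+1, nr).  ``species_flux_z``
    holds the molar flow (mol/s) of each species through every axial face,
    consistent with the finite-volume balance, so the ionic current is
    plane-independent to solver precision.
    """

    mesh: AxiMesh
    electrolyte: ElectrolyteSpec
    voltage: float
    pressure_drop: float
    psi: np.ndarray
    concentrations: dict[str, np.ndarray]
    v_r: np.ndarray
    v_z: np.ndarray
    pressure: np.ndarray
    converged: bool
    iterations: int
    residual_history: list[float] = field(default_factory=list)
    species_flux_z: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def mobile_charge_density(self) -> np.ndarray:
        rho = np.zeros_like(self.psi)
        for s in self.electrolyte.species:
            rho += s.valence * self.concentrations[s.name]
        return FARADAY * rho


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), stable near 0 and for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - 0.5 * x[small]
    xs = np.clip(x[~small], -500.0, 500.0)
    out[~small] = xs / np.expm1(xs)
    return out


class _Workspace:
    """Geometry, index maps and constant matrices for one mesh/electrolyte."""

    def __init__(self, mesh: AxiMesh, electrolyte: ElectrolyteSpec):
        self.mesh = mesh
        self.elec = electrolyte
        self.rf = mesh.r_faces * NM
        self.zf = mesh.z_faces * NM
        self.rc = 0.5 * (self.rf[:-1] + self.rf[1:])
        self.zc = 0.5 * (self.zf[:-1] + self.zf[1:])
        self.dr = np.diff(self.rf)
        self.dz = np.diff(self.zf)
        self.nr = mesh.nr
        self.nz = mesh.nz
        self.ring = np.pi * (self.rf[1:] ** 2 - self.rf[:-1] ** 2)  # axial face area
        self.vol = self.dz[:, None] * self.ring[None, :]
        self.fluid = mesh.material != MATERIAL_MEMBRANE
        self.VT = GAS_CONSTANT * electrolyte.temperature / FARADAY

        # permittivity with electrolyte value in fluid cells
        self.eps = np.where(self.fluid, electrolyte.relative_permittivity, mesh.eps_r)

        # effective diffusivity: bulk value scaled by porosity in the origami
        self.Deff = {}
        for s in electrolyte.species:
            D = np.full((self.nz, self.nr), s.diffusivity)
            D[mesh.material == MATERIAL_ORIGAMI] *= mesh.porosity[mesh.material == MATERIAL_ORIGAMI]
            self.Deff[s.name] = D

        with np.errstate(divide="ignore"):
            self.invkr = np.where(np.isfinite(mesh.kappa_rr), 1.0 / mesh.kappa_rr, 0.0)
            self.invkz = np.where(np.isfinite(mesh.kappa_zz), 1.0 / mesh.kappa_zz, 0.0)

        self._build_poisson()
        self._index_fluid()
        self._index_stokes()
        self._build_stokes()

    # ------------------------------------------------------------------ #
    # Poisson: unknowns at all cells, Dirichlet top/bottom, insulating sides
    # ------------------------------------------------------------------ #
    def _build_poisson(self) -> None:
        nr, nz = self.nr, self.nz
        n = nr * nz
        idx = np.arange(n).reshape(nz, nr)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        self.pois_bc_rows = []  # (cell index, conductance) for Dirichlet faces
        eps0 = VACUUM_PERMITTIVITY

        def add(a, b, g):
            rows.append(a)
            cols.append(b)
            vals.append(-g)

        # radial internal faces
        for i in range(1, nr):
            d = self.rc[i] - self.rc[i - 1]
            area = 2.0 * np.pi * self.rf[i] * self.dz
            epsf = 2.0 * self.eps[:, i - 1] * self.eps[:, i] / (self.eps[:, i - 1] + self.eps[:, i])
            g = eps0 * epsf * area / d
            a = idx[:, i - 1]
            b = idx[:, i]
            for j in range(nz):
                add(a[j], b[j], g[j])
                add(b[j], a[j], g[j])
                diag[a[j]] += g[j]
                diag[b[j]] += g[j]
        # axial internal faces
        for j in range(1, nz):
            d = self.zc[j] - self.zc[j - 1]
            epsf = 2.0 * self.eps[j - 1] * self.eps[j] / (self.eps[j - 1] + self.eps[j])
            g = eps0 * epsf * self.ring / d
            a = idx[j - 1]
            b = idx[j]
            for i in range(nr):
                add(a[i], b[i], g[i])
                add(b[i], a[i], g[i])
                diag[a[i]] += g[i]
                diag[b[i]] += g[i]
        # Dirichlet at bottom (trans, +V/2) and top (cis, -V/2)
        d0 = self.zc[0] - self.zf[0]
        g0 = eps0 * self.eps[0] * self.ring / d0
        d1 = self.zf[-1] - self.zc[-1]
        g1 = eps0 * self.eps[-1] * self.ring / d1
        for i in range(nr):
            diag[idx[0, i]] += g0[i]
            self.pois_bc_rows.append(("bot", idx[0, i], g0[i]))
            diag[idx[-1, i]] += g1[i]
            self.pois_bc_rows.append(("top", idx[-1, i], g1[i]))

        rows += list(range(n))
        cols += list(range(n))
        vals += list(diag)
        self.A_pois = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        self.pois_idx = idx

    def poisson_rhs_bc(self, v_bot: float, v_top: float) -> np.ndarray:
        b = np.zeros(self.nr * self.nz)
        for side, row, g in self.pois_bc_rows:
            b[row] += g * (v_bot if side == "bot" else v_top)
        return b

    # ------------------------------------------------------------------ #
    def _index_fluid(self) -> None:
        self.fid = -np.ones((self.nz, self.nr), dtype=int)
        jj, ii = np.nonzero(self.fluid)
        self.fid[jj, ii] = np.arange(len(jj))
        self.n_fluid = len(jj)
        self.fluid_j = jj
        self.fluid_i = ii

    # ------------------------------------------------------------------ #
    # Stokes–Brinkman saddle system (constant matrix, factorized once)
    # ------------------------------------------------------------------ #
    def _index_stokes(self) -> None:
        nr, nz = self.nr, self.nz
        fluid = self.fluid
        self.iu_r = -np.ones((nz, nr + 1), dtype=int)
        k = 0
        for j in range(nz):
            for i in range(1, nr):
                if fluid[j, i - 1] and fluid[j, i]:
                    self.iu_r[j, i] = k
                    k += 1
        self.n_vr = k
        self.iu_z = -np.ones((nz + 1, nr), dtype=int)
        for j in range(nz + 1):
            for i in range(nr):
                if j == 0:
                    ok = fluid[0, i]
                elif j == nz:
                    ok = fluid[nz - 1, i]
                else:
                    ok = fluid[j - 1, i] and fluid[j, i]
                if ok:
                    self.iu_z[j, i] = k
                    k += 1
        self.n_vz = k - self.n_vr
        self.ip = -np.ones((nz, nr), dtype=int)
        for j in range(nz):
            for i in range(nr):
                if fluid[j, i]:
                    self.ip[j, i] = k
                    k += 1
        self.n_stokes = k

    def _build_stokes(self) -> None:
        nr, nz = self.nr, self.nz
        eta = self.elec.viscosity
        rf, rc, zf, zc = self.rf, self.rc, self.zf, self.zc
        dr, dz = self.dr, self.dz
        rows, cols, vals = [], [], []
        # ghost-pressure coupling of open-boundary v_z faces, for the
        # pressure-driven (Poiseuille) right-hand side
        self.pghost = []  # (row, side, 1/dz)

        def add(r, c, v):
            if c >= 0:
                rows.append(r)
                cols.append(c)
                vals.append(v)

        # ---- radial momentum ------------------------------------------------
        for j in range(nz):
            for i in range(1, nr):
                row = self.iu_r[j, i]
                if row < 0:
                    continue
                dcr = rc[i] - rc[i - 1]
                # T1 = d/dr[(1/r) d(r v)/dr]
                cGi = 1.0 / (dr[i] * rc[i] * dcr)
                cGm = 1.0 / (dr[i - 1] * rc[i - 1] * dcr)
                add(row, self.iu_r[j, i + 1] if i + 1 <= nr else -1, eta * rf[i + 1] * cGi)
                add(row, row, -eta * rf[i] * (cGi + cGm))
                add(row, self.iu_r[j, i - 1] if i - 1 >= 0 else -1, eta * rf[i - 1] * cGm)
                # T2 = d2v/dz2 with half-cell wall ghosts
                zm = zp = None
                km = kp = -1
                if j > 0:
                    if self.iu_r[j - 1, i] >= 0:
                        km, zm = self.iu_r[j - 1, i], zc[j - 1]
                    else:
                        km, zm = -1, zf[j]  # wall at the face below
                if j < nz - 1:
                    if self.iu_r[j + 1, i] >= 0:
                        kp, zp = self.iu_r[j + 1, i], zc[j + 1]
                    else:
                        kp, zp = -1, zf[j + 1]
                z0 = zc[j]
                if zm is None and zp is None:
                    pass
                else:
                    dm = z0 - zm if zm is not None else (zp - z0)
                    dp = zp - z0 if zp is not None else (z0 - zm)
                    cm = 2.0 / (dm * (dm + dp))
                    cp = 2.0 / (dp * (dm + dp))
                    if zm is not None:
                        add(row, km, eta * cm)
                        add(row, row, -eta * cm)
                    if zp is not None:
                        add(row, kp, eta * cp)
                        add(row, row, -eta * cp)
                # Brinkman
                ik = 0.5 * (self.invkr[j, i - 1] + self.invkr[j, i])
                if ik:
                    add(row, row, -eta * ik)
                # pressure gradient
                add(row, self.ip[j, i], -1.0 / dcr)
                add(row, self.ip[j, i - 1], +1.0 / dcr)

        # ---- axial momentum -------------------------------------------------
        for j in range(nz + 1):
            for i in range(nr):
                row = self.iu_z[j, i]
                if row < 0:
                    continue
                As = 0.5 * (rf[i + 1] ** 2 - rf[i] ** 2)
                # T1 = (1/r) d/dr (r dv/dr)
                if i > 0:
                    if self.iu_z[j, i - 1] >= 0:
                        dn = rc[i] - rc[i - 1]
                        add(row, self.iu_z[j, i - 1], eta * rf[i] / (dn * As))
                        add(row, row, -eta * rf[i] / (dn * As))
                    else:  # wall at rf[i]
                        dn = rc[i] - rf[i]
                        add(row, row, -eta * rf[i] / (dn * As))
                if i < nr - 1:
                    if self.iu_z[j, i + 1] >= 0:
                        dn = rc[i + 1] - rc[i]
                        add(row, self.iu_z[j, i + 1], eta * rf[i + 1] / (dn * As))
                        add(row, row, -eta * rf[i + 1] / (dn * As))
                    else:  # wall at rf[i+1]
                        dn = rf[i + 1] - rc[i]
                        add(row, row, -eta * rf[i + 1] / (dn * As))
                # free-slip at the outer radial boundary: H = 0, nothing to add
                if 1 <= j <= nz - 1:
                    dm = zf[j] - zf[j - 1]
                    dp = zf[j + 1] - zf[j]
                    cm = 2.0 / (dm * (dm + dp))
                    cp = 2.0 / (dp * (dm + dp))
                    add(row, self.iu_z[j - 1, i] if self.iu_z[j - 1, i] >= 0 else -1, eta * cm)
                    add(row, row, -eta * cm)
                    add(row, self.iu_z[j + 1, i] if self.iu_z[j + 1, i] >= 0 else -1, eta * cp)
                    add(row, row, -eta * cp)
                    ik = 0.5 * (self.invkz[j - 1, i] + self.invkz[j, i])
                    if ik:
                        add(row, row, -eta * ik)
                    dcz = zc[j] - zc[j - 1]
                    add(row, self.ip[j, i], -1.0 / dcz)
                    add(row, self.ip[j - 1, i], +1.0 / dcz)
                elif j == 0:  # open bottom: ghost p, one-sided viscous
                    d = zf[1] - zf[0]
                    add(row, self.iu_z[1, i] if self.iu_z[1, i] >= 0 else -1, eta / (d * d))
                    add(row, row, -eta / (d * d))
                    add(row, self.ip[0, i], -1.0 / dz[0])
                    self.pghost.append((row, "bot", 1.0 / dz[0]))
                else:  # open top
                    d = zf[nz] - zf[nz - 1]
                    add(row, self.iu_z[nz - 1, i] if self.iu_z[nz - 1, i] >= 0 else -1, eta / (d * d))
                    add(row, row, -eta / (d * d))
                    add(row, self.ip[nz - 1, i], +1.0 / dz[nz - 1])
                    self.pghost.append((row, "top", 1.0 / dz[nz - 1]))

        # ---- continuity -----------------------------------------------------
        for j in range(nz):
            for i in range(nr):
                row = self.ip[j, i]
                if row < 0:
                    continue
                As = 0.5 * (rf[i + 1] ** 2 - rf[i] ** 2)
                add(row, self.iu_r[j, i + 1] if i + 1 <= nr else -1, rf[i + 1] * dz[j])
                add(row, self.iu_r[j, i], -rf[i] * dz[j])
                add(row, self.iu_z[j + 1, i], As)
                add(row, self.iu_z[j, i], -As)

        A = sp.csr_matrix((vals, (rows, cols)), shape=(self.n_stokes, self.n_stokes))
        # row/column equilibration before factorization: momentum and
        # continuity rows differ by many orders of magnitude in scale
        rmax = np.maximum(np.abs(A).max(axis=1).toarray().ravel(), 1e-300)
        self.Rscale = 1.0 / rmax
        A = sp.diags(self.Rscale) @ A
        cmax = np.maximum(np.abs(A).max(axis=0).toarray().ravel(), 1e-300)
        self.Cscale = 1.0 / cmax
        A = A @ sp.diags(self.Cscale)
        self.stokes_lu = spla.splu(A.tocsc())

    @staticmethod
    def _logmean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Logarithmic mean (b - a)/ln(b/a), arithmetic mean in the limit."""
        a = np.maximum(a, 0.0)
        b = np.maximum(b, 0.0)
        close = np.abs(b - a) <= 1e-10 * np.maximum(a, b)
        denom = np.log(np.where(close | (a <= 0) | (b <= 0), 1.0, b / np.maximum(a, 1e-300)))
        out = np.where(close | (denom == 0), 0.5 * (a + b), (b - a) / np.where(denom == 0, 1.0, denom))
        return out

    def _face_charge(self, conc: dict[str, np.ndarray], sl_a, sl_b) -> np.ndarray:
        """Effective mobile charge density at faces between cell slices a, b.

        Uses the per-species logarithmic mean, which makes the discrete
        body force an exact gradient of the osmotic pressure RT sum c_i at
        Boltzmann equilibrium — so the pressure field can balance it and no
        spurious equilibrium flow is generated at the (underresolved)
        Donnan interfaces of the charged sphere.
        """
        rho = 0.0
        for s in self.elec.species:
            c = conc[s.name]
            rho = rho + s.valence * self._logmean(c[sl_a], c[sl_b])
        return FARADAY * rho

    def solve_stokes(self, conc: dict[str, np.ndarray], psi: np.ndarray,
                     v_bot_psi: float, v_top_psi: float,
                     pressure_drop: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nr, nz = self.nr, self.nz
        rc, zc, zf = self.rc, self.zc, self.zf
        b = np.zeros(self.n_stokes)
        # body force: mobile space charge only (see module docstring),
        # log-mean face densities for discrete equilibrium consistency
        mask = self.iu_r[:, 1:-1] >= 0
        dcr = (rc[1:] - rc[:-1])[None, :]
        rho_f = self._face_charge(conc, (slice(None), slice(None, -1)), (slice(None), slice(1, None)))
        fr = -rho_f * (psi[:, 1:] - psi[:, :-1]) / dcr
        b[self.iu_r[:, 1:-1][mask]] = -fr[mask]

        mask = self.iu_z[1:-1, :] >= 0
        dcz = (zc[1:] - zc[:-1])[:, None]
        rho_f = self._face_charge(conc, (slice(None, -1), slice(None)), (slice(1, None), slice(None)))
        fz = -rho_f * (psi[1:] - psi[:-1]) / dcz
        b[self.iu_z[1:-1][mask]] = -fz[mask]

        bulk = {s.name: np.full(nr, s.concentration) for s in self.elec.species}
        m0 = self.iu_z[0] >= 0
        rho0 = 0.0
        rho1 = 0.0
        for s in self.elec.species:
            rho0 = rho0 + s.valence * self._logmean(bulk[s.name], conc[s.name][0])
            rho1 = rho1 + s.valence * self._logmean(conc[s.name][nz - 1], bulk[s.name])
        fz0 = -FARADAY * rho0 * (psi[0] - v_bot_psi) / (zc[0] - zf[0])
        b[self.iu_z[0][m0]] = -fz0[m0]
        m1 = self.iu_z[nz] >= 0
        fz1 = -FARADAY * rho1 * (v_top_psi - psi[nz - 1]) / (zf[nz] - zc[nz - 1])
        b[self.iu_z[nz][m1]] = -fz1[m1]

        # open-boundary ghost pressures +-dp/2: at the bottom the ghost
        # constant enters as +pg_b/dz with pg_b = +dp/2, at the top as
        # -pg_t/dz with pg_t = -dp/2 — the same RHS contribution either way
        for row, _side, inv_d in self.pghost:
            b[row] -= 0.5 * pressure_drop * inv_d
        x = self.Cscale * self.stokes_lu.solve(self.Rscale * b)
        vr = np.zeros((nz, nr + 1))
        vz = np.zeros((nz + 1, nr))
        p = np.zeros((nz, nr))
        m = self.iu_r >= 0
        vr[m] = x[self.iu_r[m]]
        m = self.iu_z >= 0
        vz[m] = x[self.iu_z[m]]
        m = self.ip >= 0
        p[m] = x[self.ip[m]]
        return vr, vz, p

    # ------------------------------------------------------------------ #
    # Nernst–Planck: Scharfetter–Gummel faces, one sparse solve per species
    # ------------------------------------------------------------------ #
    def _np_terms(self, species, psi, vr, vz, v_bot_psi, v_top_psi):
        """Vectorized SG face coefficients for one species.

        Returns (rA, rB, coef_a, coef_b) for internal faces (flux a->b =
        coef_a*c_a - coef_b*c_b, a upstream in +r/+z) plus the axial-face
        bookkeeping (zj, zi arrays into the (nz+1, nr) face grid, and a
        mask of which internal tuples are axial), and boundary arrays
        (cells, coef_cell, coef_bulk, face row index 0 or nz).
        """
        z = species.valence
        D = self.Deff[species.name]
        VT = self.VT
        nr, nz = self.nr, self.nz
        fid = self.fid
        psi_d = psi

        # radial internal faces (i = 1..nr-1)
        valid_r = self.fluid[:, :-1] & self.fluid[:, 1:]
        d_r = (self.rc[1:] - self.rc[:-1])[None, :]
        area_r = 2.0 * np.pi * self.rf[1:-1][None, :] * self.dz[:, None]
        Df_r = 2.0 * D[:, :-1] * D[:, 1:] / (D[:, :-1] + D[:, 1:])
        P_r = vr[:, 1:-1] * d_r / Df_r - z * (psi_d[:, 1:] - psi_d[:, :-1]) / VT
        g_r = area_r * Df_r / d_r
        ca_r = g_r * _bernoulli(-P_r)
        cb_r = g_r * _bernoulli(P_r)

        # axial internal faces (j = 1..nz-1)
        valid_z = self.fluid[:-1, :] & self.fluid[1:, :]
        d_z = (self.zc[1:] - self.zc[:-1])[:, None]
        Df_z = 2.0 * D[:-1, :] * D[1:, :] / (D[:-1, :] + D[1:, :])
        P_z = vz[1:-1, :] * d_z / Df_z - z * (psi_d[1:, :] - psi_d[:-1, :]) / VT
        g_z = self.ring[None, :] * Df_z / d_z
        ca_z = g_z * _bernoulli(-P_z)
        cb_z = g_z * _bernoulli(P_z)

        jr, ir = np.nonzero(valid_r)
        jz, iz = np.nonzero(valid_z)
        rA = np.concatenate([fid[jr, ir], fid[jz, iz]])
        rB = np.concatenate([fid[jr, ir + 1], fid[jz + 1, iz]])
        coef_a = np.concatenate([ca_r[jr, ir], ca_z[jz, iz]])
        coef_b = np.concatenate([cb_r[jr, ir], cb_z[jz, iz]])
        n_radial = len(jr)
        zface_j = jz + 1
        zface_i = iz

        # Dirichlet reservoir boundaries (bottom face row 0, top face row nz)
        bnd = []
        bot = self.fluid[0]
        d0 = self.zc[0] - self.zf[0]
        P0 = -vz[0, bot] * d0 / D[0, bot] - z * (v_bot_psi - psi_d[0, bot]) / VT
        g0 = self.ring[bot] * D[0, bot] / d0
        bnd.append((fid[0, bot], g0 * _bernoulli(-P0), g0 * _bernoulli(P0), 0, np.nonzero(bot)[0]))
        top = self.fluid[-1]
        d1 = self.zf[-1] - self.zc[-1]
        P1 = vz[-1, top] * d1 / D[-1, top] - z * (v_top_psi - psi_d[-1, top]) / VT
        g1 = self.ring[top] * D[-1, top] / d1
        bnd.append((fid[-1, top], g1 * _bernoulli(-P1), g1 * _bernoulli(P1), nz, np.nonzero(top)[0]))

        return rA, rB, coef_a, coef_b, n_radial, zface_j, zface_i, bnd

    def solve_np(self, species, psi, vr, vz, v_bot_psi, v_top_psi) -> np.ndarray:
        n = self.n_fluid
        rA, rB, ca, cb, _, _, _, bnd = self._np_terms(species, psi, vr, vz, v_bot_psi, v_top_psi)
        rows = np.concatenate([rA, rA, rB, rB])
        cols = np.concatenate([rA, rB, rB, rA])
        vals = np.concatenate([ca, -cb, cb, -ca])
        rhs = np.zeros(n)
        diag_rows, diag_vals = [], []
        for cells, cc, cbulk_coef, _, _ in bnd:
            diag_rows.append(cells)
            diag_vals.append(cc)
            rhs[cells] += cbulk_coef * species.concentration
        rows = np.concatenate([rows] + diag_rows)
        cols = np.concatenate([cols] + diag_rows)
        vals = np.concatenate([vals] + diag_vals)
        A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        sol = spla.spsolve(A, rhs)
        c = np.zeros((self.nz, self.nr))
        c[self.fluid_j, self.fluid_i] = sol
        return c

    def species_flux_z(self, species, c, psi, vr, vz, v_bot_psi, v_top_psi) -> np.ndarray:
        """Molar flow (mol/s, positive along +z) through every axial face."""
        flux = np.zeros((self.nz + 1, self.nr))
        rA, rB, ca, cb, n_rad, zj, zi, bnd = self._np_terms(
            species, psi, vr, vz, v_bot_psi, v_top_psi
        )
        cflat = c[self.fluid_j, self.fluid_i]
        ax = slice(n_rad, None)
        flux[zj, zi] = ca[ax] * cflat[rA[ax]] - cb[ax] * cflat[rB[ax]]
        for cells, cc, cbulk_coef, jrow, icols in bnd:
            out = cc * cflat[cells] - cbulk_coef * species.concentration
            flux[jrow, icols] = -out if jrow == 0 else out
        return flux

    # ------------------------------------------------------------------ #
    def poisson_gummel(self, psi, conc, v_bot, v_top, opts) -> np.ndarray:
        """Newton solve of Poisson with Boltzmann-damped ion densities."""
        n = self.nr * self.nz
        b_bc = self.poisson_rhs_bc(v_bot, v_top)
        fixed = (self.mesh.fixed_charge + self.mesh.surface_charge) * self.vol
        psi_ref = psi.copy()
        psi_k = psi.copy()
        VT = self.VT
        for _ in range(opts.newton_max):
            # rho(psi) with Boltzmann-damped densities; d(rho)/d(psi) =
            # -F sum z^2 c_eff / VT is always negative, so the Jacobian
            # A - diag(drho * vol) stays positive definite
            rho_m = np.zeros((self.nz, self.nr))
            drho = np.zeros((self.nz, self.nr))
            for s in self.elec.species:
                arg = np.clip(-s.valence * (psi_k - psi_ref) / VT, -50.0, 50.0)
                ceff = conc[s.name] * np.exp(arg)
                rho_m += s.valence * ceff
                drho += FARADAY * s.valence**2 * ceff / VT
            rho_m *= FARADAY
            b = b_bc + (rho_m * self.vol).ravel() + fixed.ravel()
            resid = self.A_pois @ psi_k.ravel() - b
            J = self.A_pois + sp.diags((drho * self.vol).ravel())
            dpsi = spla.spsolve(J.tocsc(), -resid)
            psi_k = psi_k + dpsi.reshape(self.nz, self.nr)
            if np.max(np.abs(dpsi)) < opts.newton_tol:
                break
        return psi_k


def solve_coupled(
    mesh: AxiMesh,
    electrolyte: ElectrolyteSpec,
    voltage: float,
    opts: SolverOptions | None = None,
    pressure_drop: float = 0.0,
) -> FieldSolution:
    """Self-consistent PNP–Stokes–Brinkman solve at applied bias ``voltage``.

    The trans (bottom) reservoir boundary is held at +voltage/2 and the cis
    (top) boundary at -voltage/2, with bulk concentrations on both; walls
    are no-slip and ion-blocking.  ``pressure_drop`` (Pa, bottom minus top
    ghost pressure) drives an optional Poiseuille component for validation
    runs.  Returns a flagged, diagnostic-carrying solution on
    non-convergence rather than raising.
    """
    if abs(voltage) > 1.0:
        raise ValueError("bias voltage outside the +-1 V validity range")
    opts = opts or SolverOptions()
    ws = _Workspace(mesh, electrolyte)
    v_bot, v_top = +0.5 * voltage, -0.5 * voltage

    conc = {s.name: np.where(ws.fluid, s.concentration, 0.0) for s in electrolyte.species}
    psi = np.zeros((ws.nz, ws.nr))
    vr = np.zeros((ws.nz, ws.nr + 1))
    vz = np.zeros((ws.nz + 1, ws.nr))
    p = np.zeros((ws.nz, ws.nr))

    history: list[float] = []
    converged = False
    it = 0
    c_scale = max(s.concentration for s in electrolyte.species)
    for it in range(1, opts.max_outer + 1):
        psi_new = ws.poisson_gummel(psi, conc, v_bot, v_top, opts)
        res_psi = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi_new)), ws.VT)
        psi = psi + opts.relax_psi * (psi_new - psi)

        res_c = 0.0
        for s in electrolyte.species:
            c_new = ws.solve_np(s, psi, vr, vz, v_bot, v_top)
            res_c = max(res_c, np.max(np.abs(c_new - conc[s.name])) / c_scale)
            conc[s.name] = conc[s.name] + opts.relax_c * (c_new - conc[s.name])

        vr_new, vz_new, p_new = ws.solve_stokes(conc, psi, v_bot, v_top, pressure_drop)
        # floor the velocity scale at 1 pm/s: configurations with no
        # electro-osmotic driving produce only roundoff-level velocities,
        # which must not be amplified into a fake residual
        v_mag = max(np.max(np.abs(vr_new)), np.max(np.abs(vz_new)), 1e-12)
        res_v = max(np.max(np.abs(vr_new - vr)), np.max(np.abs(vz_new - vz))) / v_mag
        vr = vr + opts.relax_v * (vr_new - vr)
        vz = vz + opts.relax_v * (vz_new - vz)
        p = p + opts.relax_v * (p_new - p)

        res = max(res_psi, res_c, res_v)
        history.append(res)
        if opts.verbose:
            print(f"outer {it:3d}: res_psi={res_psi:.3e} res_c={res_c:.3e} res_v={res_v:.3e}")
        if res < opts.tol:
            converged = True
            break
        # v solves a *linear* system in (psi, c); in near-neutral regions its
        # force F(c+ - c-) amplifies concentration roundoff ~1e4-fold, so the
        # velocity update can floor at ~1e-5 relative while psi and c sit at
        # machine precision.  Once the Stokes inputs are two decades below
        # tol, v is as converged as double precision permits.
        if max(res_psi, res_c) < 0.01 * opts.tol:
            converged = True
            break

    # final consistency pass: exact finite-volume species balances on the
    # final (psi, v) fields, so face fluxes conserve to solver precision
    flux_z: dict[str, np.ndarray] = {}
    for s in electrolyte.species:
        conc[s.name] = ws.solve_np(s, psi, vr, vz, v_bot, v_top)
        flux_z[s.name] = ws.species_flux_z(s, conc[s.name], psi, vr, vz, v_bot, v_top)

    return FieldSolution(
        mesh=mesh,
        electrolyte=electrolyte,
        voltage=voltage,
        pressure_drop=pressure_drop,
        psi=psi,
        concentrations=conc,
        v_r=vr,
        v_z=vz,
        pressure=p,
        converged=converged,
        iterations=it,
        residual_history=history,
        species_flux_z=flux_z,
    )


def _zface_index(mesh: AxiMesh, z_plane_nm: float) -> int:
    zf = mesh.z_faces
    if not (zf[0] <= z_plane_nm <= zf[-1]):
        raise ValueError(f"plane z={z_plane_nm} nm outside the domain [{zf[0]}, {zf[-1]}]")
    return int(np.argmin(np.abs(zf - z_plane_nm)))


def ionic_current(sol: FieldSolution, z_plane_nm: float) -> float:
    """Ionic current (A) through the axial plane nearest ``z_plane_nm``.

    I = F * sum_i z_i * (molar flow of species i through the plane); by
    construction of the finite-volume balance the value is independent of
    the chosen plane to solver precision.
    """
    jf = _zface_index(sol.mesh, z_plane_nm)
    total = 0.0
    for s in sol.electrolyte.species:
        total += s.valence * sol.species_flux_z[s.name][jf].sum()
    return float(FARADAY * total)


def flow_rate(sol: FieldSolution, z_plane_nm: float) -> float:
    """Volumetric flow rate Q (m^3/s, positive toward cis) through a plane."""
    jf = _zface_index(sol.mesh, z_plane_nm)
    rf = sol.mesh.r_faces * NM
    ring = np.pi * (rf[1:] ** 2 - rf[:-1] ** 2)
    return float((sol.v_z[jf] * ring).sum())


def axial_velocity_profile(sol: FieldSolution) -> np.ndarray:
    """(distance_nm, v_z m/s) along the pore axis.

    Distance is measured from the bottom of the origami sphere (the cis
    membrane face if no sphere is docked) pointing downward through the
    pore into the trans reservoir.
    """
    origami = sol.mesh.origami
    z_bottom = -origami.protrusion_nm if origami is not None else 0.0
    dist = z_bottom - sol.mesh.z_faces
    v_axis = sol.v_z[:, 0]
    order = np.argsort(dist)
    return np.column_stack([dist[order], v_axis[order]])
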