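"""Geometry, electrolyte and origami material models for the axisymmetric domain.

The computational domain is an axisymmetric r–z slice of a solid-state
nanopore in a membrane slab, with an optional porous DNA-origami sphere
docked over the pore mouth on the cis side.  The origami is homogenized as
a Brinkman medium: an anisotropic permeability tensor (easy flow along the
honeycomb nanochannels, hindered flow across the helix lattice) plus a
smeared fixed charge density representing the DNA backbone charge.

Coordinates: the z axis is the pore axis, z = 0 at the cis face of the
membrane slab where the sphere docks, positive z pointing from trans to
cis (toward the sphere).  All mesh coordinates are stored in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    NM,
    VACUUM_PERMITTIVITY,
)

__all__ = [
    "ConfigurationError",
    "IonSpecies",
    "ElectrolyteSpec",
    "PoreGeometry",
    "OrigamiModel",
    "AxiMesh",
    "MATERIAL_FLUID",
    "MATERIAL_MEMBRANE",
    "MATERIAL_ORIGAMI",
    "debye_length",
    "permeability_from_channels",
    "build_domain",
    "cells_per_debye",
]

MATERIAL_FLUID = 0
MATERIAL_MEMBRANE = 1
MATERIAL_ORIGAMI = 2

# Gebart's constants for transverse flow through a hexagonal fibre array
_GEBART_C_HEX = 16.0 / (9.0 * np.pi * np.sqrt(6.0))
_GEBART_VF_MAX_HEX = np.pi / (2.0 * np.sqrt(3.0))

# B-DNA helix radius used by the transverse (flow-past-rods) permeability model
DNA_ROD_RADIUS_NM = 1.0


class ConfigurationError(ValueError):
    """Raised for degenerate or inconsistent geometry/material configuration."""


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species: integer valence, diffusivity (m^2/s), bulk conc (mol/m^3)."""

    name: str
    valence: int
    diffusivity: float
    concentration: float

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ConfigurationError(f"diffusivity of {self.name} must be positive")
        if self.concentration <= 0:
            raise ConfigurationError(f"concentration of {self.name} must be positive")
        if int(self.valence) != self.valence or self.valence == 0:
            raise ConfigurationError(f"valence of {self.name} must be a nonzero integer")


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Electrolyte composition and solvent properties.

    Parameters
    ----------
    species
        Ionic species; the bulk composition must be electroneutral.
    relative_permittivity
        Solvent relative permittivity (water ~78.4 at 25 C).
    viscosity
        Dynamic viscosity eta in Pa s.
    temperature
        Absolute temperature in K.
    """

    species: tuple[IonSpecies, ...]
    relative_permittivity: float = 78.4
    viscosity: float = 1.0e-3
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigurationError("electrolyte needs at least one ionic species")
        if self.relative_permittivity <= 0 or self.viscosity <= 0 or self.temperature <= 0:
            raise ConfigurationError("permittivity, viscosity and temperature must be positive")
        net = sum(s.valence * s.concentration for s in self.species)
        scale = sum(abs(s.valence) * s.concentration for s in self.species)
        if abs(net) > 1e-9 * scale:
            raise ConfigurationError(f"bulk electrolyte is not electroneutral (sum z_i c_i = {net:g})")

    @classmethod
    def kcl(cls, molar: float = 1.0, **kwargs) -> "ElectrolyteSpec":
        """Aqueous KCl at the given molarity (mol/L)."""
        c = 1000.0 * molar  # mol/m^3
        return cls(
            species=(
                IonSpecies("K+", +1, 1.96e-9, c),
                IonSpecies("Cl-", -1, 2.03e-9, c),
            ),
            **kwargs,
        )

    @property
    def ionic_strength(self) -> float:
        """Sum z_i^2 c_i in mol/m^3 (twice the conventional ionic strength)."""
        return sum(s.valence**2 * s.concentration for s in self.species)

    @property
    def conductivity(self) -> float:
        """Ideal (Nernst–Einstein) bulk conductivity in S/m."""
        from .constants import FARADAY, GAS_CONSTANT

        return sum(
            FARADAY**2 * s.valence**2 * s.diffusivity * s.concentration
            for s in self.species
        ) / (GAS_CONSTANT * self.temperature)


def debye_length(electrolyte: ElectrolyteSpec) -> float:
    """Debye screening length in nanometres.

    lambda_D = sqrt(eps eps0 kB T / (e^2 N_A sum z_i^2 c_i)).
    """
    s = electrolyte.ionic_strength
    if s <= 0:
        raise ConfigurationError("zero ionic strength")
    lam = np.sqrt(
        electrolyte.relative_permittivity
        * VACUUM_PERMITTIVITY
        * BOLTZMANN
        * electrolyte.temperature
        / (ELEMENTARY_CHARGE**2 * AVOGADRO * s)
    )
    return float(lam / NM)


@dataclass(frozen=True)
class PoreGeometry:
    """Axisymmetric pore/membrane/reservoir geometry (lengths in nm).

    ``pore_radius_nm`` is the bare (pre-coating) SiN pore radius; the lipid
    coat of thickness ``lipid_thickness_nm`` lines the membrane faces and the
    pore wall, so the effective (fluidic) pore radius is
    ``pore_radius_nm - lipid_thickness_nm`` and the solid slab thickness is
    ``membrane_thickness_nm + 2 * lipid_thickness_nm``.
    """

    pore_radius_nm: float = 10.0
    membrane_thickness_nm: float = 20.0
    lipid_thickness_nm: float = 5.0
    reservoir_radius_nm: float = 120.0
    reservoir_height_nm: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "pore_radius_nm",
            "membrane_thickness_nm",
            "reservoir_radius_nm",
            "reservoir_height_nm",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.lipid_thickness_nm < 0:
            raise ConfigurationError("lipid_thickness_nm must be non-negative")
        if self.effective_pore_radius_nm <= 0:
            raise ConfigurationError("effective pore diameter must be positive after lipid coating")
        if self.pore_radius_nm >= self.reservoir_radius_nm:
            raise ConfigurationError("pore radius must be smaller than the reservoir radius")

    @property
    def effective_pore_radius_nm(self) -> float:
        return self.pore_radius_nm - self.lipid_thickness_nm

    @property
    def slab_thickness_nm(self) -> float:
        return self.membrane_thickness_nm + 2.0 * self.lipid_thickness_nm


def permeability_from_channels(
    channel_diameter_nm: float,
    porosity: float,
    rod_radius_nm: float = DNA_ROD_RADIUS_NM,
) -> tuple[float, float]:
    """Anisotropic origami permeability (kappa_par, kappa_perp) in m^2.

    Along the nanochannels a parallel-capillary-bundle model gives
    ``kappa_par = porosity * d_c^2 / 32``.  Across the helix lattice,
    Gebart's transverse-permeability formula for a hexagonal array of rigid
    rods is used, clamped to zero at the close-packing limit.  The transverse
    value is additionally capped at ``kappa_par / 2``: flow along open
    channels is always easier than flow squeezing between rods, and the
    dilute-limit rod formula would otherwise cross over at high porosity.
    """
    if not (0.0 < porosity < 1.0):
        raise ConfigurationError("porosity must lie strictly between 0 and 1")
    if channel_diameter_nm <= 0:
        raise ConfigurationError("channel diameter must be positive")
    d = channel_diameter_nm * NM
    kappa_par = porosity * d * d / 32.0

    vf = 1.0 - porosity  # rod (DNA) volume fraction
    a = rod_radius_nm * NM
    if vf >= _GEBART_VF_MAX_HEX:
        kappa_perp = 0.0
    else:
        kappa_perp = _GEBART_C_HEX * (np.sqrt(_GEBART_VF_MAX_HEX / vf) - 1.0) ** 2.5 * a * a
    kappa_perp = min(kappa_perp, 0.5 * kappa_par)
    if kappa_perp <= 0.0:
        # strictly positive per the material contract; floor far below kappa_par
        kappa_perp = 1e-6 * kappa_par
    return float(kappa_par), float(kappa_perp)


@dataclass(frozen=True)
class OrigamiModel:
    """Porous-sphere model of the docked DNA-origami.

    Parameters
    ----------
    radius_nm
        Sphere radius (default 20 nm, i.e. a 40 nm origami sphere).
    orientation
        'vertical' (nanochannels along the pore axis) or 'horizontal'
        (nanochannels in the membrane plane).
    porosity
        Void (nanochannel) volume fraction of the helix lattice; the DNA
        volume fraction is ``1 - porosity``.
    channel_diameter_nm
        Nanochannel diameter of the honeycomb lattice (1–2 nm).
    fixed_charge_density
        Smeared DNA charge in C/m^3 (negative).  If None, computed from two
        elementary charges per 0.34 nm of helix rise smeared over the helix
        cross-section, weighted by the DNA volume fraction.
    kappa_par / kappa_perp
        Permeability along / across the channels (m^2).  If None, derived
        from the capillary-bundle and flow-past-rods models.
    """

    radius_nm: float = 20.0
    orientation: Literal["vertical", "horizontal"] = "vertical"
    porosity: float = 0.3
    channel_diameter_nm: float = 1.5
    fixed_charge_density: float | None = None
    kappa_par: float | None = None
    kappa_perp: float | None = None
    # Seating depth of the docked sphere below the cis face.  A perfectly
    # tangent rigid sphere touches the flat membrane at a single point,
    # leaving an unsealed wedge that short-circuits the pore hydraulically;
    # a docked origami pressed on by the electrophoretic force seats into
    # the pore mouth (its central helix tips reach into the pore, which is
    # also what the deeper docked blockade indicates).  2 nm closes the
    # contact line and makes the flow solution mesh-stable.
    protrusion_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ConfigurationError("origami radius must be positive")
        if self.orientation not in ("vertical", "horizontal"):
            raise ConfigurationError("orientation must be 'vertical' or 'horizontal'")
        if not (0.0 < self.porosity < 1.0):
            raise ConfigurationError("porosity must lie strictly between 0 and 1")
        if not (0.5 <= self.channel_diameter_nm <= 3.0):
            raise ConfigurationError("nanochannel diameter outside the plausible 0.5–3 nm range")
        if self.fixed_charge_density is not None and self.fixed_charge_density >= 0:
            raise ConfigurationError("DNA fixed charge density must be negative")
        if self.protrusion_nm < 0:
            raise ConfigurationError("protrusion must be non-negative")

    @property
    def rho_fixed(self) -> float:
        """Smeared fixed charge density (C/m^3, negative)."""
        if self.fixed_charge_density is not None:
            return self.fixed_charge_density
        helix_cross_section = np.pi * (DNA_ROD_RADIUS_NM * NM) ** 2
        per_dna_volume = 2.0 * ELEMENTARY_CHARGE / (0.34 * NM * helix_cross_section)
        return -float((1.0 - self.porosity) * per_dna_volume)

    @property
    def permeabilities(self) -> tuple[float, float]:
        """(kappa_par, kappa_perp) in m^2, derived unless overridden."""
        kp, kt = permeability_from_channels(self.channel_diameter_nm, self.porosity)
        if self.kappa_par is not None:
            kp = self.kappa_par
        if self.kappa_perp is not None:
            kt = self.kappa_perp
        if not (kp > kt > 0):
            raise ConfigurationError("require kappa_par > kappa_perp > 0")
        return kp, kt


@dataclass
class AxiMesh:
    """Structured axisymmetric finite-volume mesh (tensor-product, graded).

    Cell-centred material and coefficient fields are arrays of shape
    (nz, nr); ``r_faces``/``z_faces`` are the (nr+1,)/(nz+1,) face
    coordinates in nm.  Permeabilities are np.inf outside the origami
    (no Brinkman drag); ``surface_charge`` is an equivalent volumetric
    charge (C/m^3) assigned to fluid cells abutting charged walls.
    """

    r_faces: np.ndarray
    z_faces: np.ndarray
    material: np.ndarray
    porosity: np.ndarray
    fixed_charge: np.ndarray
    kappa_rr: np.ndarray
    kappa_zz: np.ndarray
    eps_r: np.ndarray
    surface_charge: np.ndarray
    geometry: PoreGeometry | None = None
    origami: OrigamiModel | None = None

    # --- derived geometry -------------------------------------------------
    @property
    def nr(self) -> int:
        return len(self.r_faces) - 1

    @property
    def nz(self) -> int:
        return len(self.z_faces) - 1

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    @property
    def cell_volumes(self) -> np.ndarray:
        """Cell volumes in m^3, shape (nz, nr)."""
        rf = self.r_faces * NM
        zf = self.z_faces * NM
        ring = np.pi * (rf[1:] ** 2 - rf[:-1] ** 2)
        dz = np.diff(zf)
        return dz[:, None] * ring[None, :]

    def material_volume(self, material: int) -> float:
        """Total volume (m^3) of cells carrying the given material label."""
        return float(self.cell_volumes[self.material == material].sum())

    def nodes_and_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinate array (n_nodes, 2) in nm and quad connectivity."""
        rr, zz = np.meshgrid(self.r_faces, self.z_faces)
        nodes = np.column_stack([rr.ravel(), zz.ravel()])
        nrp = self.nr + 1
        j, i = np.meshgrid(np.arange(self.nz), np.arange(self.nr), indexing="ij")
        n0 = j * nrp + i
        cells = np.column_stack([n0.ravel(), (n0 + 1).ravel(), (n0 + nrp + 1).ravel(), (n0 + nrp).ravel()])
        return nodes, cells

    def export_text(self, path) -> None:
        """Write nodes, connectivity and per-cell materials as plain text."""
        nodes, cells = self.nodes_and_cells()
        with open(path, "w") as fh:
            fh.write(f"# axisymmetric mesh: {self.nr} x {self.nz} cells (r x z), coordinates in nm\n")
            fh.write(f"nodes {len(nodes)}\n")
            for r, z in nodes:
                fh.write(f"{r:.6g} {z:.6g}\n")
            fh.write(f"cells {len(cells)}\n")
            mats = self.material.ravel()
            for quad, m in zip(cells, mats):
                fh.write(" ".join(str(int(n)) for n in quad) + f" {int(m)}\n")


def _graded_axis(
    lo: float,
    hi: float,
    fine_lo: float,
    fine_hi: float,
    h_fine: float,
    growth: float,
    h_max: float,
) -> np.ndarray:
    """1D face coordinates: uniform h_fine in [fine_lo, fine_hi], geometric
    growth (ratio ``growth``, capped at ``h_max``) towards lo and hi."""
    fine_lo = max(lo, fine_lo)
    fine_hi = min(hi, fine_hi)
    n_fine = max(1, int(round((fine_hi - fine_lo) / h_fine)))
    fine = np.linspace(fine_lo, fine_hi, n_fine + 1)

    def grow(start: float, end: float, direction: float) -> list[float]:
        pts: list[float] = []
        h = h_fine
        x = start
        while (end - x) * direction > 1e-12:
            h = min(h * growth, h_max)
            x = x + direction * h
            pts.append(x)
        if pts:
            # rescale the grown block so the last face lands exactly on `end`
            arr = np.asarray(pts)
            arr = start + (arr - start) * (end - start) / (arr[-1] - start)
            return list(arr)
        return pts

    left = grow(fine_lo, lo, -1.0)[::-1]
    right = grow(fine_hi, hi, +1.0)
    return np.asarray(left + list(fine) + right)


def build_domain(
    geometry: PoreGeometry,
    origami: OrigamiModel | None = None,
    *,
    fine_cell_nm: float = 0.75,
    coarse_cell_nm: float = 8.0,
    growth: float = 1.15,
    wall_charge: float = 0.0,
    eps_r_fluid: float = 78.4,
    eps_r_membrane: float = 7.5,
) -> AxiMesh:
    """Build the graded axisymmetric mesh with per-cell material fields.

    The fine band (cell size ``fine_cell_nm``) covers the pore, the slab
    faces and the origami sphere; cells grow geometrically towards the
    reservoir boundaries.  ``wall_charge`` (C/m^2) is an optional surface
    charge on the solid walls, converted to an equivalent volumetric charge
    in the adjacent fluid cells (default 0: lipid passivation).
    """
    r_eff = geometry.effective_pore_radius_nm
    slab = geometry.slab_thickness_nm

    if origami is not None:
        if 2.0 * origami.radius_nm <= 2.0 * r_eff:
            raise ConfigurationError("origami sphere smaller than the pore cannot dock")
        z_sphere_top = 2.0 * origami.radius_nm - origami.protrusion_nm
        if geometry.reservoir_height_nm <= z_sphere_top + 10.0:
            raise ConfigurationError("cis reservoir too shallow for the docked sphere")

    z_lo = -(slab + geometry.reservoir_height_nm)
    z_hi = geometry.reservoir_height_nm
    r_fine_hi = max(r_eff, origami.radius_nm if origami else 0.0) + 6.0
    z_fine_lo = -(slab + 6.0)
    z_fine_hi = (2.0 * origami.radius_nm + 6.0 - origami.protrusion_nm) if origami else 6.0

    r_faces = _graded_axis(0.0, geometry.reservoir_radius_nm, 0.0, r_fine_hi, fine_cell_nm, growth, coarse_cell_nm)
    z_faces = _graded_axis(z_lo, z_hi, z_fine_lo, z_fine_hi, fine_cell_nm, growth, coarse_cell_nm)

    rc = 0.5 * (r_faces[:-1] + r_faces[1:])
    zc = 0.5 * (z_faces[:-1] + z_faces[1:])
    R, Z = np.meshgrid(rc, zc)

    material = np.full(R.shape, MATERIAL_FLUID, dtype=np.int8)
    in_slab = (Z >= -slab) & (Z <= 0.0) & (R >= r_eff)
    material[in_slab] = MATERIAL_MEMBRANE

    porosity = np.ones_like(R)
    fixed_charge = np.zeros_like(R)
    kappa_rr = np.full_like(R, np.inf)
    kappa_zz = np.full_like(R, np.inf)
    eps_r = np.where(material == MATERIAL_MEMBRANE, eps_r_membrane, eps_r_fluid)

    if origami is not None:
        zc_sphere = origami.radius_nm - origami.protrusion_nm
        in_sphere = (R**2 + (Z - zc_sphere) ** 2 <= origami.radius_nm**2) & (
            material != MATERIAL_MEMBRANE
        )
        material[in_sphere] = MATERIAL_ORIGAMI
        porosity[in_sphere] = origami.porosity
        fixed_charge[in_sphere] = origami.rho_fixed
        kp, kt = origami.permeabilities
        if origami.orientation == "vertical":
            kzz, krr = kp, kt
        else:
            kzz, krr = kt, kp
        kappa_rr[in_sphere] = krr
        kappa_zz[in_sphere] = kzz

    surface_charge = np.zeros_like(R)
    if wall_charge != 0.0:
        solid = material == MATERIAL_MEMBRANE
        rf_m = r_faces * NM
        zf_m = z_faces * NM
        dz_m = np.diff(zf_m)
        ring = np.pi * (rf_m[1:] ** 2 - rf_m[:-1] ** 2)
        vol = dz_m[:, None] * ring[None, :]
        # radial wall faces between fluid (j,i) and solid (j,i+-1)
        for j in range(len(zc)):
            for i in range(len(rc)):
                if solid[j, i]:
                    continue
                area = 0.0
                if i + 1 < len(rc) and solid[j, i + 1]:
                    area += 2.0 * np.pi * rf_m[i + 1] * dz_m[j]
                if i - 1 >= 0 and solid[j, i - 1]:
                    area += 2.0 * np.pi * rf_m[i] * dz_m[j]
                if j + 1 < len(zc) and solid[j + 1, i]:
                    area += ring[i]
                if j - 1 >= 0 and solid[j - 1, i]:
                    area += ring[i]
                if area:
                    surface_charge[j, i] = wall_charge * area / vol[j, i]

    return AxiMesh(
        r_faces=r_faces,
        z_faces=z_faces,
        material=material,
        porosity=porosity,
        fixed_charge=fixed_charge,
        kappa_rr=kappa_rr,
        kappa_zz=kappa_zz,
        eps_r=eps_r,
        surface_charge=surface_charge,
        geometry=geometry,
        origami=origami,
    )


def cells_per_debye(mesh: AxiMesh, electrolyte: ElectrolyteSpec) -> float:
    """Achieved mesh resolution, in cells per Debye length, in charged regions.

    Reported for the finest cell inside (or, with no charged cells, anywhere
    in) the domain; a value >= 2 resolves the screening layer.
    """
    lam = debye_length(electrolyte)
    dr = np.diff(mesh.r_faces)
    dz = np.diff(mesh.z_faces)
    charged = (mesh.fixed_charge != 0) | (mesh.surface_charge != 0)
    if charged.any():
        j, i = np.nonzero(charged)
        h = max(float(dr[i].max()), float(dz[j].max()))
    else:
        h = max(float(dr.min()), float(dz.min()))
    return lam / h
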