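"""Geometry, units and parameter containers.

The model lives on three concentric spherical domains:

* intracellular space, ``0 <= r <= r_cell`` (radius R1),
* cell-surface shell, ``r_cell <= r <= r_cell + shell_thickness`` (R1 to R2),
  a thin annular volume standing in for the plasma membrane,
* extracellular medium, ``R2 <= r <= r_outer`` (R2 to R3).

One cell owns the whole sphere of radius R3, so the outer radius is the sole
carrier of cell density: ``density = 1 / V_total``.  All lengths are in µm,
times in s and concentrations in nM.  Interface transport constants
(internalization, recycling, synthesis) are mass-transfer coefficients with
velocity units (µm/s): they describe flux per unit concentration across the
R1 interface, not first-order rates in a well-mixed compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AVOGADRO_NM_UM3",
    "Geometry",
    "KineticParameters",
    "DiffusionCoefficients",
    "InitialConditions",
    "density_from_outer_radius",
    "outer_radius_from_density",
    "shell_to_cell_concentration",
    "surface_number_density",
]

#: molecules per µm³ at 1 nM  (6.022e23 / L * 1e-9 mol/L * 1e-15 L/µm³)
AVOGADRO_NM_UM3 = 0.6022

#: µm³ per ml
_UM3_PER_ML = 1.0e12


def _sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


@dataclass(frozen=True)
class Geometry:
    """Radii of the three concentric domains (µm).

    Parameters
    ----------
    r_cell:
        Radius R1 of the intracellular sphere.
    shell_thickness:
        Width δ = R2 − R1 of the cell-surface shell.
    r_outer:
        Outer radius R3 of the extracellular medium available to one cell.
    """

    r_cell: float = 7.5
    shell_thickness: float = 0.1
    r_outer: float = 30.0

    def __post_init__(self) -> None:
        if self.r_cell <= 0:
            raise ValueError(f"r_cell must be positive, got {self.r_cell}")
        if self.shell_thickness <= 0:
            raise ValueError(
                f"shell_thickness must be positive, got {self.shell_thickness}"
            )
        if self.r_outer <= self.r_cell + self.shell_thickness:
            raise ValueError(
                "r_outer must exceed r_cell + shell_thickness "
                f"({self.r_cell + self.shell_thickness:g} µm), got {self.r_outer}"
            )

    @property
    def r_shell_outer(self) -> float:
        """R2 = R1 + δ (µm)."""
        return self.r_cell + self.shell_thickness

    @property
    def v_cell(self) -> float:
        """Intracellular volume (µm³)."""
        return _sphere_volume(self.r_cell)

    @property
    def v_shell(self) -> float:
        """Shell volume (µm³)."""
        return _sphere_volume(self.r_shell_outer) - _sphere_volume(self.r_cell)

    @property
    def v_ext(self) -> float:
        """Extracellular volume (µm³)."""
        return _sphere_volume(self.r_outer) - _sphere_volume(self.r_shell_outer)

    @property
    def v_total(self) -> float:
        """Total volume of the sphere of radius R3 (µm³)."""
        return _sphere_volume(self.r_outer)

    @property
    def a_cell(self) -> float:
        """Area of the R1 interface, 4πR1² (µm²)."""
        return 4.0 * math.pi * self.r_cell**2

    @property
    def a_shell_outer(self) -> float:
        """Area of the R2 interface, 4πR2² (µm²)."""
        return 4.0 * math.pi * self.r_shell_outer**2

    @property
    def density(self) -> float:
        """Cell density (cells/ml) implied by r_outer."""
        return density_from_outer_radius(self.r_outer)


@dataclass(frozen=True)
class KineticParameters:
    """Rate and mass-transfer constants.

    Binding follows mass action in the shell; internalization/recycling act
    across the R1 interface as mass-transfer coefficients (µm/s); synthesis
    is a constant inward boundary flux at R1 feeding free surface receptors;
    degradation and dephosphorylation are first-order intracellular rates.
    Setting any constant to zero disables that process.
    """

    k_on: float = 1.0e-3          # 1/(nM·s)
    k_off: float = 1.0e-3         # 1/s
    q_syn: float = 0.002          # nM·µm/s, boundary flux at R1
    k_int_free: float = 1.0e-3    # µm/s
    k_int_bound: float = 1.0e-3   # µm/s
    k_rec_free: float = 2.5e-3    # µm/s
    k_rec_bound: float = 2.5e-3   # µm/s
    k_deg_free: float = 2.0e-4    # 1/s
    k_deg_bound: float = 5.0e-5   # 1/s
    k_dephos: float = 0.0         # 1/s

    def __post_init__(self) -> None:
        for name in (
            "k_on", "k_off", "q_syn", "k_int_free", "k_int_bound",
            "k_rec_free", "k_rec_bound", "k_deg_free", "k_deg_bound",
            "k_dephos",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Diffusion coefficients per species and domain (µm²/s)."""

    d_ligand_ext: float = 1.0        # L in the extracellular medium
    d_free_surface: float = 0.1      # LS and RS within the shell
    d_complex_surface: float = 0.05  # LRS within the shell
    d_free_cell: float = 0.2         # RI inside the cell
    d_complex_cell: float = 0.2      # LRI inside the cell

    def __post_init__(self) -> None:
        for name in (
            "d_ligand_ext", "d_free_surface", "d_complex_surface",
            "d_free_cell", "d_complex_cell",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class InitialConditions:
    """Uniform initial concentrations per domain (nM).

    ``rs0``/``lrs0`` are referenced to the shell volume, ``ri0``/``lri0`` to
    the intracellular volume and ``l0`` to the extracellular volume — the
    volume a species occupies matters for every mass balance downstream.
    """

    l0: float = 0.0
    rs0: float = 650.0
    ri0: float = 450.0
    lrs0: float = 0.0
    lri0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("l0", "rs0", "ri0", "lrs0", "lri0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


def density_from_outer_radius(r_outer: float) -> float:
    """Cell density (cells/ml) for an extracellular outer radius (µm).

    One cell occupies the full sphere of radius ``r_outer``, hence
    ``density = 10¹² · 3 / (4π r_outer³)``.
    """
    if r_outer <= 0:
        raise ValueError(f"r_outer must be positive, got {r_outer}")
    return _UM3_PER_ML / _sphere_volume(r_outer)


def outer_radius_from_density(density: float) -> float:
    """Outer radius (µm) giving one cell per ``1/density`` ml."""
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    return (3.0 * _UM3_PER_ML / (4.0 * math.pi * density)) ** (1.0 / 3.0)


def shell_to_cell_concentration(c_shell: float, geometry: Geometry) -> float:
    """Re-reference a shell concentration (nM) to the intracellular volume.

    The same number of molecules spread over the cell instead of the thin
    shell: ``c · V_shell / V_cell``.  E.g. 650 nM of surface receptors in the
    default geometry correspond to only ≈26.3 nM once internalized.
    """
    if c_shell < 0:
        raise ValueError(f"c_shell must be >= 0, got {c_shell}")
    return c_shell * geometry.v_shell / geometry.v_cell


def surface_number_density(c_shell: float, geometry: Geometry) -> float:
    """Convert a shell concentration (nM) to molecules per µm² of membrane.

    A column of shell of unit area holds ``c · 0.6022 · δ`` molecules.
    """
    if c_shell < 0:
        raise ValueError(f"c_shell must be >= 0, got {c_shell}")
    return c_shell * AVOGADRO_NM_UM3 * geometry.shell_thickness
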