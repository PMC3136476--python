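"""Conservative radial finite-volume mesh over the three spherical domains.

Each domain is covered by cell-centered control volumes bounded by faces;
the volume of control volume *i* is exactly ``(4/3)π(r_out³ − r_in³)`` so
volumes over all three domains add up to the total sphere volume.  The
extracellular domain is geometrically graded toward the R2 interface so
that the first spacing never exceeds the shell thickness (ligand gradients
are steepest there); intracellular and shell domains are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import Geometry

__all__ = ["DomainMesh", "RadialMesh", "build_mesh"]

#: species -> domain name
SPECIES_DOMAIN = {
    "L": "ext",
    "LS": "shell",
    "RS": "shell",
    "LRS": "shell",
    "RI": "cell",
    "LRI": "cell",
}


@dataclass(frozen=True)
class DomainMesh:
    """Faces, centers and volumes of one radial domain."""

    faces: np.ndarray    # (n+1,) strictly increasing radii, µm
    centers: np.ndarray  # (n,) cell-center radii, µm
    volumes: np.ndarray  # (n,) control-volume volumes, µm³
    areas: np.ndarray    # (n+1,) face areas 4πr², µm²

    @property
    def n(self) -> int:
        return self.centers.size

    @property
    def spacing(self) -> np.ndarray:
        return np.diff(self.faces)


def _domain_mesh(faces: np.ndarray) -> DomainMesh:
    faces = np.asarray(faces, dtype=float)
    if np.any(np.diff(faces) <= 0):
        raise ValueError("mesh faces must be strictly increasing")
    centers = 0.5 * (faces[:-1] + faces[1:])
    volumes = 4.0 / 3.0 * np.pi * np.diff(faces**3)
    areas = 4.0 * np.pi * faces**2
    return DomainMesh(faces=faces, centers=centers, volumes=volumes, areas=areas)


@dataclass(frozen=True)
class RadialMesh:
    """The full discretization: three abutting domain meshes."""

    cell: DomainMesh
    shell: DomainMesh
    ext: DomainMesh
    geometry: Geometry

    def domain(self, name: str) -> DomainMesh:
        return getattr(self, name)

    def domain_of(self, species: str) -> DomainMesh:
        return self.domain(SPECIES_DOMAIN[species])

    @property
    def total_volume(self) -> float:
        return float(
            self.cell.volumes.sum() + self.shell.volumes.sum() + self.ext.volumes.sum()
        )


def _graded_faces(r_lo: float, r_hi: float, n: int, w0_max: float) -> np.ndarray:
    """Faces of a geometric grading with first width <= w0_max.

    Falls back to a uniform grid whenever uniform spacing already satisfies
    the first-width constraint.
    """
    span = r_hi - r_lo
    if span / n <= w0_max:
        return np.linspace(r_lo, r_hi, n + 1)
    w0 = w0_max

    def excess(g: float) -> float:
        return w0 * (g**n - 1.0) / (g - 1.0) - span

    # span/n > w0 guarantees a root with ratio in (1, g_hi)
    g_hi = 2.0
    while excess(g_hi) < 0:
        g_hi *= 2.0
    ratio = brentq(excess, 1.0 + 1e-12, g_hi, xtol=1e-14)
    widths = w0 * ratio ** np.arange(n)
    faces = r_lo + np.concatenate(([0.0], np.cumsum(widths)))
    faces[-1] = r_hi  # absorb accumulated round-off
    return faces


def build_mesh(
    geometry: Geometry,
    resolution: tuple[int, int, int] = (40, 8, 120),
    grade_ext: bool = True,
) -> RadialMesh:
    """Build the radial mesh.

    Parameters
    ----------
    geometry:
        Domain radii.
    resolution:
        Control volumes per domain ``(n_cell, n_shell, n_ext)``; at least 3
        each.
    grade_ext:
        Grade the extracellular domain geometrically from R2 outward so the
        near-interface spacing does not exceed the shell thickness.  With
        ``False`` the extracellular grid is uniform.
    """
    n_cell, n_shell, n_ext = resolution
    if min(n_cell, n_shell, n_ext) < 3:
        raise ValueError(f"need >= 3 control volumes per domain, got {resolution}")
    r1, r2, r3 = geometry.r_cell, geometry.r_shell_outer, geometry.r_outer
    cell = _domain_mesh(np.linspace(0.0, r1, n_cell + 1))
    shell = _domain_mesh(np.linspace(r1, r2, n_shell + 1))
    if grade_ext:
        ext_faces = _graded_faces(r2, r3, n_ext, geometry.shell_thickness)
    else:
        ext_faces = np.linspace(r2, r3, n_ext + 1)
    ext = _domain_mesh(ext_faces)
    return RadialMesh(cell=cell, shell=shell, ext=ext, geometry=geometry)
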