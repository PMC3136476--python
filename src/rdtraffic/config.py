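"""Configuration parsing and validation.

A run is described by a single YAML or JSON file with unit-suffixed keys:

.. code-block:: yaml

    geometry: {r_cell_um: 7.5, shell_thickness_um: 0.1, r_outer_um: 30.0}
    kinetics: {k_on_per_nM_s: 1.0e-3, k_off_per_s: 1.0e-3, ...}
    diffusion: {d_ligand_ext_um2_s: 100.0, ...}
    initial: {l0_nM: 0.0, rs0_nM: 650.0, ri0_nM: 450.0, ...}
    input: {mode: bolus, bolus_nM: 100.0}
    mesh: {n_cell: 40, n_shell: 8, n_ext: 120, grade_ext: true}
    solver: {method: BDF, rtol: 1.0e-6, atol: 1.0e-9, t_end_s: 3600.0,
             n_snapshots: 121}

Unknown keys are rejected with the offending key named.  The geometry block
accepts either ``r_outer_um`` or ``density_per_ml`` (not both); a density is
converted to the outer radius.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .geometry import (
    DiffusionCoefficients,
    Geometry,
    InitialConditions,
    KineticParameters,
    outer_radius_from_density,
)
from .inputs import LigandInputProgram

__all__ = ["RunConfig", "MeshSettings", "SolverSettings", "load_config",
           "config_from_mapping"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass(frozen=True)
class MeshSettings:
    n_cell: int = 40
    n_shell: int = 8
    n_ext: int = 120
    grade_ext: bool = True

    @property
    def resolution(self) -> tuple[int, int, int]:
        return (self.n_cell, self.n_shell, self.n_ext)


@dataclass(frozen=True)
class SolverSettings:
    method: str = "BDF"
    rtol: float = 1e-6
    atol: float = 1e-9
    t_end_s: float = 3600.0
    n_snapshots: int = 121

    def t_eval(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end_s, self.n_snapshots)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved, validated run description."""

    geometry: Geometry = field(default_factory=Geometry)
    kinetics: KineticParameters = field(default_factory=KineticParameters)
    diffusion: DiffusionCoefficients = field(default_factory=DiffusionCoefficients)
    initial: InitialConditions = field(default_factory=InitialConditions)
    input: LigandInputProgram = field(default_factory=LigandInputProgram)
    mesh: MeshSettings = field(default_factory=MeshSettings)
    solver: SolverSettings = field(default_factory=SolverSettings)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        """Plain-dict echo of the resolved configuration."""
        d = {name: asdict(getattr(self, name))
             for name in ("geometry", "kinetics", "diffusion", "initial",
                          "input", "mesh", "solver")}
        d["input"]["pulses"] = [list(p) for p in self.input.pulses]
        d["schema_version"] = self.schema_version
        return d


def _take(block: Mapping[str, Any], name: str, keys: dict[str, str]) -> dict:
    """Map suffixed config keys to constructor arguments, rejecting unknowns."""
    out = {}
    for key, value in block.items():
        if key not in keys:
            raise ConfigError(f"unknown key {name}.{key!r}; "
                              f"allowed: {sorted(keys)}")
        out[keys[key]] = value
    return out


_GEOMETRY_KEYS = {
    "r_cell_um": "r_cell",
    "shell_thickness_um": "shell_thickness",
    "r_outer_um": "r_outer",
    "density_per_ml": "density",
}
_KINETIC_KEYS = {
    "k_on_per_nM_s": "k_on",
    "k_off_per_s": "k_off",
    "q_syn_nM_um_per_s": "q_syn",
    "k_int_free_um_per_s": "k_int_free",
    "k_int_bound_um_per_s": "k_int_bound",
    "k_rec_free_um_per_s": "k_rec_free",
    "k_rec_bound_um_per_s": "k_rec_bound",
    "k_deg_free_per_s": "k_deg_free",
    "k_deg_bound_per_s": "k_deg_bound",
    "k_dephos_per_s": "k_dephos",
}
_DIFFUSION_KEYS = {
    "d_ligand_ext_um2_s": "d_ligand_ext",
    "d_free_surface_um2_s": "d_free_surface",
    "d_complex_surface_um2_s": "d_complex_surface",
    "d_free_cell_um2_s": "d_free_cell",
    "d_complex_cell_um2_s": "d_complex_cell",
}
_INITIAL_KEYS = {
    "l0_nM": "l0", "rs0_nM": "rs0", "ri0_nM": "ri0",
    "lrs0_nM": "lrs0", "lri0_nM": "lri0",
}
_INPUT_KEYS = {
    "mode": "mode", "bolus_nM": "bolus_conc",
    "rate_nM_per_s": "rate", "pulses": "pulses",
}
_MESH_KEYS = {k: k for k in ("n_cell", "n_shell", "n_ext", "grade_ext")}
_SOLVER_KEYS = {k: k for k in ("method", "rtol", "atol", "t_end_s",
                               "n_snapshots")}
_TOP_KEYS = ("geometry", "kinetics", "diffusion", "initial", "input",
             "mesh", "solver", "schema_version")


def config_from_mapping(data: Mapping[str, Any]) -> RunConfig:
    """Build a validated :class:`RunConfig` from a parsed mapping."""
    if not isinstance(data, Mapping):
        raise ConfigError("configuration root must be a mapping")
    for key in data:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown top-level key {key!r}; "
                              f"allowed: {sorted(_TOP_KEYS)}")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r}")

    geo_kwargs = _take(data.get("geometry", {}) or {}, "geometry", _GEOMETRY_KEYS)
    density = geo_kwargs.pop("density", None)
    if density is not None:
        if "r_outer" in geo_kwargs:
            raise ConfigError(
                "geometry may specify r_outer_um or density_per_ml, not both")
        geo_kwargs["r_outer"] = outer_radius_from_density(density)
    try:
        geometry = Geometry(**geo_kwargs)
        kinetics = KineticParameters(
            **_take(data.get("kinetics", {}) or {}, "kinetics", _KINETIC_KEYS))
        diffusion = DiffusionCoefficients(
            **_take(data.get("diffusion", {}) or {}, "diffusion",
                    _DIFFUSION_KEYS))
        initial = InitialConditions(
            **_take(data.get("initial", {}) or {}, "initial", _INITIAL_KEYS))
        inp_kwargs = _take(data.get("input", {}) or {}, "input", _INPUT_KEYS)
        if "pulses" in inp_kwargs:
            inp_kwargs["pulses"] = tuple(
                tuple(p) for p in inp_kwargs["pulses"])
        program = LigandInputProgram(**inp_kwargs)
        mesh = MeshSettings(
            **_take(data.get("mesh", {}) or {}, "mesh", _MESH_KEYS))
        solver = SolverSettings(
            **_take(data.get("solver", {}) or {}, "solver", _SOLVER_KEYS))
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    return RunConfig(geometry=geometry, kinetics=kinetics, diffusion=diffusion,
                     initial=initial, input=program, mesh=mesh, solver=solver)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return config_from_mapping(data)
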