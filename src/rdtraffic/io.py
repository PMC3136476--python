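"""Result persistence: tidy CSV, HDF5 and a checksummed manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mesh import SPECIES_DOMAIN
from .spatial import SimulationResult

__all__ = ["result_to_frame", "write_result", "read_result_csv"]

CSV_COLUMNS = ("time_s", "radius_um", "species", "conc_nM")


def result_to_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format view of a simulation: one row per (time, radius, species)."""
    blocks = []
    for species, arr in result.fields.items():
        centers = result.mesh.domain(SPECIES_DOMAIN[species]).centers
        nt, nr = arr.shape
        blocks.append(pd.DataFrame({
            "time_s": np.repeat(result.times, nr),
            "radius_um": np.tile(centers, nt),
            "species": species,
            "conc_nM": arr.ravel(),
        }))
    return pd.concat(blocks, ignore_index=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_result(
    result: SimulationResult,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv", "h5"),
    config_echo: dict | None = None,
    stem: str = "result",
) -> dict:
    """Write a simulation result and return the manifest.

    ``formats`` may include "csv" (tidy long format with the fixed column
    set ``time_s, radius_um, species, conc_nM``) and "h5" (hierarchical,
    with per-species arrays, mesh radii, ledger and a JSON parameter echo).
    The manifest lists files with SHA-256 checksums and embeds the echo.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - {"csv", "h5"}
    if unknown:
        raise ValueError(f"unknown formats: {sorted(unknown)}")
    files: dict[str, str] = {}

    if "csv" in formats:
        csv_path = out_dir / f"{stem}.csv"
        result_to_frame(result).to_csv(
            csv_path, index=False, float_format="%.17g")
        files[csv_path.name] = _sha256(csv_path)

    if "h5" in formats:
        h5_path = out_dir / f"{stem}.h5"
        with h5py.File(h5_path, "w") as fh:
            fh.create_dataset("times_s", data=result.times)
            grp = fh.create_group("fields")
            for species, arr in result.fields.items():
                grp.create_dataset(species, data=arr)
            mesh_grp = fh.create_group("mesh")
            for name in ("cell", "shell", "ext"):
                dom = result.mesh.domain(name)
                mesh_grp.create_dataset(f"{name}_faces_um", data=dom.faces)
            led = fh.create_group("ledger")
            for name, arr in result.ledger.items():
                led.create_dataset(name, data=arr)
            fh.attrs["config_json"] = json.dumps(
                config_echo if config_echo is not None else {}, sort_keys=True)
            fh.attrs["diagnostics_json"] = json.dumps(
                {k: v for k, v in result.diagnostics.items()
                 if isinstance(v, (int, float, str))}, sort_keys=True)
        files[h5_path.name] = _sha256(h5_path)

    manifest = {
        "files": files,
        "n_times": int(result.times.size),
        "species": sorted(result.fields),
        "config": config_echo if config_echo is not None else {},
    }
    manifest_path = out_dir / f"{stem}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_result_csv(path: str | Path) -> pd.DataFrame:
    """Read back a tidy result CSV, validating the column schema."""
    frame = pd.read_csv(path)
    if tuple(frame.columns) != CSV_COLUMNS:
        raise ValueError(
            f"unexpected columns {tuple(frame.columns)}; expected {CSV_COLUMNS}")
    return frame
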