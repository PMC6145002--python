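"""Plain-text raster I/O (ESRI ASCII grid) and artifact serialization.

All run artifacts are text: rasters as .asc, tables as CSV, metadata as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateStack, ScenarioTag

__all__ = ["write_ascii_grid", "read_ascii_grid", "write_stack", "read_stack",
           "write_occurrences", "read_occurrences"]

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, cell_size_km: float,
                     xll: float = 0.0, yll: float = 0.0) -> None:
    values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    header = (f"ncols {cols}\nnrows {rows}\nxllcorner {xll}\nyllcorner {yll}\n"
              f"cellsize {cell_size_km}\nNODATA_value {_NODATA}\n")
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grid rows run north->south; our row 0 is the south edge
        np.savetxt(fh, values[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1].copy()
    return values, header["cellsize"]


def write_stack(directory: str | Path, stack: ClimateStack) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, layer in stack.layers.items():
        write_ascii_grid(directory / f"{name}.asc", layer, stack.cell_size_km)
    meta = {"grid_shape": list(stack.grid_shape), "cell_size_km": stack.cell_size_km,
            "variables": stack.variable_names,
            "tag": {"time_slice": stack.tag.time_slice, "gcm_id": stack.tag.gcm_id,
                    "rcp_id": stack.tag.rcp_id}}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def read_stack(directory: str | Path) -> ClimateStack:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    layers = {}
    for name in meta["variables"]:
        values, _ = read_ascii_grid(directory / f"{name}.asc")
        layers[name] = values
    tag = ScenarioTag(**meta["tag"])
    return ClimateStack(grid_shape=tuple(meta["grid_shape"]),
                        cell_size_km=meta["cell_size_km"], layers=layers, tag=tag)


def write_occurrences(path: str | Path, occurrences: dict) -> None:
    rows = []
    for sid, occ in occurrences.items():
        for x, y in occ.presences:
            rows.append({"species_id": sid, "x_km": x, "y_km": y})
    pd.DataFrame(rows, columns=["species_id", "x_km", "y_km"]).to_csv(path, index=False)


def read_occurrences(path: str | Path) -> dict:
    from .climate import OccurrenceSet

    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("species_id", sort=False):
        out[str(sid)] = OccurrenceSet(species_id=str(sid),
                                      presences=grp[["x_km", "y_km"]].to_numpy())
    return out
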