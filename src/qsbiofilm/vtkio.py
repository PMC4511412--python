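"""File output: legacy ASCII VTK rectilinear-grid fields and CSV time series.

Field snapshots are written as VTK legacy RectilinearGrid files with the four
fields (M, N, C, A) as named CELL_DATA scalar arrays and the simulation time
in a FieldData entry; any standard VTK reader (ParaView included) loads them.
A minimal reader for this writer's own output is provided for round-trip
checks. Snapshot filenames carry a zero-padded index so lexicographic order
equals temporal order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grid import Grid, StateFields

__all__ = ["write_fields", "read_fields", "snapshot_filename", "write_run_metadata"]

_FIELDS = ("M", "N", "C", "A")


def snapshot_filename(index: int, prefix: str = "fields") -> str:
    """Zero-padded snapshot name, e.g. ``fields_000042.vtk``."""
    return f"{prefix}_{index:06d}.vtk"


def write_fields(state: StateFields, grid: Grid, path) -> None:
    """Write one snapshot as a legacy ASCII VTK rectilinear grid."""
    if state.shape != grid.shape:
        raise ValueError("write_fields: state shape does not match grid")
    xs = np.linspace(0.0, grid.L, grid.nx + 1)
    ys = np.linspace(0.0, grid.H, grid.ny + 1)
    lines = [
        "# vtk DataFile Version 3.0",
        f"qsbiofilm fields t={state.t!r}",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 1",
        f"X_COORDINATES {grid.nx + 1} double",
        " ".join(repr(float(v)) for v in xs),
        f"Y_COORDINATES {grid.ny + 1} double",
        " ".join(repr(float(v)) for v in ys),
        "Z_COORDINATES 1 double",
        "0.0",
        f"CELL_DATA {grid.n_cells}",
        "FIELD FieldData 1",
        "TIME 1 1 double",
        repr(float(state.t)),
    ]
    for name in _FIELDS:
        arr = getattr(state, name)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # C-order ravel of (ny, nx) is x-fastest, as VTK expects
        lines.append("\n".join(" ".join(repr(float(v)) for v in row) for row in arr))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fields(path) -> tuple[StateFields, Grid]:
    """Read a snapshot written by :func:`write_fields` (round-trip helper)."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)

    def seek(prefix: str) -> str:
        for line in it:
            if line.startswith(prefix):
                return line
        raise ValueError(f"read_fields: missing section {prefix!r}")

    dims = seek("DIMENSIONS").split()[1:]
    nx, ny = int(dims[0]) - 1, int(dims[1]) - 1
    seek("X_COORDINATES")
    xs = np.array(next(it).split(), dtype=float)
    seek("Y_COORDINATES")
    ys = np.array(next(it).split(), dtype=float)
    grid = Grid(nx=nx, ny=ny, L=float(xs[-1]), H=float(ys[-1]))
    seek("TIME")
    t = float(next(it))
    fields = {}
    for name in _FIELDS:
        seek(f"SCALARS {name}")
        next(it)  # LOOKUP_TABLE
        rows = [next(it).split() for _ in range(ny)]
        fields[name] = np.array(rows, dtype=float)
    return StateFields(t=t, **fields), grid


def write_run_metadata(path, params, settings, pockets, extra=None) -> None:
    """JSON run metadata: resolved parameters, grid, seed, pocket list."""
    import dataclasses

    from . import __version__

    doc = {
        "version": __version__,
        "model": dataclasses.asdict(params),
        "numerics": dataclasses.asdict(settings),
        "pockets": [list(p) for p in pockets],
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
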