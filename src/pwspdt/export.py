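"""Plain-text exports: legacy-VTK structured points and CSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd


def write_vtk_structured_points(
    path, fields: Dict[str, np.ndarray], spacing: float, origin=(0.0, 0.0, 0.0)
) -> None:
    """Write scalar voxel fields as an ASCII legacy-VTK structured-points file.

    ``spacing`` is the voxel size in μm; all fields must share one
    (nx, ny, nz) shape.  Point data are emitted in VTK's x-fastest
    order.
    """
    if not fields:
        raise ValueError("no fields to write")
    shapes = {f.shape for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    nx, ny, nz = shapes.pop()
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\npwspdt voxel fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing} {spacing} {spacing}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.6e")


def write_series_csv(path, series: pd.DataFrame) -> None:
    """Write a recorded region time series to CSV."""
    series.to_csv(path, index=False)
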