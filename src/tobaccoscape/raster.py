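"""Raster export/import for density surfaces.

ESRI ASCII grid (.asc) is the interchange text format: a 6-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed
by rows of cell values from the north-west corner — exactly the
row-major layout of :class:`~tobaccoscape.density.DensitySurface`.
GeoTIFF export writes the value grid with ModelPixelScale and
ModelTiepoint tags (planar metric coordinates, no CRS).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .density import DensitySurface

__all__ = ["write_ascii_grid", "read_ascii_grid", "write_geotiff"]

_NODATA = -9999.0


def write_ascii_grid(surface: DensitySurface, path: str | Path) -> Path:
    """Write the surface as an ESRI ASCII grid."""
    path = Path(path)
    yll = surface.y_origin - surface.nrows * surface.cell_size_m
    header = (
        f"ncols {surface.ncols}\n"
        f"nrows {surface.nrows}\n"
        f"xllcorner {surface.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {surface.cell_size_m!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, surface.values, fmt="%.10g")
    return path


def read_ascii_grid(
    path: str | Path,
    bandwidth_m: float = float("nan"),
    retailer_type: str = "all",
) -> DensitySurface:
    """Read an ESRI ASCII grid back into a :class:`DensitySurface`.

    The .asc format does not carry kernel metadata, so bandwidth and
    retailer type may be supplied by the caller.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh, ndmin=2)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"grid shape {values.shape} does not match header ({nrows}, {ncols})")
    cell = header["cellsize"]
    return DensitySurface(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        cell_size_m=cell,
        nrows=nrows,
        ncols=ncols,
        bandwidth_m=bandwidth_m,
        retailer_type=retailer_type,
        values=values,
    )


def write_geotiff(surface: DensitySurface, path: str | Path) -> Path:
    """Write the surface as a GeoTIFF with planar geotags (no CRS)."""
    import tifffile

    path = Path(path)
    cell = surface.cell_size_m
    # ModelPixelScaleTag (33550) and ModelTiepointTag (33922): raster (0,0)
    # anchors to the surface's north-west corner in planar metre coordinates.
    pixel_scale = (cell, cell, 0.0)
    tiepoint = (0.0, 0.0, 0.0, surface.x_origin, surface.y_origin, 0.0)
    tifffile.imwrite(
        path,
        surface.values.astype(np.float32),
        extratags=[
            (33550, "d", 3, pixel_scale, True),
            (33922, "d", 6, tiepoint, True),
        ],
    )
    return path
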