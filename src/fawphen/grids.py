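"""Gridded climate containers and ESRI ASCII grid I/O.

Monthly climate normals are held as 12-band numpy stacks on a regular
WGS84 lat/lon grid.  On disk each band is one ESRI ASCII grid
(``.asc``) — a plain-text raster format readable by every common GIS —
named ``<prefix>_<variable>_<month>.asc``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


class AlignmentError(ValueError):
    """Rasters do not share a geotransform / shape / nodata value."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid: lower-left corner, square cells, row 0 at the top."""

    nrows: int
    ncols: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = NODATA_DEFAULT

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row's pixel center, row 0 northernmost."""
        top = self.yllcorner + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    def lon_centers(self) -> np.ndarray:
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def matches(self, other: "GridSpec") -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
            and np.isclose(self.nodata, other.nodata)
        )


@dataclass
class ClimateGrid:
    """Monthly tmin/tmax normals: two (12, nrows, ncols) stacks in deg C."""

    tmin: np.ndarray
    tmax: np.ndarray
    spec: GridSpec

    def __post_init__(self):
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        expect = (12, self.spec.nrows, self.spec.ncols)
        if self.tmin.shape != expect or self.tmax.shape != expect:
            raise AlignmentError(
                f"expected stacks of shape {expect}, got tmin {self.tmin.shape}, "
                f"tmax {self.tmax.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        """Pixels with data in every month of both variables."""
        nod = self.spec.nodata
        return np.all(self.tmin != nod, axis=0) & np.all(self.tmax != nod, axis=0)


def write_ascii_grid(path, array: np.ndarray, spec: GridSpec) -> None:
    array = np.asarray(array, dtype=float)
    if array.shape != (spec.nrows, spec.ncols):
        raise AlignmentError(f"array shape {array.shape} != spec {(spec.nrows, spec.ncols)}")
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {float(spec.xllcorner)!r}\n"
        f"yllcorner {float(spec.yllcorner)!r}\n"
        f"cellsize {float(spec.cellsize)!r}\n"
        f"NODATA_value {float(spec.nodata)!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in array)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    lines = Path(path).read_text().splitlines()
    meta = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        key, val = lines[i].split()
        meta[key.lower()] = float(val)
        i += 1
    spec = GridSpec(
        nrows=int(meta["nrows"]),
        ncols=int(meta["ncols"]),
        xllcorner=meta["xllcorner"],
        yllcorner=meta["yllcorner"],
        cellsize=meta["cellsize"],
        nodata=meta.get("nodata_value", NODATA_DEFAULT),
    )
    data = np.loadtxt(lines[i:], dtype=float).reshape(spec.nrows, spec.ncols)
    return data, spec


def write_climate_grids(directory, grid: ClimateGrid, prefix: str = "climate") -> list[Path]:
    """Write 24 monthly ASCII grids ``<prefix>_{tmin,tmax}_{01..12}.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for var, stack in (("tmin", grid.tmin), ("tmax", grid.tmax)):
        for m in range(12):
            p = directory / f"{prefix}_{var}_{m + 1:02d}.asc"
            write_ascii_grid(p, stack[m], grid.spec)
            paths.append(p)
    return paths


def read_climate_grids(directory, prefix: str = "climate") -> ClimateGrid:
    """Read the 24 monthly grids written by :func:`write_climate_grids`.

    Raises :class:`AlignmentError` if any band disagrees on grid
    geometry or nodata.
    """
    directory = Path(directory)
    stacks = {}
    spec0 = None
    for var in ("tmin", "tmax"):
        bands = []
        for m in range(12):
            p = directory / f"{prefix}_{var}_{m + 1:02d}.asc"
            if not p.exists():
                raise FileNotFoundError(f"missing monthly band {p}")
            arr, spec = read_ascii_grid(p)
            if spec0 is None:
                spec0 = spec
            elif not spec0.matches(spec):
                raise AlignmentError(f"band {p.name} misaligned: {spec} != {spec0}")
            bands.append(arr)
        stacks[var] = np.stack(bands)
    return ClimateGrid(tmin=stacks["tmin"], tmax=stacks["tmax"], spec=spec0)
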