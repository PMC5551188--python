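"""Planar rasters and prediction surfaces.

All geometry lives in a local planar CRS in metres, y increasing north.
Rasters are stored south-up internally (``values[0, :]`` is the southern
row) so that ``y = y0 + (row + 0.5) * cell``; the ESRI ASCII grid writer
flips to the conventional north-up order on disk.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

__all__ = ["Raster", "GridSurface", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Cell values; row 0 is the southern row.
    x0, y0 : float
        Coordinates (m) of the lower-left corner of the grid.
    cell : float
        Cell size in metres.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell,
            self.y0 + self.ny * self.cell,
        )

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (clipped to the grid)."""
        col = np.clip(((np.asarray(x) - self.x0) // self.cell).astype(int), 0, self.nx - 1)
        row = np.clip(((np.asarray(y) - self.y0) // self.cell).astype(int), 0, self.ny - 1)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell lookup of raster values at arbitrary points."""
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
        )

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.x0, self.y0, self.cell)


@dataclass
class GridSurface(Raster):
    """A prediction surface (NO2 in ppb, or a delta in ppb).

    No-data cells are stored as NaN; ``mask`` is True on valid cells.
    """

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def summary(self) -> dict:
        v = self.valid_values()
        return {
            "n_valid": int(v.size),
            "mean": float(v.mean()) if v.size else float("nan"),
            "min": float(v.min()) if v.size else float("nan"),
            "max": float(v.max()) if v.size else float("nan"),
        }

    def copy(self) -> "GridSurface":
        return GridSurface(self.values.copy(), self.x0, self.y0, self.cell)

    def plot(self, ax=None, **kwargs):
        """Render the surface with matplotlib (imshow, north up)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xmin, ymin, xmax, ymax = self.extent
        im = ax.imshow(
            self.values[::-1, :],
            extent=(xmin, xmax, ymin, ymax),
            **kwargs,
        )
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        return im


def write_ascii_grid(raster: Raster, path) -> None:
    """Write a raster as an ESRI ASCII grid (text, north-up)."""
    vals = raster.values[::-1, :].copy()
    nan = ~np.isfinite(vals)
    vals[nan] = _NODATA
    header = (
        f"ncols {raster.nx}\n"
        f"nrows {raster.ny}\n"
        f"xllcorner {raster.x0!r}\n"
        f"yllcorner {raster.y0!r}\n"
        f"cellsize {raster.cell!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")


def read_ascii_grid(path, surface: bool = False) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            try:
                key, val = line.split()
                header[key.lower()] = float(val)
            except ValueError as exc:
                raise ValueError(f"malformed ASCII grid header line: {line!r}") from exc
        vals = np.loadtxt(fh, ndmin=2)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"ASCII grid body shape {vals.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    vals = vals[::-1, :]
    vals[vals == header.get("nodata_value", _NODATA)] = np.nan
    cls = GridSurface if surface else Raster
    return cls(vals, header["xllcorner"], header["yllcorner"], header["cellsize"])
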