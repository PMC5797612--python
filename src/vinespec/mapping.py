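"""Spatial interpolation of predicted psi_s by multilevel B-spline
approximation (MBA) and raster export.

Implements the Lee-Wolberg-Shin hierarchy of uniform cubic B-spline
lattices: a coarse control lattice is fitted to the scattered data by local
least squares (the BA step), each finer (dyadically refined) level is fitted
to the residuals of the accumulated surface, and the final surface is the
sum of all level surfaces evaluated at cell centres.  The data mean is
removed before fitting and restored afterwards so that regions without
support relax to the mean and a constant field is reproduced exactly.

Coordinates live in a local plot frame in metres (row-along x, row-across
y); predicted psi_s is attached to the centroid of each sub-replicate unit.
Rasters are exported as ESRI ASCII grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MapGrid",
    "mba_interpolate",
    "mba_residuals",
    "export_grid",
    "read_grid",
]

NODATA = -9999.0


@dataclass
class MapGrid:
    """Raster of interpolated psi_s over a local plot frame.

    ``values`` is (n_rows, n_cols) with row 0 the northernmost (top) row,
    matching ESRI ASCII layout; ``x0``/``y0`` are the lower-left corner.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell
        ys = self.y0 + (self.n_rows - 1 - np.arange(self.n_rows) + 0.5) * self.cell
        return xs, ys


# cubic uniform B-spline basis on t in [0, 1)
def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """(4, n) array of cubic B-spline basis values B0..B3 at parameter t."""
    t = np.asarray(t, dtype=float)
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t**3 - 6 * t**2 + 4) / 6.0,
            (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6.0,
            t**3 / 6.0,
        ]
    )


class _Lattice:
    """One BA control lattice over the domain [0, mx*h] x [0, my*h_y]."""

    def __init__(self, extent, mx: int, my: int):
        self.x0, self.x1, self.y0, self.y1 = extent
        self.mx, self.my = mx, my
        self.hx = (self.x1 - self.x0) / mx
        self.hy = (self.y1 - self.y0) / my
        self.phi = np.zeros((mx + 3, my + 3))

    def _locate(self, x, y):
        u = np.clip((np.asarray(x) - self.x0) / self.hx, 0, self.mx - 1e-12)
        v = np.clip((np.asarray(y) - self.y0) / self.hy, 0, self.my - 1e-12)
        i = np.minimum(u.astype(int), self.mx - 1)
        j = np.minimum(v.astype(int), self.my - 1)
        return i, j, _bspline_weights(u - i), _bspline_weights(v - j)

    def fit(self, x, y, z) -> None:
        """BA algorithm: local least-squares control points from scattered data."""
        i, j, bu, bv = self._locate(x, y)
        delta = np.zeros_like(self.phi)
        omega = np.zeros_like(self.phi)
        # per-point normalization sum of squared tensor weights
        w_all = bu[:, None, :] * bv[None, :, :]          # (4, 4, n)
        s2 = (w_all**2).sum(axis=(0, 1))                  # (n,)
        s2 = np.where(s2 > 0, s2, 1.0)
        z_norm = np.asarray(z) / s2
        for k in range(4):
            for l_ in range(4):
                w = w_all[k, l_]
                # phi_c = w z / sum w^2; accumulate w^2 * phi_c and w^2
                np.add.at(delta, (i + k, j + l_), w**3 * z_norm)
                np.add.at(omega, (i + k, j + l_), w**2)
        nz = omega > 0
        self.phi[nz] = delta[nz] / omega[nz]

    def evaluate(self, x, y) -> np.ndarray:
        i, j, bu, bv = self._locate(x, y)
        out = np.zeros(np.asarray(x).shape)
        for k in range(4):
            for l_ in range(4):
                out += bu[k] * bv[l_] * self.phi[i + k, j + l_]
        return out


def _fit_levels(x, y, z, extent, levels: int, init: tuple[int, int]):
    """Fit the MBA hierarchy to (x, y, z); returns lattices and per-level
    maximum absolute residual at the data points."""
    lattices = []
    resid = np.asarray(z, dtype=float).copy()
    max_resid = []
    mx, my = init
    for _ in range(levels):
        lat = _Lattice(extent, mx, my)
        lat.fit(x, y, resid)
        resid = resid - lat.evaluate(x, y)
        lattices.append(lat)
        max_resid.append(float(np.abs(resid).max()))
        mx, my = mx * 2, my * 2
    return lattices, max_resid


def _prepare_points(points):
    if isinstance(points, pd.DataFrame):
        cols = list(points.columns)
        value_col = "value" if "value" in cols else (
            "psi_pred" if "psi_pred" in cols else cols[-1]
        )
        x = points["x"].to_numpy(float)
        y = points["y"].to_numpy(float)
        z = points[value_col].to_numpy(float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y, z = arr[:, 0], arr[:, 1], arr[:, 2]
    if x.size == 0:
        raise ValueError("empty point set")
    if not np.all(np.isfinite(np.concatenate([x, y, z]))):
        raise ValueError("points contain non-finite values")
    return x, y, z


def mba_interpolate(
    points,
    cell: float = 1.0,
    levels: int = 8,
    extent: tuple[float, float, float, float] | None = None,
    init_lattice: tuple[int, int] = (4, 4),
    margin: float = 0.0,
) -> MapGrid:
    """Interpolate scattered (x, y, value) points onto a raster via MBA.

    Parameters
    ----------
    points:
        DataFrame with columns ``x, y, value`` (or ``psi_pred``), or an
        ``(n, 3)`` array.
    cell:
        Output cell size in metres.
    levels:
        Number of dyadic refinement levels; more levels approach exact
        interpolation at the data points.
    extent:
        ``(xmin, xmax, ymin, ymax)``; defaults to the point bounding box
        plus ``margin``.
    """
    if levels < 1:
        raise ValueError("need at least one refinement level")
    x, y, z = _prepare_points(points)
    if extent is None:
        extent = (
            x.min() - margin, x.max() + margin,
            y.min() - margin, y.max() + margin,
        )
    xmin, xmax, ymin, ymax = extent
    if xmax <= xmin:
        xmax = xmin + max(cell, 1.0)
    if ymax <= ymin:
        ymax = ymin + max(cell, 1.0)
    extent = (xmin, xmax, ymin, ymax)

    z_mean = float(z.mean())
    lattices, _ = _fit_levels(x, y, z - z_mean, extent, levels, init_lattice)

    n_cols = max(1, int(np.ceil((xmax - xmin) / cell)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / cell)))
    xs = xmin + (np.arange(n_cols) + 0.5) * cell
    ys = ymin + (np.arange(n_rows) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)
    surface = np.full(gx.shape, z_mean)
    inside = (
        (gx >= xmin) & (gx <= xmax) & (gy >= ymin) & (gy <= ymax)
    )
    for lat in lattices:
        surface[inside] += lat.evaluate(gx[inside], gy[inside])
    # flip so row 0 is the top (north) row, as in ESRI ASCII
    return MapGrid(x0=xmin, y0=ymin, cell=cell, values=surface[::-1])


def mba_residuals(points, levels: int = 8, extent=None,
                  init_lattice=(4, 4)) -> list[float]:
    """Maximum absolute residual at the data points after each MBA level."""
    x, y, z = _prepare_points(points)
    if extent is None:
        extent = (x.min(), x.max(), y.min(), y.max())
    z_mean = float(z.mean())
    _, max_resid = _fit_levels(x, y, z - z_mean, extent, levels, init_lattice)
    return max_resid


def export_grid(grid: MapGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc); NaN cells become the nodata value."""
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x0:.17g}\n")
        fh.write(f"yllcorner {grid.y0:.17g}\n")
        fh.write(f"cellsize {grid.cell:.17g}\n")
        fh.write(f"NODATA_value {grid.nodata:.17g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_grid(path) -> MapGrid:
    """Read an ESRI ASCII grid written by :func:`export_grid`."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    values = np.array(
        [[float(v) for v in line.split()] for line in lines[6:] if line.strip()]
    )
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match declared dimensions")
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    return MapGrid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        values=values,
        nodata=nodata,
    )
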