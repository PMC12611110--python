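"""Weighted kernel density surfaces, Ripley's-K bandwidth selection, and the
healthcare-and-mortality ratio (HMR).

Region centroids anchor one weighted Gaussian KDE per indicator, with the
quinquennial mean smoothed rate as the weight:

    fhat(x) = 1/(n h^2) * sum_i w_i k(||x - x_i|| / h),
    k(u) = (1/2pi) exp(-u^2 / 2)

so that each unit-weight point contributes total mass 1/n and the plane
integral of fhat equals (sum_i w_i)/n.  The bandwidth h is the distance at
which Ripley's K-function exceeds its complete-spatial-randomness value
pi d^2 the most:

    Khat(d) = A / (m (m-1)) * sum_{i != j} 1[d_ij <= d]

(A the study area; no edge correction; a torus metric is available for
calibration tests).  The HMR raster is then

    HMR(x) = (fhat_diag(x) + fhat_treat(x)) / (fhat_mort(x) + 1)

with the +1 guarding against division by zero, exactly as defined; values
near 1 mean healthcare-effort density comparable to mortality density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .data_model import RegionLattice
from .errors import ConfigError, InsufficientDataError, ValidationError

GAUSS_NORM = 1.0 / (2.0 * np.pi)


@dataclass
class RasterGrid:
    """Regular raster: origin (x0, y0) at the lower-left corner, square cells."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell <= 0 or self.nx <= 0 or self.ny <= 0:
            raise ConfigError("raster cell size and dimensions must be positive")

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinate vectors (x of length nx, y of length ny)."""
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        return x, y

    def center_points(self) -> np.ndarray:
        x, y = self.centers()
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell


@dataclass
class KdeSurface:
    grid: RasterGrid
    values: np.ndarray        # (ny, nx), intensity fhat
    bandwidth: float
    indicator: str
    n_points: int

    def integral(self) -> float:
        return float(self.values.sum() * self.grid.cell_area)


@dataclass
class RipleyResult:
    d: np.ndarray
    K: np.ndarray
    theoretical: np.ndarray   # pi d^2
    diff: np.ndarray          # K - pi d^2
    area: float
    n_points: int

    @property
    def argmax_d(self) -> float:
        return float(self.d[int(np.argmax(self.diff))])


@dataclass
class HmrRaster:
    grid: RasterGrid
    values: np.ndarray
    bandwidth: float
    components: dict[str, KdeSurface] = field(default_factory=dict)


def default_grid(points: np.ndarray, h: float, n_cells: int = 200,
                 margin: float = 2.0) -> RasterGrid:
    """Square-ish grid covering the points with a ``margin``-bandwidth
    margin, ~n_cells wide."""
    xmin, ymin = points.min(axis=0)
    xmax, ymax = points.max(axis=0)
    x0, y0 = xmin - margin * h, ymin - margin * h
    x1, y1 = xmax + margin * h, ymax + margin * h
    cell = max(x1 - x0, y1 - y0) / n_cells
    nx = int(np.ceil((x1 - x0) / cell))
    ny = int(np.ceil((y1 - y0) / cell))
    return RasterGrid(x0=x0, y0=y0, cell=cell, nx=nx, ny=ny)


def extract_centroids(lattice: RegionLattice, quinq: pd.DataFrame,
                      period: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Anchor points (region centroids) and per-indicator weight vectors.

    ``quinq`` is a quinquennial panel frame (region_id, indicator, period,
    mean_rate); weights are the mean smoothed rates of ``period``.
    """
    sub = quinq[quinq["period"] == period]
    if sub.empty:
        raise ValidationError(f"no quinquennial rates for period '{period}'")
    points = lattice.centroids
    weights: dict[str, np.ndarray] = {}
    for ind, grp in sub.groupby("indicator"):
        series = grp.set_index("region_id")["mean_rate"]
        missing = [rid for rid in lattice.region_ids if rid not in series.index]
        if missing:
            raise ValidationError(
                f"indicator {ind}: missing rate for region {missing[0]}")
        weights[ind] = series.reindex(lattice.region_ids).to_numpy(dtype=float)
    return points, weights


def _torus_pdist(points: np.ndarray, domain: tuple[float, float]) -> np.ndarray:
    d = np.abs(points[:, None, :] - points[None, :, :])
    d = np.minimum(d, np.array(domain) - d)
    dist = np.sqrt((d ** 2).sum(-1))
    iu = np.triu_indices(len(points), 1)
    return dist[iu]


def ripley_k(points: np.ndarray, area: float | None = None,
             d_grid: np.ndarray | None = None,
             torus_domain: tuple[float, float] | None = None) -> RipleyResult:
    """Ripley's K-function without edge correction.

    ``area`` defaults to the bounding-box area; ``torus_domain`` switches to
    wrap-around distances on a (Lx, Ly) torus (calibration mode, with
    area = Lx * Ly unless given).
    """
    points = np.asarray(points, dtype=float)
    m = len(points)
    if m < 10:
        raise InsufficientDataError(f"Ripley's K needs >= 10 points, got {m}")
    if torus_domain is not None:
        dists = _torus_pdist(points, torus_domain)
        if area is None:
            area = torus_domain[0] * torus_domain[1]
    else:
        dists = pdist(points)
        if area is None:
            ext = points.max(axis=0) - points.min(axis=0)
            area = float(ext[0] * ext[1])
    if d_grid is None:
        d_grid = np.linspace(0, dists.max() / 2, 50)[1:]
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(np.diff(d_grid) <= 0):
        raise ConfigError("d_grid must be strictly ascending")
    # each pdist entry is one unordered pair; the i != j sum counts both orders
    pair_counts = 2 * np.searchsorted(np.sort(dists), d_grid, side="right")
    K = area / (m * (m - 1)) * pair_counts
    theo = np.pi * d_grid ** 2
    return RipleyResult(d=d_grid, K=K, theoretical=theo, diff=K - theo,
                        area=float(area), n_points=m)


def select_bandwidth(ripley: RipleyResult,
                     fallback: float | None = None) -> float:
    """Bandwidth = distance maximizing K - pi d^2 (ties toward smaller d)."""
    diff = ripley.diff
    if np.all(diff <= 0):
        warnings.warn("dispersed pattern: K never exceeds CSR; "
                      "using fallback bandwidth", stacklevel=2)
        if fallback is None:
            raise ConfigError("no positive K excess and no fallback bandwidth")
        return float(fallback)
    h = float(ripley.d[int(np.argmax(diff))])   # argmax takes the first maximum
    if np.argmax(diff) == len(diff) - 1:
        warnings.warn("K excess still rising at the largest candidate "
                      "distance; bandwidth set to the boundary", stacklevel=2)
    return h


def weighted_kde(points: np.ndarray, weights: np.ndarray, h: float,
                 grid: RasterGrid, indicator: str = "",
                 chunk: int = 4096) -> KdeSurface:
    """Weighted Gaussian KDE on a raster grid.

    fhat(x) = 1/(n h^2) sum_i w_i (1/2pi) exp(-||x - x_i||^2 / (2 h^2)).
    """
    if h <= 0:
        raise ConfigError("bandwidth must be positive")
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = len(points)
    if n == 0:
        warnings.warn("empty point set: zero surface", stacklevel=2)
        return KdeSurface(grid, np.zeros((grid.ny, grid.nx)), h, indicator, 0)
    cells = grid.center_points()
    out = np.empty(len(cells))
    for lo in range(0, len(cells), chunk):
        d2 = cdist(cells[lo:lo + chunk], points, "sqeuclidean")
        out[lo:lo + chunk] = np.exp(-d2 / (2 * h * h)) @ weights
    values = GAUSS_NORM / (n * h * h) * out.reshape(grid.ny, grid.nx)
    return KdeSurface(grid, values, h, indicator, n)


def compute_hmr(diag: KdeSurface, treat: KdeSurface,
                mort: KdeSurface) -> HmrRaster:
    """HMR(x) = (fhat_diag + fhat_treat) / (fhat_mort + 1), cell-wise."""
    for other in (treat, mort):
        if other.grid != diag.grid:
            raise ValidationError("KDE surfaces are on different grids")
        if other.bandwidth != diag.bandwidth:
            raise ValidationError("KDE surfaces use different bandwidths")
    values = (diag.values + treat.values) / (mort.values + 1.0)
    return HmrRaster(grid=diag.grid, values=values, bandwidth=diag.bandwidth,
                     components={"diagnosis": diag, "treatment": treat,
                                 "death": mort})


def classify_hmr(raster: HmrRaster, tolerance: float = 0.1) -> pd.DataFrame:
    """Band each cell: low (< 1-tol), near-parity ([1-tol, 1+tol]), high (> 1+tol).

    Returns the per-band cell counts and fractions.
    """
    v = raster.values
    low = int((v < 1 - tolerance).sum())
    high = int((v > 1 + tolerance).sum())
    near = v.size - low - high
    return pd.DataFrame({
        "band": ["low", "near_parity", "high"],
        "n_cells": [low, near, high],
        "fraction": [low / v.size, near / v.size, high / v.size],
    })


def band_raster(raster: HmrRaster, tolerance: float = 0.1) -> np.ndarray:
    """Cell-wise band codes: 0 low, 1 near-parity, 2 high."""
    v = raster.values
    return np.where(v < 1 - tolerance, 0, np.where(v > 1 + tolerance, 2, 1))


def write_asc(grid: RasterGrid, values: np.ndarray, path: str | Path,
              nodata: float = -9999.0) -> None:
    """Write a raster as an Esri ASCII grid (rows top-down, as the format wants)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.nx}\nnrows {grid.ny}\n")
        fh.write(f"xllcorner {grid.x0}\nyllcorner {grid.y0}\n")
        fh.write(f"cellsize {grid.cell}\nNODATA_value {nodata}\n")
        for row in values[::-1]:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_asc(path: str | Path) -> tuple[RasterGrid, np.ndarray]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = RasterGrid(x0=header["xllcorner"], y0=header["yllcorner"],
                      cell=header["cellsize"], nx=int(header["ncols"]),
                      ny=int(header["nrows"]))
    return grid, np.atleast_2d(values)[::-1]
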