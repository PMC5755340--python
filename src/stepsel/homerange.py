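"""Kernel utilization-distribution home ranges.

Per animal-season, space use is summarized by a bivariate normal kernel density
over the relocations with the reference bandwidth h_ref = sigma * n^(-1/6)
(Worton's normal-optimal choice for bivariate data, sigma^2 the mean of the
coordinate variances), and home range / core area reported as the areas of the
90% and 50% isopleths of the utilization distribution (UD).

The UD is evaluated exactly at cell centres of a regular grid (cell size h/4,
extent the data bounding box padded by 4h), each point contributing an
isotropic normal kernel with standard deviation h, truncated at 6h where the
neglected mass is ~1e-8. Isopleths take cells in order of decreasing density
until the requested probability mass is enclosed; the area is the cell count
times cell area, and polygons are traced as the union of the selected cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "h_ref",
    "UDGrid",
    "kernel_ud",
    "isopleth",
    "HomeRangeEstimate",
    "estimate_home_range",
    "home_range_table",
]


def h_ref(points: np.ndarray, dialect: str = "mean-variance") -> float:
    """Reference kernel bandwidth (m) for bivariate relocations.

    ``dialect='mean-variance'`` (default): sigma = sqrt(0.5 * (var(x) + var(y)));
    ``dialect='mean-sd'``: sigma = 0.5 * (sd(x) + sd(y)), the convention of some
    widely used home-range software. Sample variances use n - 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = pts.shape[0]
    if n < 5:
        raise ValueError("need >= 5 points")
    vx, vy = pts[:, 0].var(ddof=1), pts[:, 1].var(ddof=1)
    if vx + vy == 0:
        raise ValueError("points have zero spread: degenerate kernel")
    if dialect == "mean-variance":
        sigma = np.sqrt(0.5 * (vx + vy))
    elif dialect == "mean-sd":
        sigma = 0.5 * (np.sqrt(vx) + np.sqrt(vy))
    else:
        raise ValueError(f"unknown h_ref dialect {dialect!r}")
    return float(sigma * n ** (-1.0 / 6.0))


@dataclass
class UDGrid:
    """Gridded utilization distribution; ``density`` integrates to 1 over cells."""

    origin: tuple[float, float]  # lower-left corner of cell (0, 0)
    cell_size: float
    density: np.ndarray  # (rows, cols), per m^2

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def mass(self) -> np.ndarray:
        return self.density * self.cell_area


def kernel_ud(
    points: np.ndarray,
    h: float,
    cell_size: float | None = None,
    padding: float | None = None,
    max_leakage: float = 0.01,
) -> UDGrid:
    """Bivariate normal kernel density of the relocations on a regular grid.

    density(cell) = mean over points of N(point, h^2 I) at the cell centre,
    renormalized to integrate to 1 over the grid. Raises if more than
    ``max_leakage`` of the kernel mass falls outside the grid.
    """
    pts = np.asarray(points, dtype=float)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    cell = cell_size if cell_size is not None else h / 4.0
    pad = padding if padding is not None else 4.0 * h
    x0 = pts[:, 0].min() - pad
    y0 = pts[:, 1].min() - pad
    cols = int(np.ceil((pts[:, 0].max() + pad - x0) / cell))
    rows = int(np.ceil((pts[:, 1].max() + pad - y0) / cell))

    xc = x0 + (np.arange(cols) + 0.5) * cell
    yc = y0 + (np.arange(rows) + 0.5) * cell
    r_cells = int(np.ceil(6.0 * h / cell))
    off = np.arange(-r_cells, r_cells + 1)

    grid = np.zeros(rows * cols)
    norm = cell**2 / (2.0 * np.pi * h * h * len(pts))
    for chunk in np.array_split(pts, max(1, len(pts) // 1000)):
        j0 = np.floor((chunk[:, 0] - x0) / cell).astype(int)
        i0 = np.floor((chunk[:, 1] - y0) / cell).astype(int)
        jj = j0[:, None] + off[None, :]
        ii = i0[:, None] + off[None, :]
        okj = (jj >= 0) & (jj < cols)
        oki = (ii >= 0) & (ii < rows)
        jj_ = np.clip(jj, 0, cols - 1)
        ii_ = np.clip(ii, 0, rows - 1)
        gx = np.exp(-0.5 * ((xc[jj_] - chunk[:, [0]]) / h) ** 2) * okj
        gy = np.exp(-0.5 * ((yc[ii_] - chunk[:, [1]]) / h) ** 2) * oki
        w = gy[:, :, None] * gx[:, None, :]  # (chunk, dy, dx)
        flat = ii_[:, :, None] * cols + jj_[:, None, :]
        np.add.at(grid, flat.ravel(), w.ravel())
    grid *= norm  # mass per cell before renormalization

    captured = grid.sum()
    if captured < 1.0 - max_leakage:
        raise ValueError(
            f"grid captures only {captured:.3f} of the kernel mass; enlarge the extent"
        )
    density = (grid / captured / cell**2).reshape(rows, cols)
    return UDGrid(origin=(x0, y0), cell_size=cell, density=density)


def isopleth(ud: UDGrid, fraction: float) -> tuple[float, shapely.Geometry, np.ndarray]:
    """Smallest set of cells holding ``fraction`` of the UD mass.

    Returns (area_km2, polygon, mask). Cells are taken in order of decreasing
    density until the cumulative mass reaches the fraction; the polygon is the
    union of the selected cells' squares.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    mass = ud.mass.ravel()
    order = np.argsort(mass, kind="stable")[::-1]
    cum = np.cumsum(mass[order])
    k = int(np.searchsorted(cum, fraction)) + 1
    k = min(k, mass.size)
    mask = np.zeros(mass.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.density.shape)
    area_km2 = k * ud.cell_area / 1e6

    ii, jj = np.nonzero(mask)
    x0, y0 = ud.origin
    boxes = shapely.box(
        x0 + jj * ud.cell_size,
        y0 + ii * ud.cell_size,
        x0 + (jj + 1) * ud.cell_size,
        y0 + (ii + 1) * ud.cell_size,
    )
    poly = shapely.union_all(boxes)
    return float(area_km2), poly, mask


@dataclass
class HomeRangeEstimate:
    animal_id: str
    season: str
    n_fixes: int
    h: float
    ud: UDGrid
    areas_km2: dict[float, float] = field(default_factory=dict)
    polygons: dict[float, shapely.Geometry] = field(default_factory=dict)

    def geo_interface(self, fraction: float) -> dict:
        """GeoJSON-compatible mapping of one isopleth polygon."""
        return shapely.geometry.mapping(self.polygons[fraction])


def estimate_home_range(
    fixes: pd.DataFrame,
    isopleths: tuple[float, ...] = (0.9, 0.5),
    href_dialect: str = "mean-variance",
    animal_id: str | None = None,
    season: str | None = None,
) -> HomeRangeEstimate:
    """Kernel home range for one animal-season relocation series."""
    pts = fixes[["x", "y"]].to_numpy(dtype=float)
    h = h_ref(pts, dialect=href_dialect)
    ud = kernel_ud(pts, h)
    est = HomeRangeEstimate(
        animal_id=animal_id or str(fixes["animal_id"].iloc[0]),
        season=season if season is not None else "",
        n_fixes=len(pts),
        h=h,
        ud=ud,
    )
    for f in isopleths:
        area, poly, _ = isopleth(ud, f)
        est.areas_km2[f] = round(area, 2)
        est.polygons[f] = poly
    return est


def home_range_table(estimates: list[HomeRangeEstimate]) -> pd.DataFrame:
    """One row per animal-season: n, h and the isopleth areas (km^2)."""
    rows = []
    for e in estimates:
        row = {"animal_id": e.animal_id, "season": e.season, "n": e.n_fixes, "h": e.h}
        for f, a in sorted(e.areas_km2.items(), reverse=True):
            row[f"area{int(round(f * 100))}"] = a
        rows.append(row)
    return pd.DataFrame(rows)
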