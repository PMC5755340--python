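"""Synthetic mountain landscapes: altitude, slope, heat load and a seasonal NDVI stack.

The generator emulates the qualitative structure of a Mediterranean high-mountain
study area: a smooth altitudinal gradient with correlated relief noise, terrain
slope derived from that surface, an independent smooth heat-load field in [0, 1],
and a Normalized Difference Vegetation Index (NDVI) stack whose seasonal cycle
depends on altitude — productivity peaks in summer at high altitude (snow-free
growing season) and is flatter, with a higher year-round mean, at low altitude.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["Landscape", "SeasonalityParams", "generate_landscape"]

_HABITAT_VARS = ("slope", "heat", "ndvi")


@dataclass
class SeasonalityParams:
    """Parameters of the altitude-dependent NDVI annual cycle.

    NDVI(cell, t) = mean(z) + amp(z) * cos(2*pi*(doy - peak_doy)/365.25), with
    ``z`` the cell's altitude rescaled to [0, 1]:

    - mean(z) = ndvi_mean_low - ndvi_mean_gradient * z   (denser vegetation low)
    - amp(z)  = ndvi_amp_low + ndvi_amp_gradient * z     (stronger cycle high)

    With the defaults the midsummer altitude-NDVI correlation is positive
    (amp_gradient > mean_gradient) and the midwinter one negative.
    """

    ndvi_mean_low: float = 0.35
    ndvi_mean_gradient: float = 0.05
    ndvi_amp_low: float = 0.05
    ndvi_amp_gradient: float = 0.25
    peak_doy: float = 196.0  # mid July
    n_dates_per_year: int = 23  # 16-day satellite compositing cadence
    altitude_min: float = 1700.0
    altitude_max: float = 3000.0
    gradient_axis: str = "y"  # altitude increases northward by default
    relief_sd: float = 120.0  # sd (m) of the correlated relief noise
    relief_corr_cells: float = 6.0  # gaussian correlation length of the noise

    def ndvi_at(self, z01: np.ndarray | float, doy: np.ndarray | float) -> np.ndarray:
        """Closed-form seasonal NDVI for normalized altitude ``z01`` and day of year."""
        mean = self.ndvi_mean_low - self.ndvi_mean_gradient * np.asarray(z01)
        amp = self.ndvi_amp_low + self.ndvi_amp_gradient * np.asarray(z01)
        phase = np.cos(2.0 * np.pi * (np.asarray(doy) - self.peak_doy) / 365.25)
        return np.clip(mean + amp * phase, -1.0, 1.0)


@dataclass
class Landscape:
    """Co-registered habitat rasters on a regular grid.

    Row 0 is the southern edge; the centre of cell (i, j) sits at
    ``(x0 + (j + 0.5) * cell_size, y0 + (i + 0.5) * cell_size)``.
    ``ndvi`` is stacked (n_dates, rows, cols) with one calendar date per layer.
    """

    origin: tuple[float, float]
    cell_size: float
    altitude: np.ndarray
    slope: np.ndarray
    heat: np.ndarray
    ndvi: np.ndarray
    ndvi_dates: list[_dt.date] = field(default_factory=list)

    def __post_init__(self) -> None:
        shp = self.altitude.shape
        if self.slope.shape != shp or self.heat.shape != shp:
            raise ValueError("altitude, slope and heat rasters must share dimensions")
        if self.ndvi.ndim != 3 or self.ndvi.shape[1:] != shp:
            raise ValueError("NDVI stack must be (n_dates, rows, cols) on the same grid")
        if len(self.ndvi_dates) != self.ndvi.shape[0]:
            raise ValueError("one calendar date required per NDVI layer")
        d = [self._to_date(t) for t in self.ndvi_dates]
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("NDVI layer dates must be strictly increasing")
        if np.any(self.slope < 0):
            raise ValueError("slope must be non-negative")
        if np.any(np.abs(self.ndvi) > 1.0 + 1e-12):
            raise ValueError("NDVI values must lie in [-1, 1]")
        self._date_ordinals = np.array([t.toordinal() for t in d], dtype=float)

    @staticmethod
    def _to_date(t) -> _dt.date:
        if isinstance(t, _dt.datetime):
            return t.date()
        if isinstance(t, _dt.date):
            return t
        return _dt.date.fromisoformat(str(t))

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.altitude.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        rows, cols = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + cols * self.cell_size, y0 + rows * self.cell_size)

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        return (
            (np.asarray(x) >= xmin)
            & (np.asarray(x) < xmax)
            & (np.asarray(y) >= ymin)
            & (np.asarray(y) < ymax)
        )

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) indices; caller is responsible for bounds."""
        x0, y0 = self.origin
        j = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        i = np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        rows, cols = self.shape
        return np.clip(i, 0, rows - 1), np.clip(j, 0, cols - 1)

    def value_at(self, name: str, x, y) -> np.ndarray:
        """Nearest-cell lookup on a static raster ('altitude', 'slope', 'heat')."""
        i, j = self.cell_index(x, y)
        return getattr(self, name)[i, j]

    def ndvi_layer_index(self, when) -> int:
        """Index of the NDVI layer with date nearest ``when``; ties -> earlier layer."""
        t = self._to_datetime(when).toordinal() + self._frac_day(when)
        d = np.abs(self._date_ordinals - t)
        # argmin returns the first (earlier) minimiser, implementing the tie rule
        return int(np.argmin(d))

    @staticmethod
    def _to_datetime(when) -> _dt.date:
        if isinstance(when, _dt.datetime):
            return when.date()
        if isinstance(when, _dt.date):
            return when
        ts = np.datetime64(when)
        return ts.astype("datetime64[D]").astype(_dt.date)

    @staticmethod
    def _frac_day(when) -> float:
        if isinstance(when, _dt.datetime):
            return (when - _dt.datetime.combine(when.date(), _dt.time())).total_seconds() / 86400.0
        return 0.0

    def ndvi_at(self, x, y, when) -> np.ndarray:
        layer = self.ndvi[self.ndvi_layer_index(when)]
        i, j = self.cell_index(x, y)
        return layer[i, j]

    def covariates_at(self, x, y, when) -> dict[str, np.ndarray]:
        """slope / heat / time-matched NDVI at point(s), nearest-cell."""
        return {
            "slope": self.value_at("slope", x, y),
            "heat": self.value_at("heat", x, y),
            "ndvi": self.ndvi_at(x, y, when),
        }

    # -- text raster I/O (ESRI ASCII grid + JSON sidecar) ------------------
    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("altitude", "slope", "heat"):
            _write_asc(out / f"{name}.asc", getattr(self, name), self.origin, self.cell_size)
        for k in range(self.ndvi.shape[0]):
            _write_asc(out / f"ndvi_{k:03d}.asc", self.ndvi[k], self.origin, self.cell_size)
        meta = {
            "ndvi_dates": [self._to_date(t).isoformat() for t in self.ndvi_dates],
            "cell_size": self.cell_size,
            "origin": list(self.origin),
        }
        (out / "landscape.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, in_dir) -> "Landscape":
        src = Path(in_dir)
        meta = json.loads((src / "landscape.json").read_text())
        rasters = {n: _read_asc(src / f"{n}.asc")[0] for n in ("altitude", "slope", "heat")}
        dates = [_dt.date.fromisoformat(s) for s in meta["ndvi_dates"]]
        ndvi = np.stack([_read_asc(src / f"ndvi_{k:03d}.asc")[0] for k in range(len(dates))])
        return cls(
            origin=tuple(meta["origin"]),
            cell_size=float(meta["cell_size"]),
            ndvi=ndvi,
            ndvi_dates=dates,
            **rasters,
        )


def _write_asc(path: Path, grid: np.ndarray, origin, cell_size: float) -> None:
    rows, cols = grid.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size}\nNODATA_value -9999\n"
    )
    # ASCII grids store row 0 at the north edge; our row 0 is the south edge
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in grid[::-1])
    path.write_text(header + body + "\n")


def _read_asc(path: Path) -> tuple[np.ndarray, tuple[float, float], float]:
    lines = path.read_text().splitlines()
    hdr = {}
    k = 0
    while k < len(lines) and lines[k].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    }:
        key, val = lines[k].split()
        hdr[key.lower()] = float(val)
        k += 1
    grid = np.loadtxt(lines[k:])[::-1]
    return grid, (hdr["xllcorner"], hdr["yllcorner"]), hdr["cellsize"]


def generate_landscape(
    dims: tuple[int, int],
    cell_size: float,
    seasonality: SeasonalityParams | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    start_date: _dt.date = _dt.date(2005, 1, 1),
    n_years: int = 2,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Landscape:
    """Generate a synthetic mountain landscape.

    Altitude is a linear gradient along ``seasonality.gradient_axis`` plus
    spatially correlated Gaussian relief; slope is the local gradient magnitude
    of the altitude surface in degrees; heat load is an independent smooth
    random field rescaled to [0, 1]; the NDVI stack evaluates the closed-form
    altitude-dependent seasonal cycle of :class:`SeasonalityParams` at
    ``n_dates_per_year`` dates per year for ``n_years`` years.
    """
    rows, cols = dims
    if rows <= 0 or cols <= 0 or cell_size <= 0:
        raise ValueError("grid dimensions and cell size must be positive")
    p = seasonality or SeasonalityParams()
    rng = np.random.default_rng(seed)

    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    axis = ii if p.gradient_axis == "y" else jj
    n_axis = rows if p.gradient_axis == "y" else cols
    ramp = axis / max(n_axis - 1, 1)
    relief = gaussian_filter(rng.standard_normal((rows, cols)), p.relief_corr_cells)
    relief *= p.relief_sd / max(relief.std(), 1e-12)
    altitude = p.altitude_min + ramp * (p.altitude_max - p.altitude_min) + relief

    gy, gx = np.gradient(altitude, cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    heat = gaussian_filter(rng.standard_normal((rows, cols)), p.relief_corr_cells)
    lo, hi = heat.min(), heat.max()
    heat = (heat - lo) / max(hi - lo, 1e-12)

    z01 = (altitude - p.altitude_min) / max(p.altitude_max - p.altitude_min, 1e-12)
    z01 = np.clip(z01, 0.0, 1.0)
    step_days = 365.25 / p.n_dates_per_year
    n_layers = int(p.n_dates_per_year * n_years)
    dates = [start_date + _dt.timedelta(days=round(k * step_days)) for k in range(n_layers)]
    doy = np.array([t.timetuple().tm_yday for t in dates], dtype=float)
    ndvi = np.stack([p.ndvi_at(z01, d) for d in doy])

    return Landscape(
        origin=origin,
        cell_size=cell_size,
        altitude=altitude,
        slope=slope,
        heat=heat,
        ndvi=ndvi,
        ndvi_dates=dates,
    )
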