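"""Planar raster grids and text raster I/O.

All grids live in planar metric coordinates (metres). A grid's ``origin`` is
the lower-left corner of the lower-left cell; row index increases northward,
column index increases eastward. Point-in-cell lookup uses half-open cell
bounds ``[x, x + cell_size)``. Rasters are written as ESRI ASCII grids
(plain text, ``nodata_value -9999``), the package-wide raster exchange
format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single georeferenced grid of float values.

    ``data[r, c]`` is the value of the cell whose lower-left corner is
    ``(origin[0] + c*cell_size, origin[1] + r*cell_size)`` — row 0 is the
    southernmost row.
    """

    data: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("RasterGrid data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    def x_centers(self) -> np.ndarray:
        x0 = self.origin[0]
        return x0 + (np.arange(self.cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        y0 = self.origin[1]
        return y0 + (np.arange(self.rows) + 0.5) * self.cell_size

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Cell indices (row, col) of points; half-open bounds [x, x+cs)."""
        c = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        r = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int)
        return r, c

    def in_bounds(self, x, y) -> np.ndarray:
        r, c = self.index_of(x, y)
        return (r >= 0) & (r < self.rows) & (c >= 0) & (c < self.cols)

    def values_at(self, x, y, outside=np.nan) -> np.ndarray:
        """Cell values at planar points; ``outside`` for off-grid points and
        NaN for nodata cells."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r, c = self.index_of(x, y)
        ok = (r >= 0) & (r < self.rows) & (c >= 0) & (c < self.cols)
        out = np.full(np.shape(x), float(outside), dtype=float)
        vals = self.data[r[ok], c[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data) & (self.data != self.nodata)

    # ---- text I/O (ESRI ASCII grid) -------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        path = Path(path)
        data = np.where(np.isfinite(self.data), self.data, self.nodata)
        header = (
            f"ncols {self.cols}\n"
            f"nrows {self.rows}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"nodata_value {self.nodata:.1f}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            # ASCII grids are stored north-to-south
            np.savetxt(fh, np.flipud(data), fmt="%.6f")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            body = np.loadtxt(fh)
        body = np.atleast_2d(body)
        if body.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError(f"grid body shape {body.shape} disagrees with header")
        return cls(
            data=np.flipud(body).copy(),
            cell_size=meta["cellsize"],
            origin=(meta["xllcorner"], meta["yllcorner"]),
            nodata=meta.get("nodata_value", NODATA),
        )

    def like(self, data: np.ndarray) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        if np.shape(data) != self.shape:
            raise ValueError("data shape mismatch")
        return RasterGrid(np.asarray(data, dtype=float), self.cell_size, self.origin, self.nodata)


# Covariate order used throughout the movement model.
COVARIATE_NAMES = (
    "elevation",
    "slope",
    "cos_aspect",
    "protein",
    "biomass",
    "protein_x_biomass",
)


@dataclass
class RasterStack:
    """Biweekly covariate surfaces for one growing season.

    Static terrain layers (elevation, slope, cos-aspect) plus one protein and
    one biomass grid per biweekly period. All layers share georeferencing.
    """

    elevation: RasterGrid
    slope: RasterGrid
    cos_aspect: RasterGrid
    protein: dict[int, RasterGrid]
    biomass: dict[int, RasterGrid]
    year: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shp = self.elevation.shape
        for g in (self.slope, self.cos_aspect, *self.protein.values(), *self.biomass.values()):
            if g.shape != shp:
                raise ValueError("all stack layers must share shape")
        if self.mask is None:
            self.mask = np.ones(shp, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def periods(self) -> list[int]:
        return sorted(self.protein)

    @property
    def cell_size(self) -> float:
        return self.elevation.cell_size

    def valid_mask(self, period: int) -> np.ndarray:
        """Cells usable at ``period``: in-mask and no nodata in any layer."""
        m = self.mask & self.elevation.valid_mask() & self.slope.valid_mask()
        m &= self.cos_aspect.valid_mask()
        m &= self.protein[period].valid_mask() & self.biomass[period].valid_mask()
        return m

    def covariates_at(self, x, y, period: int) -> np.ndarray:
        """(n, 6) design matrix [ELEV, SLOPE, cosASPECT, PROTEIN, BIOMASS,
        PROTEIN×BIOMASS] at planar points; rows with any nodata are NaN."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        cols = [
            self.elevation.values_at(x, y),
            self.slope.values_at(x, y),
            self.cos_aspect.values_at(x, y),
            self.protein[period].values_at(x, y),
            self.biomass[period].values_at(x, y),
        ]
        out = np.column_stack(cols + [cols[3] * cols[4]])
        bad = ~np.isfinite(out).all(axis=1)
        out[bad] = np.nan
        return out

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.elevation.write_ascii(path / "elevation.asc")
        self.slope.write_ascii(path / "slope.asc")
        self.cos_aspect.write_ascii(path / "cos_aspect.asc")
        mask_grid = self.elevation.like(self.mask.astype(float))
        mask_grid.write_ascii(path / "mask.asc")
        for p, g in self.protein.items():
            g.write_ascii(path / f"protein_{self.year}_{p:02d}.asc")
        for p, g in self.biomass.items():
            g.write_ascii(path / f"biomass_{self.year}_{p:02d}.asc")

    @classmethod
    def read_dir(cls, path: str | Path, year: int) -> "RasterStack":
        path = Path(path)
        elev = RasterGrid.read_ascii(path / "elevation.asc")
        slope = RasterGrid.read_ascii(path / "slope.asc")
        cosasp = RasterGrid.read_ascii(path / "cos_aspect.asc")
        mask_path = path / "mask.asc"
        mask = RasterGrid.read_ascii(mask_path).data > 0.5 if mask_path.exists() else None
        protein: dict[int, RasterGrid] = {}
        biomass: dict[int, RasterGrid] = {}
        for f in sorted(path.glob(f"protein_{year}_*.asc")):
            protein[int(f.stem.split("_")[-1])] = RasterGrid.read_ascii(f)
        for f in sorted(path.glob(f"biomass_{year}_*.asc")):
            biomass[int(f.stem.split("_")[-1])] = RasterGrid.read_ascii(f)
        if not protein or not biomass:
            raise FileNotFoundError(f"no forage layers for year {year} under {path}")
        return cls(elev, slope, cosasp, protein, biomass, year=year, mask=mask)
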