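"""Plot-to-pixel aggregation with variance decomposition, and raster export.

Plot estimates are assigned to 1-km pixels on a projected grid (World
Mercator, EPSG:3395 by default). Per pixel, the area-weighted mean AGB is
reported together with a decomposition of its variance into

* **intra-plot (estimation) variance** — the area-weighted mean of the
  plots' Monte Carlo variances, and
* **inter-plot (sampling) variance** — the area-weighted variance of the
  plots' mean AGB about the pixel mean (unbiased reliability-weighted
  form by default).

Their sum, expressed as a CV, is the pixel's total uncertainty. The pixel
table is exported as a 5-band GeoTIFF (mean AGB, plot count, mean date,
inter-plot variance, intra-plot variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec",
    "PixelRecord",
    "assign_to_pixels",
    "aggregate_pixel",
    "aggregate_all",
    "pixel_table",
    "write_raster",
    "read_raster",
    "NODATA",
]

NODATA = -9999.0
BAND_NAMES = ("mean_agb", "n_plots", "mean_date", "inter_var", "intra_var")


@dataclass(frozen=True)
class GridSpec:
    """A north-up projected grid of square pixels (default 1 km, EPSG:3395)."""

    pixel_size: float = 1000.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "EPSG:3395"

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    def pixel_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing (x, y); half-open extents."""
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((y - self.origin_y) / self.pixel_size))
        return row, col

    @property
    def epsg(self) -> int:
        return int(self.crs_label.split(":")[1])


@dataclass(frozen=True)
class PixelRecord:
    pixel_id: tuple[int, int]
    mean_agb: float
    n_plots: int
    mean_date: float
    inter_var: float
    intra_var: float
    total_cv_pct: float

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ValueError("a pixel record needs at least one plot")
        if self.inter_var < 0 or self.intra_var < 0:
            raise ValueError("variances must be non-negative")


def assign_to_pixels(plots, grid: GridSpec) -> dict[tuple[int, int], list]:
    """Group plot estimates by the pixel containing their coordinates.

    Plots with non-finite coordinates are skipped with a warning.
    """
    out: dict[tuple[int, int], list] = {}
    for p in plots:
        if not (np.isfinite(p.x) and np.isfinite(p.y)):
            warnings.warn(f"plot {p.plot_id} has non-finite coordinates; skipped",
                          stacklevel=2)
            continue
        out.setdefault(grid.pixel_of(p.x, p.y), []).append(p)
    return out


def aggregate_pixel(
    plots,
    pixel_id: tuple[int, int] = (0, 0),
    unbiased: bool = True,
) -> PixelRecord:
    """Area-weighted pixel aggregate of plot estimates.

    mean_agb = Σwᵢmᵢ/Σwᵢ with wᵢ the plot areas; intra_var = Σwᵢvᵢ/Σwᵢ;
    inter_var = Σwᵢ(mᵢ−m̄)²·Σwᵢ/((Σwᵢ)²−Σwᵢ²) (unbiased
    reliability-weighted form; population form Σwᵢ(mᵢ−m̄)²/Σwᵢ when
    ``unbiased`` is off). A single plot yields inter_var = 0.
    """
    plots = list(plots)
    if not plots:
        raise ValueError("cannot aggregate an empty pixel")
    w = np.array([p.area_ha for p in plots], dtype=float)
    m = np.array([p.mean_agb for p in plots], dtype=float)
    v = np.array([p.variance for p in plots], dtype=float)
    dates = np.array([p.date for p in plots], dtype=float)
    v1 = w.sum()
    mean = float((w * m).sum() / v1)
    intra = float((w * v).sum() / v1)
    if len(plots) == 1:
        inter = 0.0
    else:
        ss = float((w * (m - mean) ** 2).sum())
        if unbiased:
            v2 = float((w**2).sum())
            denom = v1**2 - v2
            inter = ss * v1 / denom if denom > 0 else 0.0
        else:
            inter = ss / v1
    total_cv = 100.0 * np.sqrt(inter + intra) / mean if mean > 0 else 0.0
    return PixelRecord(
        pixel_id=pixel_id,
        mean_agb=mean,
        n_plots=len(plots),
        mean_date=float((w * dates).sum() / v1),
        inter_var=max(inter, 0.0),
        intra_var=intra,
        total_cv_pct=float(total_cv),
    )


def aggregate_all(plots, grid: GridSpec, unbiased: bool = True) -> list[PixelRecord]:
    groups = assign_to_pixels(plots, grid)
    return [aggregate_pixel(v, pixel_id=k, unbiased=unbiased) for k, v in sorted(groups.items())]


def pixel_table(pixels) -> pd.DataFrame:
    rows = []
    for p in pixels:
        rows.append(
            {
                "row": p.pixel_id[0],
                "col": p.pixel_id[1],
                "mean_agb": p.mean_agb,
                "n_plots": p.n_plots,
                "mean_date": p.mean_date,
                "inter_var": p.inter_var,
                "intra_var": p.intra_var,
                "total_cv_pct": p.total_cv_pct,
            }
        )
    return pd.DataFrame(rows)


def _geotiff_tags(grid: GridSpec, row_max: int, col_min: int):
    """GeoTIFF tags: pixel scale, tiepoint at the raster's NW corner, CRS."""
    north = grid.origin_y + (row_max + 1) * grid.pixel_size
    west = grid.origin_x + col_min * grid.pixel_size
    keys = (1, 1, 0, 3,
            1024, 0, 1, 1,        # GTModelType: projected
            1025, 0, 1, 1,        # GTRasterType: PixelIsArea
            3072, 0, 1, grid.epsg)
    return [
        (33550, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),        # ModelTiepoint
        (34735, "H", len(keys), keys),                             # GeoKeyDirectory
        (42113, "s", 0, str(NODATA)),                              # GDAL_NODATA
    ]


def write_raster(pixels, grid: GridSpec, path, nodata: float = NODATA) -> None:
    """Write pixel records as a 5-band float64 GeoTIFF.

    Band order: mean AGB (Mg·ha⁻¹), number of plots, mean date
    (fractional year), inter-plot variance, intra-plot variance
    (Mg²·ha⁻²). Raster rows run north to south; empty pixels hold the
    nodata value in all bands.
    """
    pixels = list(pixels)
    if not pixels:
        raise ValueError("no pixels to write")
    rows = np.array([p.pixel_id[0] for p in pixels])
    cols = np.array([p.pixel_id[1] for p in pixels])
    row_min, row_max = int(rows.min()), int(rows.max())
    col_min, col_max = int(cols.min()), int(cols.max())
    h = row_max - row_min + 1
    w = col_max - col_min + 1
    data = np.full((5, h, w), nodata, dtype=np.float64)
    for p in pixels:
        r = row_max - p.pixel_id[0]  # north-up: larger y (row index) on top
        c = p.pixel_id[1] - col_min
        data[:, r, c] = (p.mean_agb, float(p.n_plots), p.mean_date, p.inter_var, p.intra_var)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate",
        extratags=_geotiff_tags(grid, row_max, col_min),
    )


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a raster written by :func:`write_raster`; returns (bands, tags)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        tags = {}
        for code in (33550, 33922, 34735, 42113):
            tag = page.tags.get(code)
            if tag is not None:
                tags[code] = tag.value
    if data.ndim == 2:
        data = data[None]
    return np.asarray(data, dtype=np.float64), tags
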