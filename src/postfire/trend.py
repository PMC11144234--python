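"""EVI trend analysis: annual compositing, per-pixel Sen's slope, fractions.

Sen's slope of a series (t_i, x_i) is the median of all pairwise slopes
(x_j - x_i)/(t_j - t_i) over i < j — a robust, distribution-free trend
estimator; an even pair count yields the mean of the two central slopes.
Years are the abscissa, so irregular gaps between composites are handled
by the formula itself.

A pixel is *greening* when its slope exceeds ``zero_band`` and *browning*
when it falls below ``-zero_band``; the neutral band makes the implicit
"no trend" zone explicit and defaults to 0.  Areas are pixel counts times
(pixel_size_m/1000)^2 km^2.  No Mann-Kendall significance test is applied:
classification is by slope magnitude only (an available extension).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import InputError
from .raster import IndexRaster

__all__ = [
    "TrendSeries", "TrendSummary", "annual_max_composite", "sens_slope",
    "slope_raster", "greening_browning", "slope_histogram", "evi_trend_plot",
]


@dataclass
class TrendSeries:
    times: np.ndarray  # years, strictly increasing integers
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InputError("times and values must be equal-length vectors")
        if self.times.size < 2:
            raise InputError("a trend needs at least 2 observations")
        if np.unique(self.times).size != self.times.size:
            raise InputError("duplicate times in trend series")


@dataclass
class TrendSummary:
    slope_raster: IndexRaster
    greening_fraction: float
    browning_fraction: float
    greening_km2: float
    browning_km2: float
    zero_band: float

    @property
    def neutral_fraction(self) -> float:
        return 1.0 - self.greening_fraction - self.browning_fraction

    def to_dict(self) -> dict[str, float]:
        return {
            "greening_fraction": self.greening_fraction,
            "browning_fraction": self.browning_fraction,
            "greening_km2": self.greening_km2,
            "browning_km2": self.browning_km2,
            "zero_band": self.zero_band,
        }


def annual_max_composite(stack: dict[int, list[IndexRaster]]) -> dict[int, IndexRaster]:
    """Nodata-aware per-pixel maximum of each year's rasters.

    Pixels with no valid observation in a year stay nodata; empty year
    groups are dropped with a warning.
    """
    import logging
    out: dict[int, IndexRaster] = {}
    for year in sorted(stack):
        rasters = stack[year]
        if not rasters:
            logging.getLogger(__name__).warning("year %d has no rasters; dropped", year)
            continue
        cube = np.stack([r.masked_values() for r in rasters])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
            vals = np.nanmax(cube, axis=0)
        mask = ~np.isfinite(vals)
        out[year] = IndexRaster(np.nan_to_num(vals), nodata_mask=mask,
                                pixel_size_m=rasters[0].pixel_size_m,
                                transform=rasters[0].transform,
                                index_name=rasters[0].index_name)
    return out


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=1)
    return i, j


def sens_slope(series: TrendSeries) -> float:
    """Median of all pairwise slopes (x_j - x_i)/(t_j - t_i), i < j."""
    i, j = _pair_indices(series.times.size)
    slopes = (series.values[j] - series.values[i]) / (series.times[j] - series.times[i])
    return float(np.median(slopes))


def slope_raster(yearly: dict[int, IndexRaster]) -> IndexRaster:
    """Pixelwise Sen's slope over the yearly composites.

    Pixels valid in fewer than 2 years become nodata.  Vectorized: all
    C(n,2) pairwise slope grids are computed at once and the per-pixel
    median is taken over the pairs whose endpoints are both valid.
    """
    years = sorted(yearly)
    if len(years) < 2:
        raise InputError("slope_raster needs at least 2 years")
    first = yearly[years[0]]
    cube = np.stack([yearly[y].masked_values() for y in years])  # (n, H, W)
    t = np.asarray(years, dtype=np.float64)
    i, j = _pair_indices(len(years))
    with np.errstate(invalid="ignore"):
        pair_slopes = (cube[j] - cube[i]) / (t[j] - t[i])[:, None, None]
    n_valid = np.sum(np.isfinite(cube), axis=0)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        med = np.nanmedian(pair_slopes, axis=0)
    mask = (n_valid < 2) | ~np.isfinite(med)
    return IndexRaster(np.nan_to_num(med), nodata_mask=mask,
                       pixel_size_m=first.pixel_size_m, transform=first.transform,
                       index_name="slope")


def greening_browning(slopes: IndexRaster, zero_band: float = 0.0,
                      pixel_size_m: float | None = None) -> TrendSummary:
    """Greening/browning fractions and areas from a slope raster."""
    if zero_band < 0:
        raise InputError("zero_band must be non-negative")
    px = pixel_size_m if pixel_size_m is not None else slopes.pixel_size_m
    vals = slopes.values[slopes.valid]
    n = vals.size
    n_green = int(np.sum(vals > zero_band)) if n else 0
    n_brown = int(np.sum(vals < -zero_band)) if n else 0
    km2 = (px / 1000.0) ** 2
    return TrendSummary(
        slope_raster=slopes,
        greening_fraction=n_green / n if n else 0.0,
        browning_fraction=n_brown / n if n else 0.0,
        greening_km2=n_green * km2,
        browning_km2=n_brown * km2,
        zero_band=zero_band,
    )


def slope_histogram(slopes: IndexRaster, bins: int = 50,
                    plot_path: str | os.PathLike | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, edges) of unmasked slopes; optionally writes a PNG."""
    if bins < 1:
        raise InputError("bins must be >= 1")
    vals = slopes.values[slopes.valid]
    counts, edges = np.histogram(vals, bins=bins)
    if plot_path is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               color="seagreen", edgecolor="none")
        ax.set_xlabel("Sen's slope (index units / year)")
        ax.set_ylabel("pixel count")
        ax.set_title("Distribution of per-pixel trend slopes")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return counts, edges


def evi_trend_plot(yearly: dict[int, IndexRaster],
                   plot_path: str | os.PathLike | None = None,
                   csv_path: str | os.PathLike | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Spatial-mean index per year as a line plot (PNG) plus a CSV export."""
    years = sorted(yearly)
    if len(years) < 2:
        raise InputError("trend plot needs at least 2 years")
    means = np.array([float(np.nanmean(yearly[y].masked_values())) for y in years])
    yr = np.asarray(years, dtype=float)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["year", "mean_index"])
            w.writerows(zip(years, means))
    if plot_path is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(yr, means, marker="o", color="darkolivegreen")
        ax.set_xlabel("year")
        ax.set_ylabel("spatial mean index")
        ax.set_title("Annual vegetation-index trend")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return yr, means
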