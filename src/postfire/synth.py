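"""Synthetic scenes with known ground truth for every pipeline stage.

These generators emulate the study conditions end to end so the detectors
can be validated without any satellite downloads:

* bi-temporal NDVI pairs with a burn scar depressing the index,
* multi-year index stacks with per-pixel linear trends plus noise,
* post-fire composite pairs where the scar partially relaxes toward the
  background (recovery), and
* soil-attribute tables labelled by a known decision rule.

Background fields are Gaussian-filtered white noise (the simplest
controllable model of the spatial autocorrelation of vegetation indices);
burn scars are rasterized random polygons so change detection is exercised
at real boundaries.  Every generator returns its ground truth alongside
the data and is reproducible from (config, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .errors import InputError
from .raster import IndexRaster

logger = logging.getLogger(__name__)

SOIL_GROUPS = ("acrisol", "ferralsol", "cambisol", "podzol", "luvisol", "arenosol")


# ------------------------------------------------------------ burn scenes --

@dataclass
class SceneConfig:
    """Bi-temporal burn-scene parameters.

    Defaults describe a densely vegetated pre-fire landscape (mean NDVI
    0.65 with a smooth +-0.05 field) observed at 250 m with sensor noise
    sd 0.02, and a burn scar covering ~25% of the grid that depresses the
    index by 0.5 — a strong, class-crossing burn signal.
    """

    size: int = 64
    pixel_size_m: float = 250.0
    background_mean: float = 0.65
    background_amplitude: float = 0.05
    scar_fraction: float = 0.25
    scar_vertices: list[tuple[float, float]] | None = None
    depth: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.size < 8:
            raise InputError("scene size must be >= 8")
        if not 0 <= self.scar_fraction < 1:
            raise InputError("scar_fraction must lie in [0, 1)")


def _smooth_field(size: int, mean: float, amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal((size, size))
    smooth = gaussian_filter(white, sigma=size / 8.0)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return mean + amplitude * smooth


def _random_blob(size: int, fraction: float, rng: np.random.Generator,
                 n_vertices: int = 64) -> np.ndarray:
    """Random star-shaped polygon rescaled (shoelace) to the target area."""
    angles = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    radii = 1.0 + rng.uniform(-0.25, 0.25, size=n_vertices)
    radii = gaussian_filter(radii, sigma=2, mode="wrap")  # smooth boundary
    rr = radii * np.cos(angles)
    cc = radii * np.sin(angles)
    area = 0.5 * abs(np.dot(rr, np.roll(cc, -1)) - np.dot(cc, np.roll(rr, -1)))
    target = fraction * size * size
    s = np.sqrt(target / area)
    center = size / 2.0 + rng.uniform(-size / 16, size / 16, size=2)
    return np.stack([center[0] + s * rr, center[1] + s * cc], axis=1)


def rasterize_scar(vertices: np.ndarray, size: int) -> np.ndarray:
    v = np.asarray(vertices, float)
    if np.any(v < -0.5) or np.any(v > size - 0.5):
        warnings.warn("scar polygon exceeds the raster; clipping", stacklevel=2)
        v = np.clip(v, 0, size - 1)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=(size, size))
    mask[rr, cc] = True
    return mask


def make_burn_pair(cfg: SceneConfig | None = None
                   ) -> tuple[IndexRaster, IndexRaster, np.ndarray]:
    """(pre, post, truth): post = pre-field with the scar depressed by depth."""
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    background = _smooth_field(cfg.size, cfg.background_mean,
                               cfg.background_amplitude, rng)
    if cfg.scar_vertices is not None:
        verts = np.asarray(cfg.scar_vertices, float)
    else:
        verts = _random_blob(cfg.size, cfg.scar_fraction, rng)
    scar = rasterize_scar(verts, cfg.size) if cfg.scar_fraction > 0 else \
        np.zeros((cfg.size, cfg.size), bool)
    if cfg.depth == 0:
        scar_effect = 0.0
    else:
        scar_effect = np.where(scar, cfg.depth, 0.0)
    pre_vals = background + cfg.noise_sd * rng.standard_normal(background.shape)
    post_vals = background - scar_effect + cfg.noise_sd * rng.standard_normal(background.shape)
    pre = IndexRaster(np.clip(pre_vals, -1, 1), nodata_mask=np.zeros_like(scar),
                      pixel_size_m=cfg.pixel_size_m, index_name="NDVI")
    post = IndexRaster(np.clip(post_vals, -1, 1), nodata_mask=np.zeros_like(scar),
                       pixel_size_m=cfg.pixel_size_m, index_name="NDVI")
    truth = scar if cfg.depth != 0 else np.zeros_like(scar)
    return pre, post, truth


# ------------------------------------------------------------ trend stacks -

@dataclass
class TrendStackConfig:
    """Annual-stack parameters: fixed pixel sets get linear +-slope trends."""

    size: int = 64
    years: int = 10
    start_year: int = 2000
    greening_fraction_true: float = 0.6
    browning_fraction_true: float = 0.4
    slope_magnitude: float = 0.01
    base_mean: float = 0.3
    base_amplitude: float = 0.05
    noise_sd: float = 0.002
    pixel_size_m: float = 250.0
    seed: int = 0

    def __post_init__(self):
        if self.years < 3:
            raise InputError("trend stacks need >= 3 years")
        g, b = self.greening_fraction_true, self.browning_fraction_true
        if not (0 <= g <= 1 and 0 <= b <= 1 and g + b <= 1):
            raise InputError("fractions must lie in [0,1] and sum to <= 1")


def make_trend_stack(cfg: TrendStackConfig | None = None
                     ) -> tuple[dict[int, IndexRaster], dict]:
    """Yearly rasters plus exact truth (slope grid and fractions)."""
    cfg = cfg or TrendStackConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.size * cfg.size
    n_green = int(round(cfg.greening_fraction_true * n))
    n_brown = int(round(cfg.browning_fraction_true * n))
    order = rng.permutation(n)
    slopes = np.zeros(n)
    slopes[order[:n_green]] = cfg.slope_magnitude
    slopes[order[n_green:n_green + n_brown]] = -cfg.slope_magnitude
    slope_grid = slopes.reshape(cfg.size, cfg.size)
    base = _smooth_field(cfg.size, cfg.base_mean, cfg.base_amplitude, rng)
    yearly: dict[int, IndexRaster] = {}
    for t in range(cfg.years):
        year = cfg.start_year + t
        vals = base + slope_grid * t + cfg.noise_sd * rng.standard_normal(base.shape)
        yearly[year] = IndexRaster(np.clip(vals, -1, 1),
                                   nodata_mask=np.zeros_like(base, bool),
                                   pixel_size_m=cfg.pixel_size_m, index_name="EVI")
    truth = {
        "slope": IndexRaster(slope_grid, nodata_mask=np.zeros_like(base, bool),
                             pixel_size_m=cfg.pixel_size_m, index_name="slope"),
        "greening_fraction": n_green / n,
        "browning_fraction": n_brown / n,
    }
    return yearly, truth


# --------------------------------------------------------- recovery pairs --

@dataclass
class RecoveryPairsConfig:
    n: int = 200
    size: int = 32
    background_mean: float = 0.6
    background_amplitude: float = 0.05
    scar_fraction: float = 0.25
    depth: float = 0.5
    coefficient: float = 0.6  # fraction of the scar depression that relaxes
    noise_sd: float = 0.02
    pixel_size_m: float = 375.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise InputError("need n >= 1 pairs")
        if not 0.0 <= self.coefficient <= 1.0:
            raise InputError("recovery coefficient must lie in [0, 1]")


def make_recovery_pairs(cfg: RecoveryPairsConfig | None = None
                        ) -> tuple[list[tuple[IndexRaster, IndexRaster]], dict]:
    """Pairs (scarred composite, partially recovered composite) + truth.

    target = input with the scar depression reduced by ``coefficient``, so
    at noise 0, MAE(input, target) = coefficient * depth * scar_fraction.
    """
    cfg = cfg or RecoveryPairsConfig()
    rng = np.random.default_rng(cfg.seed)
    pairs = []
    scar_fracs = []
    for _ in range(cfg.n):
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        background = _smooth_field(cfg.size, cfg.background_mean,
                                   cfg.background_amplitude, sub)
        scar = rasterize_scar(_random_blob(cfg.size, cfg.scar_fraction, sub), cfg.size)
        dep = np.where(scar, cfg.depth, 0.0)
        x = background - dep + cfg.noise_sd * sub.standard_normal(background.shape)
        y = background - (1.0 - cfg.coefficient) * dep \
            + cfg.noise_sd * sub.standard_normal(background.shape)
        mk = np.zeros_like(scar)
        pairs.append((
            IndexRaster(np.clip(x, -1, 1), nodata_mask=mk,
                        pixel_size_m=cfg.pixel_size_m, index_name="NDVI"),
            IndexRaster(np.clip(y, -1, 1), nodata_mask=mk.copy(),
                        pixel_size_m=cfg.pixel_size_m, index_name="NDVI"),
        ))
        scar_fracs.append(float(scar.mean()))
    truth = {
        "coefficient": cfg.coefficient,
        "depth": cfg.depth,
        "scar_fraction_mean": float(np.mean(scar_fracs)),
        "expected_pair_mae": cfg.coefficient * cfg.depth * float(np.mean(scar_fracs)),
    }
    return pairs, truth


# -------------------------------------------------------------- soil table -

@dataclass
class SoilRule:
    """Regrowth is possible iff ph_lo <= pH <= ph_hi and nitrogen > n_min."""

    ph_lo: float = 5.5
    ph_hi: float = 7.5
    n_min: float = 0.3

    def apply(self, ph: np.ndarray, nitrogen: np.ndarray) -> np.ndarray:
        return ((ph >= self.ph_lo) & (ph <= self.ph_hi)
                & (nitrogen > self.n_min)).astype(int)

    def analytic_prevalence(self, noise_rate: float = 0.0) -> float:
        """Label-1 probability under pH ~ U(3,9), nitrogen ~ U(0,1)."""
        p = ((self.ph_hi - self.ph_lo) / 6.0) * (1.0 - self.n_min)
        return p * (1 - noise_rate) + (1 - p) * noise_rate


def make_soil_table(n: int = 2000, rule: SoilRule | None = None,
                    noise_rate: float = 0.05, seed: int = 0
                    ) -> tuple[pd.DataFrame, dict]:
    """Soil-attribute table labelled by the rule, with noise_rate label flips."""
    if n < 1:
        raise InputError("need n >= 1 rows")
    if not 0.0 <= noise_rate < 0.5:
        raise InputError("noise_rate must lie in [0, 0.5)")
    rule = rule or SoilRule()
    rng = np.random.default_rng(seed)
    ph = rng.uniform(3.0, 9.0, n)
    nitrogen = rng.uniform(0.0, 1.0, n)
    table = pd.DataFrame({
        "latitude": rng.uniform(-60.0, 60.0, n),
        "longitude": rng.uniform(-180.0, 180.0, n),
        "ph": ph,
        "nitrogen": nitrogen,
        "organic_carbon": rng.uniform(0.5, 10.0, n),
        "bulk_density": rng.uniform(0.9, 1.8, n),
        "soil_group": rng.choice(SOIL_GROUPS, n),
    })
    clean = rule.apply(ph, nitrogen)
    flips = rng.random(n) < noise_rate
    table["label"] = np.where(flips, 1 - clean, clean)
    truth = {
        "rule": {"ph_lo": rule.ph_lo, "ph_hi": rule.ph_hi, "n_min": rule.n_min},
        "noise_rate": noise_rate,
        "clean_label": clean,
        "analytic_prevalence": rule.analytic_prevalence(noise_rate),
    }
    return table, truth
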