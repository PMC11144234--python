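"""Raster data model, vegetation indices and five-class NDVI thresholding.

The in-memory container is :class:`IndexRaster`: a 2-D float grid of
vegetation-index values with an explicit boolean nodata mask (nodata is a
mask, never a sentinel, so arithmetic stays well defined), the ground
sampling distance in metres and opaque georeferencing metadata.  Grids are
row/col indexed with row 0 at the top; no reprojection or resampling is
performed — all operations assume aligned grids.

NDVI = (NIR − Red) / (NIR + Red) and
EVI  = G (NIR − Red) / (NIR + C1·Red − C2·Blue + L)
with the usual MODIS coefficients G=2.5, C1=6, C2=7.5, L=1.

The five-class vegetation scheme maps NDVI onto
{no vegetation, bare, low, moderate, high} via half-open intervals
[−1,0), [0,0.1), [0.1,0.25), [0.25,0.4), [0.4,1], which covers [−1,1]
totally and assigns every unmasked pixel exactly one class.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image

from .errors import FormatError, InputError

#: Default affine placement: (x-origin, pixel width, row rotation,
#: y-origin, column rotation, pixel height).  Carried as opaque metadata.
DEFAULT_TRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)

CLASS_NAMES = (
    "No vegetation",
    "Bare area",
    "Low vegetation",
    "Moderate vegetation",
    "High vegetation",
)

#: Metadata tag used to round-trip raster metadata through GeoTIFF.
_DESCRIPTION_KEY = "postfire"


@dataclass
class ClassScheme:
    """Ordered NDVI breakpoints defining the five vegetation classes.

    ``boundaries`` are the four interior breakpoints on [−1, 1]; class i
    covers [b_{i-1}, b_i) with b_{-1} = −1 and the last class closed at 1.
    """

    boundaries: tuple[float, float, float, float] = (0.0, 0.1, 0.25, 0.4)
    names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) != 4 or len(self.names) != 5:
            raise InputError("scheme needs 4 breakpoints and 5 class names")
        if any(b[i] >= b[i + 1] for i in range(3)):
            raise InputError("breakpoints must be strictly increasing")
        if b[0] <= -1.0 or b[-1] >= 1.0:
            raise InputError("breakpoints must lie strictly inside [-1, 1]")
        self.boundaries = b

    def to_json(self) -> str:
        return json.dumps({"boundaries": list(self.boundaries), "names": list(self.names)})

    @classmethod
    def from_json(cls, text: str) -> "ClassScheme":
        d = json.loads(text)
        return cls(boundaries=tuple(d["boundaries"]), names=tuple(d["names"]))


@dataclass
class IndexRaster:
    """Single-band vegetation-index grid with nodata mask.

    ``values`` holds finite floats at unmasked pixels; masked entries are
    ignored by every operation (their stored value is irrelevant).
    """

    values: np.ndarray
    nodata_mask: np.ndarray = None  # True = nodata
    pixel_size_m: float = 250.0
    transform: tuple = DEFAULT_TRANSFORM
    index_name: str = "NDVI"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("raster values must be a 2-D grid")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise InputError("values and nodata_mask shapes differ")
        if not self.pixel_size_m > 0:
            raise InputError("pixel_size_m must be positive")
        if self.index_name in ("NDVI", "EVI"):
            valid = self.values[~self.nodata_mask]
            if valid.size and (np.any(valid < -1 - 1e-9) or np.any(valid > 1 + 1e-9)):
                raise InputError(f"{self.index_name} values must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def masked_values(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out

    def with_values(self, values: np.ndarray, index_name: str | None = None) -> "IndexRaster":
        return replace(self, values=values, index_name=index_name or self.index_name)


@dataclass
class ClassMap:
    """Categorical raster over the five NDVI vegetation classes (codes 0-4)."""

    labels: np.ndarray
    nodata_mask: np.ndarray
    pixel_size_m: float = 250.0
    scheme: ClassScheme = field(default_factory=ClassScheme)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.labels.shape != self.nodata_mask.shape:
            raise InputError("labels and nodata_mask shapes differ")
        lab = self.labels[~self.nodata_mask]
        if lab.size and (lab.min() < 0 or lab.max() > 4):
            raise InputError("class codes must lie in 0..4")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels[~self.nodata_mask], minlength=5)


def _check_bands(*bands: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(b, dtype=np.float64) for b in bands]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise InputError("band rasters must share one shape")
        if np.any(a[np.isfinite(a)] < 0):
            raise InputError("reflectances must be non-negative")
    return tuple(arrs)


def compute_ndvi(red: np.ndarray, nir: np.ndarray, pixel_size_m: float = 250.0) -> IndexRaster:
    """NDVI = (NIR − Red)/(NIR + Red); zero-sum pixels become nodata."""
    red, nir = _check_bands(red, nir)
    denom = nir + red
    bad = (denom == 0) | ~np.isfinite(denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (nir - red) / denom
    vals = np.where(bad, 0.0, vals)
    return IndexRaster(np.clip(vals, -1.0, 1.0), nodata_mask=bad,
                       pixel_size_m=pixel_size_m, index_name="NDVI")


def compute_evi(
    red: np.ndarray,
    nir: np.ndarray,
    blue: np.ndarray,
    coeffs: tuple[float, float, float, float] = (2.5, 6.0, 7.5, 1.0),
    pixel_size_m: float = 250.0,
) -> IndexRaster:
    """EVI = G(NIR−Red)/(NIR + C1·Red − C2·Blue + L), clipped to [−1, 1]."""
    red, nir, blue = _check_bands(red, nir, blue)
    g, c1, c2, L = coeffs
    denom = nir + c1 * red - c2 * blue + L
    bad = (denom == 0) | ~np.isfinite(denom) | ~np.isfinite(red + nir + blue)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = g * (nir - red) / denom
    vals = np.where(bad, 0.0, vals)
    return IndexRaster(np.clip(vals, -1.0, 1.0), nodata_mask=bad,
                       pixel_size_m=pixel_size_m, index_name="EVI")


def classify_ndvi(index: IndexRaster, scheme: ClassScheme | None = None) -> ClassMap:
    """Threshold an NDVI raster into the five vegetation classes."""
    if index.index_name != "NDVI":
        raise InputError(f"classify_ndvi expects an NDVI raster, got {index.index_name!r}")
    scheme = scheme or ClassScheme()
    # np.digitize with right=False implements the half-open intervals
    # [−1,b0), [b0,b1), [b1,b2), [b2,b3), [b3,1].
    labels = np.digitize(index.values, scheme.boundaries, right=False)
    labels[index.nodata_mask] = 0
    return ClassMap(labels, index.nodata_mask.copy(),
                    pixel_size_m=index.pixel_size_m, scheme=scheme)


# --------------------------------------------------------------------------
# File I/O.  GeoTIFF: single-band float32, NaN marks nodata, raster metadata
# as a JSON ImageDescription tag (bit-exact float round trip).  PNG/JPEG:
# 8-bit, linear rescale of [−1,1] to 0..255, alpha channel carries the mask.
# --------------------------------------------------------------------------

def write_raster(raster: IndexRaster, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        data = raster.masked_values().astype(np.float32)
        meta = json.dumps({
            _DESCRIPTION_KEY: {
                "pixel_size_m": raster.pixel_size_m,
                "transform": list(raster.transform),
                "index_name": raster.index_name,
            }
        })
        tifffile.imwrite(path, data, description=meta)
    elif ext in (".png", ".jpg", ".jpeg"):
        scaled = np.round(np.clip((raster.values + 1.0) * 127.5, 0, 255)).astype(np.uint8)
        if ext == ".png":
            alpha = np.where(raster.nodata_mask, 0, 255).astype(np.uint8)
            Image.fromarray(np.stack([scaled, alpha], axis=-1), mode="LA").save(path)
        else:
            Image.fromarray(scaled, mode="L").save(path)
    else:
        raise FormatError(f"unsupported raster extension: {ext!r}")


def read_raster(path: str | os.PathLike, index_name: str | None = None) -> IndexRaster:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"raster file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tf:
                data = tf.series[0].asarray()
                desc = tf.pages[0].description or ""
        except Exception as exc:  # pragma: no cover - corrupt files
            raise FormatError(f"cannot read GeoTIFF {path}: {exc}") from exc
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
        if data.ndim != 2:
            raise FormatError(f"expected a single-band raster, got shape {data.shape}")
        meta = {}
        try:
            meta = json.loads(desc).get(_DESCRIPTION_KEY, {})
        except (json.JSONDecodeError, AttributeError):
            pass
        data = np.asarray(data, dtype=np.float64)
        return IndexRaster(
            np.nan_to_num(data, nan=0.0),
            nodata_mask=~np.isfinite(data),
            pixel_size_m=float(meta.get("pixel_size_m", 250.0)),
            transform=tuple(meta.get("transform", DEFAULT_TRANSFORM)),
            index_name=index_name or meta.get("index_name", "NDVI"),
        )
    if ext in (".png", ".jpg", ".jpeg"):
        try:
            img = Image.open(path)
        except Exception as exc:
            raise FormatError(f"cannot read image {path}: {exc}") from exc
        arr = np.asarray(img)
        if arr.ndim == 3 and arr.shape[-1] == 2:  # LA: alpha is the mask
            mask = arr[..., 1] == 0
            arr = arr[..., 0]
        elif arr.ndim == 2:
            mask = np.zeros(arr.shape, dtype=bool)
        else:
            raise FormatError(f"expected grayscale image, got shape {arr.shape}")
        vals = arr.astype(np.float64) / 127.5 - 1.0
        return IndexRaster(np.clip(vals, -1, 1), nodata_mask=mask,
                           index_name=index_name or "NDVI")
    raise FormatError(f"unsupported raster extension: {ext!r}")


def rasters_aligned(a: IndexRaster, b: IndexRaster) -> None:
    if a.shape != b.shape:
        raise InputError(f"rasters are misaligned: {a.shape} vs {b.shape}")
    if not np.isclose(a.pixel_size_m, b.pixel_size_m):
        raise InputError("rasters have different pixel sizes")
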