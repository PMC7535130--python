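"""Band rasters, multispectral scenes and their file formats.

A *scene* is one crop plot imaged in up to four spectral bands (green,
red, red-edge, near-infrared), each a single-channel raster of identical
shape, plus an optional binary ground-truth canopy mask.  Bands are
assumed pre-aligned; this module only validates geometry.

Mask convention: 1 (PNG: 255) = canopy / foreground, 0 = soil / background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
import yaml

BAND_NAMES = ("green", "red", "red_edge", "nir")

#: default composite channel order; red-edge is appended when available
DEFAULT_COMPOSITE = ("red", "green", "nir", "red_edge")


@dataclass
class BandRaster:
    """A single spectral band: a 2-D array of reflectance values.

    Values are dimensionless reflectances, expected in [0, 1] once
    integer digital numbers have been rescaled by the configured divisor.
    """

    values: np.ndarray
    band_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.band_name not in BAND_NAMES:
            raise ValueError(
                f"unknown band name {self.band_name!r}; expected one of {BAND_NAMES}"
            )
        if self.values.ndim != 2:
            raise ValueError(f"band raster must be 2-D, got shape {self.values.shape}")
        if self.values.size == 0:
            raise ValueError("band raster must have at least one pixel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("band raster contains non-finite values")
        if np.issubdtype(self.values.dtype, np.floating) and np.any(self.values < 0):
            raise ValueError("float band raster contains negative reflectance")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MultispectralScene:
    """Aligned band rasters for one plot, with an optional truth mask."""

    bands: dict[str, BandRaster]
    composite_order: tuple[str, ...]
    ground_truth_mask: np.ndarray | None = None
    scene_id: str = ""

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("scene needs at least one band")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"bands have mismatching shapes: {sorted(shapes)}")
        self.composite_order = tuple(self.composite_order)
        for name in self.composite_order:
            if name not in self.bands:
                raise ValueError(f"composite references missing band {name!r}")
        if len(set(self.composite_order)) != len(self.composite_order):
            raise ValueError("duplicate band in composite order")
        if self.ground_truth_mask is not None:
            m = np.asarray(self.ground_truth_mask)
            if m.shape != self.shape:
                raise ValueError("ground-truth mask shape differs from bands")
            if not np.isin(m, (0, 1)).all():
                raise ValueError("ground-truth mask must be strictly binary")
            self.ground_truth_mask = m.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def n_channels(self) -> int:
        return len(self.composite_order)

    @property
    def composite(self) -> np.ndarray:
        """H x W x C working image z, channels in ``composite_order``."""
        return np.stack(
            [self.bands[name].values for name in self.composite_order], axis=-1
        ).astype(np.float64)

    def band(self, name: str) -> np.ndarray:
        return self.bands[name].values


def _default_divisor(dtype: np.dtype) -> float:
    if dtype == np.uint8:
        return 255.0
    if dtype == np.uint16:
        return 65535.0
    return 1.0


def read_band(path: str | Path, band_name: str, divisor: float | None = None) -> BandRaster:
    """Read a single-channel TIFF/PNG raster as one spectral band.

    Integer digital numbers are rescaled to [0, 1] by ``divisor``
    (default 255 for 8-bit, 65535 for 16-bit files); pass ``divisor=1``
    to keep raw DN.  Float rasters are loaded verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"{path} is not single-channel (shape {arr.shape})")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path} has non-numeric content ({arr.dtype})")
    if np.issubdtype(arr.dtype, np.integer):
        d = _default_divisor(arr.dtype) if divisor is None else float(divisor)
        arr = arr.astype(np.float64) / d
    else:
        arr = arr.astype(np.float64)
    return BandRaster(arr, band_name)


def write_band(raster: BandRaster, path: str | Path) -> None:
    """Write a band losslessly: float64 TIFF (or 16-bit PNG, scaled)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raster.values.astype(np.float64))
    else:
        scaled = np.clip(raster.values, 0.0, 1.0)
        iio.imwrite(path, np.round(scaled * 65535).astype(np.uint16))


def stack_scene(
    bands: dict[str, BandRaster],
    composite_order: tuple[str, ...] | None = None,
    ground_truth_mask: np.ndarray | None = None,
    scene_id: str = "",
) -> MultispectralScene:
    """Assemble aligned bands into a working composite.

    Default channel order is red, green, NIR (the RGN colour space), with
    red-edge appended as a fourth channel when present.
    """
    for name in bands:
        if name not in BAND_NAMES:
            raise ValueError(f"unknown band name {name!r}")
    if composite_order is None:
        composite_order = tuple(b for b in DEFAULT_COMPOSITE if b in bands)
    return MultispectralScene(
        bands=dict(bands),
        composite_order=composite_order,
        ground_truth_mask=ground_truth_mask,
        scene_id=scene_id,
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a strictly binary canopy mask (PNG: {0, 255}; TIFF: {0, 1})."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be strictly binary (0/1)")
    path = Path(path)
    m = mask.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, m)
    else:
        iio.imwrite(path, m * 255)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask` back to {0, 1}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError(f"{path} is not a binary mask (values {vals[:10]})")
    return (arr > 0).astype(np.uint8)


def load_scene(manifest_path: str | Path) -> MultispectralScene:
    """Load a scene from a YAML manifest.

    Manifest keys: ``bands`` (band name -> file path), optional ``mask``,
    ``scene_id``, ``divisor`` and ``composite_order``.  Relative paths are
    resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "bands" not in spec:
        raise ValueError(f"{manifest_path}: manifest must map 'bands' to file paths")
    base = manifest_path.parent
    divisor = spec.get("divisor")
    bands = {
        name: read_band(base / p, name, divisor=divisor)
        for name, p in spec["bands"].items()
    }
    mask = read_mask(base / spec["mask"]) if spec.get("mask") else None
    order = tuple(spec["composite_order"]) if spec.get("composite_order") else None
    return stack_scene(
        bands,
        composite_order=order,
        ground_truth_mask=mask,
        scene_id=str(spec.get("scene_id", manifest_path.stem)),
    )
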