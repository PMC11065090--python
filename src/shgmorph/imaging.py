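"""Scan I/O and acquisition-level preprocessing.

A sample is a registered three-channel nonlinear-microscopy scan: forward-
detected SHG, backward-detected SHG, and TPEF. SHG (emission at half the
excitation wavelength) carries fibrillar-collagen contrast; TPEF provides
tissue context. Raw intensities are photon counts accumulated over the pixel
dwell time; dividing by the dwell time puts every scan on a common
counts-per-microsecond scale regardless of acquisition speed.

The lamina propria region of interest (ROI) is supplied as a binary mask with
the same geometry as the scan. Ridge detection operates on an ROI-restricted,
lightly blurred, 8-bit rendition of one SHG channel (the backward channel by
default, the one used for fiber segmentation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

log = logging.getLogger(__name__)

#: Default physical calibration: 1024 px spanning 381 um.
DEFAULT_PIXEL_SIZE_UM = 381.0 / 1024.0
#: Default pixel dwell time (us); acquisitions ranged over a few us per pixel.
DEFAULT_DWELL_TIME_US = 5.0

#: Multi-page TIFF page order used by every reader/writer in this package.
CHANNEL_ORDER = ("forward_shg", "backward_shg", "tpef")


@dataclasses.dataclass(frozen=True)
class MultichannelScan:
    """One sample's registered forward-SHG / backward-SHG / TPEF rasters.

    Parameters
    ----------
    forward_shg, backward_shg, tpef
        2-D nonnegative float arrays of identical shape, in raw counts per
        pixel (per dwell) until :func:`normalize_dwell_time` is applied.
    pixel_size_um
        Physical pixel pitch in micrometers.
    dwell_time_us
        Pixel dwell time in microseconds; 1.0 after normalization.
    """

    forward_shg: np.ndarray
    backward_shg: np.ndarray
    tpef: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    dwell_time_us: float = DEFAULT_DWELL_TIME_US

    def __post_init__(self) -> None:
        shapes = {self.forward_shg.shape, self.backward_shg.shape, self.tpef.shape}
        if len(shapes) != 1 or self.forward_shg.ndim != 2:
            raise ValueError(f"channel rasters must share one 2-D shape, got {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.dwell_time_us <= 0:
            raise ValueError("dwell_time_us must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.forward_shg.shape

    @property
    def field_width_um(self) -> float:
        return self.shape[1] * self.pixel_size_um

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_ORDER:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_ORDER}")
        return getattr(self, name)


@dataclasses.dataclass(frozen=True)
class RoiMask:
    """Binary lamina-propria mask sharing the scan geometry."""

    mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.mask.ndim != 2 or self.mask.dtype != bool:
            object.__setattr__(self, "mask", np.asarray(self.mask, bool))
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask must contain at least one pixel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @classmethod
    def full(cls, shape: tuple[int, int], pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> "RoiMask":
        return cls(np.ones(shape, bool), pixel_size_um)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size_um**2

    @property
    def area_mm2(self) -> float:
        return self.area_um2 * 1e-6


def write_scan(path: str | Path, scan: MultichannelScan) -> Path:
    """Write a scan as a 3-page grayscale float32 TIFF with JSON metadata."""
    path = Path(path)
    stack = np.stack([scan.forward_shg, scan.backward_shg, scan.tpef]).astype(np.float32)
    meta = {
        "channel_order": list(CHANNEL_ORDER),
        "pixel_size_um": scan.pixel_size_um,
        "dwell_time_us": scan.dwell_time_us,
    }
    tifffile.imwrite(path, stack, photometric="minisblack", description=json.dumps(meta))
    return path


def read_scan(
    path: str | Path,
    pixel_size_um: float | None = None,
    dwell_time_us: float | None = None,
) -> MultichannelScan:
    """Read a 3-page grayscale TIFF (forward-SHG, backward-SHG, TPEF).

    Calibration metadata embedded by :func:`write_scan` is honored; explicit
    arguments override it; with neither, documented defaults are applied and a
    warning is logged.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 3:
            raise ValueError(
                f"{path}: expected a 3-page TIFF in page order "
                f"{CHANNEL_ORDER}, got {len(tif.pages)} page(s)"
            )
        pages = [p.asarray() for p in tif.pages]
        desc = tif.pages[0].description or ""
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise ValueError(f"{path}: page {i} is not grayscale (shape {page.shape})")
    if len({p.shape for p in pages}) != 1:
        raise ValueError(f"{path}: pages have mismatched shapes")

    meta: dict = {}
    try:
        parsed = json.loads(desc)
        if isinstance(parsed, dict):
            meta = parsed
    except (json.JSONDecodeError, TypeError):
        pass

    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um")
    if dwell_time_us is None:
        dwell_time_us = meta.get("dwell_time_us")
    if pixel_size_um is None:
        pixel_size_um = DEFAULT_PIXEL_SIZE_UM
        log.warning("%s: no pixel size metadata; assuming %.4f um/px", path, pixel_size_um)
    if dwell_time_us is None:
        dwell_time_us = DEFAULT_DWELL_TIME_US
        log.warning("%s: no dwell time metadata; assuming %.1f us/px", path, dwell_time_us)

    f, b, t = (np.asarray(p, np.float64) for p in pages)
    return MultichannelScan(f, b, t, float(pixel_size_um), float(dwell_time_us))


def write_mask_png(path: str | Path, mask: np.ndarray) -> Path:
    """Write a binary mask as an 8-bit PNG (255 = foreground)."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask_png(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> RoiMask:
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any color/alpha channels
        arr = arr[..., 0]
    return RoiMask(arr > 0, pixel_size_um)


def normalize_dwell_time(scan: MultichannelScan) -> MultichannelScan:
    """Divide every channel by the dwell time, yielding counts per us.

    Idempotent: the returned scan carries ``dwell_time_us = 1``.
    """
    d = scan.dwell_time_us
    if d <= 0:
        raise ValueError("dwell_time_us must be positive")
    return MultichannelScan(
        scan.forward_shg / d,
        scan.backward_shg / d,
        scan.tpef / d,
        scan.pixel_size_um,
        1.0,
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # x is nonnegative here; round-half-away-from-zero == floor(x + 0.5)
    return np.floor(x + 0.5)


def preprocess_for_ridges(
    scan: MultichannelScan,
    roi: RoiMask,
    blur_radius_px: float = 1.0,
    shg_channel: str = "backward_shg",
) -> np.ndarray:
    """Blur, ROI-restrict, and convert one SHG channel to 8 bits.

    A Gaussian blur (sigma = ``blur_radius_px``) suppresses shot noise;
    pixels outside the ROI are zeroed; the [min, max] intensity range over
    the ROI is then mapped linearly onto [0, 255] with round-half-away-from-
    zero. A constant ROI maps to all zeros. The mapping is monotone, so
    contrast ordering inside the ROI is preserved.

    Returns a ``uint8`` raster ready for :func:`shgmorph.ridges.detect_ridges`.
    """
    if blur_radius_px < 0:
        raise ValueError("blur_radius_px must be >= 0")
    if scan.shape != roi.mask.shape:
        raise ValueError("scan and ROI shapes differ")
    img = np.asarray(scan.channel(shg_channel), np.float64)
    if blur_radius_px > 0:
        img = gaussian_filter(img, blur_radius_px)
    inside = roi.mask
    vals = img[inside]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros(img.shape, np.uint8)
    if hi > lo:
        scaled = _round_half_away(255.0 * (img[inside] - lo) / (hi - lo))
        out[inside] = np.clip(scaled, 0, 255).astype(np.uint8)
    return out
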