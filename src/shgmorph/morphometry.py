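"""Hybrid fiber mask, ECM pore extraction, and the six per-sample readouts.

The collagen fiber mask is the union of (a) the rasterized ridge-detected
fibers and (b) a strict median threshold of the SHG signal inside the
lamina-propria ROI. Pores are the 8-connected components of the inverted
mask within the ROI; each pore's outer boundary is extracted by
Moore-Neighbor tracing with Jacob's stopping criterion and its area is the
pixel count times the pixel area.

Per-sample readouts (:class:`MorphometrySummary`):

- mean fiber width (um): unweighted mean of per-fiber mean widths
- fiber coverage (%): mask pixels / ROI pixels
- SHG/TPEF ratio: mean backward-SHG over mask / mean TPEF over mask
- F/B ratio: mean forward-SHG over mask / mean backward-SHG over mask
- mean pore area (um^2)
- pore density (pores / mm^2 of ROI)

Because pores are defined as the exact complement of the mask, fiber
coverage and total pore fraction sum to 1 in pixel units for every sample.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_erosion, find_objects, gaussian_filter, label

from .imaging import (
    MultichannelScan,
    RoiMask,
    normalize_dwell_time,
    preprocess_for_ridges,
)
from .ridges import Fiber, RidgeParams, detect_ridges, rasterize_fibers

_EIGHT = np.ones((3, 3), int)


@dataclasses.dataclass(frozen=True)
class FiberMask:
    """Binary collagen mask restricted to the ROI."""

    mask: np.ndarray
    roi: RoiMask
    source: str = "union"  # {ridge, threshold, union}

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, bool)
        object.__setattr__(self, "mask", m & self.roi.mask)

    @property
    def coverage_pct(self) -> float:
        return 100.0 * int(self.mask.sum()) / self.roi.n_pixels


@dataclasses.dataclass
class Pore:
    """One connected void region with its traced outer boundary."""

    boundary: np.ndarray  # ordered (row, col) pixel path, closed circuit
    area_um2: float
    touches_border: bool


@dataclasses.dataclass
class PoreSet:
    pores: list[Pore]
    pixel_size_um: float

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([p.area_um2 for p in self.pores])

    def __len__(self) -> int:
        return len(self.pores)


def build_fiber_mask(ridge_raster: np.ndarray, shg_image: np.ndarray, roi: RoiMask) -> FiberMask:
    """Union of the ridge raster and a strict median threshold of the SHG.

    Threshold mask: ROI pixels with SHG strictly above the median over the
    ROI (strict, so a constant ROI contributes no threshold pixels). The
    returned mask always contains ``ridge_raster & roi``.
    """
    if ridge_raster.shape != roi.mask.shape or shg_image.shape != roi.mask.shape:
        raise ValueError("ridge raster, SHG image and ROI must share shape")
    med = float(np.median(shg_image[roi.mask]))
    thresh = (shg_image > med) & roi.mask
    union = (np.asarray(ridge_raster, bool) | thresh) & roi.mask
    return FiberMask(union, roi, source="union")


def mean_fiber_width(fibers: Sequence[Fiber]) -> float:
    """Unweighted mean of per-fiber mean widths (um).

    Raises on an empty list: a sample with no detected fibers carries an
    undefined width readout and must be flagged, not silently zeroed.
    """
    if len(fibers) == 0:
        raise ValueError("no fibers: mean fiber width undefined")
    widths = np.array([f.mean_width_um for f in fibers])
    widths = widths[np.isfinite(widths)]
    if widths.size == 0:
        raise ValueError("no finite per-fiber widths")
    return float(widths.mean())


def fiber_coverage(mask: FiberMask) -> float:
    """Percentage of ROI pixels inside the fiber mask."""
    return mask.coverage_pct


def intensity_ratio(numerator: np.ndarray, denominator: np.ndarray, mask: FiberMask) -> float:
    """Ratio of channel means over the fiber mask (ratio-of-means)."""
    m = mask.mask
    if not m.any():
        raise ValueError("empty fiber mask: ratio undefined")
    num = float(np.asarray(numerator, float)[m].mean())
    den = float(np.asarray(denominator, float)[m].mean())
    if den == 0:
        raise ValueError("zero-mean denominator: ratio undefined")
    return num / den


# ---------------------------------------------------------------------------
# Moore-Neighbor boundary tracing

# clockwise Moore neighborhood starting from W (left)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def moore_trace(component: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a connected foreground region.

    Standard Moore-Neighbor tracing: start from the first foreground pixel
    in row-major order (entered from its left, which is background by
    construction) and walk the 8-neighborhood clockwise from the backtrack
    pixel. Termination follows Jacob's stopping criterion in its loop-safe
    form (stop when the first boundary transition recurs). Returns the
    ordered closed (row, col) circuit; a single-pixel region yields that
    pixel.
    """
    comp = np.asarray(component, bool)
    rs, cs = np.nonzero(comp)
    if rs.size == 0:
        return np.empty((0, 2), int)
    start = (int(rs[0]), int(cs[0]))
    H, W = comp.shape

    def fg(p):
        r, c = p
        return 0 <= r < H and 0 <= c < W and comp[r, c]

    boundary = [start]
    cur = start
    backtrack = (start[0], start[1] - 1)  # background left of the start
    # Jacob's stopping criterion, in its loop-safe form: terminate when the
    # first boundary transition (next pixel, entered with the same
    # backtrack) recurs. The naive "start re-entered from the original
    # direction" form can fail to trigger on one-pixel-wide regions.
    first_state: tuple | None = None
    max_steps = 8 * (rs.size + 2)
    for _ in range(max_steps):
        k0 = _MOORE_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        nxt = None
        prev = backtrack
        for d in range(1, 9):
            off = _MOORE[(k0 + d) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if fg(cand):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated single pixel
            break
        state = (nxt, prev)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        boundary.append(nxt)
        cur, backtrack = nxt, prev
    if len(boundary) > 1 and boundary[-1] == start:
        boundary.pop()
    return np.array(boundary, int)


def trace_pores(
    mask: FiberMask,
    min_pore_area_um2: float = 0.0,
    include_border_pores: bool = True,
    trace_boundaries: bool = True,
) -> PoreSet:
    """Extract pores: components of ``ROI AND NOT mask`` under 8-connectivity.

    Each component's outer boundary is Moore-Neighbor traced; its area is
    the pixel count times the pixel area. Components touching the ROI
    border are flagged and, by default, included (excluding them would bias
    mean pore area downward in narrow lamina-propria strips).
    """
    roi = mask.roi
    ps = roi.pixel_size_um
    pore_raster = roi.mask & ~mask.mask
    labels, n = label(pore_raster, structure=_EIGHT)
    if n == 0:
        return PoreSet([], ps)
    border_zone = roi.mask & ~binary_erosion(roi.mask, structure=_EIGHT, border_value=0)
    slices = find_objects(labels)
    counts = np.bincount(labels.ravel())
    pores: list[Pore] = []
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        area = counts[idx] * ps**2
        comp = labels[sl] == idx
        touches = bool((comp & border_zone[sl]).any())
        if area < min_pore_area_um2:
            continue
        if not include_border_pores and touches:
            continue
        if trace_boundaries:
            b = moore_trace(comp)
            b[:, 0] += sl[0].start
            b[:, 1] += sl[1].start
        else:
            b = np.empty((0, 2), int)
        pores.append(Pore(boundary=b, area_um2=float(area), touches_border=touches))
    return PoreSet(pores, ps)


def pore_stats(pores: PoreSet, roi: RoiMask) -> tuple[float, float]:
    """(mean pore area in um^2, pore density in pores/mm^2).

    Zero pores: mean is NaN (undefined, to be flagged by the caller),
    density is 0.
    """
    n = len(pores)
    density = n / roi.area_mm2
    mean_area = float(pores.areas_um2.mean()) if n else float("nan")
    return mean_area, density


@dataclasses.dataclass
class MorphometrySummary:
    """The six per-sample readouts plus bookkeeping counts and flags."""

    mean_fiber_width_um: float
    fiber_coverage_pct: float
    shg_tpef_ratio: float
    fb_ratio: float
    mean_pore_area_um2: float
    pore_density_per_mm2: float
    n_fibers: int
    n_pores: int
    lp_area_mm2: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flags"] = ";".join(self.flags)
        return d


@dataclasses.dataclass
class MorphometryConfig:
    """Pipeline stage options for one sample."""

    blur_radius_px: float = 1.0
    shg_channel: str = "backward_shg"
    ridge: RidgeParams = dataclasses.field(default_factory=RidgeParams)
    min_pore_area_um2: float = 0.0
    include_border_pores: bool = True
    trace_boundaries: bool = True


def summarize_sample(
    scan: MultichannelScan,
    roi: RoiMask,
    config: MorphometryConfig | None = None,
) -> MorphometrySummary:
    """Run the full per-sample pipeline: preprocess -> detect -> mask ->
    ratios -> pores. Deterministic for fixed inputs and configuration."""
    config = config or MorphometryConfig()
    scan_n = normalize_dwell_time(scan)
    img8 = preprocess_for_ridges(scan_n, roi, config.blur_radius_px, config.shg_channel)

    ridge_params = dataclasses.replace(config.ridge, prior_blur_sigma_px=config.blur_radius_px)
    fibers = detect_ridges(img8, ridge_params, scan.pixel_size_um)
    ridge_raster = rasterize_fibers(fibers, scan_n.shape, scan.pixel_size_um)

    # median threshold operates on the blurred, dwell-normalized SHG channel
    shg = np.asarray(scan_n.channel(config.shg_channel), float)
    if config.blur_radius_px > 0:
        shg = gaussian_filter(shg, config.blur_radius_px)
    fmask = build_fiber_mask(ridge_raster, shg, roi)

    flags: list[str] = []
    try:
        width = mean_fiber_width(fibers)
    except ValueError:
        width = float("nan")
        flags.append("no_fibers")
    try:
        shg_tpef = intensity_ratio(scan_n.backward_shg, scan_n.tpef, fmask)
        fb = intensity_ratio(scan_n.forward_shg, scan_n.backward_shg, fmask)
    except ValueError:
        shg_tpef = fb = float("nan")
        flags.append("undefined_ratio")

    pores = trace_pores(
        fmask,
        min_pore_area_um2=config.min_pore_area_um2,
        include_border_pores=config.include_border_pores,
        trace_boundaries=config.trace_boundaries,
    )
    mean_pore, density = pore_stats(pores, roi)
    if not len(pores):
        flags.append("no_pores")

    return MorphometrySummary(
        mean_fiber_width_um=width,
        fiber_coverage_pct=fmask.coverage_pct,
        shg_tpef_ratio=shg_tpef,
        fb_ratio=fb,
        mean_pore_area_um2=mean_pore,
        pore_density_per_mm2=density,
        n_fibers=len(fibers),
        n_pores=len(pores),
        lp_area_mm2=roi.area_mm2,
        flags=tuple(flags),
    )


def pores_to_frame(pores: PoreSet):
    """One row per pore: pore_id, area_um2, touches_border."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pore_id": np.arange(len(pores)),
            "area_um2": [p.area_um2 for p in pores.pores],
            "touches_border": [p.touches_border for p in pores.pores],
        }
    )
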