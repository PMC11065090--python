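"""Curvilinear fiber detection and width estimation (Steger's method).

Collagen fibers appear in SHG images as bright curvilinear ridges. Steger's
line detector models them locally as 1-D profiles and finds, per pixel, the
sub-pixel location where the first directional derivative across the line
vanishes while the second directional derivative is strongly negative.

Pipeline:

1. Gaussian-derivative responses (first and second order) at scale
   ``sigma_px`` derived from the expected line width.
2. Hessian eigen-decomposition per pixel; the eigenvector of the
   largest-magnitude eigenvalue is the line normal, and that eigenvalue is
   the second directional derivative across the line (salience when
   negative).
3. Sub-pixel line point where the first derivative along the normal is zero
   within +/-0.5 px of the pixel center.
4. Salience thresholding with hysteresis (seed points above the upper
   threshold, grown through points above the lower threshold), linking into
   ordered polylines that split at junctions.
5. Per-point line width from the distance between the flanking
   gradient-magnitude maxima along the normal, with a line-model bias
   correction (widths measured on a Gaussian-smoothed image overestimate the
   underlying line width by a known amount; see :func:`correct_line_width`).

Widths and lengths are reported in micrometers.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.ndimage import gaussian_filter, label, map_coordinates, spline_filter
from skimage.morphology import skeletonize

from .imaging import DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "RidgeParams",
    "Fiber",
    "linewidth_to_sigma",
    "contrast_to_salience",
    "correct_line_width",
    "detect_ridges",
    "rasterize_fibers",
    "fibers_to_frame",
    "fiber_summary_frame",
]


def linewidth_to_sigma(linewidth_px: float) -> float:
    """Derivative scale for a given expected line width.

    Uses the standard parameterization ``sigma = w / (2*sqrt(3)) + 0.5``,
    which places the detector at its canonical operating point for lines of
    full width ``w`` pixels (6 px -> sigma ~= 2.2321 px).
    """
    if linewidth_px <= 0:
        raise ValueError("linewidth_px must be positive")
    return linewidth_px / (2.0 * math.sqrt(3.0)) + 0.5


def contrast_to_salience(contrast: float, linewidth_px: float, sigma_px: float) -> float:
    """Map an 8-bit contrast threshold to a second-derivative salience.

    For a bar line of height ``h`` and width ``w`` the peak second-derivative
    response at scale sigma is ``2 h (w/2) / (sqrt(2 pi) sigma^3) *
    exp(-(w/2)^2 / (2 sigma^2))``; thresholds specified as gray-level
    contrasts are converted through this model.
    """
    half = linewidth_px / 2.0
    return (
        2.0
        * contrast
        * half
        / (math.sqrt(2.0 * math.pi) * sigma_px**3)
        * math.exp(-(half**2) / (2.0 * sigma_px**2))
    )


def correct_line_width(measured_px: np.ndarray, sigma_eff_px: float, floor_px: float = 0.4) -> np.ndarray:
    """Undo the Gaussian-smoothing bias of flank-to-flank width measurements.

    A line with Gaussian cross-section of inflection-to-inflection width
    ``w = 2 s`` observed through total Gaussian smoothing ``sigma_eff`` has
    its gradient-magnitude flank maxima at ``+/- sqrt(s^2 + sigma_eff^2)``,
    i.e. a measured width ``d = sqrt(w^2 + 4 sigma_eff^2)``. The inverse,
    ``w = sqrt(d^2 - 4 sigma_eff^2)``, is exact for that line model.
    Unresolvable measurements (``d <= 2 sigma_eff``) are floored.
    """
    d2 = np.square(measured_px) - 4.0 * sigma_eff_px**2
    return np.sqrt(np.maximum(d2, floor_px**2))


@dataclasses.dataclass
class RidgeParams:
    """Detector configuration.

    ``upper_contrast``/``lower_contrast`` (8-bit gray levels) give absolute
    salience thresholds via the bar-line model; when ``None`` (default) the
    thresholds adapt per image: the upper threshold is the
    ``upper_quantile`` quantile of the salience over candidate line points
    and the lower threshold is ``lower_fraction`` of it.
    """

    linewidth_px: float = 6.0
    upper_contrast: float | None = None
    lower_contrast: float | None = None
    #: adaptive seeding keeps any ridge component whose salience reaches the
    #: upper threshold; junction splitting isolates individual fibers, so an
    #: aggressive quantile would drop whole wide (low-curvature) fibers
    upper_quantile: float = 0.70
    lower_fraction: float = 0.5
    min_fiber_length_px: float = 5.0
    correct_width: bool = True
    #: sigma of any blur applied upstream of the detector (added in
    #: quadrature to the detector's own sigma in the width correction).
    prior_blur_sigma_px: float = 0.0
    #: centerline points dropped at each polyline end before width
    #: statistics (junction neighborhoods corrupt flank search).
    width_end_trim: int = 3
    #: flank-asymmetry ratio beyond which a point's width is discarded.
    max_flank_asymmetry: float = 1.5

    def __post_init__(self) -> None:
        if self.linewidth_px <= 0:
            raise ValueError("linewidth_px must be positive")
        if self.upper_contrast is not None and self.lower_contrast is not None:
            if not (0 <= self.lower_contrast <= self.upper_contrast <= 255):
                raise ValueError("need 0 <= lower_contrast <= upper_contrast <= 255")
        if not (0 < self.upper_quantile <= 1):
            raise ValueError("upper_quantile must be in (0, 1]")
        if not (0 < self.lower_fraction <= 1):
            raise ValueError("lower_fraction must be in (0, 1]")

    @property
    def sigma_px(self) -> float:
        return linewidth_to_sigma(self.linewidth_px)

    @property
    def sigma_eff_px(self) -> float:
        return math.hypot(self.sigma_px, self.prior_blur_sigma_px)


@dataclasses.dataclass
class Fiber:
    """One detected curvilinear ridge.

    ``centerline`` is an ordered array of sub-pixel (row, col) points;
    ``point_widths_um`` holds the per-point width estimates (NaN where the
    flank search was rejected); ``mean_width_um`` averages the valid ones.
    """

    centerline: np.ndarray
    point_widths_um: np.ndarray
    mean_width_um: float
    length_um: float

    def __post_init__(self) -> None:
        if len(self.centerline) < 2:
            raise ValueError("a fiber needs at least two centerline points")


# ---------------------------------------------------------------------------
# line-point extraction


def _line_points(image: np.ndarray, sigma: float):
    """Gaussian-derivative field, per-pixel normals, salience and offsets."""
    f = np.asarray(image, np.float64)
    r_r = gaussian_filter(f, sigma, order=(1, 0))
    r_c = gaussian_filter(f, sigma, order=(0, 1))
    r_rr = gaussian_filter(f, sigma, order=(2, 0))
    r_cc = gaussian_filter(f, sigma, order=(0, 2))
    r_rc = gaussian_filter(f, sigma, order=(1, 1))

    mean = 0.5 * (r_rr + r_cc)
    disc = np.sqrt(np.square(0.5 * (r_rr - r_cc)) + np.square(r_rc))
    lam1 = mean + disc
    lam2 = mean - disc
    lam = np.where(np.abs(lam1) >= np.abs(lam2), lam1, lam2)

    # eigenvector of lam: (r_rc, lam - r_rr), with fallbacks for the
    # degenerate diagonal case; ties broken toward the row axis.
    vr = r_rc.copy()
    vc = lam - r_rr
    norm = np.hypot(vr, vc)
    degen = norm < 1e-12
    # diagonal Hessian: the eigenvector is the axis whose diagonal entry
    # the eigenvalue matches; exact ties fall back to the row axis
    row_axis = np.abs(lam - r_rr) <= np.abs(lam - r_cc)
    vr = np.where(degen & row_axis, 1.0, vr)
    vc = np.where(degen & row_axis, 0.0, vc)
    vr = np.where(degen & ~row_axis, 0.0, vr)
    vc = np.where(degen & ~row_axis, 1.0, vc)
    norm = np.hypot(vr, vc)
    vr /= norm
    vc /= norm

    with np.errstate(divide="ignore", invalid="ignore"):
        t = -(r_r * vr + r_c * vc) / lam
        t = np.where(np.abs(lam) > 1e-12, t, np.inf)
        off_r = np.where(np.isfinite(t), t * vr, np.inf)
        off_c = np.where(np.isfinite(t), t * vc, np.inf)

    # Acceptance bound slightly above the textbook 0.5 px: with exactly 0.5
    # a near-45-degree or near-axis line can yield rows whose every pixel
    # rejects the sub-pixel point, breaking the ridge into fragments; the
    # wider band is re-thinned by skeletonization before linking.
    is_line = (lam < 0) & (np.abs(off_r) <= 0.75) & (np.abs(off_c) <= 0.75)
    salience = np.where(is_line, -lam, 0.0)
    grad_mag = np.hypot(r_r, r_c)
    return is_line, salience, vr, vc, off_r, off_c, grad_mag


_EIGHT = np.ones((3, 3), int)


def _hysteresis(salience: np.ndarray, low: float, high: float) -> np.ndarray:
    """Keep components of (salience >= low) containing a pixel >= high."""
    low_mask = salience >= low
    if not low_mask.any():
        return low_mask
    labels, n = label(low_mask, structure=_EIGHT)
    seeds = np.unique(labels[salience >= high])
    seeds = seeds[seeds > 0]
    keep = np.zeros(n + 1, bool)
    keep[seeds] = True
    return keep[labels]


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_polylines(skel: np.ndarray) -> list[list[tuple[int, int]]]:
    """Order skeleton pixels into polylines, splitting at junctions."""
    coords = np.argwhere(skel)
    pixset = {tuple(p) for p in map(tuple, coords)}
    neighbors: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for p in pixset:
        r, c = p
        nb = [(r + dr, c + dc) for dr, dc in _NEIGH if (r + dr, c + dc) in pixset]
        neighbors[p] = nb
    junctions = {p for p, nb in neighbors.items() if len(nb) >= 3}
    avail = pixset - junctions
    # neighbor lists restricted to non-junction pixels
    nb2 = {p: [q for q in neighbors[p] if q in avail] for p in avail}

    visited: set[tuple[int, int]] = set()
    chains: list[list[tuple[int, int]]] = []

    def walk(start: tuple[int, int]) -> list[tuple[int, int]]:
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = None
            cands = [q for q in nb2[cur] if q not in visited]
            if not cands:
                break
            if len(cands) > 1:
                # prefer 4-adjacent continuation, then continuation of the
                # current travel direction
                if len(chain) >= 2:
                    dr = cur[0] - chain[-2][0]
                    dc = cur[1] - chain[-2][1]
                    cands.sort(
                        key=lambda q: (
                            -(dr * (q[0] - cur[0]) + dc * (q[1] - cur[1])),
                            abs(q[0] - cur[0]) + abs(q[1] - cur[1]),
                        )
                    )
                else:
                    cands.sort(key=lambda q: abs(q[0] - cur[0]) + abs(q[1] - cur[1]))
            nxt = cands[0]
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        return chain

    endpoints = sorted(p for p in avail if len(nb2[p]) <= 1)
    for p in endpoints:
        if p not in visited:
            chains.append(walk(p))
    for p in sorted(avail):  # remaining loops
        if p not in visited:
            chains.append(walk(p))
    return [c for c in chains if len(c) >= 2]


def _flank_widths(
    grad_mag: np.ndarray,
    points: np.ndarray,
    normals: np.ndarray,
    sigma: float,
    step: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each line point to the first gradient-magnitude maximum
    along +normal and -normal (search range 2.5 sigma each side)."""
    radii = np.arange(0.2, 2.5 * sigma + step, step)
    n_pts = len(points)
    dists = np.empty((2, n_pts))
    profiles = []
    # cubic-spline sampling: piecewise-linear interpolation snaps flank
    # maxima onto the pixel grid, which quantizes widths noticeably
    coeffs = spline_filter(grad_mag, order=3)
    for sign in (1.0, -1.0):
        rr = points[:, 0:1] + sign * normals[:, 0:1] * radii[None, :]
        cc = points[:, 1:2] + sign * normals[:, 1:2] * radii[None, :]
        prof = map_coordinates(
            coeffs, [rr.ravel(), cc.ravel()], order=3, mode="nearest", prefilter=False
        )
        profiles.append(prof.reshape(n_pts, len(radii)))

    for k, prof in enumerate(profiles):
        # first strict local maximum along the ray; fall back to global max
        left = prof[:, 1:-1] > prof[:, :-2]
        right = prof[:, 1:-1] >= prof[:, 2:]
        is_max = left & right
        any_max = is_max.any(axis=1)
        first = np.where(any_max, is_max.argmax(axis=1) + 1, prof.argmax(axis=1))
        # parabolic sub-step refinement where the neighborhood allows it
        j = first
        interior = (j >= 1) & (j <= len(radii) - 2)
        jm = np.clip(j - 1, 0, None)
        jp = np.clip(j + 1, None, len(radii) - 1)
        idx = np.arange(n_pts)
        y0, y1, y2 = prof[idx, jm], prof[idx, j], prof[idx, jp]
        denom = y0 - 2.0 * y1 + y2
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (y0 - y2) / denom
        delta = np.where(interior & (np.abs(denom) > 1e-12), np.clip(delta, -0.5, 0.5), 0.0)
        dists[k] = radii[j] + delta * step
    return dists[0], dists[1]


def detect_ridges(
    image: np.ndarray,
    params: RidgeParams | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[Fiber]:
    """Detect bright curvilinear fibers in an 8-bit preprocessed raster.

    Returns one :class:`Fiber` per linked centerline (split at junctions),
    each carrying sub-pixel centerline coordinates and per-point width
    estimates in micrometers. A blank or structureless image yields an
    empty list.
    """
    params = params or RidgeParams()
    img = np.asarray(image, np.float64)
    if img.size == 0 or img.max() == img.min():
        return []
    sigma = params.sigma_px

    is_line, salience, vr, vc, off_r, off_c, grad_mag = _line_points(img, sigma)
    if not is_line.any():
        return []

    if params.upper_contrast is not None:
        high = contrast_to_salience(params.upper_contrast, params.linewidth_px, sigma)
        low_contrast = (
            params.lower_contrast
            if params.lower_contrast is not None
            else params.upper_contrast / 2.0
        )
        low = contrast_to_salience(low_contrast, params.linewidth_px, sigma)
    else:
        vals = salience[is_line]
        high = float(np.quantile(vals, params.upper_quantile))
        low = params.lower_fraction * high
    keep = _hysteresis(np.where(is_line, salience, 0.0), low, high)
    if not keep.any():
        return []

    skel = skeletonize(keep)
    chains = _trace_polylines(skel)
    if not chains:
        return []

    # gather all retained pixels, compute sub-pixel points and widths in bulk
    all_px = np.array([p for chain in chains for p in chain])
    rr, cc = all_px[:, 0], all_px[:, 1]
    on_line = is_line[rr, cc]
    pts = all_px.astype(np.float64)
    pts[on_line, 0] += off_r[rr, cc][on_line]
    pts[on_line, 1] += off_c[rr, cc][on_line]
    normals = np.column_stack([vr[rr, cc], vc[rr, cc]])

    t_plus, t_minus = _flank_widths(grad_mag, pts, normals, sigma)
    measured = t_plus + t_minus
    asym = np.maximum(t_plus, t_minus) / np.maximum(np.minimum(t_plus, t_minus), 1e-9)
    if params.correct_width:
        widths_px = correct_line_width(measured, params.sigma_eff_px)
    else:
        widths_px = measured
    widths_px = np.where(asym <= params.max_flank_asymmetry, widths_px, np.nan)
    widths_um = widths_px * pixel_size_um

    fibers: list[Fiber] = []
    pos = 0
    for chain in chains:
        n = len(chain)
        cl = pts[pos : pos + n]
        w = widths_um[pos : pos + n].copy()
        pos += n
        seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
        length_px = float(seg.sum())
        if length_px < params.min_fiber_length_px:
            continue
        trim = params.width_end_trim
        if n > 2 * trim + 1 and trim > 0:
            w[:trim] = np.nan
            w[-trim:] = np.nan
        valid = np.isfinite(w)
        mean_w = float(np.nanmean(w)) if valid.any() else float("nan")
        fibers.append(
            Fiber(
                centerline=cl,
                point_widths_um=w,
                mean_width_um=mean_w,
                length_um=length_px * pixel_size_um,
            )
        )
    return fibers


def rasterize_fibers(
    fibers: list[Fiber],
    shape: tuple[int, int],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> np.ndarray:
    """Stroke each centerline at its local width; return the union raster.

    Each centerline is resampled densely and a disk of radius half the local
    width (in pixels) is painted at every sample; NaN point widths fall back
    to the fiber's mean width.
    """
    out = np.zeros(shape, bool)
    H, W = shape
    disk_cache: dict[int, np.ndarray] = {}

    def disk(radius_px: float) -> tuple[np.ndarray, int]:
        # quantize stamp radii to 1/4 px; cache the offset disks
        q = max(int(round(radius_px * 4)), 1)
        if q not in disk_cache:
            r = q / 4.0
            k = int(math.ceil(r))
            yy, xx = np.mgrid[-k : k + 1, -k : k + 1]
            # open inequality: pixel-center-in-open-band convention, matching
            # a dense polygon fill of the stroke outline
            disk_cache[q] = yy * yy + xx * xx < r * r
        return disk_cache[q], disk_cache[q].shape[0] // 2

    for fib in fibers:
        cl = fib.centerline
        w_um = fib.point_widths_um.copy()
        fallback = fib.mean_width_um if np.isfinite(fib.mean_width_um) else pixel_size_um
        w_um = np.where(np.isfinite(w_um), w_um, fallback)
        radii_px = np.maximum(w_um / pixel_size_um / 2.0, 0.5)
        # dense resampling along arc length
        seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        n_samp = max(int(total / 0.7) + 1, 2)
        si = np.linspace(0.0, total, n_samp)
        pr = np.rint(np.interp(si, s, cl[:, 0])).astype(int)
        pc = np.rint(np.interp(si, s, cl[:, 1])).astype(int)
        rad = np.interp(si, s, radii_px)
        for r0, c0, rd in zip(pr, pc, rad):
            stamp, k = disk(rd)
            r_lo, r_hi = r0 - k, r0 + k + 1
            c_lo, c_hi = c0 - k, c0 + k + 1
            sr_lo, sc_lo = max(-r_lo, 0), max(-c_lo, 0)
            sr_hi = stamp.shape[0] - max(r_hi - H, 0)
            sc_hi = stamp.shape[1] - max(c_hi - W, 0)
            if sr_lo >= sr_hi or sc_lo >= sc_hi:
                continue
            out[max(r_lo, 0) : min(r_hi, H), max(c_lo, 0) : min(c_hi, W)] |= stamp[
                sr_lo:sr_hi, sc_lo:sc_hi
            ]
    return out


def fibers_to_frame(fibers: list[Fiber]):
    """Long-format table: one row per centerline point."""
    import pandas as pd

    rows = []
    for i, fib in enumerate(fibers):
        for j, ((r, c), w) in enumerate(zip(fib.centerline, fib.point_widths_um)):
            rows.append((i, j, r, c, w))
    return pd.DataFrame(rows, columns=["fiber_id", "point", "row", "col", "width_um"])


def fiber_summary_frame(fibers: list[Fiber]):
    """One row per fiber: mean width and length in micrometers."""
    import pandas as pd

    return pd.DataFrame(
        {
            "fiber_id": np.arange(len(fibers)),
            "mean_width_um": [f.mean_width_um for f in fibers],
            "length_um": [f.length_um for f in fibers],
        }
    )
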