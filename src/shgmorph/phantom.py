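"""Synthetic SHG phantoms and cohorts with exact ground truth.

No imaging data were deposited with the study this package emulates, so
every downstream stage is exercised on synthetic scenes with known fiber and
pore ground truth.

Two scene generators are provided:

``generate_fiber_phantom``
    Random smooth curves (or straight segments) with Gaussian cross-section.
    The planted "width" of a fiber is the inflection-to-inflection width of
    its Gaussian profile, i.e. exactly the quantity a Steger-style line
    detector estimates, which makes detector recovery well-posed.

``generate_mesh_phantom``
    Fibers laid along the edges of a Voronoi tessellation, so the enclosed
    cells form a controllable pore structure. Used by the cohort generator,
    where mean pore area is the headline group effect.

``generate_cohort`` draws per-sample phantom parameters around per-group
targets for the morphometric readouts, plus peak eosinophil counts (PEC,
negative-binomial) and ordinal EoEHSS histology features (truncated
discretized normals), all coupled to one latent severity variable so that
rank correlations between imaging readouts and histology carry signal.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np
from scipy.ndimage import label
from scipy.interpolate import CubicSpline
from scipy.spatial import Voronoi, cKDTree

from .imaging import (
    DEFAULT_DWELL_TIME_US,
    DEFAULT_PIXEL_SIZE_UM,
    MultichannelScan,
    RoiMask,
)
from .stats import EOEHSS_FEATURES, HistopathologyScores

_EIGHT = np.ones((3, 3), int)

#: intensity support cutoff for the Gaussian cross-section, in units of the
#: profile sigma; beyond this the rendered intensity is exactly zero.
_SUPPORT_SIGMA = 4.0
#: fraction of the forward-SHG signal bleeding into the TPEF channel.
_TPEF_BLEED = 0.05


@dataclasses.dataclass
class PhantomParams:
    """Scene parameters for the random-curve phantom.

    Intensities are photon rates (counts per pixel per microsecond);
    recorded channels accumulate ``rate * dwell_time`` counts, Poisson-drawn
    when ``noise_model="poisson"``.
    """

    image_size: int = 1024
    field_width_um: float = 381.0
    n_fibers: int = 40
    fiber_width_mean_um: float = 2.23
    fiber_width_sd_um: float = 0.3
    orientation_kappa: float = 0.0
    fiber_intensity: float = 30.0
    background_tpef: float = 3.0
    fb_intensity_ratio: float = 2.0
    noise_model: Literal["none", "poisson"] = "none"
    curvature: float = 0.12
    roi_mode: Literal["full", "polygon"] = "full"
    dwell_time_us: float = DEFAULT_DWELL_TIME_US
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.fiber_width_mean_um <= 0:
            raise ValueError("fiber_width_mean_um must be positive")
        if self.fiber_width_sd_um < 0:
            raise ValueError("fiber_width_sd_um must be >= 0")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        for name in ("fiber_intensity", "background_tpef", "fb_intensity_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fb_intensity_ratio == 0:
            raise ValueError("fb_intensity_ratio must be positive")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError("noise_model must be 'none' or 'poisson'")

    @property
    def pixel_size_um(self) -> float:
        return self.field_width_um / self.image_size


@dataclasses.dataclass
class MeshPhantomParams:
    """Scene parameters for the Voronoi-mesh phantom (pore-controlled)."""

    image_size: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    pore_density_per_mm2: float = 10000.0
    fiber_width_mean_um: float = 2.1
    fiber_width_sd_um: float = 0.15
    fiber_intensity: float = 30.0
    background_tpef: float = 3.0
    fb_intensity_ratio: float = 2.0
    noise_model: Literal["none", "poisson"] = "none"
    dwell_time_us: float = DEFAULT_DWELL_TIME_US
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.pore_density_per_mm2 <= 0:
            raise ValueError("pore_density_per_mm2 must be positive")
        if self.fiber_width_mean_um <= 0:
            raise ValueError("fiber_width_mean_um must be positive")
        if self.fiber_width_sd_um < 0:
            raise ValueError("fiber_width_sd_um must be >= 0")


@dataclasses.dataclass
class SyntheticSample:
    """A synthetic scan plus exact ground truth.

    ``truth_pore_areas_um2`` are the areas of the 8-connected components of
    ``NOT truth_fiber_mask`` inside the ROI, so truth coverage and truth pore
    fraction sum to 1 exactly in pixel units.
    """

    scan: MultichannelScan
    roi: RoiMask
    truth_fiber_mask: np.ndarray
    truth_widths_um: np.ndarray
    truth_pore_areas_um2: np.ndarray
    sample_id: str = "sample"


# ---------------------------------------------------------------------------
# rendering helpers


def _render_from_samples(
    size: int,
    sample_pts: np.ndarray,
    sample_sigma_px: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a unit-amplitude fiber field from dense centerline samples.

    Every pixel takes its intensity from the nearest centerline sample
    (``exp(-d^2 / 2 s^2)``), which combines crossing fibers by maximum
    rather than by sum, keeping planted widths meaningful at crossings.
    Returns (intensity in [0, 1], truth mask of pixels within one profile
    sigma, i.e. half the planted width, of a centerline).
    """
    intensity = np.zeros((size, size))
    mask = np.zeros((size, size), bool)
    if len(sample_pts) == 0:
        return intensity, mask
    tree = cKDTree(sample_pts)
    yy, xx = np.mgrid[0:size, 0:size]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)
    dist, idx = tree.query(pix, workers=-1)
    s = sample_sigma_px[idx]
    inside = dist <= _SUPPORT_SIGMA * s
    vals = np.zeros(len(pix))
    vals[inside] = np.exp(-0.5 * (dist[inside] / s[inside]) ** 2)
    intensity = vals.reshape(size, size)
    mask = (dist <= s).reshape(size, size)
    return intensity, mask


def _polygon_roi(size: int, rng: np.random.Generator, pixel_size_um: float) -> RoiMask:
    """Irregular convex-ish polygon ROI covering most of the tile."""
    from skimage.draw import polygon

    n_vert = 8
    ang = np.sort(rng.uniform(0, 2 * math.pi, n_vert))
    rad = rng.uniform(0.55, 0.95, n_vert) * (size / 2 - 2)
    rr = size / 2 + rad * np.sin(ang)
    cc = size / 2 + rad * np.cos(ang)
    m = np.zeros((size, size), bool)
    pr, pc = polygon(rr, cc, shape=(size, size))
    m[pr, pc] = True
    return RoiMask(m, pixel_size_um)


def _finish_sample(
    params,
    size: int,
    pixel_size: float,
    intensity: np.ndarray,
    truth_mask: np.ndarray,
    widths_um: np.ndarray,
    roi: RoiMask,
    rng: np.random.Generator,
    sample_id: str,
) -> SyntheticSample:
    """Channels, noise, truth pores; shared by both scene generators."""
    fwd_rate = params.fiber_intensity * intensity
    bwd_rate = fwd_rate / params.fb_intensity_ratio
    tpef_rate = params.background_tpef + _TPEF_BLEED * fwd_rate
    dwell = params.dwell_time_us
    if params.noise_model == "poisson":
        fwd = rng.poisson(fwd_rate * dwell).astype(np.float64)
        bwd = rng.poisson(bwd_rate * dwell).astype(np.float64)
        tpef = rng.poisson(tpef_rate * dwell).astype(np.float64)
    else:
        fwd = fwd_rate * dwell
        bwd = bwd_rate * dwell
        tpef = tpef_rate * dwell
    scan = MultichannelScan(fwd, bwd, tpef, pixel_size, dwell)

    pore_raster = roi.mask & ~truth_mask
    labels, n = label(pore_raster, structure=_EIGHT)
    if n:
        counts = np.bincount(labels.ravel())[1:]
        pore_areas = counts * pixel_size**2
    else:
        pore_areas = np.empty(0)
    return SyntheticSample(
        scan=scan,
        roi=roi,
        truth_fiber_mask=truth_mask,
        truth_widths_um=np.asarray(widths_um, np.float64),
        truth_pore_areas_um2=np.asarray(pore_areas, np.float64),
        sample_id=sample_id,
    )


def generate_fiber_phantom(params: PhantomParams, sample_id: str = "phantom") -> SyntheticSample:
    """Render ``n_fibers`` random smooth curves with Gaussian cross-section.

    Deterministic for a given (params, seed): the same seed yields
    bit-identical arrays. With ``curvature = 0`` fibers are straight
    segments (the analytic test mode).
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    pixel_size = params.pixel_size_um

    widths_list: list[float] = []
    pts_list = []
    sig_list = []
    for _ in range(params.n_fibers):
        if params.fiber_width_sd_um > 0:
            w = -1.0
            while w < 0.5:
                w = rng.normal(params.fiber_width_mean_um, params.fiber_width_sd_um)
        else:
            w = params.fiber_width_mean_um
        widths_list.append(w)
        s_px = (w / pixel_size) / 2.0  # profile sigma: half the planted width

        if params.orientation_kappa > 0:
            theta = rng.vonmises(0.0, params.orientation_kappa) / 2.0
        else:
            theta = rng.uniform(0, math.pi)
        length = rng.uniform(0.4, 0.9) * size
        start = rng.uniform(0.05 * size, 0.95 * size, 2)
        direction = np.array([math.sin(theta), math.cos(theta)])
        n_ctrl = 5
        chord = np.linspace(0.0, length, n_ctrl)
        lateral = np.zeros(n_ctrl)
        if params.curvature > 0:
            lateral[1:] = np.cumsum(rng.normal(0.0, params.curvature * length / n_ctrl, n_ctrl - 1))
        perp = np.array([-direction[1], direction[0]])
        ctrl = start[None, :] + chord[:, None] * direction[None, :] + lateral[:, None] * perp[None, :]
        spline = CubicSpline(chord, ctrl, axis=0)
        dense_t = np.arange(0.0, length, 0.25)
        dense = spline(dense_t)
        inb = (
            (dense[:, 0] >= -_SUPPORT_SIGMA * s_px)
            & (dense[:, 0] < size + _SUPPORT_SIGMA * s_px)
            & (dense[:, 1] >= -_SUPPORT_SIGMA * s_px)
            & (dense[:, 1] < size + _SUPPORT_SIGMA * s_px)
        )
        dense = dense[inb]
        if len(dense):
            pts_list.append(dense)
            sig_list.append(np.full(len(dense), s_px))

    widths_um = np.asarray(widths_list, np.float64)
    sample_pts = np.concatenate(pts_list) if pts_list else np.empty((0, 2))
    sample_sig = np.concatenate(sig_list) if sig_list else np.empty(0)
    intensity, truth_mask = _render_from_samples(size, sample_pts, sample_sig)

    if params.roi_mode == "polygon":
        roi = _polygon_roi(size, rng, pixel_size)
    else:
        roi = RoiMask.full((size, size), pixel_size)
    return _finish_sample(
        params, size, pixel_size, intensity, truth_mask, widths_um, roi, rng, sample_id
    )


def generate_mesh_phantom(params: MeshPhantomParams, sample_id: str = "mesh") -> SyntheticSample:
    """Render fibers along Voronoi-cell edges.

    Cell seeds are drawn with intensity matching ``pore_density_per_mm2``
    (cells become pores once edges are stroked at the planted fiber width),
    in a padded box so the tessellation has no boundary artifacts inside
    the tile.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    pixel_size = params.pixel_size_um

    lam_px = params.pore_density_per_mm2 * (pixel_size**2) * 1e-6  # cells per px^2
    mean_cell_px = 1.0 / lam_px
    pad = 2.0 * math.sqrt(mean_cell_px)
    lo, hi = -pad, size + pad
    # deterministic seed count (rounded expectation): the planted pore
    # density is a per-sample target, so its between-sample spread must come
    # from the cohort's group effects, not from scene-level count noise
    n_seeds = max(int(round(lam_px * (hi - lo) ** 2)), 4)
    seeds = rng.uniform(lo, hi, (n_seeds, 2))
    vor = Voronoi(seeds)

    pts_list = []
    sig_list = []
    widths = []
    for (i0, i1) in vor.ridge_vertices:
        if i0 < 0 or i1 < 0:
            continue
        p0, p1 = vor.vertices[i0], vor.vertices[i1]
        w = -1.0
        while w < 0.8:
            w = rng.normal(params.fiber_width_mean_um, params.fiber_width_sd_um) if params.fiber_width_sd_um > 0 else params.fiber_width_mean_um
        seg_len = float(np.linalg.norm(p1 - p0))
        if seg_len < 1e-9:
            continue
        n_samp = max(int(seg_len / 0.25) + 1, 2)
        t = np.linspace(0.0, 1.0, n_samp)
        dense = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        s_px = (w / pixel_size) / 2.0
        inb = (
            (dense[:, 0] >= -_SUPPORT_SIGMA * s_px)
            & (dense[:, 0] < size + _SUPPORT_SIGMA * s_px)
            & (dense[:, 1] >= -_SUPPORT_SIGMA * s_px)
            & (dense[:, 1] < size + _SUPPORT_SIGMA * s_px)
        )
        dense = dense[inb]
        if len(dense) >= 2:
            pts_list.append(dense)
            sig_list.append(np.full(len(dense), s_px))
            # the truth width list covers edges visible in the tile proper
            in_tile = (
                (dense[:, 0] >= 0) & (dense[:, 0] < size)
                & (dense[:, 1] >= 0) & (dense[:, 1] < size)
            )
            if in_tile.any():
                widths.append(w)

    sample_pts = np.concatenate(pts_list) if pts_list else np.empty((0, 2))
    sample_sig = np.concatenate(sig_list) if sig_list else np.empty(0)
    intensity, truth_mask = _render_from_samples(size, sample_pts, sample_sig)
    roi = RoiMask.full((size, size), pixel_size)
    return _finish_sample(
        params, size, pixel_size, intensity, truth_mask, np.asarray(widths), roi, rng, sample_id
    )


def ground_truth_metrics(sample: SyntheticSample):
    """Six morphometric readouts computed from ground truth, no detection.

    Uses the same unit conventions as :mod:`shgmorph.morphometry`; intensity
    ratios are computed over the truth fiber mask from the (dwell-
    normalized) recorded channels.
    """
    from .morphometry import MorphometrySummary

    roi = sample.roi
    mask = sample.truth_fiber_mask & roi.mask
    n_mask = int(mask.sum())
    coverage = 100.0 * n_mask / roi.n_pixels
    areas = sample.truth_pore_areas_um2
    n_pores = len(areas)
    mean_pore = float(areas.mean()) if n_pores else float("nan")
    density = n_pores / roi.area_mm2
    widths = sample.truth_widths_um
    mean_width = float(widths.mean()) if len(widths) else float("nan")

    dwell = sample.scan.dwell_time_us
    flags = []
    if n_mask:
        fwd = float(sample.scan.forward_shg[mask].mean()) / dwell
        bwd = float(sample.scan.backward_shg[mask].mean()) / dwell
        tpef = float(sample.scan.tpef[mask].mean()) / dwell
        shg_tpef = bwd / tpef if tpef > 0 else float("nan")
        fb = fwd / bwd if bwd > 0 else float("nan")
    else:
        shg_tpef = fb = float("nan")
        flags.append("empty_truth_mask")
    if not len(widths):
        flags.append("no_fibers")
    if not n_pores:
        flags.append("no_pores")
    return MorphometrySummary(
        mean_fiber_width_um=mean_width,
        fiber_coverage_pct=coverage,
        shg_tpef_ratio=shg_tpef,
        fb_ratio=fb,
        mean_pore_area_um2=mean_pore,
        pore_density_per_mm2=density,
        n_fibers=len(widths),
        n_pores=n_pores,
        lp_area_mm2=roi.area_mm2,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# cohorts

GROUPS = ("aEoE", "iEoE", "nonEoE")


@dataclasses.dataclass
class GroupEffects:
    """Per-group targets for the imaging readouts and histology scores."""

    fiber_width_um: float
    fiber_width_sd_um: float
    pore_area_um2: float
    pore_area_sd_um2: float
    pec_mean: float
    pec_dispersion: float
    eoehss_medians: dict[str, float]
    severity: float  # latent severity center, drives rank correlations


#: Default group effects: fiber width and pore area group means/SDs follow
#: the study's reported values; PEC and EoEHSS medians follow its cohort
#: table; severity centers order the groups aEoE > iEoE > nonEoE.
DEFAULT_GROUP_EFFECTS: dict[str, GroupEffects] = {
    "aEoE": GroupEffects(
        fiber_width_um=2.12, fiber_width_sd_um=0.06,
        pore_area_um2=50.0, pore_area_sd_um2=10.0,
        pec_mean=75.0, pec_dispersion=3.0,
        eoehss_medians=dict(ei=2, bzh=3, ea=1, esl=1, dis=3, sea=0.4, dec=0.4, lpf=2),
        severity=1.2,
    ),
    "iEoE": GroupEffects(
        fiber_width_um=2.09, fiber_width_sd_um=0.07,
        pore_area_um2=33.0, pore_area_sd_um2=5.0,
        pec_mean=3.5, pec_dispersion=1.5,
        eoehss_medians=dict(ei=1, bzh=1, ea=0, esl=0, dis=0.3, sea=0, dec=0, lpf=0.3),
        severity=0.2,
    ),
    "nonEoE": GroupEffects(
        fiber_width_um=2.04, fiber_width_sd_um=0.04,
        pore_area_um2=32.0, pore_area_sd_um2=6.0,
        pec_mean=0.4, pec_dispersion=1.0,
        eoehss_medians=dict(ei=0.2, bzh=0.2, ea=0, esl=0, dis=0, sea=0, dec=0, lpf=0),
        severity=0.0,
    ),
}


@dataclasses.dataclass
class CohortConfig:
    """Synthetic cohort layout: 11 samples per group by default.

    ``image_size`` controls the tile side of each sample's scan; the pixel
    size is fixed at the acquisition calibration, so smaller tiles are
    smaller fields, not coarser sampling.
    """

    n_per_group: int = 11
    group_effects: dict[str, GroupEffects] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    image_size: int = 512
    noise_model: Literal["none", "poisson"] = "poisson"
    fiber_intensity: float = 30.0
    background_tpef: float = 3.0
    fb_intensity_ratio: float = 2.0
    #: rank-coupling strength between the latent severity and each readout
    severity_coupling: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (group statistics undefined below)")
        if set(self.group_effects) != set(GROUPS):
            raise ValueError(f"group_effects must cover exactly {GROUPS}")
        for g, eff in self.group_effects.items():
            for name in ("fiber_width_um", "pore_area_um2", "pec_mean"):
                if getattr(eff, name) < 0:
                    raise ValueError(f"{g}.{name} must be nonnegative")
            for feat, m in eff.eoehss_medians.items():
                if not (0 <= m <= 3):
                    raise ValueError(f"{g}.eoehss_medians[{feat}] must be in [0, 3]")


def _pore_density_for_targets(
    pore_area_um2: float, roi_area_um2: float, roi_perimeter_um: float
) -> float:
    """Cell intensity (per mm^2) so the pipeline's median-threshold porosity
    readout lands near the target mean pore area.

    On a clean scene whose intensity decreases monotonically with distance
    from the nearest fiber, the strict median threshold keeps exactly half
    the ROI as fibers, so mean pore area ~= 0.5 / realized pore density.
    The realized density exceeds the cell intensity lam because cells
    straddling the window boundary are counted as (truncated) pores: for a
    Poisson-Voronoi tessellation observed through a convex window of area A
    and perimeter P the expected intersecting-cell count is about
    ``lam A + sqrt(lam) P / (2 sqrt(pi)) + 1``. Solving the resulting
    quadratic in sqrt(lam) calibrates the seed intensity for the window.
    """
    a = pore_area_um2
    A = roi_area_um2
    P = roi_perimeter_um
    # a * (u^2 + u * P/(2 sqrt(pi) A) + 1/A) = 0.5, with u = sqrt(lam)
    b = P / (2.0 * math.sqrt(math.pi) * A)
    c = 1.0 / A - 0.5 / a
    u = (-b + math.sqrt(b * b - 4.0 * c)) / 2.0
    return (u * u) * 1e6


def _draw_ordinal(rng: np.random.Generator, median: float, z: float, spread: float = 0.7) -> int:
    v = rng.normal(median + 0.7 * z, spread)
    return int(np.clip(round(v), 0, 3))


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SyntheticSample], list[HistopathologyScores]]:
    """Draw a full synthetic cohort: phantoms plus histology scores.

    Per sample, a latent severity ``z`` perturbs the group's targets for
    fiber width and pore area (correlation ``severity_coupling``), drives
    the PEC draw (log-scale shift of a negative-binomial mean) and the
    EoEHSS ordinal draws, and tilts the F/B ratio against fiber width.
    """
    config = config or CohortConfig()
    master = np.random.default_rng(config.seed)
    seeds = master.spawn(len(GROUPS) * config.n_per_group)

    samples: list[SyntheticSample] = []
    scores: list[HistopathologyScores] = []
    k = 0
    for group in GROUPS:
        eff = config.group_effects[group]
        for i in range(config.n_per_group):
            rng = seeds[k]
            k += 1
            sample_id = f"{group}_{i:02d}"
            z = rng.normal()
            rho = config.severity_coupling
            mix = lambda: rho * z + math.sqrt(max(1 - rho**2, 0.0)) * rng.normal()
            w_i = max(eff.fiber_width_um + eff.fiber_width_sd_um * mix(), 1.0)
            a_i = max(eff.pore_area_um2 + eff.pore_area_sd_um2 * mix(), 8.0)
            fb_i = max(config.fb_intensity_ratio * (1.0 - 0.12 * mix()), 0.3)

            side_um = config.image_size * DEFAULT_PIXEL_SIZE_UM
            params = MeshPhantomParams(
                image_size=config.image_size,
                pore_density_per_mm2=_pore_density_for_targets(
                    a_i, side_um**2, 4.0 * side_um
                ),
                fiber_width_mean_um=w_i,
                fiber_width_sd_um=0.15,
                fiber_intensity=config.fiber_intensity,
                background_tpef=config.background_tpef * (1.0 + 0.15 * (eff.severity + 0.4 * z)),
                fb_intensity_ratio=fb_i,
                noise_model=config.noise_model,
                seed=int(rng.integers(2**31 - 1)),
            )
            samples.append(generate_mesh_phantom(params, sample_id))

            # histology: NB counts for PEC, truncated discretized normals
            # for ordinal features, both shifted by the latent severity
            pec_mean = max(eff.pec_mean * math.exp(0.4 * z), 0.05)
            r = eff.pec_dispersion
            p = r / (r + pec_mean)
            pec = int(rng.negative_binomial(r, p))
            feats = {
                f: _draw_ordinal(rng, eff.eoehss_medians[f], z) for f in EOEHSS_FEATURES
            }
            scores.append(HistopathologyScores(sample_id=sample_id, group=group, pec=pec, **feats))
    return samples, scores


def cohort_config_from_yaml(path) -> CohortConfig:
    """Load a CohortConfig (including nested group effects) from YAML."""
    import yaml

    data = yaml.safe_load(open(path)) or {}
    if "group_effects" in data:
        data["group_effects"] = {
            g: GroupEffects(**eff) for g, eff in data["group_effects"].items()
        }
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**data)
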