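# Methods

`shgmorph` quantifies structural remodeling of the esophageal lamina propria
(LP) from second-harmonic-generation (SHG) microscopy scans. SHG arises from
non-centrosymmetric fibrillar collagen (types I/II) and provides label-free
collagen contrast; a parallel two-photon fluorescence (TPEF) channel gives
tissue context. The pipeline turns one scan into six morphometric readouts
and a cohort of scans into group comparisons, histology correlations, and a
diagnostic threshold.

## Image model and preprocessing

A sample is a registered triple of rasters — forward-detected SHG,
backward-detected SHG, TPEF — with a physical calibration (default
381/1024 ≈ 0.372 um/px) and a pixel dwell time. Channels are divided by the
dwell time so all intensities are counts per microsecond, making scans
acquired at different speeds comparable.

For fiber detection the backward-SHG channel (the channel used for fiber
segmentation) is Gaussian-blurred (sigma = 1 px by default, against shot
noise), restricted to the LP region-of-interest mask, and linearly rescaled
so the ROI's [min, max] maps onto [0, 255] with round-half-away-from-zero.
Per-image min–max scaling was chosen over a global scale so that detection
contrast behaves comparably across samples of different brightness; the
mapping is monotone, so it cannot reorder intensities. A constant ROI maps
to zero (no structure).

## Fiber detection (Steger's method)

Collagen fibers are bright curvilinear ridges. The detector follows Steger's
construction: Gaussian-derivative responses at scale
`sigma = w/(2*sqrt(3)) + 0.5` for a nominal line width `w` (default 6 px ≈
2.23 um, giving sigma ≈ 2.2321 px); per-pixel Hessian eigen-decomposition;
the eigenvector of the largest-magnitude (negative) eigenvalue is the line
normal; a pixel carries a line point when the first directional derivative
along the normal vanishes within the pixel. The sub-pixel acceptance bound
is 0.75 px rather than the textbook 0.5 px: at exactly 0.5 a near-axis or
near-diagonal ridge can produce rows in which every pixel rejects the
sub-pixel point, fragmenting the ridge; the wider band is re-thinned by
skeletonization before linking, so no spurious parallel lines result.

Salience (the magnitude of the negative eigenvalue) is thresholded with
hysteresis: components of the line-point set above the lower threshold are
kept when they contain a point above the upper threshold. By default the
upper threshold is the 0.70 quantile of salience over line points and the
lower threshold is half of it. The quantile is deliberately modest: linked
lines split at junctions, so each fiber must reach the seed threshold on its
own, and ridge salience falls with increasing line width (wider, flatter
profiles curve less) — an aggressive quantile silently discards the widest
fibers and biases width statistics. Absolute thresholds in 8-bit contrast
units are available through the standard bar-line response model for users
who prefer fixed operating points. Quantile thresholds also make detection
invariant to a rescaling of image contrast.

Kept points are skeletonized and linked into ordered polylines; pixels with
three or more skeleton neighbors are junctions, and chains terminate there
(no merging across crossings). Chains shorter than 5 px are discarded as
single-point noise.

### Width estimation

At each centerline point the gradient magnitude is sampled along the normal
in both directions (cubic-spline interpolation; linear interpolation snaps
flank maxima onto the pixel grid and visibly quantizes widths). The first
local maximum on each side — not the global one, which a neighboring fiber
can capture — marks the line edge; a parabolic refinement gives sub-step
accuracy. The flank-to-flank distance `d` overestimates the line width
because of smoothing: for a line with Gaussian cross-section of
inflection-to-inflection width `W = 2s` observed through total smoothing
`sigma_eff` (detector sigma plus any preprocessing blur, in quadrature), the
flanks sit at `±sqrt(s² + sigma_eff²)`. The estimator inverts that model
exactly: `W = sqrt(d² − 4·sigma_eff²)`. This Gaussian-line inversion
replaces the bar-profile correction tables sometimes used with Steger's
method; it is exact for the package's phantom line model and agrees with
planted widths to ~1–2% on isolated fibers at any orientation (rotation
spread ≤ 2%).

Two robustness rules suppress junction artifacts: points whose two flank
distances differ by more than a factor 1.5 are discarded (a ray crossing a
junction wedge sees one legitimate and one inflated flank), and three points
at each chain end — the junction neighborhoods — are excluded from width
statistics. A fiber's width is the mean of its remaining point widths; a
sample's fiber-width readout is the unweighted mean over fibers.

## Fiber mask, pores, and the six readouts

The binary collagen mask is the union of (a) the detected centerlines
stroked at their local widths and (b) the pixels strictly above the median
SHG intensity within the ROI. The strict inequality means a featureless
(constant) ROI contributes no threshold pixels rather than declaring 100%
collagen. Pores are the 8-connected components of the inverted mask inside
the ROI; each outer boundary is extracted by Moore-Neighbor tracing. The
stopping rule is Jacob's criterion in its loop-safe form — terminate when
the first boundary transition recurs — because the naive "start re-entered
from the initial direction" form fails to trigger on one-pixel-wide regions.
Pore areas are pixel counts times the pixel area; pores touching the ROI
border are flagged but included by default (excluding them biases mean pore
area downward in narrow LP strips; the flag lets either policy be
reproduced). No minimum pore size is applied by default; a configurable
cutoff exists.

Per sample the pipeline reports: mean fiber width (um); fiber coverage
(mask pixels / ROI pixels, %); SHG/TPEF ratio and forward/backward (F/B)
SHG ratio, both computed as ratios of channel means over the mask pixels of
the dwell-normalized raw channels (ratio-of-means is robust to zero-valued
denominator pixels, unlike mean-of-ratios); mean pore area (um²); and pore
density (pores per mm² of ROI). Because pores are defined as the exact mask
complement, coverage/100 + total pore fraction ≡ 1 in pixel units — an
identity the tests verify to machine precision. Degenerate inputs are
flagged rather than zeroed: a blank scene yields an undefined fiber width,
0% coverage, and one ROI-sized pore.

## Synthetic phantoms and the cohort generator

No clinical scans accompany this package, so every stage is validated on
synthetic scenes with exact ground truth.

**Random-curve phantoms** render smooth piecewise-cubic curves (or straight
segments for analytic tests) with a Gaussian cross-section. The planted
"width" is defined as the inflection-to-inflection width of that profile —
precisely the quantity the ridge detector estimates — which makes parameter
recovery well-posed. Overlapping fibers combine by maximum (nearest-
centerline rule), not addition, so the planted width remains meaningful at
crossings. Forward SHG is the profile times a brightness; backward SHG is
forward divided by the planted F/B ratio; TPEF is a diffuse background plus
5% bleed-through of the forward signal. With Poisson noise enabled, each
channel draws photon counts at `rate × dwell time`. All randomness flows
from one seed; identical parameters give bit-identical scenes.

**Voronoi-mesh phantoms** lay fibers along the edges of a Poisson-Voronoi
tessellation, so the enclosed cells become pores with controllable area and
count. This is the cohort scene model: ECM porosity is the headline group
effect, and a mesh makes it steerable. The seed intensity is calibrated
analytically: on a clean scene whose intensity decreases monotonically with
distance from the nearest fiber, the strict median threshold keeps exactly
half the ROI, so the measured mean pore area is ~0.5 divided by the realized
pore density; the realized density exceeds the seed intensity by the
expected number of cells straddling the window boundary
(`sqrt(lam)·P/(2·sqrt(pi)) + 1` for a convex window with perimeter P).
The seed count is the rounded expectation rather than a Poisson draw, so the
between-sample spread of the porosity readouts comes from the cohort's
planted group effects alone, matching their role as between-sample SDs.
Inverting this chain reproduces target mean pore areas within ~2–4% through
the full pipeline at 256 px tiles.

**Cohorts** default to 11 samples per group for the three groups: active
EoE (aEoE), inactive EoE (iEoE), and non-EoE controls. Default group
targets: fiber width 2.12/2.09/2.04 um (SD 0.06/0.07/0.04), mean pore area
50/33/32 um² (SD 10/5/6); printed SDs are treated as between-sample SDs.
A per-sample latent severity couples (correlation 0.7) the imaging targets
to the histology draws: peak eosinophil count (PEC, eos/hpf with hpf =
0.237 mm²) from a negative-binomial with group means ~75/3.5/0.4 and a
log-scale severity shift, and the eight EoEHSS ordinal features (graded
0–3) from truncated discretized normals centered on the group medians
(e.g., basal-zone hyperplasia 3/1/0, LP fibrosis 2/0/0). Negative-binomial
counts and truncated normals were chosen to match the right-skewed,
zero-inflated shape of such cohort tables. The F/B ratio tilts against
fiber width (wider bundles scatter more forward-to-backward imbalance into
the backward channel), giving the negative width–F/B association real data
show.

Because the median-threshold rule pins measured coverage near 50% on these
clean scenes, the generator steers fiber width and mean pore area and lets
pore density and coverage follow from the complement identity; the group
*ordering* of density (lowest in aEoE) and coverage is preserved, but their
absolute levels are tied to mean pore area rather than independently
steerable. Real biopsy images, with non-monotone intensity textures, break
that tie; synthetic passes therefore validate the measurement chain and the
statistics, not the independent steerability of all six readouts.

What the phantoms do not emulate: optics (no point-spread function,
polarization dependence, or depth attenuation), tissue heterogeneity
(uniform fiber brightness up to noise), stitching artifacts, epithelium or
muscularis structures in the TPEF channel, and sectioning artifacts.

## Statistics

Group comparisons use classical one-way ANOVA (equal-variance, mirroring
the standard design for three-group morphometry) with Tukey
honestly-significant-difference pairwise p-values from the
studentized-range distribution; the tests verify these against a
permutation null of the maximum studentized range. Associations between
imaging readouts and histology (PEC, BZH, LPF, total EoEHSS = mean of the
eight feature grades) use Spearman rank correlation with average ranks for
ties; p-values use the t-approximation by default, with a permutation
option for small cohorts. No multiplicity correction is applied across the
correlation matrix (readouts are reported with conventional star
thresholds). Diagnostic accuracy of a chosen readout (default: mean pore
area) uses the empirical ROC curve; AUC is the trapezoid rule (identical to
the Mann-Whitney U statistic scaled by the group sizes, which the tests
assert to 1e-12). The operating threshold maximizes Youden's J
(sensitivity + specificity − 1) over midpoints between adjacent distinct
values, with ties broken toward higher specificity; a fixed
maximum-specificity rule is available since the selection rule behind a
single published threshold is often unstated.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts at 256 px tiles
(the acquisition pixel size with a smaller field) and detector checks at
512 px; these sizes keep a full run in minutes while leaving ~50–130 pores
and ~60–100 fibers per tile, enough that per-sample measurement noise stays
well below the planted between-sample spread. Width-recovery checks use
noise-free scenes and no pre-blur, isolating estimator accuracy from
denoising. Flank search covers 2.5 sigma each side at 0.1 px steps.
Unresolvable width measurements (`d ≤ 2 sigma_eff`) are floored at 0.4 px
and excluded from fiber means via the asymmetry filter when junction-driven.
Eigen-decomposition ties (isotropic Hessian) fall back to the row axis.

## Known limitations

- Widths below ~2 sigma_eff (≈1.4 um at default settings) approach the
  resolution floor of the flank-based estimator.
- The per-fiber unweighted mean overweights short junction fragments in
  dense meshes; end-trimming and the asymmetry filter mitigate but do not
  eliminate this.
- Coverage and pore density are not independently steerable in the mesh
  generator (see above).
- ROC operating points from 11-vs-11 cohorts are inherently coarse
  (sensitivity quantized to 1/11); single-run thresholds should be read
  with that granularity in mind.
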