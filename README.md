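# shgmorph

Morphometric analysis of second-harmonic-generation (SHG) microscopy images
of the esophageal lamina propria, for quantifying fibrotic remodeling in
eosinophilic esophagitis (EoE).

## The problem

Lamina propria fibrosis (LPF) — pathologic remodeling of the collagen
matrix beneath the esophageal epithelium — drives the fibrostenotic
complications of EoE, but its clinical assessment rests on a pathologist's
visual grading of stained sections, which is subjective and inconsistent
between observers. SHG microscopy images fibrillar collagen directly and
label-free: collagen's non-centrosymmetric structure emits light at exactly
half the excitation wavelength, so the collagen fiber network of the lamina
propria can be mapped at sub-micron resolution and *measured* instead of
eyeballed.

`shgmorph` implements that measurement chain for researchers working with
multiphoton scans of mucosal biopsies:

1. **Fiber detection** — Steger's curvilinear ridge detector (Gaussian
   derivatives, Hessian eigen-analysis, sub-pixel line points, hysteresis
   linking) run at a line width of 6 px ≈ 2.23 um on the backward-SHG
   channel, with per-point line widths estimated from the flanking
   gradient maxima and corrected for smoothing bias:
   `W = sqrt(d² − 4σ_eff²)` for a Gaussian line profile.
2. **Fiber mask and ECM pores** — the detected fibers, stroked at their
   measured widths, are united with a strict median threshold of the SHG
   signal in the lamina-propria ROI; the mask complement is decomposed
   into pores by 8-connected labeling with Moore-Neighbor boundary
   tracing.
3. **Six per-sample readouts** — mean fiber width (um), fiber coverage
   (%), SHG/TPEF ratio, forward/backward (F/B) SHG ratio, mean pore area
   (um²), pore density (pores/mm²).
4. **Cohort statistics** — one-way ANOVA with Tukey HSD pairwise
   comparisons across {active EoE, inactive EoE, non-EoE}; Spearman rank
   correlations against histology (peak eosinophil count, EoEHSS feature
   grades, total EoEHSS); ROC analysis of the headline readout with a
   Youden-index operating threshold.

Because no imaging data ship with the package, a synthetic-phantom module
generates scenes with exact ground truth — random curvilinear fibers for
detector validation, and Voronoi-mesh scenes (fibers enclosing pores) for
full cohorts with planted group effects, coupled histology scores, and
Poisson photon noise. Every stage of the pipeline is tested against that
ground truth or against independent brute-force oracles.

## Worked example

Detect fibers in a noise-free phantom with a planted width of 2.23 um
(`examples/01_detect_fibers_in_phantom.py`):

```
planted fibers : 6 at width 2.23 um
detected fibers: 9
mean detected width: 2.187 um
fiber lengths (um): [15.3, 20.9, 38.4, 44.4, 45.6, 53.7, 67.1, 71.7, 155.8]
```

Nine detections from six planted fibers: fibers cross, and linked lines
split at junctions as they do in tissue. The mean detected width lands
within 2% of the planted 2.23 um.

Simulate a 33-sample cohort and run the group statistics
(`examples/03_cohort_statistics.py`, ~2 min):

```
group means:
        mean_fiber_width_um  mean_pore_area_um2  pore_density_per_mm2
group
aEoE                   2.14               50.69              10491.17
iEoE                   2.06               31.08              15902.09
nonEoE                 2.04               31.32              16262.82

Tukey-adjusted p, mean pore area:
  aEoE vs iEoE: p = 0.0000
  aEoE vs nonEoE: p = 0.0000
  iEoE vs nonEoE: p = 0.9977

Spearman r vs histology:
  mean_pore_area_um2: r(PEC) = +0.60, r(LPF) = +0.64
  pore_density_per_mm2: r(PEC) = -0.60, r(LPF) = -0.64
  mean_fiber_width_um: r(PEC) = +0.56, r(LPF) = +0.58

ROC of mean pore area:
      contrast  auc  threshold  sensitivity_pct  specificity_pct
  aEoE_vs_iEoE 0.91      39.62            81.82            100.0
aEoE_vs_nonEoE 0.90      41.29            81.82            100.0
```

Read: pores in active EoE are enlarged (~51 vs ~31 um²) and sparser than in
inactive disease or controls; pore area rises and pore density falls with
eosinophil burden and fibrosis grade; and a pore-area threshold near
40 um² separates active from inactive disease with 81.8% sensitivity and
100% specificity. The p-values are Tukey-adjusted for the three pairwise
contrasts.

## Command-line use

```bash
shgmorph simulate --out-dir cohort --n-per-group 11 --image-size 512 --seed 0
shgmorph run --base-dir cohort --out-dir cohort/run
shgmorph process cohort/aEoE_00.tiff --roi cohort/aEoE_00_roi.png
shgmorph stats results.csv cohort.csv --out-dir stats_out
```

`run` writes per-sample results (`results.csv`), the statistics tables
(`group_comparisons.csv`, `correlations.csv`, `roc.csv`), a failures
manifest for any unreadable samples, and `run_summary.json`; the resolved
configuration is saved next to the outputs so a run can be reproduced
exactly. Real biopsy scans enter the same way: 3-page grayscale TIFFs
(forward SHG, backward SHG, TPEF) plus a PNG mask of the lamina propria.

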