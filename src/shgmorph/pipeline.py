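"""Batch orchestration: simulate a cohort to disk, process scans, report.

File layout written by :func:`simulate` and consumed by :func:`run_pipeline`:

- ``<sample_id>.tiff``      3-page scan (forward-SHG, backward-SHG, TPEF)
- ``<sample_id>_roi.png``   binary lamina-propria ROI
- ``cohort.csv``            sample_id, group, pec, eight EoEHSS columns
- ``manifest.csv``          sample_id, tiff_path, roi_path, group
- ``config.yaml``           resolved configuration, for reproducibility

``run_pipeline`` processes every manifest row, writes ``results.csv`` (one
MorphometrySummary row per sample), the statistics tables
(``group_comparisons.csv``, ``correlations.csv``, ``roc.csv``) and
``run_summary.json``. Failures on individual samples are recorded in
``failures.csv`` without aborting the batch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imaging import (
    DEFAULT_DWELL_TIME_US,
    DEFAULT_PIXEL_SIZE_UM,
    read_mask_png,
    read_scan,
    write_mask_png,
    write_scan,
)
from .morphometry import MorphometryConfig, summarize_sample
from .phantom import CohortConfig, generate_cohort
from .ridges import RidgeParams
from .stats import run_cohort_analysis, scores_to_frame

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration for one batch run."""

    manifest: str = "manifest.csv"
    cohort_table: str = "cohort.csv"
    out_dir: str = "run"
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    dwell_time_us: float = DEFAULT_DWELL_TIME_US
    blur_radius_px: float = 1.0
    shg_channel: str = "backward_shg"
    linewidth_px: float = 6.0
    min_fiber_length_px: float = 5.0
    correct_width: bool = True
    min_pore_area_um2: float = 0.0
    include_border_pores: bool = True
    roc_metric: str = "mean_pore_area_um2"
    threshold_rule: str = "youden"
    spearman_method: str = "t"
    seed: int = 0

    def morphometry_config(self) -> MorphometryConfig:
        return MorphometryConfig(
            blur_radius_px=self.blur_radius_px,
            shg_channel=self.shg_channel,
            ridge=RidgeParams(
                linewidth_px=self.linewidth_px,
                min_fiber_length_px=self.min_fiber_length_px,
                correct_width=self.correct_width,
            ),
            min_pore_area_um2=self.min_pore_area_um2,
            include_border_pores=self.include_border_pores,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def simulate(config: CohortConfig | None, out_dir: str | Path) -> pd.DataFrame:
    """Write a synthetic cohort to disk; returns the manifest table."""
    config = config or CohortConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, scores = generate_cohort(config)

    rows = []
    for sample in samples:
        tiff = out / f"{sample.sample_id}.tiff"
        roi_png = out / f"{sample.sample_id}_roi.png"
        write_scan(tiff, sample.scan)
        write_mask_png(roi_png, sample.roi.mask)
        write_mask_png(out / f"{sample.sample_id}_truth_fibers.png", sample.truth_fiber_mask)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "tiff_path": tiff.name,
                "roi_path": roi_png.name,
                "group": sample.sample_id.rsplit("_", 1)[0],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    scores_to_frame(scores).to_csv(out / "cohort.csv", index=False)

    cfg = dataclasses.asdict(config)
    cfg["group_effects"] = {g: dataclasses.asdict(e) for g, e in config.group_effects.items()}
    (out / "cohort_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return manifest


def process_samples(
    manifest: pd.DataFrame,
    base_dir: str | Path,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run morphometry on every manifest row; returns (results, failures)."""
    base = Path(base_dir)
    mconfig = config.morphometry_config()
    results = []
    failures = []
    for row in manifest.itertuples(index=False):
        t0 = time.perf_counter()
        try:
            scan = read_scan(base / row.tiff_path)
            roi = read_mask_png(base / row.roi_path, scan.pixel_size_um)
            summary = summarize_sample(scan, roi, mconfig)
            rec = {"sample_id": row.sample_id, "group": row.group}
            rec.update(summary.to_dict())
            results.append(rec)
            log.info(
                "%s: width=%.3f um, coverage=%.1f%%, pore=%.1f um^2 (%.2fs)",
                row.sample_id,
                summary.mean_fiber_width_um,
                summary.fiber_coverage_pct,
                summary.mean_pore_area_um2,
                time.perf_counter() - t0,
            )
        except Exception as exc:  # keep the batch alive, record the failure
            log.error("%s: %s", row.sample_id, exc)
            failures.append({"sample_id": row.sample_id, "error": str(exc)})
    return pd.DataFrame(results), pd.DataFrame(failures)


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> int:
    """Process a full cohort and write per-sample plus cohort outputs.

    Returns 0 when at least one sample processed and the statistics stage
    completed; 1 on a hard (batch-level) error.
    """
    base = Path(base_dir)
    out = Path(config.out_dir)
    if not out.is_absolute():
        out = base / out
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    manifest_path = base / config.manifest
    if not manifest_path.exists():
        log.error("manifest not found: %s", manifest_path)
        return 1
    manifest = pd.read_csv(manifest_path)
    required = {"sample_id", "tiff_path", "roi_path", "group"}
    if not required.issubset(manifest.columns):
        log.error("manifest missing columns: %s", sorted(required - set(manifest.columns)))
        return 1

    results, failures = process_samples(manifest, base, config)
    if len(failures):
        failures.to_csv(out / "failures.csv", index=False)
    if results.empty:
        log.error("no sample processed successfully")
        return 1
    results.to_csv(out / "results.csv", index=False)

    summary: dict = {
        "n_samples": int(len(results)),
        "n_failures": int(len(failures)),
        "seed": config.seed,
    }
    status = 0
    cohort_path = base / config.cohort_table
    if cohort_path.exists():
        try:
            histo = pd.read_csv(cohort_path)
            report = run_cohort_analysis(
                results,
                histo,
                roc_metric=config.roc_metric,
                threshold_rule=config.threshold_rule,
                spearman_method=config.spearman_method,
                seed=config.seed,
            )
            report.comparisons_frame().to_csv(out / "group_comparisons.csv", index=False)
            report.correlations.to_csv(out / "correlations.csv", index=False)
            report.rocs_frame().to_csv(out / "roc.csv", index=False)
            summary["roc"] = report.rocs_frame().to_dict(orient="records")
            summary["group_means"] = {
                c.metric: c.group_means for c in report.comparisons
            }
        except Exception as exc:  # partial per-sample results are preserved
            log.error("statistics stage failed: %s", exc)
            summary["statistics_error"] = str(exc)
            status = 1
    else:
        log.warning("no cohort table at %s; statistics stage skipped", cohort_path)
    (out / "run_summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    return status


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
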