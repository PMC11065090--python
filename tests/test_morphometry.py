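import numpy as np
import pytest
from scipy.ndimage import label

import shgmorph as sm
from shgmorph.morphometry import FiberMask, MorphometryConfig, moore_trace

from conftest import PS, mesh_sample


def full_roi(size=16):
    return sm.RoiMask.full((size, size), PS)


def fiber(widths_um, n=10):
    cl = np.column_stack([np.full(n, 5.0), np.arange(n, dtype=float)])
    w = np.full(n, float(np.mean(widths_um)))
    return sm.Fiber(cl, w, float(np.mean(widths_um)), (n - 1) * PS)


class TestFiberMask:
    def test_median_threshold_oracle(self):
        # half the ROI at 10, half at 20; median 15 -> mask = bright half
        size = 16
        shg = np.full((size, size), 10.0)
        shg[:, size // 2 :] = 20.0
        mask = sm.build_fiber_mask(np.zeros((size, size), bool), shg, full_roi(size))
        assert mask.coverage_pct == pytest.approx(50.0)
        assert mask.mask[:, size // 2 :].all()
        assert not mask.mask[:, : size // 2].any()

    def test_constant_shg_gives_ridge_only_mask(self):
        size = 16
        ridges = np.zeros((size, size), bool)
        ridges[3:5, :] = True
        mask = sm.build_fiber_mask(ridges, np.full((size, size), 4.0), full_roi(size))
        np.testing.assert_array_equal(mask.mask, ridges)

    def test_union_contains_ridge_raster(self):
        rng = np.random.default_rng(0)
        size = 32
        ridges = rng.random((size, size)) < 0.2
        shg = rng.uniform(0, 50, (size, size))
        roi_mask = rng.random((size, size)) < 0.8
        roi_mask[0, 0] = True
        roi = sm.RoiMask(roi_mask, PS)
        mask = sm.build_fiber_mask(ridges, shg, roi)
        assert np.all(mask.mask[ridges & roi.mask])


class TestReadouts:
    def test_mean_fiber_width_is_unweighted(self):
        assert sm.mean_fiber_width([fiber([2.0]), fiber([2.0]), fiber([2.0])]) == 2.0
        # unweighted across fibers regardless of fiber length
        assert sm.mean_fiber_width([fiber([1.0], n=5), fiber([3.0], n=500)]) == 2.0

    def test_mean_fiber_width_empty_flags(self):
        with pytest.raises(ValueError):
            sm.mean_fiber_width([])

    def test_coverage_extremes(self):
        roi = full_roi(4)
        assert sm.fiber_coverage(FiberMask(np.ones((4, 4), bool), roi)) == 100.0
        quarter = np.zeros((2, 2), bool)
        quarter[0, 0] = True
        roi2 = sm.RoiMask.full((2, 2), PS)
        assert sm.fiber_coverage(FiberMask(quarter, roi2)) == 25.0

    def test_intensity_ratio_basics(self):
        size = 8
        mask = FiberMask(np.ones((size, size), bool), full_roi(size))
        assert sm.intensity_ratio(np.full((size, size), 7.0), np.full((size, size), 7.0), mask) == 1.0
        assert sm.intensity_ratio(np.full((size, size), 10.0), np.full((size, size), 5.0), mask) == 2.0
        with pytest.raises(ValueError):
            sm.intensity_ratio(np.ones((size, size)), np.zeros((size, size)), mask)

    def test_pore_stats(self):
        pores = sm.PoreSet(
            [sm.Pore(np.empty((0, 2), int), a, False) for a in (10.0, 20.0, 30.0)], PS
        )
        roi = full_roi(16)
        mean, dens = sm.pore_stats(pores, roi)
        assert mean == pytest.approx(20.0)
        assert dens == pytest.approx(3 / roi.area_mm2)
        mean0, dens0 = sm.pore_stats(sm.PoreSet([], PS), roi)
        assert np.isnan(mean0) and dens0 == 0.0


class TestPores:
    def test_full_mask_zero_pores(self):
        roi = full_roi(16)
        pores = sm.trace_pores(FiberMask(np.ones((16, 16), bool), roi))
        assert len(pores) == 0

    def test_square_hole_area(self):
        size = 64
        mask = np.ones((size, size), bool)
        mask[20:30, 20:30] = False
        pores = sm.trace_pores(FiberMask(mask, full_roi(size)))
        assert len(pores) == 1
        assert pores.pores[0].area_um2 == pytest.approx(100 * PS**2)
        assert not pores.pores[0].touches_border

    def test_diagonal_holes_are_one_pore(self):
        size = 16
        mask = np.ones((size, size), bool)
        mask[5, 5] = False
        mask[6, 6] = False
        pores = sm.trace_pores(FiberMask(mask, full_roi(size)))
        assert len(pores) == 1

    def test_border_pore_flagged_and_excludable(self):
        size = 16
        mask = np.ones((size, size), bool)
        mask[0:3, 4:8] = False
        fm = FiberMask(mask, full_roi(size))
        pores = sm.trace_pores(fm)
        assert len(pores) == 1 and pores.pores[0].touches_border
        assert len(sm.trace_pores(fm, include_border_pores=False)) == 0

    def test_min_pore_area_filter(self):
        size = 32
        mask = np.ones((size, size), bool)
        mask[4, 4] = False  # 1 px
        mask[10:20, 10:20] = False  # 100 px
        fm = FiberMask(mask, full_roi(size))
        assert len(sm.trace_pores(fm)) == 2
        assert len(sm.trace_pores(fm, min_pore_area_um2=10 * PS**2)) == 1

    def test_component_count_matches_flood_fill_oracle(self):
        # brute-force fixpoint label propagation as the independent oracle
        rng = np.random.default_rng(42)
        for _ in range(50):
            mask = rng.random((64, 64)) < rng.uniform(0.3, 0.7)
            fm = FiberMask(mask, sm.RoiMask.full((64, 64), PS))
            pores = sm.trace_pores(fm, trace_boundaries=False)
            assert len(pores) == _flood_fill_count(~mask)


def _flood_fill_count(fg: np.ndarray) -> int:
    """8-connected component count by iterated min-label propagation."""
    lab = np.where(fg, np.arange(fg.size, dtype=np.int64).reshape(fg.shape) + 1, 0)
    while True:
        padded = np.pad(lab, 1)
        stacked = np.stack(
            [padded[1 + dr : 1 + dr + fg.shape[0], 1 + dc : 1 + dc + fg.shape[1]]
             for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        )
        stacked = np.where(stacked > 0, stacked, np.iinfo(np.int64).max)
        new = np.where(fg, stacked.min(axis=0), 0)
        if np.array_equal(new, lab):
            break
        lab = new
    return len(np.unique(lab[fg]))


class TestMooreTrace:
    def _valid_circuit(self, boundary, comp):
        pts = [tuple(p) for p in boundary]
        assert all(comp[p] for p in pts)
        if len(pts) > 1:
            closed = pts + [pts[0]]
            steps = np.abs(np.diff(np.array(closed), axis=0)).max(axis=1)
            assert np.all(steps <= 1)  # 8-connected closed circuit

    def test_single_pixel(self):
        comp = np.zeros((3, 3), bool)
        comp[1, 1] = True
        b = moore_trace(comp)
        assert b.tolist() == [[1, 1]]

    def test_solid_square_visits_perimeter(self):
        comp = np.zeros((5, 5), bool)
        comp[1:4, 1:4] = True
        b = moore_trace(comp)
        self._valid_circuit(b, comp)
        expected = {(r, c) for r in range(1, 4) for c in range(1, 4)} - {(2, 2)}
        assert set(map(tuple, b)) == expected

    def test_domino_terminates(self):
        comp = np.zeros((3, 4), bool)
        comp[1, 1:3] = True
        b = moore_trace(comp)
        self._valid_circuit(b, comp)
        assert set(map(tuple, b)) == {(1, 1), (1, 2)}

    def test_random_shapes_boundary_encloses_component(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            mask = rng.random((16, 16)) < 0.45
            labels, n = label(mask, structure=np.ones((3, 3), int))
            for i in range(1, n + 1):
                comp = labels == i
                b = moore_trace(comp)
                self._valid_circuit(b, comp)
                # every component pixel 4-adjacent to the OUTSIDE background
                # (not to an enclosed hole) lies on the traced outer boundary
                padded = np.pad(comp, 1)
                bg_labels, _ = label(~padded, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
                outside = bg_labels == bg_labels[0, 0]
                near_out = (
                    outside[:-2, 1:-1] | outside[2:, 1:-1]
                    | outside[1:-1, :-2] | outside[1:-1, 2:]
                )
                edge = comp & near_out
                traced = set(map(tuple, b))
                assert {tuple(p) for p in np.argwhere(edge)} <= traced


class TestSummarize:
    def test_deterministic(self, mesh_summary):
        summary, sample = mesh_summary
        again = sm.summarize_sample(sample.scan, sample.roi)
        assert summary == again

    def test_blank_scene_contract(self):
        size = 64
        zeros = np.zeros((size, size))
        scan = sm.MultichannelScan(zeros, zeros, np.full((size, size), 5.0), PS, 1.0)
        summary = sm.summarize_sample(scan, sm.RoiMask.full((size, size), PS))
        assert "no_fibers" in summary.flags
        assert np.isnan(summary.mean_fiber_width_um)
        assert summary.fiber_coverage_pct == 0.0
        assert summary.n_pores == 1
        assert summary.mean_pore_area_um2 == pytest.approx(size * size * PS**2)

    def test_complement_identity_machine_precision(self, mesh_summary):
        summary, sample = mesh_summary
        total_pore_frac = (
            summary.mean_pore_area_um2 * summary.n_pores / sample.roi.area_um2
        )
        assert summary.fiber_coverage_pct / 100 + total_pore_frac == pytest.approx(1.0, abs=1e-12)

    def test_scale_consistency(self):
        # doubling pixel size quadruples areas and quarters density
        sample = mesh_sample(size=128, seed=3)
        base = sm.summarize_sample(sample.scan, sample.roi)
        scan2 = sm.MultichannelScan(
            sample.scan.forward_shg,
            sample.scan.backward_shg,
            sample.scan.tpef,
            2 * PS,
            sample.scan.dwell_time_us,
        )
        roi2 = sm.RoiMask(sample.roi.mask, 2 * PS)
        doubled = sm.summarize_sample(scan2, roi2)
        assert doubled.mean_pore_area_um2 == pytest.approx(4 * base.mean_pore_area_um2, rel=1e-6)
        assert doubled.pore_density_per_mm2 == pytest.approx(base.pore_density_per_mm2 / 4, rel=1e-6)
        assert doubled.lp_area_mm2 == pytest.approx(4 * base.lp_area_mm2)
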