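"""Evaluation metrics against brute-force oracles, plus the expert
revision scale and composite accuracy score."""

import numpy as np
import pytest

from selfseg import (
    ContractError,
    LabelMap,
    UndefinedMetricError,
    asd,
    composite_accuracy,
    dsc,
    evaluate_cases,
    evaluate_pair,
    hausdorff,
    hd95,
    revision_score,
    summarize_report,
    surface_points,
)
from tests.conftest import random_mask


def brute_surface(mask):
    """Exhaustive neighbor scan for boundary voxels (face connectivity,
    grid edge counts as background)."""
    pts = []
    for idx in np.argwhere(mask):
        for ax in range(3):
            for d in (-1, 1):
                n = idx.copy()
                n[ax] += d
                if (n < 0).any() or (n >= np.array(mask.shape)).any() \
                        or not mask[tuple(n)]:
                    pts.append(tuple(idx))
                    break
            else:
                continue
            break
    return set(pts)


def brute_distances(pred, ref, spacing):
    sp = np.array(sorted(brute_surface(pred)), float) * spacing
    sg = np.array(sorted(brute_surface(ref)), float) * spacing
    d_pg = [min(np.linalg.norm(p - g) for g in sg) for p in sp]
    d_gp = [min(np.linalg.norm(g - p) for p in sp) for g in sg]
    return np.array(d_pg), np.array(d_gp)


class TestDSC:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dsc(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((1, 1, 8), bool)
        b = np.zeros((1, 1, 8), bool)
        a[0, 0, :4] = True   # |P| = 4
        b[0, 0, 2:6] = True  # |G| = 4, intersection 2
        assert dsc(a, b) == 0.5

    def test_empty_conventions(self):
        e = np.zeros((3, 3, 3), bool)
        f = np.ones((3, 3, 3), bool)
        assert dsc(e, e) == 1.0
        assert dsc(e, f) == 0.0 and dsc(f, e) == 0.0

    def test_symmetry_and_dilation_monotonicity(self, rng):
        from scipy import ndimage
        g = np.zeros((8, 8, 8), bool)
        g[2:6, 2:6, 2:6] = True
        p = np.zeros_like(g)
        p[3:5, 3:5, 3:5] = True
        scores = []
        for _ in range(3):
            assert dsc(p, g) == dsc(g, p)
            scores.append(dsc(p, g))
            p = ndimage.binary_dilation(p) & g  # grow toward G, stay nested
        assert scores == sorted(scores)


class TestSurfacePoints:
    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert surface_points(m, (1, 1, 1)).points.shape == (1, 3)

    def test_3x3x3_block_has_26_surface_voxels(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert len(surface_points(m, (1, 1, 1)).points) == 26

    def test_grid_edge_voxels_are_boundary(self):
        m = np.ones((2, 2, 2), bool)
        assert len(surface_points(m, (1, 1, 1)).points) == 8

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            m = random_mask(rng, (7, 7, 7), p=0.5)
            if not m.any():
                continue
            pts = surface_points(m, (1.0, 1.0, 1.0)).points
            got = {tuple(int(v) for v in p) for p in pts}
            assert got == brute_surface(m)

    def test_empty_mask_raises(self):
        with pytest.raises(UndefinedMetricError):
            surface_points(np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestDistances:
    SPACING = (6.5, 0.664, 0.664)

    def test_identical_masks_are_zero(self, rng):
        m = random_mask(rng, (6, 6, 6))
        m[2, 3, 3] = True
        assert hausdorff(m, m, self.SPACING) == 0.0
        assert hd95(m, m, self.SPACING) == 0.0
        assert asd(m, m, self.SPACING) == 0.0

    def test_single_voxels_three_slices_apart(self):
        a = np.zeros((5, 3, 3), bool)
        b = np.zeros((5, 3, 3), bool)
        a[0, 1, 1] = True
        b[3, 1, 1] = True
        assert hausdorff(a, b, self.SPACING) == pytest.approx(19.5)
        assert asd(a, b, self.SPACING) == pytest.approx(19.5)

    def test_asd_two_points_formula(self):
        a = np.zeros((1, 1, 5), bool)
        b = np.zeros((1, 1, 5), bool)
        a[0, 0, 0] = True
        b[0, 0, 4] = True
        d = 4 * 0.664
        assert asd(a, b, self.SPACING) == pytest.approx(d)

    def test_hd95_bounded_by_hausdorff(self, rng):
        for _ in range(20):
            p = random_mask(rng, (6, 6, 6), p=0.3)
            g = random_mask(rng, (6, 6, 6), p=0.3)
            if not (p.any() and g.any()):
                continue
            assert hd95(p, g, self.SPACING) <= hausdorff(p, g, self.SPACING) + 1e-12

    def test_all_metrics_match_brute_force(self, rng):
        spacing = np.array([2.0, 0.7, 1.3])
        for _ in range(15):
            p = random_mask(rng, (5, 5, 5), p=0.4)
            g = random_mask(rng, (5, 5, 5), p=0.4)
            if not (p.any() and g.any()):
                continue
            d_pg, d_gp = brute_distances(p, g, spacing)
            pooled = np.concatenate([d_pg, d_gp])
            assert hausdorff(p, g, spacing) == pytest.approx(pooled.max(), abs=1e-9)
            assert hd95(p, g, spacing) == pytest.approx(
                np.percentile(pooled, 95), abs=1e-9)
            assert asd(p, g, spacing) == pytest.approx(pooled.mean(), abs=1e-9)

    def test_empty_mask_is_undefined_not_zero(self):
        full = np.ones((3, 3, 3), bool)
        empty = np.zeros((3, 3, 3), bool)
        for fn in (hausdorff, hd95, asd):
            with pytest.raises(UndefinedMetricError):
                fn(full, empty, (1, 1, 1))


class TestRevisionScore:
    @pytest.mark.parametrize("fraction,score", [
        (0.0, 5), (0.1, 4), (0.2, 4), (0.25, 3), (0.30, 3), (0.4, 3),
        (0.5, 2), (0.65, 1), (0.8, 1), (0.81, 0), (1.0, 0),
    ])
    def test_bins(self, fraction, score):
        assert revision_score(fraction) == score

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            revision_score(1.2)


class TestCompositeAccuracy:
    def test_single_organ(self):
        assert composite_accuracy([0.9], [4]) == pytest.approx(1.7)

    def test_upper_bound(self):
        assert composite_accuracy([1.0] * 5, [5] * 5) == pytest.approx(10.0)

    def test_zero_floor(self):
        assert composite_accuracy([0.0] * 4, [0] * 4) == 0.0

    def test_multiple_experts_averaged(self):
        assert composite_accuracy([0.8], [[3, 5]]) == pytest.approx(0.8 + 0.8)

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            composite_accuracy([], [])


class TestReports:
    def test_report_rows_and_summary(self, phantom_case):
        _, lab = phantom_case
        report = evaluate_cases([(lab, lab)])
        assert len(report) == 4
        assert (report["dsc"] == 1.0).all()
        assert (report[["hd_mm", "hd95_mm", "asd_mm"]] == 0.0).all().all()
        summary = summarize_report(report)
        assert len(summary) == 4

    def test_missing_organ_flagged_undefined(self, phantom_case):
        _, lab = phantom_case
        empty = LabelMap(np.zeros_like(lab.data), lab.spacing_mm,
                         case_id="empty")
        rows = evaluate_pair(empty, lab)
        assert all(not r["defined"] for r in rows)
        assert all(r["dsc"] == 0.0 for r in rows)
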