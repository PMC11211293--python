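"""Trunk/branch continuity classification: geometry, coverage, thresholds."""

import numpy as np
import pytest
from scipy import ndimage

from hepavol import (
    Centerline,
    CenterlineError,
    ClassificationResult,
    LabelVolume,
    Structure,
    VesselTree,
    accuracy_table,
    classify_vessel,
    coverage_profile,
    extract_centerline,
    longest_covered_run,
)
from hepavol.phantom import rasterize_capsule
from hepavol.volume import DEFAULT_LABEL_MAP


# ------------------------------------------------------------------ helpers
def straight_line(length=100.0, y=6.0, z=6.0):
    return Centerline(np.array([[0.0, y, z], [length, y, z]]))


def tube_volume(covered_x, shape=(110, 12, 12), y=6, z=6, label="RHV"):
    """Label volume whose vessel mask covers the x-intervals in covered_x."""
    grid = np.zeros(shape, dtype=np.int16)
    for lo, hi in covered_x:
        grid[lo : hi + 1, y - 1 : y + 2, z - 1 : z + 2] = DEFAULT_LABEL_MAP[label]
    return LabelVolume(grid=grid, spacing=(1, 1, 1), label_map=dict(DEFAULT_LABEL_MAP))


def brute_force_longest_run(profile, arc):
    """O(n^2) oracle: scan all index pairs of an all-true stretch."""
    best = 0.0
    n = len(profile)
    for i in range(n):
        for j in range(i, n):
            if all(profile[i : j + 1]):
                best = max(best, arc[j] - arc[i])
    return best


# ------------------------------------------------------------- Centerline
class TestCenterline:
    def test_needs_two_distinct_points(self):
        with pytest.raises(ValueError):
            Centerline(np.array([[0.0, 0, 0]]))
        with pytest.raises(ValueError, match="distinct"):
            Centerline(np.array([[0.0, 0, 0], [0.0, 0, 0]]))

    def test_arc_length_strictly_increasing(self):
        c = Centerline(np.array([[0, 0, 0], [3.0, 0, 0], [3.0, 4.0, 0]]))
        assert np.all(np.diff(c.arc_length) > 0)
        assert c.length == pytest.approx(7.0)

    def test_resample_preserves_endpoints_and_length(self):
        c = Centerline(np.array([[0, 0, 0], [10.0, 0, 0], [10.0, 10.0, 0]]))
        r = c.resample(0.5)
        assert np.allclose(r.points[0], c.points[0])
        assert np.allclose(r.points[-1], c.points[-1])
        assert r.length == pytest.approx(c.length, rel=1e-9)


# ------------------------------------------------------ coverage + runs
class TestCoverage:
    def test_truth_tube_fully_covered(self):
        vol = tube_volume([(0, 100)])
        profile, _ = coverage_profile(straight_line(), vol.mask("RHV"), vol.spacing, 1.0)
        assert profile.all()

    def test_empty_prediction_all_false(self):
        vol = tube_volume([])
        profile, _ = coverage_profile(straight_line(), vol.mask("RHV"), vol.spacing, 1.0)
        assert not profile.any()

    def test_deleted_middle_third(self):
        vol = tube_volume([(0, 32), (67, 100)])
        profile, arc = coverage_profile(
            straight_line(), vol.mask("RHV"), vol.spacing, 0.25
        )
        mid = (arc > 35) & (arc < 64)
        ends = (arc < 30) | (arc > 70)
        assert not profile[mid].any()
        assert profile[ends].all()


class TestLongestRun:
    def test_all_true(self):
        arc = np.linspace(0, 100, 201)
        assert longest_covered_run(np.ones(201, bool), arc) == pytest.approx(100.0)

    def test_two_runs_with_gap(self):
        arc = np.linspace(0, 100, 201)
        profile = (arc <= 40) | (arc >= 60)
        assert longest_covered_run(profile, arc) == pytest.approx(40.0)

    def test_all_false(self):
        arc = np.linspace(0, 100, 201)
        assert longest_covered_run(np.zeros(201, bool), arc) == 0.0

    def test_matches_quadratic_oracle_on_random_profiles(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 200))
            arc = np.cumsum(rng.uniform(0.1, 2.0, n))
            arc -= arc[0]
            profile = rng.random(n) < rng.uniform(0.2, 0.9)
            assert longest_covered_run(profile, arc) == pytest.approx(
                brute_force_longest_run(profile, arc)
            )


# ------------------------------------------------------- classification
def _tree(branches=()):
    return VesselTree(vessel=Structure.RHV, trunk=straight_line(), branches=branches)


class TestClassifyVessel:
    def test_contiguous_80_of_100_is_accurate(self):
        res = classify_vessel(_tree(), tube_volume([(0, 80)]), tolerance_mm=0.25)
        assert res.trunk_accurate
        assert res.branches_accurate is None

    def test_70_of_100_is_not_accurate(self):
        res = classify_vessel(_tree(), tube_volume([(0, 70)]), tolerance_mm=0.25)
        assert not res.trunk_accurate

    def test_continuity_two_runs_of_45_fail_despite_90_total(self):
        res = classify_vessel(
            _tree(), tube_volume([(0, 45), (55, 100)]), tolerance_mm=0.25
        )
        assert not res.trunk_accurate

    def test_exact_three_quarters_threshold_inclusive(self):
        res = classify_vessel(_tree(), tube_volume([(0, 75)]), tolerance_mm=0.25)
        assert res.trunk_accurate

    def test_branch_rule_requires_every_branch(self):
        b1 = Centerline(np.array([[0.0, 3.0, 6.0], [40.0, 3.0, 6.0]]))
        b2 = Centerline(np.array([[0.0, 9.0, 6.0], [40.0, 9.0, 6.0]]))
        tree = VesselTree(vessel=Structure.RHV, trunk=straight_line(), branches=(b1, b2))
        grid = np.zeros((110, 12, 12), dtype=np.int16)
        code = DEFAULT_LABEL_MAP["RHV"]
        grid[0:101, 5:8, 5:8] = code          # trunk fully covered
        grid[0:31, 2:5, 5:8] = code           # b1: 30/40 covered (>= 1/2)
        grid[0:11, 8:11, 5:8] = code          # b2: 10/40 covered (< 1/2)
        vol = LabelVolume(grid=grid, spacing=(1, 1, 1), label_map=dict(DEFAULT_LABEL_MAP))
        res = classify_vessel(tree, vol, tolerance_mm=0.25)
        assert res.trunk_accurate
        assert res.branches_accurate is False
        # covering b2 to half its length flips the branch verdict
        grid2 = grid.copy()
        grid2[0:21, 8:11, 5:8] = code
        vol2 = LabelVolume(grid=grid2, spacing=(1, 1, 1), label_map=dict(DEFAULT_LABEL_MAP))
        assert classify_vessel(tree, vol2, tolerance_mm=0.25).branches_accurate is True

    def test_unknown_label_rejected(self):
        vol = tube_volume([(0, 100)])
        tree = VesselTree(vessel=Structure.LHV, trunk=straight_line())
        lm = {k: v for k, v in DEFAULT_LABEL_MAP.items() if k != "LHV"}
        vol2 = LabelVolume(grid=vol.grid, spacing=vol.spacing, label_map=lm)
        with pytest.raises(KeyError):
            classify_vessel(tree, vol2)

    def test_truth_classifies_accurate_on_phantom(self, phantom):
        for vessel, tree in phantom.trees.items():
            res = classify_vessel(tree, phantom.truth)
            assert res.trunk_accurate, vessel
            if tree.branches:
                assert res.branches_accurate is True
            else:
                assert res.branches_accurate is None

    def test_enlarging_prediction_never_hurts(self, phantom, perturbed):
        """Dilating the predicted mask is monotone for both flags."""
        for vessel in (Structure.RHV, Structure.LPV):
            tree = phantom.trees[vessel]
            before = classify_vessel(tree, perturbed)
            grid = perturbed.grid.copy()
            grown = ndimage.binary_dilation(perturbed.mask(vessel), iterations=2)
            grid[grown & (grid == 0)] = perturbed.code(vessel)
            after = classify_vessel(tree, perturbed.with_grid(grid))
            assert after.trunk_accurate >= before.trunk_accurate
            if tree.branches:
                assert after.branches_accurate >= before.branches_accurate


# --------------------------------------------------- centerline extraction
class TestExtractCenterline:
    def test_axis_aligned_cylinder_length(self):
        mask = np.zeros((50, 13, 13), dtype=bool)
        rasterize_capsule(mask, np.array([5.0, 6, 6]), np.array([45.0, 6, 6]), 3.0, (1, 1, 1))
        line = extract_centerline(mask, (1, 1, 1))
        assert 36.0 <= line.length <= 44.0

    def test_degenerate_mask_rejected(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        with pytest.raises(CenterlineError, match="too small"):
            extract_centerline(mask, (1, 1, 1))

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((20, 8, 8), dtype=bool)
        mask[1:5, 2:5, 2:5] = True
        mask[10:14, 2:5, 2:5] = True
        with pytest.raises(CenterlineError, match="connected component"):
            extract_centerline(mask, (1, 1, 1))

    def test_branched_mask_rejected(self):
        mask = np.zeros((40, 40, 9), dtype=bool)
        sp = (1.0, 1.0, 1.0)
        rasterize_capsule(mask, np.array([3.0, 20, 4]), np.array([36.0, 20, 4]), 2.0, sp)
        rasterize_capsule(mask, np.array([20.0, 20, 4]), np.array([20.0, 36, 4]), 2.0, sp)
        with pytest.raises(CenterlineError, match="branched"):
            extract_centerline(mask, sp)

    def test_curved_tube_length_within_ten_percent(self):
        # quarter arc of radius 25 mm: true length = pi/2 * 25 ~ 39.3 mm
        t = np.linspace(0, np.pi / 2, 24)
        pts = np.column_stack([30 + 25 * np.cos(t), 30 - 25 * np.sin(t) + 25, np.full_like(t, 5)])
        pts[:, 1] = 5 + 25 * np.sin(t)
        mask = np.zeros((64, 40, 11), dtype=bool)
        for a, b in zip(pts[:-1], pts[1:]):
            rasterize_capsule(mask, a, b, 2.2, (1, 1, 1))
        truth = Centerline(pts)
        line = extract_centerline(mask, (1, 1, 1))
        assert line.length == pytest.approx(truth.length, rel=0.10)


# ------------------------------------------------------------ accuracy table
class TestAccuracyTable:
    def _results(self, vessel, n, k, branches=None):
        return [
            ClassificationResult(vessel=vessel, trunk_accurate=(i < k),
                                 branches_accurate=branches)
            for i in range(n)
        ]

    def test_printed_count_arithmetic(self):
        df = accuracy_table(self._results(Structure.RHV, 178, 176)).set_index("part")
        assert df.loc["trunk", "accuracy_pct"] == pytest.approx(98.88, abs=0.005)
        assert df.loc["trunk", "ci_high_pct"] == 100.0
        df2 = accuracy_table(self._results(Structure.LPV, 178, 145)).set_index("part")
        assert df2.loc["trunk", "accuracy_pct"] == pytest.approx(81.46, abs=0.005)

    def test_zero_accuracy_ci_floor(self):
        df = accuracy_table(self._results(Structure.MHV, 5, 0)).set_index("part")
        assert df.loc["trunk", "accuracy_pct"] == 0.0
        assert df.loc["trunk", "ci_low_pct"] == 0.0

    def test_branchless_vessels_report_na(self):
        df = accuracy_table(self._results(Structure.MPV, 4, 4, branches=None))
        row = df[(df.vessel == "MPV") & (df.part == "branches")].iloc[0]
        assert row["n"] == 0 and np.isnan(row["accuracy_pct"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            accuracy_table([])
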