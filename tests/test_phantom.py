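"""Phantom generator and segmentation-perturbation simulator."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from hepavol import (
    PerturbationConfig,
    PerturbationError,
    PhantomConfig,
    PhantomError,
    Structure,
    evaluate_structure_groups,
    generate_cohort,
    generate_phantom,
    generate_vessel_tree,
    perturb_segmentation,
)
from hepavol.flr import intrahepatic_vessel_masks, liver_region_mask, parenchyma_mask
from hepavol.phantom import TreeParams, _allocate, child_seed
from tests.conftest import TEST_TARGET_DSC, small_phantom_config


# ------------------------------------------------------------ vessel trees
class TestGenerateVesselTree:
    def _open_mask(self, shape=(60, 30, 30)):
        return np.ones(shape, dtype=bool)

    def test_straight_single_tube_length(self):
        mask = self._open_mask()
        params = TreeParams(direction=(1, 0, 0), trunk_length_mm=40.0,
                            trunk_radius_mm=2.5, n_primary=0, jitter_deg=0.0, clip=None)
        tube, tree, _ = generate_vessel_tree(
            mask, (1, 1, 1), (8.0, 15.0, 15.0), params, np.random.default_rng(0)
        )
        assert len(tree.branches) == 0
        assert tree.trunk.length == pytest.approx(40.0, abs=2.0)
        # straight tube: chord length equals arc length
        chord = np.linalg.norm(tree.trunk.points[-1] - tree.trunk.points[0])
        assert chord == pytest.approx(tree.trunk.length, abs=1e-9)

    def test_two_primary_branches(self):
        params = TreeParams(direction=(1, 0, 0), trunk_length_mm=25.0,
                            trunk_radius_mm=2.5, n_primary=2, jitter_deg=0.0, clip=None)
        _, tree, _ = generate_vessel_tree(
            self._open_mask(), (1, 1, 1), (5.0, 15.0, 15.0), params,
            np.random.default_rng(1)
        )
        assert len(tree.branches) == 2

    def test_taper_arithmetic_with_floor(self):
        params = TreeParams(direction=(1, 0, 0), trunk_length_mm=25.0,
                            trunk_radius_mm=3.0, taper=0.5, n_primary=2,
                            jitter_deg=0.0, min_radius_mm=1.0, clip=None)
        _, _, polylines = generate_vessel_tree(
            self._open_mask(), (1, 1, 1), (5.0, 15.0, 15.0), params,
            np.random.default_rng(2)
        )
        radii = sorted({r for _, r in polylines}, reverse=True)
        assert radii[0] == 3.0
        assert 1.5 in radii            # primary = taper * trunk
        assert min(radii) >= 1.0       # secondary floored at the 2 mm diameter

    def test_trunk_radius_below_floor_rejected(self):
        params = TreeParams(direction=(1, 0, 0), trunk_length_mm=25.0,
                            trunk_radius_mm=0.8, n_primary=0, clip=None)
        with pytest.raises(PhantomError, match="floor"):
            generate_vessel_tree(self._open_mask(), (1, 1, 1), (5.0, 15.0, 15.0),
                                 params, np.random.default_rng(3))

    def test_root_outside_liver_rejected(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[10:30, 10:30, 10:30] = True
        params = TreeParams(direction=(1, 0, 0), trunk_length_mm=15.0,
                            trunk_radius_mm=2.0)
        with pytest.raises(PhantomError, match="outside the liver"):
            generate_vessel_tree(mask, (1, 1, 1), (2.0, 2.0, 2.0), params,
                                 np.random.default_rng(4))

    def test_centerlines_lie_inside_mask(self):
        mask = np.zeros((64, 48, 48), dtype=bool)
        mask[6:58, 6:42, 6:42] = True
        params = TreeParams(direction=(1, 0.2, 0.1), trunk_length_mm=30.0,
                            trunk_radius_mm=2.5, n_primary=2)
        tube, tree, _ = generate_vessel_tree(
            mask, (1, 1, 1), (12.0, 24.0, 24.0), params, np.random.default_rng(5)
        )
        for line in (tree.trunk, *tree.branches):
            for p in line.points:
                assert tube[tuple(np.round(p).astype(int))]


# ----------------------------------------------------------- whole phantom
class TestGeneratePhantom:
    def test_seeded_determinism(self, small_config, phantom):
        again = generate_phantom(small_config, seed=11)
        assert np.array_equal(again.truth.grid, phantom.truth.grid)
        assert again.plan == phantom.plan
        for v, tree in phantom.trees.items():
            assert np.allclose(again.trees[v].trunk.points, tree.trunk.points)

    def test_blood_pool_calibrated_to_nine_percent(self, phantom):
        assert 0.0675 <= phantom.blood_fraction <= 0.1125
        # recount from the label grid itself
        hv, pv = intrahepatic_vessel_masks(phantom.truth)
        region = liver_region_mask(phantom.truth)
        measured = (hv | pv).sum() / region.sum()
        assert 0.0675 <= measured <= 0.1125

    def test_geometry_invariants(self, phantom):
        truth = phantom.truth
        region = liver_region_mask(truth)
        hv = truth.mask_union([Structure.RHV, Structure.MHV, Structure.LHV,
                               Structure.SRHV, Structure.IRHV])
        assert not (hv & ~region).any()            # hepatic veins inside the liver
        ivc = truth.mask(Structure.IVC)
        assert ivc.any() and not (ivc & region).any()  # IVC outside the liver
        # the resection plane partitions the parenchyma exactly
        sp = np.asarray(truth.spacing)
        remnant_pts = np.argwhere(truth.mask(Structure.REMNANT)) * sp
        resect_pts = np.argwhere(truth.mask(Structure.RESECT)) * sp
        assert not phantom.plan.resect_side(remnant_pts).any()
        assert phantom.plan.resect_side(resect_pts).all()
        # lesion lies on the resected side and inside the liver
        lesion_pts = np.argwhere(truth.mask(Structure.LESION)) * sp
        assert phantom.plan.resect_side(lesion_pts).mean() > 0.99
        assert not (truth.mask(Structure.LESION) & ~region).any()

    def test_minimum_tube_diameter(self, phantom):
        """EDT radius at interior centerline points respects the 2 mm floor
        (up to the half-voxel discretization of the capsule rasterization)."""
        truth = phantom.truth
        half_diag = np.linalg.norm(truth.spacing) / 2
        for vessel, tree in phantom.trees.items():
            mask = truth.mask(vessel)
            edt = ndimage.distance_transform_edt(mask, sampling=truth.spacing)
            samples = tree.trunk.resample(2.0).points[1:-1]
            for p in samples:
                assert edt[truth.voxel_of(p)] >= 1.0 - half_diag

    def test_labels_partition_voxels(self, phantom):
        # one label per voxel by construction; parenchyma = remnant + resect
        truth = phantom.truth
        parenchyma = parenchyma_mask(truth)
        remnant = truth.mask(Structure.REMNANT)
        resect = truth.mask(Structure.RESECT)
        assert not (remnant & resect).any()
        assert (remnant | resect).sum() == parenchyma.sum()

    def test_resection_presets_change_remnant_share(self):
        flr = {}
        for resection in ("left", "right", "extended_right"):
            cfg = small_phantom_config(resection=resection)
            ph = generate_phantom(cfg, seed=3)
            remnant = ph.truth.mask(Structure.REMNANT).sum()
            resect = ph.truth.mask(Structure.RESECT).sum()
            flr[resection] = remnant / (remnant + resect)
        assert flr["left"] > flr["right"] > flr["extended_right"]

    def test_infeasible_min_radius_rejected(self):
        cfg = small_phantom_config(min_radius_mm=4.0, trunk_radius_mm=2.0)
        with pytest.raises(PhantomError):
            generate_phantom(cfg, seed=1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="min_radius"):
            PhantomConfig(min_radius_mm=0.5)
        with pytest.raises(ValueError, match="blood_fraction"):
            PhantomConfig(blood_fraction_target=0.5)
        with pytest.raises(ValueError, match="ramification"):
            PhantomConfig(generations=3)


class TestGenerateCohort:
    def test_singleton(self, small_config):
        cohort = generate_cohort(1, small_config, seed=2)
        assert len(cohort) == 1

    def test_determinism_and_unique_ids(self, small_config):
        a = generate_cohort(2, small_config, seed=9)
        b = generate_cohort(2, small_config, seed=9)
        assert [p.id for p in a] == [p.id for p in b]
        assert len({p.id for p in a}) == 2
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.truth.grid, pb.truth.grid)

    def test_mix_allocation_matches_study_proportions(self):
        rng = np.random.default_rng(0)
        conditions = _allocate(32, {"healthy": 27 / 32, "fatty": 3 / 32,
                                    "cirrhosis": 2 / 32}, rng)
        assert sorted(conditions).count("healthy") == 27
        assert conditions.count("fatty") == 3 and conditions.count("cirrhosis") == 2
        resections = _allocate(32, {"left": 10 / 32, "right": 21 / 32,
                                    "extended_right": 1 / 32}, rng)
        assert (resections.count("left"), resections.count("right"),
                resections.count("extended_right")) == (10, 21, 1)

    def test_invalid_size(self, small_config):
        with pytest.raises(ValueError):
            generate_cohort(0, small_config, seed=1)


def test_child_seed_stable_and_bounded():
    assert child_seed(7, "phantom", 3) == child_seed(7, "phantom", 3)
    assert child_seed(7, "phantom", 3) != child_seed(7, "phantom", 4)
    assert 0 <= child_seed(2**31 - 1, "x") < 2**31


# ------------------------------------------------------------ perturbation
class TestPerturbSegmentation:
    def test_identity_when_target_is_one(self, phantom):
        cfg = PerturbationConfig(target_dsc=1.0, branch_dropout_prob=0.0, seed=0)
        out = perturb_segmentation(phantom.truth, cfg)
        assert np.array_equal(out.grid, phantom.truth.grid)

    def test_hits_group_dice_targets(self, phantom, perturbed):
        df = evaluate_structure_groups(perturbed, phantom.truth).set_index("group")
        for group, target in TEST_TARGET_DSC.items():
            assert df.loc[group, "dsc"] == pytest.approx(target, abs=0.05)

    def test_deterministic_given_seed(self, phantom, perturbed):
        cfg = PerturbationConfig(target_dsc=dict(TEST_TARGET_DSC), seed=101)
        again = perturb_segmentation(phantom.truth, cfg, trees=phantom.trees)
        assert np.array_equal(again.grid, perturbed.grid)

    def test_noise_monotonically_degrades_dice(self, phantom):
        """Fixed field, growing amplitude: group Dice never increases."""
        scores = []
        for scale in (0.0, 0.5, 1.0, 2.0, 4.0):
            cfg = PerturbationConfig(target_dsc=None, boundary_noise_scale=scale, seed=7)
            out = perturb_segmentation(phantom.truth, cfg)
            df = evaluate_structure_groups(out, phantom.truth).set_index("group")
            scores.append(df.loc["hepatic_veins", "dsc"])
        assert scores[0] == pytest.approx(1.0)
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_full_branch_dropout_removes_primary_branch_voxels(self, phantom):
        cfg = PerturbationConfig(target_dsc=None, boundary_noise_scale=0.0,
                                 branch_dropout_prob=1.0, seed=3)
        out = perturb_segmentation(phantom.truth, cfg, trees=phantom.trees)
        sp = np.asarray(phantom.truth.spacing)
        for vessel, tree in phantom.trees.items():
            if not tree.branches or not phantom.truth.has(vessel):
                continue
            remaining = np.argwhere(out.mask(vessel)) * sp
            if not len(remaining):
                continue
            # every surviving voxel is closer to the trunk than to any branch
            trunk_kd = cKDTree(tree.trunk.resample(1.0).points)
            branch_pts = np.vstack([b.resample(1.0).points for b in tree.branches])
            branch_kd = cKDTree(branch_pts)
            d_trunk, _ = trunk_kd.query(remaining)
            d_branch, _ = branch_kd.query(remaining)
            # 1 mm slack: the ownership rule samples the centerlines discretely
            assert (d_trunk <= d_branch + 1.0).all(), vessel

    def test_dropout_conflicts_with_perfect_target(self, phantom):
        cfg = PerturbationConfig(target_dsc=1.0, branch_dropout_prob=0.5, seed=0)
        with pytest.raises(PerturbationError, match="conflicts"):
            perturb_segmentation(phantom.truth, cfg, trees=phantom.trees)

    def test_dropout_requires_trees(self, phantom):
        cfg = PerturbationConfig(target_dsc=0.8, branch_dropout_prob=0.5, seed=0)
        with pytest.raises(PerturbationError, match="trees"):
            perturb_segmentation(phantom.truth, cfg)

    def test_unreachable_target_after_heavy_dropout(self, phantom):
        cfg = PerturbationConfig(
            target_dsc={"liver": 1.0, "hepatic_veins": 0.99, "portal_veins": 0.99},
            branch_dropout_prob=1.0, seed=3,
        )
        with pytest.raises(PerturbationError, match="unreachable|conflicts"):
            perturb_segmentation(phantom.truth, cfg, trees=phantom.trees)
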