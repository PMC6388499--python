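import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdday import RunConfig
from birdday.patches import (Patch, build_patches, count_revisits, daily_union,
                             sci, standard_distance)
from birdday.segmentation import segment_day
from conftest import make_bird_day


def day_with_anchors(anchor_xy, run_config):
    """One single-fix segment per anchor position."""
    return segment_day(make_bird_day(np.asarray(anchor_xy, dtype=float)), run_config)


def patch_from_points(xy, config):
    segs = day_with_anchors(xy, config)
    return build_patches(segs, config)


class TestBuildPatches:
    def test_revisit_grouping(self, run_config):
        # A at 0, B at 1 km, A' 150 m from A -> {A, A'}, {B}
        segs = day_with_anchors([[0, 0], [1000, 0], [150, 0]], run_config)
        patches = build_patches(segs, run_config)
        sizes = sorted(p.n_segments for p in patches)
        assert sizes == [1, 2]
        assert count_revisits(patches) == 1

    def test_all_far_apart_one_patch_each(self, run_config):
        segs = day_with_anchors([[0, 0], [400, 0], [800, 0], [1200, 0]], run_config)
        # consecutive anchors 400 m apart: each its own segment AND patch?
        # 400 > 300 join distance, so no chaining
        patches = build_patches(segs, run_config)
        assert len(patches) == len(segs)

    def test_single_linkage_chains(self, run_config):
        # anchors at 0, 250 and 500 m: the ends are 500 m apart but chain
        # through the middle anchor under single linkage
        import pandas as pd
        from birdday.patches import Patch
        from birdday.segmentation import Segment

        segs = [Segment(segment_id=i + 1, animal_id="b1", date=None,
                        anchor_x=250.0 * i, anchor_y=0.0,
                        fixes=pd.DataFrame({"x": [250.0 * i], "y": [0.0]}))
                for i in range(3)]
        patches = build_patches(segs, run_config)
        assert len(patches) == 1
        assert patches[0].n_segments == 3

    def test_n_patches_never_exceeds_n_segments(self, run_config):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.choice([10.0, 600.0], size=(30, 1)) *
                       rng.standard_normal((30, 2)), axis=0)
        segs = segment_day(make_bird_day(xy), run_config)
        patches = build_patches(segs, run_config)
        assert len(patches) <= len(segs)
        assert sum(p.n_fixes for p in patches) == sum(s.n_fixes for s in segs)


class TestMcpArea:
    def test_single_fix_disk_area(self, run_config):
        patches = patch_from_points([[0, 0]], run_config)
        assert patches[0].area_ha == pytest.approx(np.pi * 10 ** 2 / 1e4, rel=5e-3)

    def test_two_fix_capsule_area(self, run_config):
        patches = patch_from_points([[0, 0], [100, 0]], run_config)
        capsule_ha = (100 * 20 + np.pi * 10 ** 2) / 1e4
        assert patches[0].area_ha == pytest.approx(capsule_ha, rel=5e-3)

    def test_square_hull_area(self, run_config):
        xy = [[0, 0], [100, 0], [100, 100], [0, 100]]
        patches = patch_from_points(xy, run_config)
        # hull of 4 buffered corners: 100x100 square + 4 edge strips + disk
        expect_ha = (100 * 100 + 4 * 100 * 10 + np.pi * 10 ** 2) / 1e4
        assert patches[0].area_ha == pytest.approx(expect_ha, rel=5e-3)


class TestDailyUnion:
    def test_disjoint_patches_no_overlap(self, run_config):
        patches = patch_from_points([[0, 0]], run_config) + \
            patch_from_points([[5000, 0]], run_config)
        total, overlap = daily_union(patches)
        assert total == pytest.approx(2 * patches[0].area_ha, rel=1e-6)
        assert overlap == pytest.approx(0.0, abs=1e-9)

    def test_identical_patches_fifty_pct_overlap(self, run_config):
        p1 = patch_from_points([[0, 0], [50, 0]], run_config)[0]
        p2 = patch_from_points([[0, 0], [50, 0]], run_config)[0]
        total, overlap = daily_union([p1, p2])
        assert total == pytest.approx(p1.area_ha, rel=1e-6)
        assert overlap == pytest.approx(50.0, rel=1e-6)

    def test_single_patch_zero_overlap(self, run_config):
        patches = patch_from_points([[0, 0]], run_config)
        _, overlap = daily_union(patches)
        assert overlap == 0.0

    def test_union_never_exceeds_sum(self, run_config):
        rng = np.random.default_rng(1)
        xy = np.cumsum(rng.choice([10.0, 500.0], size=(20, 1)) *
                       rng.standard_normal((20, 2)), axis=0)
        segs = segment_day(make_bird_day(xy), run_config)
        patches = build_patches(segs, run_config)
        total, _ = daily_union(patches)
        assert total <= sum(p.area_ha for p in patches) + 1e-9


class TestRevisits:
    def test_all_singletons_zero(self, run_config):
        patches = patch_from_points([[0, 0]], run_config) + \
            patch_from_points([[5000, 0]], run_config)
        assert count_revisits(patches) == 0

    def test_four_segment_patch_three_revisits(self, run_config):
        segs = day_with_anchors([[0, 0], [50, 0], [100, 0], [150, 0]], run_config)
        # these chain into one segment; instead force separate segments far
        # apart in time via alternating excursions
        segs = day_with_anchors(
            [[0, 0], [1000, 0], [10, 0], [1010, 0], [20, 0], [1020, 0], [30, 0]],
            run_config)
        patches = build_patches(segs, run_config)
        assert count_revisits(patches) == sum(p.n_segments - 1 for p in patches)
        assert count_revisits(patches) == len(segs) - len(patches)


def sci_of(centers, weights):
    """Direct formula evaluation used as the independent oracle: both
    standard distances are taken about the unweighted layout centre."""
    c = np.asarray(centers, float)
    w = np.asarray(weights, float)
    cu = c.mean(axis=0)
    sd_u = np.sqrt(((c - cu) ** 2).sum(axis=1).mean())
    sd_w = np.sqrt((w * ((c - cu) ** 2).sum(axis=1)).sum() / w.sum())
    return sd_w / sd_u


def make_patches_with(centers, weights, run_config):
    patches = []
    for i, (c, w) in enumerate(zip(centers, weights)):
        xy = np.tile(c, (int(w), 1)).astype(float)
        segs = day_with_anchors(xy, run_config)
        p = build_patches(segs, run_config)[0]
        p.patch_id = i + 1
        patches.append(p)
    return patches


class TestSci:
    def test_equilateral_equal_weights_is_one(self, run_config):
        centers = [[0, 0], [1000, 0], [500, 1000 * np.sqrt(3) / 2]]
        patches = make_patches_with(centers, [5, 5, 5], run_config)
        ratio, log_ratio = sci(patches)
        assert ratio == pytest.approx(1.0, abs=1e-12)
        assert log_ratio == pytest.approx(0.0, abs=1e-12)

    def test_time_in_clustered_patches_below_one(self, run_config):
        patches = make_patches_with([[0, 0], [100, 0], [2000, 0]], [20, 20, 8],
                                    run_config)
        ratio, _ = sci(patches)
        assert ratio < 1.0

    def test_time_in_remote_patch_above_one_matches_oracle(self, run_config):
        centers = [[0, 0], [100, 0], [2000, 0]]
        weights = [4, 4, 40]
        patches = make_patches_with(centers, weights, run_config)
        ratio, _ = sci(patches)
        assert ratio > 1.0
        assert ratio == pytest.approx(sci_of(centers, weights), rel=1e-9)

    def test_fewer_than_three_patches_undefined(self, run_config):
        patches = make_patches_with([[0, 0], [2000, 0]], [5, 5], run_config)
        assert sci(patches) is None

    def test_coincident_centers_undefined(self, run_config):
        patches = make_patches_with([[0, 0], [0, 0], [0, 0]], [5, 5, 5], run_config)
        assert sci(patches) is None

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0), st.floats(0.1, 50.0))
    def test_scale_and_weight_invariance(self, seed, k_coord, k_weight):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0, 5000, size=(5, 2))
        weights = rng.integers(1, 30, size=5).astype(float)
        base = sci_of(centers, weights)
        assert sci_of(centers * k_coord, weights) == pytest.approx(base, rel=1e-9)
        assert sci_of(centers, weights * k_weight) == pytest.approx(base, rel=1e-9)

    def test_equal_weights_give_unit_sci_for_any_layout(self):
        rng = np.random.default_rng(3)
        centers = rng.uniform(0, 5000, size=(6, 2))
        w = np.full(6, 7.0)
        assert sci_of(centers, w) == pytest.approx(1.0, abs=1e-12)


def test_standard_distance_rejects_bad_weights():
    with pytest.raises(ValueError):
        standard_distance(np.zeros((3, 2)), np.array([-1.0, 1.0, 1.0]))
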