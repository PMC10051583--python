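"""Restriction analysis: compatibility maps, regions, recovery."""

import numpy as np
import pytest

from memtopo.csa import CSATensor, MotionModel, Orientation, amide_frame, averaged_shift
from memtopo.topology import (CompatibilityMap, ShiftRestraint, classify_topology,
                              degeneracy_classes, find_regions, intersect_maps,
                              restriction_analysis, scan_restraint)


def flood_fill_oracle(mask):
    """Brute-force component count with pitch wrap-around: naive
    8-neighbour flood fill where the column index is taken modulo the
    width (the pitch axis is periodic)."""
    h, w = mask.shape
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                while stack:
                    a, b = stack.pop()
                    b %= w
                    if not 0 <= a < h:
                        continue
                    if not mask[a, b] or labels[a, b]:
                        continue
                    labels[a, b] = current
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            stack.append((a + da, b + db))
    return current


class TestScanRestraint:
    def test_band_covering_all_shifts_gives_full_mask(self, ideal_model,
                                                      default_tensor, default_motion):
        span = default_tensor.sigma33 - default_tensor.sigma11
        restraint = ShiftRestraint(11, default_tensor.isotropic, span)
        cmap = scan_restraint(ideal_model, default_tensor, default_motion,
                              restraint, grid_step=5.0)
        assert cmap.mask.all()

    def test_forward_invert_consistency(self, ideal_model, default_tensor,
                                        default_motion):
        truth = Orientation(90.0, 130.0)
        shift = averaged_shift(amide_frame(ideal_model, 11), default_tensor,
                               truth, default_motion)
        cmap = scan_restraint(ideal_model, default_tensor, default_motion,
                              ShiftRestraint(11, shift, 2.0), grid_step=1.0)
        i = np.argmin(np.abs(cmap.tilt_grid - truth.tilt))
        j = np.argmin(np.abs(cmap.pitch_grid - truth.pitch))
        assert cmap.mask[i, j]

    def test_unknown_residue_rejected(self, ideal_model, default_tensor,
                                      default_motion):
        with pytest.raises(ValueError):
            scan_restraint(ideal_model, default_tensor, default_motion,
                           ShiftRestraint(99, 80.0, 2.5))

    def test_error_must_be_positive(self):
        with pytest.raises(ValueError):
            ShiftRestraint(11, 80.0, 0.0)


class TestIntersect:
    def _map(self, mask):
        t = np.linspace(0, 180, mask.shape[0])
        p = np.arange(mask.shape[1]) * (360.0 / mask.shape[1])
        return CompatibilityMap(tilt_grid=t, pitch_grid=p, mask=mask,
                                restraint_ids=[1])

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = self._map(rng.random((7, 12)) > 0.5)
        out = intersect_maps([m, m])
        assert np.array_equal(out.mask, m.mask)

    def test_complement_is_empty(self):
        rng = np.random.default_rng(4)
        mask = rng.random((7, 12)) > 0.5
        out = intersect_maps([self._map(mask), self._map(~mask)])
        assert not out.mask.any()

    def test_grid_mismatch_rejected(self):
        a = self._map(np.ones((7, 12), dtype=bool))
        b = self._map(np.ones((9, 12), dtype=bool))
        b.tilt_grid = np.linspace(0, 180, 9)
        b.mask = np.ones((9, 12), dtype=bool)
        with pytest.raises(ValueError):
            intersect_maps([a, b])


class TestFindRegions:
    def _map(self, mask):
        t = np.arange(mask.shape[0], dtype=float)
        p = np.arange(mask.shape[1], dtype=float)
        return CompatibilityMap(tilt_grid=t, pitch_grid=p, mask=mask,
                                restraint_ids=[])

    def test_empty_mask(self):
        cmap = self._map(np.zeros((10, 20), dtype=bool))
        assert find_regions(cmap, min_area=1.0) == []

    def test_seam_split_blob_merges_across_wraparound(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask[4:6, 18:] = True   # blob touching the right edge...
        mask[4:6, :2] = True    # ...continues on the left: one region
        mask[1:3, 8:11] = True  # separate interior blob
        regions = find_regions(self._map(mask), min_area=1.0)
        assert len(regions) == flood_fill_oracle(mask) == 2
        areas = sorted(r.n_cells for r in regions)
        assert areas == [6, 8]

    def test_component_count_matches_flood_fill_on_random_masks(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            mask = rng.random((12, 18)) > 0.65
            regions = find_regions(self._map(mask), min_area=0.5)
            assert len(regions) == flood_fill_oracle(mask)

    def test_seam_region_centroid_uses_circular_mean(self):
        t = np.linspace(0.0, 180.0, 10)
        p = np.arange(0.0, 360.0, 20.0)  # 18 columns, last at 340 deg
        mask = np.zeros((10, 18), dtype=bool)
        mask[5, 17] = True  # pitch 340
        mask[5, 0] = True   # pitch 0
        cmap = CompatibilityMap(tilt_grid=t, pitch_grid=p, mask=mask,
                                restraint_ids=[])
        (region,) = find_regions(cmap, min_area=1.0)
        # circular mean of 340 and 0 degrees is 350, not the arithmetic 170
        assert region.centroid.pitch == pytest.approx(350.0, abs=1e-9)

    def test_min_area_filters_specks(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask[2, 5] = True
        mask[6:9, 10:14] = True
        regions = find_regions(self._map(mask), min_area=3.0)
        assert len(regions) == 1
        assert regions[0].n_cells == 12

    def test_labels_sorted_by_area(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask[1:3, 2:4] = True     # 4 cells
        mask[5:9, 10:16] = True   # 24 cells
        regions = find_regions(self._map(mask), min_area=1.0)
        assert [r.label for r in regions] == ["I", "II"]
        assert regions[0].n_cells == 24


class TestClassify:
    @pytest.mark.parametrize("tilt,expected", [
        (90.0, "in-plane"), (80.0, "in-plane"), (10.0, "transmembrane"),
        (172.0, "transmembrane"), (45.0, "tilted"),
    ])
    def test_topology_classes(self, tilt, expected):
        from memtopo.topology import SolutionRegion
        region = SolutionRegion(label="I", cells=[(tilt, 0.0)],
                                centroid=Orientation(tilt, 0.0), area=1.0)
        assert classify_topology(region) == expected


class TestRecovery:
    def test_random_ground_truth_contained_in_a_region(self, ideal_model,
                                                       default_tensor,
                                                       default_motion):
        """Forward/invert round trip: 20 random orientations, restraints on
        neighbouring residues 11/12 with the experimental error widths."""
        rng = np.random.default_rng(11)
        frames = {r: amide_frame(ideal_model, r) for r in (11, 12)}
        for _ in range(20):
            truth = Orientation(rng.uniform(5, 175), rng.uniform(0, 360))
            restraints = [
                ShiftRestraint(r, averaged_shift(frames[r], default_tensor,
                                                 truth, default_motion), err)
                for r, err in ((11, 2.5), (12, 4.0))]
            _, regions = restriction_analysis(
                ideal_model, restraints, tensor=default_tensor,
                motion=default_motion, grid_step=2.0, min_area=1.0)
            assert any(
                any(abs(ct - truth.tilt) <= 2.0
                    and min((cp - truth.pitch) % 360, (truth.pitch - cp) % 360) <= 2.0
                    for ct, cp in reg.cells)
                for reg in regions)

    def test_shrinking_errors_shrink_compatible_set(self, ideal_model,
                                                    default_tensor, default_motion):
        big = scan_restraint(ideal_model, default_tensor, default_motion,
                             ShiftRestraint(11, 80.0, 4.0), grid_step=2.0)
        small = scan_restraint(ideal_model, default_tensor, default_motion,
                               ShiftRestraint(11, 80.0, 1.5), grid_step=2.0)
        assert not (small.mask & ~big.mask).any()
        assert small.mask.sum() < big.mask.sum()

    def test_region_count_stable_to_grid_refinement(self, ideal_model,
                                                    measured_restraints,
                                                    default_tensor, default_motion):
        _, coarse = restriction_analysis(ideal_model, measured_restraints,
                                         tensor=default_tensor,
                                         motion=default_motion, grid_step=1.0)
        _, fine = restriction_analysis(ideal_model, measured_restraints,
                                       tensor=default_tensor,
                                       motion=default_motion, grid_step=0.5,
                                       min_area=0.75)
        assert len(coarse) == len(fine)
        for rc in coarse:
            best = min(fine, key=lambda rf: abs(rf.centroid.tilt - rc.centroid.tilt)
                       + abs((rf.centroid.pitch - rc.centroid.pitch + 180) % 360 - 180))
            assert abs(best.centroid.tilt - rc.centroid.tilt) < 2.0
            d_pitch = abs((best.centroid.pitch - rc.centroid.pitch + 180) % 360 - 180)
            assert d_pitch < 2.0


def test_degeneracy_pairing(ideal_model, measured_restraints, default_tensor,
                            default_motion):
    """Solution regions pair up under (tilt, pitch) -> (180-tilt, pitch+180)."""
    _, regions = restriction_analysis(ideal_model, measured_restraints,
                                      tensor=default_tensor, motion=default_motion)
    classes = degeneracy_classes(regions)
    assert all(len(c) == 2 for c in classes)
    for pair in classes:
        a, b = pair
        assert a.centroid.tilt == pytest.approx(180.0 - b.centroid.tilt, abs=1.0)
        assert a.n_cells == b.n_cells
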