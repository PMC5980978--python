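"""Nucleus detection/splitting, compartment assignment, erasure, dedup."""

import numpy as np
import pytest
from skimage import measure

from viastack import (
    ChannelStack,
    NucleusRecord,
    RoiSet,
    RunConfig,
    ValidationError,
    classify_compartment,
    dedup_across_slices,
    detect_nuclei,
    erase_nuclei,
    run_nucleus_pass,
)
from viastack.nuclei import check_erasure_safety

from _oracle import components, seed_of
from conftest import arrays_to_stacks, disk_mask


def make_record(id, z, xy, vital="live", pixels=None, area=10):
    return NucleusRecord(
        id=id, slice_index=z, seed_xy=xy, area_px=area, vital_state=vital,
        pixels=np.asarray(pixels) if pixels is not None else None,
    )


class TestDetectNuclei:
    def test_disjoint_disks(self):
        m = disk_mask((64, 64), (16, 16), 10) | disk_mask((64, 64), (45, 45), 10)
        recs = detect_nuclei(m, min_area=5)
        assert len(recs) == 2
        for r in recs:
            x, y = r.seed_xy
            assert m[y, x]

    def test_fused_disks_split_by_watershed(self):
        # two equal disks overlapping by ~30% of the radius: one 8-connected
        # component, but two planted nuclei
        r = 10
        centers = [(32, 20), (32, 20 + int(1.7 * r))]
        m = disk_mask((64, 64), centers[0], r) | disk_mask((64, 64), centers[1], r)
        assert measure.label(m, connectivity=2).max() == 1
        recs = detect_nuclei(m, min_area=5)
        assert len(recs) == 2
        total = sum(rec.area_px for rec in recs)
        assert total == int(m.sum())

    def test_blank_mask(self):
        assert detect_nuclei(np.zeros((16, 16), bool), min_area=5) == []

    def test_shallow_component_still_detected(self):
        # a 2-px-thin bar has distance relief below the h-maxima depth;
        # the fallback seed must keep it as one nucleus
        m = np.zeros((16, 16), dtype=bool)
        m[4:6, 2:14] = True
        recs = detect_nuclei(m, min_area=5, h=2.0)
        assert len(recs) == 1
        assert recs[0].area_px == 24


class TestClassifyCompartment:
    def _rois(self, label_img):
        return RoiSet(labels=[label_img], dilation=0)

    def test_membership_definition(self):
        lab = np.zeros((16, 16), dtype=int)
        lab[4:8, 4:8] = 2
        rois = self._rois(lab)
        inside = make_record(0, 0, (5, 5))
        outside = make_record(1, 0, (3, 5))  # 1 px left of the ROI
        out = classify_compartment([inside, outside], rois)
        assert out[0].compartment == "msc"
        assert out[1].compartment == "islet"

    def test_slice_out_of_range(self):
        with pytest.raises(ValidationError):
            classify_compartment([make_record(0, 3, (1, 1))], self._rois(np.zeros((4, 4), int)))

    def test_random_seeds_equal_pixel_lookup(self, rng):
        lab = measure.label(rng.uniform(size=(32, 32)) < 0.2, connectivity=2)
        recs = [
            make_record(i, 0, (int(rng.integers(0, 32)), int(rng.integers(0, 32))))
            for i in range(50)
        ]
        out = classify_compartment(recs, self._rois(lab))
        for rec in out:
            x, y = rec.seed_xy
            assert rec.compartment == ("msc" if lab[y, x] > 0 else "islet")


class TestEraseNuclei:
    def test_flood_fill_removal_preserves_others(self):
        m = (
            disk_mask((48, 48), (10, 10), 4)
            | disk_mask((48, 48), (10, 35), 4)
            | disk_mask((48, 48), (35, 20), 4)
        )
        out = erase_nuclei(m, [make_record(0, 0, (10, 10))])
        assert measure.label(out, connectivity=2).max() == 2
        survivor = disk_mask((48, 48), (10, 35), 4) | disk_mask((48, 48), (35, 20), 4)
        np.testing.assert_array_equal(out, survivor)

    def test_erase_everything(self):
        m = disk_mask((32, 32), (16, 16), 6)
        out = erase_nuclei(m, [make_record(0, 0, (16, 16))])
        assert not out.any()

    def test_background_seed_warns_and_skips(self):
        m = disk_mask((32, 32), (16, 16), 5)
        with pytest.warns(UserWarning, match="background"):
            out = erase_nuclei(m, [make_record(0, 0, (1, 1))])
        np.testing.assert_array_equal(out, m)

    def test_random_subset_matches_label_deletion_oracle(self, rng):
        m = rng.uniform(size=(48, 48)) < 0.25
        comps = components(m)
        victims = [c for i, c in enumerate(comps) if i % 3 == 0]
        recs = [make_record(i, 0, seed_of(c)) for i, c in enumerate(victims)]
        out = erase_nuclei(m, recs)
        expected = m.copy()
        for c in victims:
            for r, col in c:
                expected[r, col] = False
        np.testing.assert_array_equal(out, expected)

    def test_erasure_never_adds_pixels(self, rng):
        m = rng.uniform(size=(32, 32)) < 0.3
        comps = components(m)
        recs = [make_record(i, 0, seed_of(c)) for i, c in enumerate(comps[::2])]
        out = erase_nuclei(m, recs)
        assert not (out & ~m).any()


def chain_records(positions):
    """Records with square 3x3 footprints at (slice, (x, y)) positions."""
    recs = []
    for i, (z, (x, y)) in enumerate(positions):
        pix = [(y + dy, x + dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
        recs.append(make_record(i, z, (x, y), pixels=pix, area=9))
    return recs


class TestDedup:
    @pytest.mark.parametrize("mode", ["overlap", "centroid"])
    def test_consecutive_slices_counted_once(self, mode):
        recs = chain_records([(3, (10, 10)), (4, (10, 11))])
        out = dedup_across_slices(recs, mode=mode, tolerance=3)
        assert [r.is_duplicate for r in out] == [False, True]
        assert out[1].dedup_of == out[0].id

    @pytest.mark.parametrize("mode", ["overlap", "centroid"])
    def test_gap_means_counted_twice(self, mode):
        recs = chain_records([(3, (10, 10)), (5, (10, 10))])
        out = dedup_across_slices(recs, mode=mode, tolerance=3)
        assert [r.is_duplicate for r in out] == [False, False]

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_chain_collapses_to_first_occurrence(self, k):
        recs = chain_records([(2 + dz, (10, 10 + dz)) for dz in range(k)])
        out = dedup_across_slices(recs, mode="overlap")
        assert sum(not r.is_duplicate for r in out) == 1
        assert sum(r.is_duplicate for r in out) == k - 1
        for r in out:
            if r.is_duplicate:
                assert any(p.slice_index == r.slice_index - 1 and p.id == r.dedup_of for p in out)

    def test_vital_states_do_not_cross_match(self):
        a = chain_records([(1, (5, 5))])[0]
        b = make_record(1, 2, (5, 5), vital="dead", pixels=[(5, 5)], area=1)
        out = dedup_across_slices([a, b], mode="overlap")
        assert not any(r.is_duplicate for r in out)

    def test_centroid_tolerance_boundary(self):
        recs = [
            make_record(0, 0, (10, 10), area=1, pixels=[(10, 10)]),
            make_record(1, 1, (13, 14), area=1, pixels=[(14, 13)]),  # distance 5
        ]
        assert dedup_across_slices(recs, "centroid", tolerance=5)[1].is_duplicate
        assert not dedup_across_slices(recs, "centroid", tolerance=4.9)[1].is_duplicate

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            dedup_across_slices([], mode="nearest")

    def test_idempotent(self):
        recs = chain_records([(z, (10, 10)) for z in range(4)] + [(2, (30, 30))])
        once = dedup_across_slices(recs, "overlap")
        twice = dedup_across_slices(once, "overlap")
        assert [(r.id, r.dedup_of) for r in once] == [(r.id, r.dedup_of) for r in twice]


class TestNucleusPass:
    @staticmethod
    def _scene():
        """16 live islet + 4 live MSC disks inside one big green blob."""
        h = w = 128
        green = np.zeros((3, h, w), np.uint8)
        blue = np.zeros_like(green)
        red = np.zeros_like(green)
        for z in range(3):
            m = disk_mask((h, w), (96, 96), 24)
            green[z][m] = 150
        k = 0
        for gy in range(4):
            for gx in range(4):
                m = disk_mask((h, w), (12 + 16 * gy, 12 + 16 * gx), 4)
                blue[k % 3][m] = 200
                k += 1
        for i, (dy, dx) in enumerate([(-8, -8), (-8, 8), (8, -8), (8, 8)]):
            m = disk_mask((h, w), (96 + dy, 96 + dx), 4)
            blue[i % 3][m] = 200
        return arrays_to_stacks(green, blue, red)

    def test_well_separated_counts_and_partition(self, default_cfg):
        stacks = self._scene()
        records, masks, rois = run_nucleus_pass(stacks, default_cfg)
        surviving = [r for r in records if not r.is_duplicate]
        by_class = {}
        for r in surviving:
            by_class[f"{r.compartment}_{r.vital_state}"] = (
                by_class.get(f"{r.compartment}_{r.vital_state}", 0) + 1
            )
        assert by_class == {"islet_live": 16, "msc_live": 4}
        # partition: every surviving record is in exactly one class
        assert sum(by_class.values()) == len(surviving)
        assert check_erasure_safety(records, rois)
        # MSC nuclei were erased from the islet working masks
        for z, m in enumerate(masks["islet_live"]):
            lab = measure.label(m, connectivity=2)
            assert lab.max() == sum(
                1 for r in surviving if r.compartment == "islet" and r.slice_index == z
            )

    def test_msc_dropped_but_still_erased_when_disabled(self, default_cfg):
        stacks = self._scene()
        cfg = default_cfg.with_overrides(analyze_msc=False)
        records, masks, _ = run_nucleus_pass(stacks, cfg)
        assert all(r.compartment == "islet" for r in records)
        # the erased MSC signal must not reappear in the islet masks
        for m in masks["islet_live"]:
            lab = measure.label(m, connectivity=2)
            assert lab.max() <= 6  # only islet nuclei per slice

    def test_blank_dead_channel(self, default_cfg):
        stacks = self._scene()
        records, _, _ = run_nucleus_pass(stacks, default_cfg)
        assert not any(r.vital_state == "dead" for r in records)

    def test_slice_count_mismatch(self, default_cfg):
        stacks = self._scene()
        bad = ChannelStack(
            slices=stacks["dead_nuclei"].slices[:2], channel_role="dead_nuclei"
        )
        stacks["dead_nuclei"] = bad
        with pytest.raises(ValidationError, match="slice counts"):
            run_nucleus_pass(stacks, default_cfg)
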