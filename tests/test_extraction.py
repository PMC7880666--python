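"""ROI building, lesion exclusion and mean-FA extraction."""
import numpy as np
import pandas as pd
import pytest

from tractdx import (BinaryMask, FAVolume, GridMismatchError, LabelVolume,
                     SubjectRecord, VoxelGrid, apply_lesion_exclusion,
                     build_cohort_table, build_roi_set, derive_skeleton,
                     extract_mean_fa)
from tractdx.simulate import sphere_mask

GRID = VoxelGrid((16, 16, 16), np.diag([2.0, 2.0, 2.0, 1.0]))


def make_atlas_and_skeleton():
    labels = np.zeros(GRID.shape, dtype=np.int16)
    labels[0:4] = 1      # ROI A: 4*16*16 voxels
    labels[6:10] = 2     # ROI B
    skeleton = np.zeros(GRID.shape, dtype=np.uint8)
    skeleton[:, :, 8] = 1  # one plane
    atlas = LabelVolume(labels, GRID, name_map={"A": {1}, "B": {2}})
    return atlas, BinaryMask(skeleton, GRID)


class TestBuildROISet:
    def test_intersection_with_skeleton(self):
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        assert rois.voxel_counts == {"A": 4 * 16, "B": 4 * 16}
        assert rois.mask_version is None

    def test_off_skeleton_roi_flagged_missing(self):
        atlas, _ = make_atlas_and_skeleton()
        empty_skel = BinaryMask(np.zeros(GRID.shape, dtype=np.uint8), GRID)
        with pytest.warns(UserWarning, match="missing"):
            rois = build_roi_set(atlas, empty_skel, ["A"])
        assert rois.missing == {"A"} and not rois.masks

    def test_overlapping_label_groups_rejected(self):
        labels = np.zeros(GRID.shape, dtype=np.int16)
        labels[0:4] = 1
        atlas = LabelVolume(labels, GRID, name_map={"A": {1}, "Abis": {1}})
        _, skel = make_atlas_and_skeleton()
        with pytest.raises(ValueError, match="overlapping"):
            build_roi_set(atlas, skel, ["A", "Abis"])

    def test_unknown_name_rejected(self):
        atlas, skel = make_atlas_and_skeleton()
        with pytest.raises(KeyError, match="C"):
            build_roi_set(atlas, skel, ["C"])

    def test_grid_mismatch_raises(self):
        atlas, _ = make_atlas_and_skeleton()
        other = VoxelGrid((16, 16, 16), np.diag([1.0, 2.0, 2.0, 1.0]))
        skel = BinaryMask(np.zeros(GRID.shape, dtype=np.uint8), other)
        with pytest.raises(GridMismatchError):
            build_roi_set(atlas, skel)


class TestLesionExclusion:
    def test_subtraction_counts(self):
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        lesion = np.zeros(GRID.shape, dtype=np.uint8)
        lesion[0:2, 0:8, :] = 1  # hits half of A's skeleton rows
        corrected = apply_lesion_exclusion(rois, BinaryMask(lesion, GRID), "p1")
        assert corrected.mask_version == "p1"
        assert corrected.voxel_counts["A"] == 4 * 16 - 2 * 8
        assert corrected.voxel_counts["B"] == rois.voxel_counts["B"]
        # monotone: counts never increase
        assert all(corrected.voxel_counts[n] <= rois.voxel_counts[n]
                   for n in corrected.masks)

    def test_disjoint_lesion_identity(self):
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        lesion = np.zeros(GRID.shape, dtype=np.uint8)
        lesion[12:14, :, :] = 1  # off both ROIs
        corrected = apply_lesion_exclusion(rois, BinaryMask(lesion, GRID), "p2")
        for name in rois.masks:
            np.testing.assert_array_equal(corrected.masks[name], rois.masks[name])
        assert corrected.mask_version == "p2"

    def test_fully_covered_roi_goes_missing(self):
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        lesion = np.zeros(GRID.shape, dtype=np.uint8)
        lesion[0:4] = 1  # covers all of A
        with pytest.warns(UserWarning, match="fully covered"):
            corrected = apply_lesion_exclusion(rois, BinaryMask(lesion, GRID), "p3")
        assert "A" in corrected.missing
        np.testing.assert_array_equal(corrected.masks["B"], rois.masks["B"])


class TestExtractMeanFA:
    def test_uniform_fa(self):
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        fa = FAVolume(np.where(skel.data, 0.5, 0.0), GRID)
        means = extract_mean_fa(fa, rois)
        assert means["A"] == pytest.approx(0.5) and means["B"] == pytest.approx(0.5)
        assert means["WSKL"] == pytest.approx(0.5)

    def test_two_voxel_mean(self):
        labels = np.zeros(GRID.shape, dtype=np.int16)
        labels[0, 0, 0] = labels[0, 0, 1] = 1
        atlas = LabelVolume(labels, GRID, name_map={"A": {1}})
        skel = BinaryMask((labels > 0).astype(np.uint8), GRID)
        rois = build_roi_set(atlas, skel, ["A"])
        data = np.zeros(GRID.shape)
        data[0, 0, 0], data[0, 0, 1] = 0.4, 0.6
        means = extract_mean_fa(FAVolume(data, GRID), rois)
        assert means["A"] == pytest.approx(0.5, abs=1e-15)

    def test_matches_brute_force_voxel_loop(self):
        rng = np.random.default_rng(11)
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        fa = FAVolume(rng.uniform(0, 1, GRID.shape) * skel.data, GRID)
        means = extract_mean_fa(fa, rois)
        for name, mask in rois.masks.items():
            total, count = 0.0, 0
            for idx in zip(*np.nonzero(mask)):
                total += fa.data[idx]
                count += 1
            assert means[name] == pytest.approx(total / count, abs=1e-12)

    def test_locality_under_lesion(self):
        """Lesion disjoint from an ROI leaves its mean bit-identical."""
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        fa = FAVolume(np.random.default_rng(3).uniform(0, 1, GRID.shape) * skel.data, GRID)
        lesion = sphere_mask(GRID, center=(8, 8, 8), radius=2.5)  # inside B only
        assert not (lesion.data & rois.masks["A"]).any()
        corrected = apply_lesion_exclusion(rois, lesion, "px")
        before = extract_mean_fa(fa, rois)
        after = extract_mean_fa(fa, corrected)
        assert after["A"] == before["A"]  # to the last bit
        assert after["B"] != before["B"]


class TestQCExport:
    def test_roi_set_round_trips_through_label_volume(self):
        from tractdx.extraction import roi_set_to_labels
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        qc = roi_set_to_labels(rois)
        for name in rois.masks:
            np.testing.assert_array_equal(qc.group_mask(name), rois.masks[name])


class TestSkeletonDerivation:
    def test_threshold_definition(self):
        data = np.zeros(GRID.shape)
        data[0, 0, 0] = 0.19
        data[0, 0, 1] = 0.2
        data[0, 0, 2] = 0.55
        skel = derive_skeleton(FAVolume(data, GRID))
        assert skel.n_voxels == 2  # >= 0.2 kept
        # skeleton is a subset of nonzero voxels of the mean-FA volume
        assert not (skel.data & (data == 0)).any()


class TestBuildCohortTable:
    def make_inputs(self):
        atlas, skel = make_atlas_and_skeleton()
        rois = build_roi_set(atlas, skel, ["A", "B"])
        rng = np.random.default_rng(5)
        records, volumes = [], {}
        for i in range(5):
            sid = f"c{i}"
            records.append(SubjectRecord(sid, "control", 30.0 + i))
            volumes[sid] = FAVolume(rng.uniform(0.3, 0.7, GRID.shape) * skel.data, GRID)
        records.append(SubjectRecord("p0", "patient", 44.0))
        volumes["p0"] = FAVolume(rng.uniform(0.3, 0.7, GRID.shape) * skel.data, GRID)
        return records, volumes, rois

    def test_lesion_free_single_table(self):
        records, volumes, rois = self.make_inputs()
        tables = build_cohort_table(records, volumes, rois)
        assert set(tables) == {None}
        assert len(tables[None]) == 6
        assert tables[None].mask_version is None

    def test_lesioned_patient_gets_patient_specific_table(self):
        records, volumes, rois = self.make_inputs()
        lesion = np.zeros(GRID.shape, dtype=np.uint8)
        lesion[0:1, 0:4, :] = 1  # clips ROI A only
        tables = build_cohort_table(records, volumes, rois,
                                    lesion_masks={"p0": BinaryMask(lesion, GRID)})
        assert set(tables) == {None, "p0"}
        corrected = tables["p0"]
        assert corrected.mask_version == "p0"
        base = tables[None]
        # control means change only in the ROI the lesion touches
        for cid in [f"c{i}" for i in range(5)]:
            assert corrected.frame.loc[cid, "B"] == base.frame.loc[cid, "B"]
            assert corrected.frame.loc[cid, "A"] != base.frame.loc[cid, "A"]

    def test_missing_volume_raises(self):
        records, volumes, rois = self.make_inputs()
        volumes.pop("c3")
        with pytest.raises(KeyError, match="c3"):
            build_cohort_table(records, volumes, rois)
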