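"""Hybrid-ROI geometry: sliding windows, composition, capping, labelling."""

import numpy as np
import pytest

from cysurv.datatypes import ContractError
from cysurv.roi import (
    HALF_SHAPE,
    ROI_SHAPE,
    ROIDatasetConfig,
    build_roi_dataset,
    compose_hybrid,
    dataset_arrays,
    extract_subrois,
)
from cysurv.simulate import SimConfig, generate_cohort


def brute_force_offsets(size: int, window: int, stride: int) -> list[int]:
    return [o for o in range(0, size, stride) if o + window <= size]


def _bbox(y0, y1, x0, x1):
    return ((0, 1), (y0, y1), (x0, x1))


class TestExtractSubrois:
    def test_window_counts_match_brute_force_enumeration(self, rng):
        vol = rng.normal(size=(1, 80, 80))
        for h, w, stride in [(32, 16, 4), (40, 31, 5), (32, 20, 1), (50, 33, 7)]:
            rois = extract_subrois(vol, _bbox(0, h, 0, w), 0, HALF_SHAPE, stride)
            expected = len(brute_force_offsets(h, 32, stride)) * len(
                brute_force_offsets(w, 16, stride)
            )
            assert len(rois) == expected

    def test_exact_window_size_gives_single_window(self, rng):
        vol = rng.normal(size=(1, 40, 40))
        rois = extract_subrois(vol, _bbox(0, 32, 0, 16), 0, HALF_SHAPE, stride=7)
        assert len(rois) == 1 and rois[0].origin == (0, 0)

    def test_32x31_voi_stride_5_gives_offsets_0_5_10_15(self, rng):
        vol = rng.normal(size=(1, 32, 31))
        rois = extract_subrois(vol, _bbox(0, 32, 0, 31), 0, HALF_SHAPE, stride=5)
        assert [r.origin[1] for r in rois] == [0, 5, 10, 15]

    def test_stride_1_on_32x20_gives_5_windows(self, rng):
        vol = rng.normal(size=(1, 32, 20))
        rois = extract_subrois(vol, _bbox(0, 32, 0, 20), 0, HALF_SHAPE, stride=1)
        assert len(rois) == 5

    def test_small_voi_zero_padded_and_flagged(self, rng):
        vol = rng.normal(size=(1, 40, 40))
        rois = extract_subrois(vol, _bbox(10, 20, 10, 18), 0, HALF_SHAPE, stride=4)
        assert len(rois) == 1
        assert rois[0].padded
        assert rois[0].pixels.shape == HALF_SHAPE
        # symmetric padding leaves zero margins around the copied VOI
        assert np.allclose(rois[0].pixels[:11], 0.0)
        assert np.allclose(rois[0].pixels[-11:], 0.0)


class TestComposeHybrid:
    def test_output_is_32x32_with_identity_halves(self):
        patch = compose_hybrid(np.zeros(HALF_SHAPE), np.ones(HALF_SHAPE),
                               intensity_window=(0.0, 1.0))
        assert patch.shape == ROI_SHAPE
        assert np.all(patch[:, :16] == 0.0)
        assert np.all(patch[:, 16:] == 1.0)

    def test_swapping_arguments_mirrors_block_structure(self, rng):
        a = rng.random(HALF_SHAPE)
        b = rng.random(HALF_SHAPE)
        ab = compose_hybrid(a, b, (0.0, 1.0))
        ba = compose_hybrid(b, a, (0.0, 1.0))
        assert np.array_equal(ab[:, :16], ba[:, 16:])
        assert np.array_equal(ab[:, 16:], ba[:, :16])

    def test_normalization_clips_to_unit_interval(self, rng):
        patch = compose_hybrid(rng.normal(0, 500, HALF_SHAPE),
                               rng.normal(0, 500, HALF_SHAPE),
                               intensity_window=(-50.0, 150.0))
        assert patch.min() >= 0.0 and patch.max() <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            compose_hybrid(np.zeros((32, 15)), np.zeros(HALF_SHAPE))


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SimConfig(n_patients=6, seed=9))


class TestBuildDataset:
    def test_cross_product_count_and_cap(self, cohort):
        pairs, masks, records, _ = cohort
        labels = {r.patient_id: r.label_5yr for r in records}
        uncapped = build_roi_dataset(
            pairs, masks, labels, ROIDatasetConfig(stride=4, max_hybrids_per_case=10_000)
        )
        capped = build_roi_dataset(
            pairs, masks, labels, ROIDatasetConfig(stride=4, max_hybrids_per_case=5, seed=3)
        )
        per_case = {}
        for r in uncapped:
            per_case[r.patient_id] = per_case.get(r.patient_id, 0) + 1
        for pid, n in per_case.items():
            n_capped = sum(1 for r in capped if r.patient_id == pid)
            assert n_capped == min(n, 5)
        # capping is reproducible under the same seed
        capped2 = build_roi_dataset(
            pairs, masks, labels, ROIDatasetConfig(stride=4, max_hybrids_per_case=5, seed=3)
        )
        for a, b in zip(capped, capped2):
            assert a.patient_id == b.patient_id
            assert np.array_equal(a.patch, b.patch)

    def test_every_patch_carries_its_case_label(self, cohort):
        pairs, masks, records, _ = cohort
        labels = {r.patient_id: 1 for r in records}
        rois = build_roi_dataset(pairs, masks, labels,
                                 ROIDatasetConfig(max_hybrids_per_case=4))
        assert all(r.label == 1 for r in rois)

    def test_halves_never_mix_phases(self, cohort):
        """Marking the two phases with disjoint constants must yield patches
        whose left half holds only the pre constant and right half only the
        post constant."""
        import dataclasses

        pairs, masks, records, _ = cohort
        labels = {r.patient_id: r.label_5yr for r in records}
        marked = [
            dataclasses.replace(p, pre_volume=np.full_like(p.pre_volume, 10.0),
                                post_volume=np.full_like(p.post_volume, 90.0))
            for p in pairs
        ]
        rois = build_roi_dataset(marked, masks, labels,
                                 ROIDatasetConfig(max_hybrids_per_case=4,
                                                  intensity_window=(0.0, 100.0)))
        for r in rois:
            left = np.unique(r.patch[:, :16])
            right = np.unique(r.patch[:, 16:])
            assert set(left) <= {0.0, 0.1}  # padding zeros or pre constant
            assert set(right) <= {0.0, 0.9}

    def test_patch_order_independent_of_case_iteration_order(self, cohort):
        pairs, masks, records, _ = cohort
        labels = {r.patient_id: r.label_5yr for r in records}
        cfg = ROIDatasetConfig(max_hybrids_per_case=6, seed=1)
        fwd = build_roi_dataset(pairs, masks, labels, cfg)
        rev = build_roi_dataset(pairs[::-1], masks, labels, cfg)
        by_id_fwd = {}
        for r in fwd:
            by_id_fwd.setdefault(r.patient_id, []).append(r.patch)
        by_id_rev = {}
        for r in rev:
            by_id_rev.setdefault(r.patient_id, []).append(r.patch)
        for pid in by_id_fwd:
            for a, b in zip(by_id_fwd[pid], by_id_rev[pid]):
                assert np.array_equal(a, b)

    def test_dataset_arrays_shapes(self, cohort):
        pairs, masks, records, _ = cohort
        labels = {r.patient_id: r.label_5yr for r in records}
        rois = build_roi_dataset(pairs, masks, labels,
                                 ROIDatasetConfig(max_hybrids_per_case=4))
        X, y, ids = dataset_arrays(rois)
        assert X.shape[1:] == ROI_SHAPE
        assert X.shape[0] == y.size == ids.size == len(rois)
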