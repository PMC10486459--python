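"""Cohort IO round-trips, clinical-record invariants and the serial split."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from cysurv.cohort import load_cohort, read_split, save_cohort, serial_split, write_split
from cysurv.datatypes import (
    AlignmentError,
    ClinicalRecord,
    LesionAnnotation,
    LesionMask,
    SchemaError,
    SplitError,
    VolumePair,
    derive_label_5yr,
)


def _record(pid: str, day: int, months: float = 30.0, event: bool = True) -> ClinicalRecord:
    return ClinicalRecord(
        patient_id=pid, path_stage="pT2", lvi=False, node_stage="N0",
        neoadjuvant_chemo=True, adjuvant_radiotherapy=False,
        survival_months=months, event=event,
        exam_date=date(2006, 1, 1) + timedelta(days=day),
    )


class TestCohortIO:
    def test_round_trip_preserves_everything(self, small_cohort, tmp_path):
        pairs, masks, records, _ = small_cohort
        save_cohort(tmp_path, pairs, masks, records)
        pairs2, masks2, records2 = load_cohort(tmp_path)
        assert len(pairs2) == len(pairs)
        assert len(masks2) == 2 * len(pairs)
        assert len(records2) == len(records)
        by_id = {p.patient_id: p for p in pairs2}
        for p in pairs:
            q = by_id[p.patient_id]
            np.testing.assert_allclose(q.pre_volume, p.pre_volume, rtol=1e-6)
            np.testing.assert_allclose(q.post_volume, p.post_volume, rtol=1e-6)
            assert q.voxel_spacing_pre == pytest.approx(p.voxel_spacing_pre)
            assert q.exam_date_pre == p.exam_date_pre
            assert q.exam_date_post == p.exam_date_post
        masks_by = {(m.patient_id, m.phase): m for m in masks2}
        for m in masks:
            q = masks_by[(m.patient_id, m.phase)]
            assert np.array_equal(q.mask, m.mask)
            assert q.voi_bbox == m.voi_bbox
        recs_by = {r.patient_id: r for r in records2}
        for r in records:
            q = recs_by[r.patient_id]
            for f in ("path_stage", "lvi", "node_stage", "neoadjuvant_chemo",
                      "adjuvant_radiotherapy", "survival_months", "event",
                      "label_5yr", "exam_date"):
                assert getattr(q, f) == getattr(r, f), f

    def test_missing_column_names_the_column(self, small_cohort, tmp_path):
        pairs, masks, records, _ = small_cohort
        save_cohort(tmp_path, pairs, masks, records)
        table = pd.read_csv(tmp_path / "clinical.csv")
        table.drop(columns=["lvi"]).to_csv(tmp_path / "clinical.csv", index=False)
        with pytest.raises(SchemaError, match="lvi"):
            load_cohort(tmp_path)

    def test_mask_volume_shape_mismatch_is_alignment_error(
        self, small_cohort, tmp_path
    ):
        pairs, masks, records, _ = small_cohort
        bad = [
            LesionMask(
                patient_id=m.patient_id, phase=m.phase,
                mask=np.pad(m.mask, ((0, 2), (0, 0), (0, 0))),
                voi_bbox=m.voi_bbox,
            )
            for m in masks
        ]
        save_cohort(tmp_path, pairs, bad, records)
        with pytest.raises(AlignmentError, match="shape"):
            load_cohort(tmp_path)


class TestClinicalRecord:
    def test_label_derived_with_60_month_horizon(self):
        assert derive_label_5yr(72.0, True) == 1
        assert derive_label_5yr(60.0, False) == 1
        assert derive_label_5yr(40.0, True) == 0
        assert derive_label_5yr(40.0, False) == 0  # censored early: not known alive
        assert _record("a", 0, months=80, event=False).label_5yr == 1
        assert _record("a", 0, months=30, event=True).label_5yr == 0

    def test_inconsistent_supplied_label_rejected(self):
        with pytest.raises(SchemaError, match="inconsistent"):
            ClinicalRecord(
                patient_id="x", path_stage="pT2", lvi=False, node_stage="N0",
                neoadjuvant_chemo=True, adjuvant_radiotherapy=False,
                survival_months=20.0, event=True, exam_date=date(2010, 1, 1),
                label_5yr=1,
            )

    def test_annotation_diameter_ordering_enforced(self):
        from cysurv.datatypes import ConfigError

        with pytest.raises(ConfigError):
            LesionAnnotation(longest_diameter_mm=10, perpendicular_diameter_mm=12)

    def test_volume_pair_rejects_reversed_exam_dates(self):
        from cysurv.datatypes import ConfigError

        vol = np.zeros((4, 4, 4))
        with pytest.raises(ConfigError, match="exam_date"):
            VolumePair(
                patient_id="x", pre_volume=vol, post_volume=vol,
                voxel_spacing_pre=(1, 1, 1), voxel_spacing_post=(1, 1, 1),
                exam_date_pre=date(2010, 5, 1), exam_date_post=date(2010, 1, 1),
            )


class TestSerialSplit:
    def test_cohort_of_163_splits_92_7_64(self):
        records = [_record(f"P{i:03d}", i) for i in range(163)]
        split = serial_split(records, (0.56, 0.04, 0.40))
        assert split.counts() == {"train": 92, "validation": 7, "test": 64}

    def test_latest_exams_become_the_test_set(self):
        records = [_record(f"P{i}", i) for i in range(10)]
        split = serial_split(records, (0.5, 0.2, 0.3))
        test = {f"P{i}" for i in (7, 8, 9)}
        assert set(split.patients("test")) == test
        # every test exam is at least as late as every train/validation exam
        dates = {r.patient_id: r.exam_date for r in records}
        latest_dev = max(dates[p] for p in split.patients("train")
                         + split.patients("validation"))
        assert all(dates[p] >= latest_dev for p in split.patients("test"))

    def test_invariant_to_input_order(self, rng):
        records = [_record(f"P{i:02d}", int(d))
                   for i, d in enumerate(rng.integers(0, 400, 30))]
        a = serial_split(records, (0.5, 0.2, 0.3))
        shuffled = list(records)
        rng.shuffle(shuffled)
        b = serial_split(shuffled, (0.5, 0.2, 0.3))
        assert a.assignment == b.assignment

    def test_date_ties_break_by_patient_id(self):
        records = [_record(p, 0) for p in ("B", "A", "D", "C")]
        split = serial_split(records, (0.5, 0.25, 0.25))
        assert split["A"] == "train" and split["B"] == "train"
        assert split["C"] == "validation" and split["D"] == "test"

    def test_too_few_records_rejected(self):
        with pytest.raises(SplitError):
            serial_split([_record("a", 0), _record("b", 1)], (0.5, 0.25, 0.25))

    def test_split_file_round_trip(self, tmp_path):
        records = [_record(f"P{i}", i) for i in range(10)]
        split = serial_split(records, (0.5, 0.2, 0.3))
        write_split(split, tmp_path / "split.csv")
        assert read_split(tmp_path / "split.csv").assignment == split.assignment
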