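"""Cohort file IO and the chronological (serial) train/validation/test split.

On-disk layout
--------------
``<dir>/<patient_id>_<phase>.nii.gz`` — intensity volumes, ``<phase>`` in
{pre, post}; ``<dir>/<patient_id>_<phase>_mask.nii.gz`` — binary masks;
``<dir>/clinical.csv`` — one row per patient with columns
``patient_id, path_stage, lvi, node_stage, neoadjuvant_chemo,
adjuvant_radiotherapy, survival_months, event, exam_date, exam_date_post``
and optionally ``label_5yr, contrast_phase``.

Arrays are stored in NIfTI ``(x, y, z)`` order and transposed to the package
``(z, y, x)`` convention on load; the affine is diagonal with the voxel
spacing.
"""

from __future__ import annotations

import math
import warnings
from datetime import date
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    AlignmentError,
    ClinicalRecord,
    ContrastPhase,
    LesionMask,
    Phase,
    SchemaError,
    SplitAssignment,
    SplitError,
    VolumePair,
)

__all__ = ["load_cohort", "save_cohort", "serial_split", "write_split", "read_split"]

REQUIRED_COLUMNS = (
    "patient_id",
    "path_stage",
    "lvi",
    "node_stage",
    "neoadjuvant_chemo",
    "adjuvant_radiotherapy",
    "survival_months",
    "event",
    "exam_date",
    "exam_date_post",
)

_BOOL_MAP = {
    "true": True, "false": False, "yes": True, "no": False, "1": True, "0": False,
    True: True, False: False, 1: True, 0: False,
}


def _as_bool(value) -> bool:
    key = value.strip().lower() if isinstance(value, str) else value
    try:
        return _BOOL_MAP[key]
    except KeyError:
        raise SchemaError(f"cannot interpret {value!r} as a boolean") from None


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value).strip())


def _nifti_path(directory: Path, patient_id: str, phase: Phase, mask: bool) -> Path:
    suffix = "_mask" if mask else ""
    return directory / f"{patient_id}_{phase.value}{suffix}.nii.gz"


def _write_nifti(path: Path, array: np.ndarray, spacing: tuple[float, float, float]) -> None:
    dz, dy, dx = spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.asarray(array).transpose(2, 1, 0), affine)
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    return data, (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def save_cohort(
    directory: str | Path,
    pairs: list[VolumePair],
    masks: list[LesionMask],
    records: list[ClinicalRecord],
) -> Path:
    """Write volumes, masks and the clinical table to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_id = {p.patient_id: p for p in pairs}
    for pair in pairs:
        for phase in Phase:
            _write_nifti(
                _nifti_path(directory, pair.patient_id, phase, mask=False),
                pair.volume(phase).astype(np.float32),
                pair.spacing(phase),
            )
    for m in masks:
        pair = by_id[m.patient_id]
        _write_nifti(
            _nifti_path(directory, m.patient_id, m.phase, mask=True),
            m.mask.astype(np.uint8),
            pair.spacing(m.phase),
        )
    rows = []
    for r in records:
        pair = by_id.get(r.patient_id)
        rows.append(
            {
                "patient_id": r.patient_id,
                "path_stage": r.path_stage,
                "lvi": r.lvi,
                "node_stage": r.node_stage,
                "neoadjuvant_chemo": r.neoadjuvant_chemo,
                "adjuvant_radiotherapy": r.adjuvant_radiotherapy,
                "survival_months": r.survival_months,
                "event": r.event,
                "label_5yr": r.label_5yr,
                "exam_date": r.exam_date.isoformat(),
                "exam_date_post": (
                    pair.exam_date_post.isoformat() if pair else r.exam_date.isoformat()
                ),
                "contrast_phase": (
                    pair.contrast_phase.value if pair else ContrastPhase.UNKNOWN.value
                ),
            }
        )
    pd.DataFrame(rows).to_csv(directory / "clinical.csv", index=False)
    return directory


def load_cohort(
    volume_dir: str | Path, clinical_table: str | Path | None = None
) -> tuple[list[VolumePair], list[LesionMask], list[ClinicalRecord]]:
    """Load a cohort from disk, matching masks to volumes by patient and phase.

    Raises :class:`SchemaError` if required clinical columns are missing and
    :class:`AlignmentError` on mask/volume shape mismatch. Patients present in
    the table but lacking either scan (or vice versa) are reported via
    :class:`UserWarning` and skipped from the pair list.
    """
    volume_dir = Path(volume_dir)
    clinical_table = Path(clinical_table) if clinical_table else volume_dir / "clinical.csv"
    if not clinical_table.exists():
        raise SchemaError(f"clinical table not found: {clinical_table}")
    table = pd.read_csv(clinical_table, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"clinical table missing required column(s): {missing}")

    records: list[ClinicalRecord] = []
    pairs: list[VolumePair] = []
    masks: list[LesionMask] = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        record = ClinicalRecord(
            patient_id=pid,
            path_stage=str(row["path_stage"]),
            lvi=_as_bool(row["lvi"]),
            node_stage=str(row["node_stage"]),
            neoadjuvant_chemo=_as_bool(row["neoadjuvant_chemo"]),
            adjuvant_radiotherapy=_as_bool(row["adjuvant_radiotherapy"]),
            survival_months=float(row["survival_months"]),
            event=_as_bool(row["event"]),
            exam_date=_as_date(row["exam_date"]),
            label_5yr=(int(row["label_5yr"]) if "label_5yr" in table.columns
                       and not pd.isna(row.get("label_5yr")) else None),
        )
        records.append(record)

        vol_paths = {ph: _nifti_path(volume_dir, pid, ph, mask=False) for ph in Phase}
        if not all(p.exists() for p in vol_paths.values()):
            warnings.warn(f"patient {pid}: missing volume file(s); pair skipped")
            continue
        volumes, spacings = {}, {}
        for ph, path in vol_paths.items():
            volumes[ph], spacings[ph] = _read_nifti(path)
        phase_str = str(row.get("contrast_phase", "unknown"))
        pair = VolumePair(
            patient_id=pid,
            pre_volume=volumes[Phase.PRE],
            post_volume=volumes[Phase.POST],
            voxel_spacing_pre=spacings[Phase.PRE],
            voxel_spacing_post=spacings[Phase.POST],
            exam_date_pre=_as_date(row["exam_date"]),
            exam_date_post=_as_date(row["exam_date_post"]),
            contrast_phase=ContrastPhase(phase_str) if phase_str else ContrastPhase.UNKNOWN,
        )
        pairs.append(pair)
        for ph in Phase:
            mpath = _nifti_path(volume_dir, pid, ph, mask=True)
            if not mpath.exists():
                warnings.warn(f"patient {pid}: missing {ph.value} mask; skipped")
                continue
            mask_arr, _ = _read_nifti(mpath)
            if mask_arr.shape != volumes[ph].shape:
                raise AlignmentError(
                    f"patient {pid} ({ph.value}): mask shape {mask_arr.shape} "
                    f"!= volume shape {volumes[ph].shape}"
                )
            masks.append(
                LesionMask(
                    patient_id=pid,
                    phase=ph,
                    mask=mask_arr > 0,
                    voi_bbox=LesionMask.bbox_from_mask(mask_arr > 0),
                )
            )
    return pairs, masks, records


def serial_split(
    records: list[ClinicalRecord],
    fractions: tuple[float, float, float] = (0.56, 0.04, 0.40),
) -> SplitAssignment:
    """Chronological cohort split: earliest exams train, latest exams test.

    Records are sorted by exam date (ties broken by patient id); the earliest
    block becomes the training set, the next the validation set and the most
    recent the test set, emulating deployment of a frozen model on incoming
    cases. Block sizes are ``ceil(n*f_train)`` and ``round(n*f_val)`` with the
    remainder to test, which reproduces a 92/7/64 split of 163 patients at
    fractions (0.56, 0.04, 0.40).
    """
    if len(records) < 3:
        raise SplitError(f"need at least 3 records to split, got {len(records)}")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise SplitError(f"fractions must sum to 1, got {fractions}")
    n = len(records)
    n_train = math.ceil(n * fractions[0])
    n_val = round(n * fractions[1])
    n_test = n - n_train - n_val
    if min(n_train, n_test) < 1 or n_val < 0 or n_test < 0:
        raise SplitError(f"fractions {fractions} give empty train or test for n={n}")
    ordered = sorted(records, key=lambda r: (r.exam_date, r.patient_id))
    assignment: dict[str, str] = {}
    for i, rec in enumerate(ordered):
        if i < n_train:
            assignment[rec.patient_id] = "train"
        elif i < n_train + n_val:
            assignment[rec.patient_id] = "validation"
        else:
            assignment[rec.patient_id] = "test"
    return SplitAssignment(assignment)


def write_split(split: SplitAssignment, path: str | Path) -> None:
    pd.DataFrame(
        sorted(split.assignment.items()), columns=["patient_id", "split"]
    ).to_csv(path, index=False)


def read_split(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path, dtype=str)
    if not {"patient_id", "split"} <= set(df.columns):
        raise SchemaError("split file must have columns patient_id, split")
    return SplitAssignment(dict(zip(df["patient_id"], df["split"])))
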