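"""Domain types shared across the survival-prediction pipeline.

Conventions: arrays are indexed ``(z, y, x)`` with 0-based coordinates and
half-open bounding boxes; voxel spacing is ``(dz, dy, dx)`` in millimetres;
dates are :class:`datetime.date`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np

__all__ = [
    "ContrastPhase",
    "Phase",
    "LesionLocation",
    "VolumePair",
    "LesionMask",
    "LesionAnnotation",
    "ClinicalRecord",
    "SplitAssignment",
    "PATH_STAGE_LEVELS",
    "NODE_STAGE_LEVELS",
    "CysurvError",
    "SchemaError",
    "AlignmentError",
    "SplitError",
    "ExtractionError",
    "SelectionError",
    "ConfigError",
    "ContractError",
    "AssemblyError",
    "EvaluationError",
    "TrainingError",
]


class CysurvError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CysurvError):
    """A tabular or JSON input violates the documented schema."""


class AlignmentError(CysurvError):
    """A mask does not align with its volume."""


class SplitError(CysurvError):
    """The cohort cannot be split as requested."""


class ExtractionError(CysurvError):
    """Feature or ROI extraction failed on the given input."""


class SelectionError(CysurvError):
    """Feature selection preconditions violated."""


class ConfigError(CysurvError):
    """A configuration object is invalid or degenerate."""


class ContractError(CysurvError):
    """An inter-stage calling contract was violated."""


class AssemblyError(CysurvError):
    """Descriptor blocks required for a combination are missing."""


class EvaluationError(CysurvError):
    """An evaluation statistic is undefined on the given input."""


class TrainingError(CysurvError):
    """A model cannot be trained on the given data (e.g. single class)."""


class ContrastPhase(str, enum.Enum):
    EARLY = "early"
    DELAYED = "delayed"
    NON_CONTRAST = "non_contrast"
    UNKNOWN = "unknown"


class Phase(str, enum.Enum):
    PRE = "pre"
    POST = "post"


class LesionLocation(str, enum.Enum):
    BLADDER = "bladder"
    URETER = "ureter"
    OTHER = "other"


#: Ordinal pathologic tumour stage levels, least to most advanced.
PATH_STAGE_LEVELS = ("pT0", "pTa/pTi/pTis", "pT1", "pT2", "pT3", "pT4")

#: Ordinal pathologic node stage levels.
NODE_STAGE_LEVELS = ("N0", "N1", "N2", "N3")


def _check_volume(name: str, vol: np.ndarray, spacing: tuple[float, float, float]) -> None:
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise AlignmentError(f"{name} must be a rank-3 array, got rank {vol.ndim}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ConfigError(f"{name} spacing must be 3 positive values, got {spacing!r}")


@dataclass
class VolumePair:
    """Paired pre-/post-treatment scan volumes for one patient.

    The pre scan precedes neoadjuvant chemotherapy and the post scan follows
    it; both are scalar intensity volumes (e.g. Hounsfield units).
    """

    patient_id: str
    pre_volume: np.ndarray
    post_volume: np.ndarray
    voxel_spacing_pre: tuple[float, float, float]
    voxel_spacing_post: tuple[float, float, float]
    exam_date_pre: date
    exam_date_post: date
    contrast_phase: ContrastPhase = ContrastPhase.UNKNOWN

    def __post_init__(self) -> None:
        _check_volume("pre_volume", self.pre_volume, self.voxel_spacing_pre)
        _check_volume("post_volume", self.post_volume, self.voxel_spacing_post)
        if self.exam_date_pre > self.exam_date_post:
            raise ConfigError(
                f"patient {self.patient_id}: exam_date_pre {self.exam_date_pre} "
                f"after exam_date_post {self.exam_date_post}"
            )

    def volume(self, phase: Phase | str) -> np.ndarray:
        return self.pre_volume if Phase(phase) is Phase.PRE else self.post_volume

    def spacing(self, phase: Phase | str) -> tuple[float, float, float]:
        return (
            self.voxel_spacing_pre
            if Phase(phase) is Phase.PRE
            else self.voxel_spacing_post
        )


@dataclass
class LesionMask:
    """Binary lesion segmentation aligned to one phase's volume.

    ``voi_bbox`` is the axis-aligned volume of interest, 0-based half-open,
    as ``((z0, z1), (y0, y1), (x0, x1))``.
    """

    patient_id: str
    phase: Phase
    mask: np.ndarray
    voi_bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        self.phase = Phase(self.phase)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise AlignmentError("mask must be rank 3")
        (z0, z1), (y0, y1), (x0, x1) = self.voi_bbox
        if not self.mask[z0:z1, y0:y1, x0:x1].any():
            raise AlignmentError(
                f"patient {self.patient_id} ({self.phase.value}): "
                "mask is empty inside voi_bbox"
            )

    def check_alignment(self, volume: np.ndarray) -> None:
        if self.mask.shape != np.asarray(volume).shape:
            raise AlignmentError(
                f"patient {self.patient_id} ({self.phase.value}): mask shape "
                f"{self.mask.shape} != volume shape {np.asarray(volume).shape}"
            )

    @staticmethod
    def bbox_from_mask(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
        """Tight half-open bounding box of the nonzero voxels."""
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise AlignmentError("cannot derive a VOI bbox from an empty mask")
        nz = np.nonzero(mask)
        return tuple((int(ax.min()), int(ax.max()) + 1) for ax in nz)


@dataclass
class LesionAnnotation:
    """Radiologist lesion measurements and qualitative ratings."""

    longest_diameter_mm: float
    perpendicular_diameter_mm: float
    location: LesionLocation = LesionLocation.BLADDER
    lesion_type: str = ""
    edge: str = ""
    likelihood: str = ""

    def __post_init__(self) -> None:
        self.location = LesionLocation(self.location)
        if self.longest_diameter_mm <= 0 or self.perpendicular_diameter_mm <= 0:
            raise ConfigError("lesion diameters must be positive")
        if self.perpendicular_diameter_mm > self.longest_diameter_mm:
            raise ConfigError("perpendicular diameter exceeds longest diameter")


def derive_label_5yr(survival_months: float, event: bool) -> int:
    """Five-year survival label from follow-up time and event status.

    1 means the patient is known alive at 60 months (death after 60 months or
    censoring at/after 60 months). Patients who died before 60 months are 0.
    Patients censored before 60 months have an unknown 5-year status; they are
    labelled 0 here, a documented convention (not knowledge of death).
    """
    return int(survival_months >= 60.0)


@dataclass
class ClinicalRecord:
    """One patient's clinical indices and survival outcome.

    The five prognostic indices are post-surgery pathologic stage,
    lymphovascular invasion, pathologic node stage, neoadjuvant chemotherapy
    and adjuvant radiotherapy.
    """

    patient_id: str
    path_stage: str
    lvi: bool
    node_stage: str
    neoadjuvant_chemo: bool
    adjuvant_radiotherapy: bool
    survival_months: float
    event: bool
    exam_date: date
    label_5yr: int | None = None

    def __post_init__(self) -> None:
        if self.path_stage not in PATH_STAGE_LEVELS:
            raise SchemaError(
                f"unknown path_stage {self.path_stage!r}; expected one of {PATH_STAGE_LEVELS}"
            )
        if self.node_stage not in NODE_STAGE_LEVELS:
            raise SchemaError(
                f"unknown node_stage {self.node_stage!r}; expected one of {NODE_STAGE_LEVELS}"
            )
        if self.survival_months < 0:
            raise SchemaError("survival_months must be non-negative")
        derived = derive_label_5yr(self.survival_months, self.event)
        if self.label_5yr is None:
            self.label_5yr = derived
        else:
            self.label_5yr = int(self.label_5yr)
            # A supplied label must be consistent with follow-up: a patient
            # labelled alive-at-5-years cannot have died before 60 months, and
            # one followed past 60 months cannot be labelled 0.
            if self.label_5yr == 1 and self.survival_months < 60 and self.event:
                raise SchemaError(
                    f"patient {self.patient_id}: label_5yr=1 inconsistent with "
                    f"death at {self.survival_months} months"
                )
            if self.label_5yr == 0 and self.survival_months >= 60:
                raise SchemaError(
                    f"patient {self.patient_id}: label_5yr=0 inconsistent with "
                    f"follow-up of {self.survival_months} months"
                )


@dataclass
class SplitAssignment:
    """Partition of patients into train / validation / test sets."""

    assignment: Mapping[str, str] = field(default_factory=dict)

    VALID = ("train", "validation", "test")

    def __post_init__(self) -> None:
        bad = {s for s in self.assignment.values() if s not in self.VALID}
        if bad:
            raise SplitError(f"invalid split names: {sorted(bad)}")

    def __getitem__(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def patients(self, split: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == split]

    def counts(self) -> dict[str, int]:
        return {s: len(self.patients(s)) for s in self.VALID}
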