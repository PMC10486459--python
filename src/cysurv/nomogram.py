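"""Points-based survival nomogram evaluation.

A nomogram maps each of the five clinical indices (pathologic stage,
lymphovascular invasion, pathologic node stage, neoadjuvant chemotherapy,
adjuvant radiotherapy) to a point value; the total points map to a 5-year
survival probability through a monotone non-increasing piecewise-linear
curve, the machine-readable form of the graphical probability axis of a
published nomogram.

The packaged default spec (:func:`synthetic_nomogram_spec`) has the correct
structure and a *synthetic placeholder calibration* — monotone in stage, LVI
and node severity — and must be replaced by a spec transcribed from a
published nomogram for any clinical use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalRecord,
    EvaluationError,
    NODE_STAGE_LEVELS,
    PATH_STAGE_LEVELS,
    SchemaError,
)

__all__ = [
    "NomogramSpec",
    "ClinicalDescriptor",
    "load_nomogram_spec",
    "write_nomogram_spec",
    "synthetic_nomogram_spec",
    "evaluate_nomogram",
    "clinical_points_frame",
    "CLINICAL_INDICES",
]

#: The five clinical indices, in the frozen descriptor column order.
CLINICAL_INDICES = (
    "path_stage",
    "lvi",
    "node_stage",
    "neoadjuvant_chemo",
    "adjuvant_radiotherapy",
)

_REQUIRED_LEVELS: dict[str, tuple[str, ...]] = {
    "path_stage": PATH_STAGE_LEVELS,
    "lvi": ("no", "yes"),
    "node_stage": NODE_STAGE_LEVELS,
    "neoadjuvant_chemo": ("no", "yes"),
    "adjuvant_radiotherapy": ("no", "yes"),
}


@dataclass
class NomogramSpec:
    """Point mappings plus the total-points -> survival-probability curve."""

    points: dict[str, dict[str, float]]
    survival_curve: list[tuple[float, float]]
    horizon_years: int = 5

    def __post_init__(self) -> None:
        for index, levels in _REQUIRED_LEVELS.items():
            if index not in self.points:
                raise SchemaError(f"nomogram spec missing index {index!r}")
            for level in levels:
                if level not in self.points[index]:
                    raise SchemaError(
                        f"nomogram spec missing level {level!r} of index {index!r}"
                    )
        unknown = set(self.points) - set(_REQUIRED_LEVELS)
        if unknown:
            raise SchemaError(f"unknown nomogram index name(s): {sorted(unknown)}")
        if len(self.survival_curve) < 2:
            raise SchemaError("survival curve needs at least 2 knots")
        self.survival_curve = [(float(t), float(p)) for t, p in self.survival_curve]
        totals = [t for t, _ in self.survival_curve]
        probs = [p for _, p in self.survival_curve]
        if any(b <= a for a, b in zip(totals, totals[1:])):
            raise SchemaError("survival-curve knots must have increasing total points")
        if any(b > a for a, b in zip(probs, probs[1:])):
            raise SchemaError(
                "survival probability must be monotone non-increasing in total points"
            )
        if min(probs) < 0 or max(probs) > 1:
            raise SchemaError("survival probabilities must lie in [0, 1]")

    def probability(self, total_points: float) -> float:
        """Linear interpolation between knots, clamped at the end knots."""
        totals = np.array([t for t, _ in self.survival_curve])
        probs = np.array([p for _, p in self.survival_curve])
        return float(np.interp(total_points, totals, probs))


@dataclass
class ClinicalDescriptor:
    """Per-index points, their total, and the mapped survival probability."""

    patient_id: str
    index_points: dict[str, float]
    total_points: float = field(init=False)
    survival_probability: float = 0.0

    def __post_init__(self) -> None:
        self.total_points = float(sum(self.index_points.values()))


def synthetic_nomogram_spec() -> NomogramSpec:
    """Synthetic placeholder nomogram with plausible monotone point axes.

    The point values are NOT transcribed from any published nomogram; they
    only preserve the structure (monotone severity ordering, a 0-100 point
    scale per index, a decreasing probability curve).
    """
    return NomogramSpec(
        points={
            "path_stage": {
                "pT0": 0.0, "pTa/pTi/pTis": 8.0, "pT1": 20.0,
                "pT2": 45.0, "pT3": 75.0, "pT4": 100.0,
            },
            "lvi": {"no": 0.0, "yes": 40.0},
            "node_stage": {"N0": 0.0, "N1": 45.0, "N2": 60.0, "N3": 70.0},
            "neoadjuvant_chemo": {"no": 0.0, "yes": 5.0},
            "adjuvant_radiotherapy": {"no": 0.0, "yes": 10.0},
        },
        survival_curve=[
            (0.0, 0.92), (50.0, 0.80), (100.0, 0.62),
            (150.0, 0.40), (200.0, 0.22), (260.0, 0.08),
        ],
        horizon_years=5,
    )


def load_nomogram_spec(path: str | Path) -> NomogramSpec:
    """Load and validate a nomogram spec from JSON."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"nomogram spec is not valid JSON: {exc}") from exc
    try:
        return NomogramSpec(
            points={k: {lv: float(p) for lv, p in v.items()}
                    for k, v in payload["points"].items()},
            survival_curve=[tuple(knot) for knot in payload["survival_curve"]],
            horizon_years=int(payload.get("horizon_years", 5)),
        )
    except KeyError as exc:
        raise SchemaError(f"nomogram spec missing key {exc}") from exc


def write_nomogram_spec(spec: NomogramSpec, path: str | Path) -> None:
    payload = {
        "points": spec.points,
        "survival_curve": [list(k) for k in spec.survival_curve],
        "horizon_years": spec.horizon_years,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _level_of(record: ClinicalRecord, index: str) -> str:
    value = getattr(record, index)
    if isinstance(value, bool):
        return "yes" if value else "no"
    return str(value)


def evaluate_nomogram(record: ClinicalRecord, spec: NomogramSpec) -> ClinicalDescriptor:
    """Map one patient's indices to points, total points and probability."""
    index_points: dict[str, float] = {}
    for index in CLINICAL_INDICES:
        level = _level_of(record, index)
        try:
            index_points[index] = float(spec.points[index][level])
        except KeyError:
            raise EvaluationError(
                f"nomogram spec has no points for level {level!r} of {index!r}"
            ) from None
    desc = ClinicalDescriptor(patient_id=record.patient_id, index_points=index_points)
    desc.survival_probability = spec.probability(desc.total_points)
    return desc


def clinical_points_frame(
    records: list[ClinicalRecord], spec: NomogramSpec
) -> pd.DataFrame:
    """Per-patient point values (5 columns), total points and probability."""
    rows = {}
    for r in records:
        d = evaluate_nomogram(r, spec)
        row = {f"points_{idx}": d.index_points[idx] for idx in CLINICAL_INDICES}
        row["total_points"] = d.total_points
        row["survival_probability"] = d.survival_probability
        rows[r.patient_id] = row
    df = pd.DataFrame(rows).T.sort_index()
    df.index.name = "patient_id"
    return df
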