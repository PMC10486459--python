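"""Hybrid-ROI construction from paired pre/post-treatment scans.

A hybrid ROI is a 32x32 patch whose left half (columns 0-15) is a 32x16
sub-window of the pre-treatment central lesion slice and whose right half
(columns 16-31) is a 32x16 sub-window of the post-treatment slice, so each
training sample encodes treatment change directly. Sub-windows are cut from
the lesion VOI with a sliding window; per case, pre/post window pairings are
formed (cross product by default) and capped by seeded subsampling so large
lesions cannot dominate the dataset. Every patch inherits its case's 5-year
survival label.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ContractError, LesionMask, Phase, VolumePair
from .radiomics import select_central_slice

__all__ = [
    "ROI_SHAPE",
    "HALF_SHAPE",
    "HybridROI",
    "ROIDatasetConfig",
    "extract_subrois",
    "compose_hybrid",
    "build_roi_dataset",
    "dataset_arrays",
    "dataset_manifest",
]

#: Full hybrid patch shape (rows, columns).
ROI_SHAPE = (32, 32)
#: Shape of each phase's half (rows, columns).
HALF_SHAPE = (32, 16)


@dataclass
class SubROI:
    """One 32x16 window cut from a phase's central slice."""

    pixels: np.ndarray
    origin: tuple[int, int]  # (row, col) of the window in the padded VOI frame
    padded: bool = False


@dataclass
class HybridROI:
    """A composed 32x32 patch with provenance."""

    patch: np.ndarray
    patient_id: str
    label: int
    pre_origin: tuple[int, int]
    post_origin: tuple[int, int]
    padded: bool = False


@dataclass
class ROIDatasetConfig:
    """Controls sub-window extraction, pairing and capping."""

    stride: int = 4
    max_hybrids_per_case: int = 64
    intensity_window: tuple[float, float] = (-50.0, 150.0)
    pairing: str = "cross_product"  # or "random_pairs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ContractError("stride must be >= 1")
        if self.max_hybrids_per_case < 1:
            raise ContractError("max_hybrids_per_case must be >= 1")
        lo, hi = self.intensity_window
        if hi <= lo:
            raise ContractError("intensity_window must be (lower, upper) with upper > lower")
        if self.pairing not in ("cross_product", "random_pairs"):
            raise ContractError(f"unknown pairing rule {self.pairing!r}")


def extract_subrois(
    volume: np.ndarray,
    voi_bbox,
    slice_index: int,
    window: tuple[int, int] = HALF_SHAPE,
    stride: int = 4,
) -> list[SubROI]:
    """Sliding 32x16 windows over the VOI at ``slice_index``.

    If the VOI is smaller than the window along an axis it is symmetrically
    zero-padded up to the window size along that axis (windows flagged
    ``padded``); a VOI smaller than the window in both axes yields a single
    centred zero-padded window. Windows are returned in deterministic
    row-major origin order.
    """
    wh, ww = window
    (_, _), (y0, y1), (x0, x1) = voi_bbox
    region = np.asarray(volume, dtype=np.float64)[slice_index, y0:y1, x0:x1]
    padded = False
    if region.shape[0] < wh:
        deficit = wh - region.shape[0]
        region = np.pad(region, ((deficit // 2, deficit - deficit // 2), (0, 0)))
        padded = True
    if region.shape[1] < ww:
        deficit = ww - region.shape[1]
        region = np.pad(region, ((0, 0), (deficit // 2, deficit - deficit // 2)))
        padded = True
    h, w = region.shape
    out = []
    for r in range(0, h - wh + 1, stride):
        for c in range(0, w - ww + 1, stride):
            out.append(SubROI(region[r : r + wh, c : c + ww].copy(), (r, c), padded))
    return out


def compose_hybrid(
    pre_roi: np.ndarray,
    post_roi: np.ndarray,
    intensity_window: tuple[float, float] = (-50.0, 150.0),
) -> np.ndarray:
    """Concatenate normalized pre (left) and post (right) halves into 32x32.

    Intensities are mapped to [0, 1] by the fixed window ``(lower, upper)``
    and clipped, keeping pre and post halves on a common scale.
    """
    pre_roi = np.asarray(pre_roi, dtype=np.float64)
    post_roi = np.asarray(post_roi, dtype=np.float64)
    if pre_roi.shape != HALF_SHAPE or post_roi.shape != HALF_SHAPE:
        raise ContractError(
            f"hybrid halves must be {HALF_SHAPE}, got {pre_roi.shape} and {post_roi.shape}"
        )
    lo, hi = intensity_window
    patch = np.concatenate([pre_roi, post_roi], axis=1)
    return np.clip((patch - lo) / (hi - lo), 0.0, 1.0)


def _case_rng(seed: int, patient_id: str) -> np.random.Generator:
    # Stable per-case stream, independent of case iteration order.
    return np.random.default_rng(
        (int(seed) * 2654435761 + zlib.crc32(patient_id.encode())) % (2**31)
    )


def build_roi_dataset(
    pairs: list[VolumePair],
    masks: list[LesionMask],
    labels: dict[str, int],
    config: ROIDatasetConfig,
) -> list[HybridROI]:
    """Build the labelled hybrid-ROI dataset for a set of cases.

    Pairings of pre/post windows are generated per the configured rule, then
    truncated to ``max_hybrids_per_case`` by seeded uniform subsampling.
    Cases without windows in either phase are skipped with a warning.
    """
    by_case: dict[str, dict[Phase, LesionMask]] = {}
    for m in masks:
        by_case.setdefault(m.patient_id, {})[m.phase] = m
    out: list[HybridROI] = []
    for pair in pairs:
        pid = pair.patient_id
        case_masks = by_case.get(pid, {})
        if Phase.PRE not in case_masks or Phase.POST not in case_masks:
            warnings.warn(f"case {pid}: missing mask(s); skipped")
            continue
        windows: dict[Phase, list[SubROI]] = {}
        for phase in Phase:
            mask = case_masks[phase]
            z = select_central_slice(mask)
            windows[phase] = extract_subrois(
                pair.volume(phase), mask.voi_bbox, z, HALF_SHAPE, config.stride
            )
        if not windows[Phase.PRE] or not windows[Phase.POST]:
            warnings.warn(f"case {pid}: no windows extracted; skipped")
            continue
        rng = _case_rng(config.seed, pid)
        n_pre, n_post = len(windows[Phase.PRE]), len(windows[Phase.POST])
        if config.pairing == "cross_product":
            pairings = [(i, j) for i in range(n_pre) for j in range(n_post)]
        else:  # random_pairs: one random post partner per pre window
            pairings = [(i, int(rng.integers(n_post))) for i in range(n_pre)]
        if len(pairings) > config.max_hybrids_per_case:
            keep = rng.choice(len(pairings), config.max_hybrids_per_case, replace=False)
            pairings = [pairings[k] for k in sorted(keep)]
        label = int(labels[pid])
        for i, j in pairings:
            pre_w, post_w = windows[Phase.PRE][i], windows[Phase.POST][j]
            out.append(
                HybridROI(
                    patch=compose_hybrid(
                        pre_w.pixels, post_w.pixels, config.intensity_window
                    ),
                    patient_id=pid,
                    label=label,
                    pre_origin=pre_w.origin,
                    post_origin=post_w.origin,
                    padded=pre_w.padded or post_w.padded,
                )
            )
    return out


def dataset_arrays(rois: list[HybridROI]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a ROI list into ``(patches, labels, patient_ids)`` arrays."""
    X = np.stack([r.patch for r in rois]).astype(np.float32)
    y = np.array([r.label for r in rois], dtype=np.int64)
    ids = np.array([r.patient_id for r in rois], dtype=object)
    return X, y, ids


def dataset_manifest(
    rois: list[HybridROI], split: dict[str, str] | None = None
) -> pd.DataFrame:
    """Provenance table: one row per patch."""
    rows = [
        {
            "patient_id": r.patient_id,
            "label": r.label,
            "pre_row": r.pre_origin[0],
            "pre_col": r.pre_origin[1],
            "post_row": r.post_origin[0],
            "post_col": r.post_origin[1],
            "padded": r.padded,
            "split": (split or {}).get(r.patient_id, ""),
        }
        for r in rois
    ]
    return pd.DataFrame(rows)
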