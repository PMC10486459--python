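"""Synthetic paired-scan cohort generator with controllable planted signal.

The generator emulates the structure of a post-cystectomy CT-urography study:
each patient has a pre-treatment and a post-treatment scan containing one
ellipsoidal bladder lesion, five clinical indices, and a survival outcome.
Three independent effect dials plant signal for the downstream stages:

``shrinkage_effect``
    Extra mean fractional pre-to-post lesion volume reduction in 5-year
    survivors relative to non-survivors (responders shrink more). Drives the
    difference-feature radiomics and the hybrid-ROI CNN.
``texture_effect``
    Extra post-treatment intra-lesion noise scale (intensity units) in
    non-survivors (residual disease is rougher). Drives texture features.
``clinical_effect``
    Log-odds shift towards favourable pathologic stage / node stage / absent
    LVI in survivors relative to non-survivors (applied symmetrically, half
    to each group, so the marginal index frequencies stay near the emulated
    cohort's). Drives the nomogram-based clinical descriptor.

With all three at zero, every descriptor is pure noise with respect to the
outcome. Generation is fully deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datatypes import (
    ClinicalRecord,
    ConfigError,
    ContrastPhase,
    LesionMask,
    NODE_STAGE_LEVELS,
    PATH_STAGE_LEVELS,
    Phase,
    VolumePair,
)

__all__ = ["SimConfig", "IntensityParams", "render_lesion", "generate_cohort"]

# Marginal index frequencies of the emulated cohort (163 patients):
# pT0/pTa/pT1/pT2/pT3/pT4 = 35/15/16/36/45/16, LVI yes = 61, N0-N3 = 112/24/23/4.
_STAGE_BASE = np.array([35, 15, 16, 36, 45, 16], dtype=float) / 163.0
_NODE_BASE = np.array([112, 24, 23, 4], dtype=float) / 163.0
_LVI_BASE = 61.0 / 163.0
# Severity scores used to tilt index distributions for survivors; roughly the
# relative prognostic weight of each level.
_STAGE_SEVERITY = np.array([0.0, 0.2, 0.35, 0.55, 0.8, 1.0])
_NODE_SEVERITY = np.array([0.0, 0.6, 0.8, 1.0])


@dataclass
class IntensityParams:
    """Intensity model for a rendered scan, in CT-like units (HU)."""

    background: float = 30.0
    lesion_contrast: float = 45.0
    background_noise: float = 5.0
    noise_correlation_px: float = 1.2


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator."""

    n_patients: int = 40
    seed: int = 0
    volume_shape: tuple[int, int, int] = (28, 56, 56)
    voxel_spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    lesion_radius_range_mm: tuple[float, float] = (8.0, 18.0)
    shrinkage_effect: float = 0.4
    texture_effect: float = 6.0
    clinical_effect: float = 1.0
    censor_rate: float = 0.15
    survivor_rate: float = 0.5
    base_shrinkage: float = 0.25
    base_noise_scale: float = 10.0
    intensity: IntensityParams = field(default_factory=IntensityParams)
    first_exam: date = date(2006, 1, 15)
    exam_interval_days: int = 9

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ConfigError("n_patients must be at least 4")
        if not (0.0 <= self.shrinkage_effect <= 1.0):
            raise ConfigError("shrinkage_effect must lie in [0, 1]")
        if self.texture_effect < 0 or self.clinical_effect < 0:
            raise ConfigError("texture_effect and clinical_effect must be >= 0")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ConfigError("censor_rate must lie in [0, 1]")
        lo, hi = self.lesion_radius_range_mm
        if not (0 < lo <= hi):
            raise ConfigError("lesion_radius_range_mm must be 0 < lo <= hi")
        max_extent_mm = min(
            s * d for s, d in zip(self.volume_shape, self.voxel_spacing)
        )
        if 2 * hi >= max_extent_mm:
            raise ConfigError(
                f"largest lesion diameter {2 * hi} mm does not fit in a volume "
                f"of {max_extent_mm} mm minimum extent"
            )


def render_lesion(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii_mm: tuple[float, float, float],
    spacing: tuple[float, float, float],
    intensity_params: IntensityParams,
    noise_scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one ellipsoidal lesion into a noisy background volume.

    ``center`` is in voxel coordinates (z, y, x); ``radii_mm`` are the
    ellipsoid semi-axes in millimetres. The lesion adds a constant contrast
    plus spatially correlated noise of standard deviation ``noise_scale``
    inside the mask. Returns ``(volume, mask)``.
    """
    shape = tuple(int(s) for s in shape)
    radii_vox = np.asarray(radii_mm, float) / np.asarray(spacing, float)
    if np.any(radii_vox < 0.5):
        raise ConfigError(f"lesion radii {radii_mm} mm are below voxel size")
    center = np.asarray(center, float)
    if np.any(center - radii_vox < 0) or np.any(center + radii_vox > np.asarray(shape) - 1):
        raise ConfigError("ellipsoid extends outside the volume")

    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    mask = dist2 <= 1.0
    if not mask.any():
        raise ConfigError("degenerate lesion: empty mask")

    p = intensity_params
    volume = np.full(shape, p.background, dtype=np.float32)
    if p.background_noise > 0:
        bg = gaussian_filter(rng.standard_normal(shape), p.noise_correlation_px)
        sd = bg.std()
        if sd > 0:
            volume += (p.background_noise * bg / sd).astype(np.float32)
    volume[mask] += p.lesion_contrast
    if noise_scale > 0:
        tex = gaussian_filter(rng.standard_normal(shape), p.noise_correlation_px)
        sd = tex[mask].std()
        if sd > 0:
            volume[mask] += (noise_scale * tex[mask] / sd).astype(np.float32)
    return volume, mask


def _tilted(base: np.ndarray, severity: np.ndarray, shift: float) -> np.ndarray:
    """Tilt a categorical distribution towards low-severity levels."""
    w = base * np.exp(-shift * severity)
    return w / w.sum()


def _sample_clinical(
    rng: np.random.Generator, survivor: bool, effect: float
) -> dict[str, object]:
    shift = 0.5 * effect if survivor else -0.5 * effect
    stage_p = _tilted(_STAGE_BASE, _STAGE_SEVERITY, shift)
    node_p = _tilted(_NODE_BASE, _NODE_SEVERITY, shift)
    lvi_logit = np.log(_LVI_BASE / (1 - _LVI_BASE)) - shift
    lvi_p = 1.0 / (1.0 + np.exp(-lvi_logit))
    return {
        "path_stage": PATH_STAGE_LEVELS[rng.choice(len(stage_p), p=stage_p)],
        "node_stage": NODE_STAGE_LEVELS[rng.choice(len(node_p), p=node_p)],
        "lvi": bool(rng.random() < lvi_p),
        # All emulated patients received neoadjuvant chemotherapy and none
        # received adjuvant radiotherapy, matching the cohort structure.
        "neoadjuvant_chemo": True,
        "adjuvant_radiotherapy": False,
    }


def _sample_survival(
    rng: np.random.Generator, survivor: bool, censor_rate: float
) -> tuple[float, bool]:
    """Survival time (months) and event flag consistent with the latent label.

    Non-survivors die before 60 months (always observed). Survivors live past
    60 months; with probability ``censor_rate`` they are administratively
    censored at a time beyond 60 months, so the 5-year label stays derivable.
    """
    if not survivor:
        return float(np.round(rng.uniform(3.0, 58.0), 1)), True
    t_death = 60.0 + rng.exponential(30.0)
    if rng.random() < censor_rate:
        t_cens = rng.uniform(60.5, 130.0)
        if t_cens < t_death:
            return float(np.round(t_cens, 1)), False
    return float(np.round(min(t_death, 180.0), 1)), True


def generate_cohort(
    config: SimConfig,
) -> tuple[list[VolumePair], list[LesionMask], list[ClinicalRecord], pd.DataFrame]:
    """Generate a fully synthetic cohort with planted survival signal.

    Returns volume pairs, lesion masks (pre and post per patient), clinical
    records and a truth table recording every latent parameter per patient.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.volume_shape
    spacing = config.voxel_spacing
    lo, hi = config.lesion_radius_range_mm

    pairs: list[VolumePair] = []
    masks: list[LesionMask] = []
    records: list[ClinicalRecord] = []
    truth_rows: list[dict] = []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        survivor = bool(rng.random() < config.survivor_rate)

        # Pre-treatment lesion geometry. In-plane semi-axes are drawn from the
        # configured range; the through-plane semi-axis is mildly flattened.
        ry, rx = rng.uniform(lo, hi, size=2)
        rz = 0.8 * rng.uniform(lo, hi)
        radii_pre = (rz, ry, rx)
        margin = np.asarray(radii_pre) / np.asarray(spacing) + 1.5
        center = np.array(
            [rng.uniform(m, s - 1 - m) for m, s in zip(margin, shape)]
        )

        mean_shrink = config.base_shrinkage + (config.shrinkage_effect if survivor else 0.0)
        shrink = float(np.clip(rng.normal(mean_shrink, 0.12), 0.0, 0.9))
        scale = (1.0 - shrink) ** (1.0 / 3.0)
        radii_post = tuple(max(r * scale, 2.2) for r in radii_pre)

        noise_pre = config.base_noise_scale
        noise_post = config.base_noise_scale + (0.0 if survivor else config.texture_effect)

        vol_pre, mask_pre = render_lesion(
            shape, center, radii_pre, spacing, config.intensity, noise_pre, rng
        )
        vol_post, mask_post = render_lesion(
            shape, center, radii_post, spacing, config.intensity, noise_post, rng
        )

        exam_pre = config.first_exam + timedelta(days=config.exam_interval_days * i)
        exam_post = exam_pre + timedelta(days=90)
        pairs.append(
            VolumePair(
                patient_id=pid,
                pre_volume=vol_pre,
                post_volume=vol_post,
                voxel_spacing_pre=spacing,
                voxel_spacing_post=spacing,
                exam_date_pre=exam_pre,
                exam_date_post=exam_post,
                contrast_phase=ContrastPhase.EARLY,
            )
        )
        for phase, m in ((Phase.PRE, mask_pre), (Phase.POST, mask_post)):
            masks.append(
                LesionMask(
                    patient_id=pid,
                    phase=phase,
                    mask=m,
                    voi_bbox=LesionMask.bbox_from_mask(m),
                )
            )

        clin = _sample_clinical(rng, survivor, config.clinical_effect)
        survival_months, event = _sample_survival(rng, survivor, config.censor_rate)
        records.append(
            ClinicalRecord(
                patient_id=pid,
                survival_months=survival_months,
                event=event,
                exam_date=exam_pre,
                label_5yr=int(survivor),
                **clin,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "survivor": int(survivor),
                "shrinkage": shrink,
                "radius_z_mm": radii_pre[0],
                "radius_y_mm": radii_pre[1],
                "radius_x_mm": radii_pre[2],
                "noise_scale_pre": noise_pre,
                "noise_scale_post": noise_post,
                "survival_months": survival_months,
                "event": int(event),
                **{k: clin[k] for k in ("path_stage", "node_stage", "lvi")},
            }
        )
    truth = pd.DataFrame(truth_rows)
    return pairs, masks, records, truth
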