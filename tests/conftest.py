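"""Shared fixtures: small synthetic cohorts and geometric test slices."""

from __future__ import annotations

import numpy as np
import pytest

from cysurv.cnn import CNNConfig
from cysurv.fusion import BPNNConfig
from cysurv.pipeline import PipelineConfig
from cysurv.roi import ROIDatasetConfig
from cysurv.simulate import SimConfig, generate_cohort


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    size = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:size, :size]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-patient cohort with all planted effects at moderate levels."""
    cfg = SimConfig(n_patients=8, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def fast_pipeline_config(
    n_patients: int,
    seed: int,
    shrinkage_effect: float,
    texture_effect: float,
    clinical_effect: float,
    combinations: tuple[str, ...] = ("C", "CRD"),
    cnn_epochs: int = 3,
) -> PipelineConfig:
    """Reduced-size pipeline settings used for repeated simulation studies.

    A small CNN (6/12 conv channels, one locally connected layer, few
    epochs), a per-case ROI cap of 8 and a coarse stride keep one full
    pipeline run to a few seconds while preserving every stage.
    """
    return PipelineConfig(
        seed=0,
        sim=SimConfig(
            n_patients=n_patients,
            seed=seed,
            shrinkage_effect=shrinkage_effect,
            texture_effect=texture_effect,
            clinical_effect=clinical_effect,
        ),
        roi=ROIDatasetConfig(stride=6, max_hybrids_per_case=8, seed=seed + 1),
        cnn=CNNConfig(
            conv_channels=(6, 12), local_channels=(12,), epochs=cnn_epochs,
            learning_rate=0.02, seed=seed + 2,
        ),
        bpnn=BPNNConfig(max_iter=100, seed=seed + 3),
        combinations=combinations,
    )
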