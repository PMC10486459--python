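"""End-to-end pipeline: simulate/load -> split -> features -> selection ->
hybrid ROIs -> CNN -> nomogram -> fusion -> evaluation.

Stages communicate through on-disk artifacts with documented schemas inside
one run directory; a manifest records stage order, seeds and SHA-256 hashes
of every output, so a rerun with the same configuration and master seed
reproduces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .cnn import CNNConfig, score_cohort, train_cnn
from .cohort import load_cohort, save_cohort, serial_split, write_split
from .datatypes import ConfigError, Phase
from .evaluation import (
    bonferroni_adjust,
    compare_aucs,
    cutoff_least_misclassification,
    km_logrank,
    roc_auc,
)
from .fusion import BPNNConfig, COMBINATIONS, assemble_descriptors, predict_bpnn, train_bpnn
from .nomogram import (
    clinical_points_frame,
    load_nomogram_spec,
    synthetic_nomogram_spec,
    write_nomogram_spec,
)
from .radiomics import extract_cohort_features, write_catalog
from .roi import ROIDatasetConfig, build_roi_dataset, dataset_arrays, dataset_manifest
from .selection import MutualInfoSelector, pearson_matrix
from .simulate import SimConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

STAGES = (
    "simulate", "split", "extract_features", "select_features",
    "build_rois", "train_cnn", "nomogram", "fuse", "evaluate",
)


def _sub_seed(master: int, k: int) -> int:
    return int((int(master) * 1000003 + 7919 * (k + 1)) % (2**31))


@dataclass
class PipelineConfig:
    """One configuration object for the whole workflow."""

    seed: int = 0
    sim: SimConfig | None = None
    data_dir: str | None = None  # used instead of simulation when sim is None
    split_fractions: tuple[float, float, float] = (0.56, 0.04, 0.40)
    mi_threshold: float | None = None
    mi_k_features: int = 12
    roi: ROIDatasetConfig = field(default_factory=ROIDatasetConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    bpnn: BPNNConfig = field(default_factory=BPNNConfig)
    nomogram_path: str | None = None  # None -> packaged synthetic spec
    combinations: tuple[str, ...] = ("C", "R", "D", "CR", "CD", "CRD")
    aggregation: str = "mean"
    enable_radiomics: bool = True
    enable_deep: bool = True

    def __post_init__(self) -> None:
        for comb in self.combinations:
            if comb.upper() not in COMBINATIONS:
                raise ConfigError(f"unknown combination {comb!r}")
            if "R" in comb.upper() and not self.enable_radiomics:
                raise ConfigError(
                    f"combination {comb} requires the radiomics stage "
                    "(enable_radiomics=false)"
                )
            if "D" in comb.upper() and not self.enable_deep:
                raise ConfigError(
                    f"combination {comb} requires the deep-learning stage "
                    "(enable_deep=false)"
                )
        if self.sim is None and self.data_dir is None:
            raise ConfigError("either a simulation config or a data_dir is required")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "sim" in raw and raw["sim"] is not None:
        sim = dict(raw["sim"])
        for key in ("volume_shape", "voxel_spacing", "lesion_radius_range_mm"):
            if key in sim:
                sim[key] = tuple(sim[key])
        kwargs["sim"] = SimConfig(**sim)
    if "roi" in raw:
        roi = dict(raw["roi"])
        if "intensity_window" in roi:
            roi["intensity_window"] = tuple(roi["intensity_window"])
        kwargs["roi"] = ROIDatasetConfig(**roi)
    if "cnn" in raw:
        cnn = dict(raw["cnn"])
        for key in ("conv_channels", "local_channels"):
            if key in cnn:
                cnn[key] = tuple(cnn[key])
        kwargs["cnn"] = CNNConfig(**cnn)
    if "bpnn" in raw:
        kwargs["bpnn"] = BPNNConfig(**raw["bpnn"])
    for key in ("seed", "data_dir", "mi_threshold", "mi_k_features",
                "nomogram_path", "aggregation", "enable_radiomics", "enable_deep"):
        if key in raw:
            kwargs[key] = raw[key]
    if "split_fractions" in raw:
        kwargs["split_fractions"] = tuple(raw["split_fractions"])
    if "combinations" in raw:
        kwargs["combinations"] = tuple(raw["combinations"])
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.entries: list[dict] = []
        self.config = config

    def record(self, stage: str, seed: int | None, outputs: list[Path]) -> None:
        self.entries.append(
            {
                "stage": stage,
                "seed": seed,
                "outputs": {
                    str(p.relative_to(self.out_dir)): _sha256(p) for p in outputs
                },
            }
        )
        self.write()

    def write(self) -> None:
        payload = {
            "package_version": __version__,
            "master_seed": self.config.seed,
            "stages": self.entries,
        }
        (self.out_dir / "manifest.json").write_text(json.dumps(payload, indent=2))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, writing artifacts and a manifest to ``out_dir``.

    Returns the evaluation report (also written as ``evaluation.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir, config)

    # -- stage 1: cohort ---------------------------------------------------
    if config.sim is not None:
        sim_cfg = config.sim
        if config.seed and sim_cfg.seed == 0:
            sim_cfg = SimConfig(**{**asdict(sim_cfg), "seed": _sub_seed(config.seed, 0),
                                   "intensity": sim_cfg.intensity})
        pairs, masks, records, truth = generate_cohort(sim_cfg)
        cohort_dir = out_dir / "cohort"
        save_cohort(cohort_dir, pairs, masks, records)
        truth_path = cohort_dir / "truth.csv"
        truth.to_csv(truth_path, index=False)
        manifest.record("simulate", sim_cfg.seed,
                        [truth_path, cohort_dir / "clinical.csv"])
    else:
        pairs, masks, records = load_cohort(config.data_dir)
        manifest.record("simulate", None, [])

    labels = pd.Series({r.patient_id: int(r.label_5yr) for r in records}).sort_index()

    # -- stage 2: serial split --------------------------------------------
    split = serial_split(records, config.split_fractions)
    split_path = out_dir / "split.csv"
    write_split(split, split_path)
    manifest.record("split", None, [split_path])
    split_of = split.assignment
    train_ids = sorted(split.patients("train"))
    val_ids = sorted(split.patients("validation"))
    test_ids = sorted(split.patients("test"))

    # -- stage 3: radiomics ------------------------------------------------
    radiomics_selected = None
    if config.enable_radiomics:
        features = extract_cohort_features(pairs, masks)
        feats_path = out_dir / "features.csv"
        features.to_csv(feats_path)
        catalog_path = out_dir / "feature_catalog.json"
        write_catalog(catalog_path)
        manifest.record("extract_features", None, [feats_path, catalog_path])

        # -- stage 4: MI selection (fit on the training split only) -------
        selector = MutualInfoSelector(
            threshold=config.mi_threshold, k_features=config.mi_k_features
        )
        selector.fit(features.loc[train_ids], labels.loc[train_ids])
        sel_path = out_dir / "selection.json"
        sel_path.write_text(json.dumps({
            "threshold": selector.threshold_,
            "selected": selector.selected_names_,
            "excluded_missing": selector.excluded_missing_,
            "scores": {k: (None if not np.isfinite(v) else float(v))
                       for k, v in selector.scores_.items()},
        }, indent=2))
        outputs = [sel_path]
        if len(selector.selected_names_) >= 2:
            corr = pearson_matrix(features.loc[train_ids, selector.selected_names_])
            corr_path = out_dir / "correlation.csv"
            corr.matrix.to_csv(corr_path)
            outputs.append(corr_path)
        manifest.record("select_features", None, outputs)
        radiomics_selected = features.loc[:, selector.selected_names_]
    else:
        manifest.record("extract_features", None, [])
        manifest.record("select_features", None, [])

    # -- stages 5-6: hybrid ROIs and CNN ----------------------------------
    dl_scores = None
    if config.enable_deep:
        roi_cfg = config.roi
        if config.seed and roi_cfg.seed == 0:
            roi_cfg = ROIDatasetConfig(**{**asdict(roi_cfg),
                                          "seed": _sub_seed(config.seed, 1)})
        rois = build_roi_dataset(pairs, masks, labels.to_dict(), roi_cfg)
        manifest_df = dataset_manifest(rois, split_of)
        rois_path = out_dir / "roi_manifest.csv"
        manifest_df.to_csv(rois_path, index=False)
        manifest.record("build_rois", roi_cfg.seed, [rois_path])

        cnn_cfg = config.cnn
        if config.seed and cnn_cfg.seed == 0:
            cnn_cfg = CNNConfig(**{**asdict(cnn_cfg), "seed": _sub_seed(config.seed, 2)})
        train_rois = [r for r in rois if split_of[r.patient_id] == "train"]
        val_rois = [r for r in rois if split_of[r.patient_id] == "validation"]
        Xtr, ytr, _ = dataset_arrays(train_rois)
        Xva = yva = None
        if val_rois:
            Xva, yva, _ = dataset_arrays(val_rois)
        model = train_cnn(Xtr, ytr, Xva, yva, config=cnn_cfg)
        hist_path = out_dir / "cnn_history.csv"
        model.history_.to_csv(hist_path, index=False)
        dl_scores = score_cohort(model, rois, config.aggregation)
        dl_path = out_dir / "dl_scores.csv"
        dl_scores.rename_axis("patient_id").to_csv(dl_path)
        manifest.record("train_cnn", cnn_cfg.seed, [hist_path, dl_path])
    else:
        manifest.record("build_rois", None, [])
        manifest.record("train_cnn", None, [])

    # -- stage 7: nomogram -------------------------------------------------
    spec = (load_nomogram_spec(config.nomogram_path) if config.nomogram_path
            else synthetic_nomogram_spec())
    spec_path = out_dir / "nomogram_spec.json"
    write_nomogram_spec(spec, spec_path)
    clinical = clinical_points_frame(records, spec)
    clin_path = out_dir / "clinical_points.csv"
    clinical.to_csv(clin_path)
    manifest.record("nomogram", None, [spec_path, clin_path])

    # -- stage 8: fusion ---------------------------------------------------
    bpnn_cfg = config.bpnn
    if config.seed and bpnn_cfg.seed == 0:
        bpnn_cfg = BPNNConfig(**{**asdict(bpnn_cfg), "seed": _sub_seed(config.seed, 3)})
    predictions: dict[str, pd.Series] = {}
    pred_rows = []
    for comb in config.combinations:
        comb = comb.upper()
        kwargs = dict(
            labels=labels, clinical_points=clinical,
            radiomics_selected=radiomics_selected, dl_likelihood=dl_scores,
        )
        ds_train = assemble_descriptors(comb, patient_ids=train_ids, **kwargs)
        ds_val = (assemble_descriptors(comb, patient_ids=val_ids, **kwargs)
                  if val_ids else None)
        ds_all = assemble_descriptors(
            comb, patient_ids=train_ids + val_ids + test_ids, **kwargs
        )
        model = train_bpnn(ds_train, ds_val, bpnn_cfg)
        scores = predict_bpnn(model, ds_all)
        predictions[comb] = scores
        for pid, s in scores.items():
            pred_rows.append({
                "patient_id": pid, "combination": comb, "score": s,
                "label": int(labels[pid]), "split": split_of[pid],
            })
    pred_path = out_dir / "predictions.csv"
    pd.DataFrame(pred_rows).to_csv(pred_path, index=False)
    manifest.record("fuse", bpnn_cfg.seed, [pred_path])

    # -- stage 9: evaluation ----------------------------------------------
    report = _evaluate(
        predictions, labels, records, split_of, train_ids, val_ids, test_ids
    )
    eval_path = out_dir / "evaluation.json"
    eval_path.write_text(json.dumps(report, indent=2))
    manifest.record("evaluate", None, [eval_path])
    return report


def _evaluate(predictions, labels, records, split_of, train_ids, val_ids, test_ids):
    """Test-set ROC/AUC per combination, paired comparisons, KM stratification."""
    y_test = labels.loc[test_ids].to_numpy()
    report: dict = {"auc": {}, "comparisons": [], "km": {}}
    for comb, scores in predictions.items():
        r = roc_auc(scores.loc[test_ids].to_numpy(), y_test)
        report["auc"][comb] = {"auc": r.auc, "se": r.se,
                               "n_pos": r.n_pos, "n_neg": r.n_neg}
    # Pairwise: each single descriptor vs the full combination.
    if "CRD" in predictions:
        singles = [c for c in ("C", "R", "D") if c in predictions]
        alpha = bonferroni_adjust(0.05, len(singles)) if singles else 0.05
        for c in singles:
            cmp = compare_aucs(
                predictions[c].loc[test_ids].to_numpy(),
                predictions["CRD"].loc[test_ids].to_numpy(),
                y_test, label=f"{c} vs CRD", adjusted_alpha=alpha,
            )
            report["comparisons"].append({
                "label": cmp.label, "auc_a": cmp.auc_a, "auc_b": cmp.auc_b,
                "delta_auc": cmp.delta_auc, "p_value": cmp.p_value,
                "adjusted_alpha": cmp.adjusted_alpha,
                "significant": cmp.significant,
            })
    # KM stratification of the test set at the least-misclassification
    # cutoff chosen on train+validation.
    by_id = {r.patient_id: r for r in records}
    for comb in ("C", "CRD"):
        if comb not in predictions:
            continue
        dev_ids = train_ids + val_ids
        cutoff = cutoff_least_misclassification(
            predictions[comb].loc[dev_ids].to_numpy(),
            labels.loc[dev_ids].to_numpy(),
        )
        groups = np.where(
            predictions[comb].loc[test_ids].to_numpy() >= cutoff,
            "predicted_alive", "predicted_deceased",
        )
        if len(np.unique(groups)) < 2:
            report["km"][comb] = {"cutoff": cutoff, "degenerate": True}
            continue
        km = km_logrank(
            [by_id[p].survival_months for p in test_ids],
            [by_id[p].event for p in test_ids],
            groups, cutoff=cutoff,
        )
        report["km"][comb] = {
            "cutoff": cutoff,
            "statistic": None if np.isnan(km.statistic) else km.statistic,
            "p_value": None if np.isnan(km.p_value) else km.p_value,
            "degenerate": km.degenerate,
            "group_sizes": km.group_sizes,
        }
    return report
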