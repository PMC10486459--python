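# cysurv

Five-year survival prediction for bladder-cancer patients after radical
cystectomy, combining three kinds of per-patient descriptors:

- **C — clinical**: the five histopathological indices collected at surgery
  (pathologic stage pT0–pT4, lymphovascular invasion, pathologic node stage
  N0–N3, neoadjuvant chemotherapy, adjuvant radiotherapy), mapped through a
  points-based nomogram;
- **R — radiomics**: 91 morphology / intensity / texture features extracted
  from the central lesion slice of the pre-treatment and post-treatment CT
  urography scans, plus their relative changes
  `f_diff = (f_pre − f_post) / f_pre`, 273 features per case, reduced by
  mutual-information selection;
- **D — deep learning**: a small CNN scoring 32×32 *hybrid ROIs* — patches
  whose left 32×16 half is cut from the pre-treatment lesion and whose right
  32×16 half from the post-treatment lesion, so each sample encodes the
  treatment response directly; per-ROI likelihoods are averaged into one
  case-level survival likelihood.

A back-propagation neural network (one hidden layer, 13 nodes) fuses any
combination of the blocks (C, R, D, CR, CD, CRD) into a survival score.
Models are compared by test-set AUC (Mann–Whitney estimate, Hanley–McNeil
standard error, DeLong paired test with Bonferroni-adjusted α = 0.05/3 =
0.017) and by Kaplan–Meier stratification of predicted-alive vs
predicted-deceased groups at the least-misclassification cutoff, with the
two-sample log-rank test.

Because real CT-urography cohorts of this kind are not publicly available,
the package includes a first-class synthetic cohort generator
(`cysurv.simulate`) that emulates the study design — paired pre/post scans
with one segmented lesion each, correlated clinical indices, survival
outcomes — with three independently controllable planted effects
(lesion shrinkage, post-treatment texture, clinical log-odds shift). Every
stage of the pipeline is testable offline against cohorts whose ground
truth is known, including the null case in which every descriptor is pure
noise.

The package is aimed at methodologists who want a reproducible,
fully-inspectable reference implementation of this multi-descriptor fusion
design, not at clinical use: the shipped nomogram calibration is an
explicitly synthetic placeholder (see `cysurv.nomogram`), to be replaced
with a transcription of a published nomogram for any real analysis.

## Worked example

```python
from cysurv import PipelineConfig, SimConfig, run_pipeline
from cysurv.roi import ROIDatasetConfig
from cysurv.cnn import CNNConfig
from cysurv.fusion import BPNNConfig

config = PipelineConfig(
    sim=SimConfig(n_patients=120, seed=5, shrinkage_effect=0.4,
                  texture_effect=6.0, clinical_effect=2.5),
    roi=ROIDatasetConfig(stride=6, max_hybrids_per_case=8, seed=6),
    cnn=CNNConfig(conv_channels=(6, 12), local_channels=(12,), epochs=4,
                  learning_rate=0.02, seed=7),
    bpnn=BPNNConfig(max_iter=100, seed=8),
    combinations=("C", "R", "D", "CRD"),
)
report = run_pipeline(config, "runs/demo")
for comb, stats in report["auc"].items():
    print(f"{comb:>4}: test AUC = {stats['auc']:.2f} +/- {stats['se']:.2f}")
for cmp in report["comparisons"]:
    print(f"{cmp['label']}: p = {cmp['p_value']:.3f} "
          f"(adjusted alpha = {cmp['adjusted_alpha']})")
km = report["km"]["CRD"]
print(f"KM stratification by CRD: cutoff = {km['cutoff']:.3f}, "
      f"log-rank p = {km['p_value']:.2g}")
```

prints

```
   C: test AUC = 0.86 +/- 0.06
   R: test AUC = 0.99 +/- 0.02
   D: test AUC = 0.89 +/- 0.05
 CRD: test AUC = 1.00 +/- 0.00
C vs CRD: p = 0.007 (adjusted alpha = 0.017)
R vs CRD: p = 0.289 (adjusted alpha = 0.017)
D vs CRD: p = 0.015 (adjusted alpha = 0.017)
KM stratification by CRD: cutoff = 0.448, log-rank p = 7.3e-14
```

Reading: on this 120-patient synthetic cohort with strong planted clinical
and imaging effects, each descriptor alone is predictive on the held-out
chronological test block; the fused CRD model is at least as good as any
single block, and splitting the test patients at the CRD score cutoff
(chosen on the training+validation patients only) yields survival curves
that separate decisively. The run directory contains every intermediate
artifact (features, selection report, ROI manifest, CNN history, per-patient
scores) plus a manifest with seeds and SHA-256 hashes; rerunning the same
config reproduces the outputs byte for byte.

The same workflow is available from the shell:

```bash
cysurv simulate --out runs/cohort --seed 5 --n-patients 120
cysurv split --data runs/cohort --out runs/split.csv
cysurv extract-features --data runs/cohort --out runs/features.csv
cysurv run-all --config docs/pipeline.example.yaml --out runs/full
```

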