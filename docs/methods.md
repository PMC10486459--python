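# Methods

This note documents the models, estimators and design choices behind
`cysurv`, and what its synthetic-cohort experiments do and do not
demonstrate.

## Study design being modelled

Each patient contributes one pre-treatment and one post-treatment
CT-urography scan bracketing neoadjuvant chemotherapy, a binary lesion
segmentation per scan, five clinical/histopathological indices recorded at
radical cystectomy (pathologic stage, lymphovascular invasion, node stage,
neoadjuvant chemotherapy, adjuvant radiotherapy), follow-up time and vital
status. The prediction target is the binary five-year survival label
(1 = known alive at 60 months). Cohorts are split **chronologically**
("serial" split): patients are ordered by exam date, the earliest block
becomes the training set, the next the validation set, the most recent the
test set — emulating deployment of a frozen model on incoming cases. Block
sizes are `ceil(n·f_train)` and `round(n·f_val)` with the remainder to
test; at fractions (0.56, 0.04, 0.40) a 163-patient cohort splits
92/7/64. Date ties break by patient id.

Patients censored before 60 months have an unknown five-year status; when
a label must be derived from follow-up, they are labelled 0 ("not known to
have survived"), a documented convention rather than knowledge of death.
The synthetic generator sidesteps the ambiguity by censoring only latent
survivors and only beyond the 60-month horizon.

## Synthetic cohort generator

`cysurv.simulate` renders one ellipsoidal lesion per patient into a noisy
background volume (default 28×56×56 voxels at 2×1×1 mm; background 30 HU,
lesion contrast +45 HU, correlated Gaussian noise fields). Three
independent effect dials plant signal:

- `shrinkage_effect` (default 0.4): survivors' lesions lose an extra 40%
  of volume pre→post on average (baseline shrinkage 0.25, per-patient SD
  0.12) — detectable by the difference radiomics and the hybrid-ROI CNN;
- `texture_effect` (default 6 HU): non-survivors' post-treatment lesions
  carry extra intra-lesion noise — detectable by texture features;
- `clinical_effect` (default 1.0): the log-odds shift towards favourable
  stage / N0 / LVI-negative in survivors relative to non-survivors, applied
  half to each group so marginal index frequencies stay near the emulated
  cohort's (stage 35/15/16/36/45/16, LVI 61/163, nodes 112/24/23/4 out of
  163; chemotherapy always given, radiotherapy never — as in the cohort the
  generator emulates).

Survivor fraction defaults to 0.5 (the emulated cohort is 79/84).
Non-survivors die uniformly in (3, 58) months; survivors live 60 months
plus an exponential tail (mean 30), with administrative censoring beyond
60 months at rate `censor_rate`. Generation is bit-reproducible given the
integer seed.

What the generator does **not** emulate: irregular lesion shapes, CT
physics and artifacts, contrast-phase differences, registration error,
multi-lesion disease, and any dependence structure between imaging and
clinical indices beyond the shared latent outcome. Tests passing on these
fixtures therefore demonstrate that the pipeline recovers planted,
feature-detectable signal and is calibrated under the null — not that it
would achieve any particular accuracy on real scans.

## Radiomics

Features are 2D, taken from the **central slice** of each lesion, defined
as the axial slice with maximal in-mask area (ties to the lower index) —
the representative slice rather than the geometric middle. The base
catalog is frozen at exactly 91 names in three families:

- **morphology (20)** — contour-based: area, perimeter, equivalent
  diameter, circularity `4πA/P²`, eccentricity, solidity, extent,
  convexity (convex-hull perimeter / perimeter), major/minor axis, aspect
  ratio, maximal Feret diameter, roundness, seven Hu moments. The
  perimeter is the marching-squares boundary polygon smoothed by a 5-point
  circular moving average, which cancels the staircase bias (within ~1% of
  the analytic circumference for disks of radius ≥ 10 px). Millimetre
  spacing (dy, dx) is applied to contour coordinates, so anisotropic pixels
  are handled exactly; Hu moments are computed on the pixel grid (they are
  scale invariants).
- **intensity (23)** — first-order statistics of in-mask intensities:
  location (mean, median, min, max, percentiles 10/25/75/90, trimmed mean),
  dispersion (SD, variance, range, IQR, decile range, mean/median absolute
  deviation, CV), shape (skewness, kurtosis — defined as 0 for constant
  regions), energy, RMS, histogram entropy and uniformity (32 bins over the
  in-mask range).
- **texture (48)** — computed after equal-width quantization of the
  in-mask intensity range into 32 grey levels: grey-level co-occurrence
  statistics (contrast, dissimilarity, homogeneity, ASM, correlation,
  entropy, cluster shade) at four unit offsets (0°, 45°, 90°, 135°), with a
  sentinel-level trick restricting pixel pairs to the mask; eleven
  grey-level run-length statistics (SRE, LRE, GLN, RLN, RP, LGLRE, HGLRE
  and the four joint variants) averaged over the same four directions, runs
  broken by mask boundaries; nine Sobel gradient-magnitude statistics.

Because texture is quantized over the in-mask range, adding a constant to
the image changes only the documented location-type features
(`SHIFT_SENSITIVE` in `cysurv.radiomics`); everything else, including all
texture, is shift-invariant, and all features are invariant to whole-pixel
translations. The 91-name catalog is the package's own frozen definition
spanning the three families; any analysis depending on the exact member
list should treat it as this implementation's contract.

Difference features are the relative change `(pre − post) / pre` per base
feature. A zero pre-treatment value makes the ratio undefined; the value
is flagged missing (NaN), never ±infinity. A case contributes 91 × 3 = 273
features (`pre.*`, `post.*`, `diff.*`).

## Feature selection

Relevance is mutual information `I(F;C) = H(F) − H(F|C)` between a feature
and the binary label, estimated by equal-frequency discretization into
`k = min(10, floor(√n))` bins followed by the plug-in discrete estimator,
in nats, clamped at 0. Bin edges are order statistics of the data (the
`lower`-method quantiles) with strictly-less assignment, so ties always
share a bin and the score is **exactly** invariant under strictly
increasing transforms of the feature; the estimator equals the brute-force
`Σ p log(p/(p_f p_c))` evaluation on the binned joint to 1e-12 (tested).
The plug-in bias at independence is ≈ `(k−1)(c−1)/(2n)` nats, well under
0.02 at n = 1000.

Columns with missing values in the fit matrix are excluded and reported.
With an explicit threshold, all features scoring ≥ threshold are selected;
by default the threshold is placed at the 12th-ranked score, reproducing a
selection cardinality of 12 on comparable data. Selection is **fit on the
training split only** and applied unchanged elsewhere. Redundancy among
selected features is summarized by the Pearson matrix (constant columns
flagged, their correlations reported as 0).

A feature selected on training data can still be missing in a test row
(the relative difference at `pre = 0`); the fusion classifier imputes such
values at the training mean (standardized 0) at prediction time.

## Hybrid ROIs and the CNN

From the central lesion slice of each phase, 32×16 sub-windows are cut
from the VOI bounding box by a sliding window (default stride 4 px in the
library, row-major order, deterministic). A VOI smaller than the window is
symmetrically zero-padded up to window size and flagged. One pre-window
and one post-window concatenate into a 32×32 hybrid patch — pre left,
post right — after mapping intensities to [0, 1] with a fixed window
(default −50…150 HU) shared by both halves. Per case, the cross product of
pre and post windows is formed and capped (default 64) by seeded uniform
subsampling; the per-case random stream is derived from (seed, patient id)
so results do not depend on case iteration order. Every patch carries its
case's five-year label; the stride, cap, window and pairing rule are
configuration, as no published values exist for them.

The CNN maps a 32×32 patch to a survival likelihood: two convolution
blocks (5×5 kernels, stride 1, pad 2; 16 then 32 channels by default),
each followed by cross-channel local response normalization (size 5,
k = 2, α = 1e-4, β = 0.75), ReLU and overlapping 3×3/stride-2 max-pooling;
two locally connected (unshared-weight) 3×3 layers; a 10-unit fully
connected layer with sigmoid; and a sigmoid output unit. The channel
counts, LRN constants and the reading of "FC10" as a 10-unit penultimate
layer are documented package choices. Training is SGD with momentum 0.9
on binary cross-entropy (computed on logits for stability), seeded
end-to-end; when a validation set exists, the epoch with the best
validation ROI-level AUC is restored. Per patient, ROI likelihoods are
aggregated by the mean (median and max available) into the deep
descriptor. Both networks run on the in-repo NumPy engine (`cysurv._nn`);
every layer's backward pass is verified against central finite differences
at tolerance 1e-7.

## Nomogram and fusion

The nomogram maps each index level to points, sums the five point values,
and maps total points to five-year survival probability by linear
interpolation on a monotone non-increasing knot list (clamped at the end
knots) — the machine-readable form of a graphical points axis. The shipped
calibration is synthetic (monotone in stage/LVI/node severity, 0–100
points per index) and is validated structurally, not clinically. The
fusion classifier consumes the five **per-index point values** (not the
total), the selected radiomics values, and the deep likelihood, per the
chosen reading of the descriptor definition.

The BPNN is a single-hidden-layer network (13 nodes, sigmoid activations,
sigmoid output) trained by full-batch gradient descent with momentum
(default rate 0.5, 200 iterations maximum — an order of magnitude above
the ~40 iterations such models typically need). Inputs are standardized
with training-split statistics only; constant training columns are dropped
with a warning; the best-validation-AUC iteration is restored;
`max_iter=0` leaves the seeded initialization untouched, giving a
well-defined untrained baseline.

## Evaluation statistics

- AUC by the Mann–Whitney identity (ties credited ½), reported with the
  Hanley–McNeil standard error; ROC points at every distinct threshold,
  whose trapezoidal integral equals the Mann–Whitney value.
- Paired model comparison by the DeLong covariance-structure z-test
  (two-sided), the standard nonparametric choice for correlated ROC
  curves; reports label the SE and comparison methods explicitly. A model
  compared with itself returns Δ = 0, p = 1.
- Bonferroni adjustment `α/m` reported at three decimals (0.05/3 → 0.017).
- The stratification cutoff minimizes FP + FN over midpoints of
  consecutive distinct scores (ties to the lower threshold), chosen on the
  training+validation patients and applied to the test set.
- Kaplan–Meier product-limit curves per predicted group (via lifelines)
  with the two-sample log-rank test; with no events anywhere the statistic
  is undefined and the result is flagged degenerate rather than invented.
  Curves use the full follow-up axis in months, not truncated at 60.

## Problem sizes used by the test and acceptance experiments

Simulation-based checks use reduced settings chosen to keep full-pipeline
Monte Carlo practical while preserving every stage: 28×56×56 volumes,
ROI stride 6 with per-case cap 8, a 6/12-channel CNN with one locally
connected layer trained 1–4 epochs, and a 100-iteration BPNN. Under these
settings one 100-patient pipeline run takes ~10 s on one CPU. The null
calibration averages the fused test AUC over 40 cohorts of 100 patients
with all effects zero and tests the mean against the exact Mann–Whitney
null band; the type-I error of the DeLong test is measured on 1000
simulated null score pairs; signal recovery runs ten 200-patient cohorts
with complementary clinical (1.0) and imaging (0.4 shrinkage, 6 HU
texture) effects and requires mean AUC(CRD) ≥ mean AUC(C) plus log-rank
separation of the CRD-predicted groups in a majority of cohorts.

## Known limitations

- The 91-name catalog, the MI binning scheme, the ROI stride/cap, the CNN
  channel counts and the nomogram calibration are documented package
  choices standing in for unpublished details; results depending on their
  exact values should be read as properties of this implementation.
- 2D-only radiomics; no wavelet/filtered features; no IBSI certification.
- The NumPy networks are reference implementations tuned for determinism
  and inspectability, not speed; cohorts beyond a few hundred patients
  will train slowly.
- Equal-frequency MI is exactly invariant to increasing transforms only;
  order-reversing transforms can shift bin edges by one sample.
- The synthetic cohorts cannot validate clinical performance; they
  validate mechanics, calibration and signal recovery.
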