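# Methods notes

## Problem setting

The pipeline classifies CSF-related regions of interest on 2D axial
T2-weighted MRI slices as infected vs. non-infected. Each patient
contributes two bilateral ROIs (left/right) in each of two anatomical
regions: the lateral-ventricle lumen and the sub-lentiform nucleus
parenchyma including perivascular spaces. Masks are inputs; segmentation
itself is out of scope (a Dice utility is provided for agreement
reporting). Analysis is strictly 2D.

## Radiomics features

378 features per ROI over four image sources: the original slice and
three Laplacian-of-Gaussian (LoG) responses. Per source: 18 first-order
features (17 on LoG sources — Total Energy, a pixel-area-weighted copy of
Energy, is only reported for the original image), 9 shape features
(original only), and 75 texture features (GLCM 24, GLSZM 16, GLRLM 16,
NGTDM 5, GLDM 14), giving 102 + 3×92 = 378. Names follow IBSI
nomenclature; the full (name, source, family) manifest is exported by the
catalog.

Numerical conventions, chosen where the method description leaves them
open and fixed package-wide:

- **LoG scales**: the fine/medium/coarse kernels are interpreted as 2D
  in-plane kernels of size 3/5/7 px with sigmas 0.5/1.0/1.5 px, so ~3σ of
  support fits each kernel; implemented as Gaussian smoothing followed by
  the 5-point discrete Laplacian with edge replication. A millimeter
  labeling of the scales (fine ≈ 2 mm, medium ≈ 4 mm) is carried in the
  feature manifest as metadata only — phantom pixel spacing is arbitrary.
- **Discretization**: 32 equal-width bins over the in-mask [min, max]
  range (bin count configurable). Fixed bin *count* rather than width
  because LoG responses have signed, data-dependent ranges. A constant
  ROI maps to level 1. This makes every texture feature invariant to
  adding a constant to the image.
- **Texture geometry**: GLCM and GLRLM use the four in-plane directions
  at distance 1 and average feature values over directions (the most
  common convention; merged-matrix aggregation was deliberately not
  used). GLSZM zones are 8-connected; NGTDM uses the 8-neighborhood;
  GLDM uses distance 1, similarity threshold α = 0, and defines the
  dependence size of a pixel as 1 + the number of matching in-mask
  neighbors. Out-of-mask pixels never contribute: they break runs and are
  excluded from pairs, zones and neighborhoods.
- **Degenerate inputs**: single-gray-level ROIs yield entropy 0,
  GLCM correlation 1 (by convention), NGTDM contrast 0 and a capped
  coarseness (1e6); an infinite ANOVA F (perfect separator) is replaced
  by a large finite sentinel so rankings are total. All 378 outputs are
  finite by contract.
- **Shape**: area and perimeter come from the marching-squares polygon of
  the largest connected component, with a 3-point moving average applied
  to each closed contour first — raw marching-squares contours of binary
  masks overestimate a digital disk's perimeter by ~7%, which the
  smoothing reduces to <2% (a radius-20 disk reads sphericity ≈ 0.99).
  Diameters and axis lengths use pixel-center coordinates (maximum
  pairwise hull distance; 4·√eigenvalue of the coordinate covariance).

## Feature selection

Per outer fold, features are ranked on the training+validation pool by
the one-way ANOVA F statistic (mutual information available via config)
and the top 50 are kept, ties broken by catalog order. The "filter-based"
statistic is not further specified by the method description; the F score
is the canonical deterministic filter for continuous features with binary
labels. Selected features are z-scored with statistics fitted on the
training subset only before entering the network's radiomics branch —
raw radiomics magnitudes (e.g. Energy ~ 10^3) would destabilize the dense
layers. Leakage is enforced mechanically: ranking raises if any supplied
sample belongs to the fold's test patients, and the CV driver re-checks
train/val/test patient disjointness.

## Architectures

Both classifiers are implemented on a small numpy layer engine (NHWC
convolutions with stride/dilation via im2col, batch normalization, dense,
inverted dropout, average/global pooling, broadcast upsampling, channel
concatenation; hand-derived backward passes verified against finite
differences; Adam optimizer). The base classifier is backbone → global
average pooling → Dense(256) → Dropout(0.3) → softmax(2). The fusion
model adds the ASPP module (four 3×3 convolutions at dilations 1/6/12/18,
512 filters, BN+ReLU), a global-context path (pooled backbone map →
1×1 conv 512 → upsampling back to the grid), 1×1 compression of the
7×7×2560 concatenation to 512 channels, and a radiomics branch
(50 → Dense 128 → Dense 512 with dropout 0.3 each → reshape 1×1×512 →
upsample 7×7×512), fused channel-wise to 7×7×1024.

Design choices worth recording:

- **Backbones.** The published geometry pins only the backbone's final
  feature map: 7×7 at 224×224 input with 1920 channels (dense style) or
  960 (mobile style). The package builds compact trunks with those exact
  output geometries — concatenative dense-connectivity blocks for the
  dense style, narrow 1×1-expansion blocks for the mobile style — rather
  than 200-layer reference networks; every downstream tensor shape
  (7×7×512 paths, 1×1×1920 pooled context, 7×7×2560, 7×7×1024) is exact.
- **Upsampling from 1×1** (context path and radiomics branch) is
  broadcast replication; bilinear interpolation from a single cell is
  constant, so the two are identical.
- ASPP convolutions use shape-preserving padding at all dilation rates;
  at dilation 18 on a 7×7 grid the effective support degenerates toward
  the center tap, which is accepted as specified.
- The dropout rate inside the radiomics branch is unstated upstream; the
  head rate (0.3) is reused.
- The 70% freeze rule counts *layer objects with parameters* in
  construction order (not parameter tensors); frozen batch-norm layers
  also stop updating their running statistics.
- Dense layers in the head use ReLU; decisions are argmax of the softmax
  (threshold 0.5); ROC curves use the infection-class probability.

## Training and evaluation protocol

Nested CV: 5 outer folds, patient-grouped and label-stratified (remainder
patients rotated across classes so outer folds differ by ≤1 in size; 104
patients split 21/21/21/21/20). The pool of each outer fold is split into
3 inner folds; inner fold 1 is the validation set for early stopping and
plateau detection (training all three rotations is a config option).
Augmentation applies rotation ±15°, zoom ±10%, translation ±10% and
horizontal/vertical flips, each with probability 0.5, bilinear with edge
replication, from a per-fold seeded stream.

Phase 1 trains all layers (Adam, lr 1e-4, ×0.5 on a validation-loss
plateau with patience 5 — the plateau patience is unstated upstream —
floored at 1e-7, ≤200 epochs, early stop after 10 non-improving epochs,
best-validation weights restored). Phase 2 freezes the first 70% of
layers and fine-tunes at lr 1e-5 for ≤20 epochs with patience 5. The
monitored quantity is validation loss. Weight carry-over between
consecutive outer folds is implemented (`weight_carryover=True` /
`--paper-faithful`) but off by default: fold f would otherwise start from
weights trained while fold f−1's test patients were visible.

ROI-level metrics (accuracy, precision, recall, F1, infection = positive
class) are computed per fold and reported mean ± sample sd; the mean ROC
is obtained by vertical averaging of per-fold TPR on a 0.01-step FPR grid
with a ±1 sd band. The strict patient-wise rule marks an infected patient
correct if ≥1 of their two ROIs is flagged and a control correct only if
both are clear; bilateral discordance is the fraction of patients whose
two ROI predictions disagree, mean ± sd across folds.

## Phantom cohort

The generator emulates the statistical structure the pipeline assumes: a
balanced two-class cohort (default 52 patients per class, matching the
clinical cohort size), four ROIs per patient (2 regions × 2 hemispheres),
elliptical ROIs with randomized axes (8–16 px) and orientation over a
darker parenchyma-like background (level 0.35 with slow spatial drift),
ROI level 0.5 on a [0, 1] intensity scale. Class signal enters exactly
where the feature families can measure it: infected ROIs are offset by
`class_contrast` (default 0.3) and their correlated-Gaussian texture has
a longer correlation length (2 px vs. 1 px control) at noise sd 0.05. No
quantitative effect size for infected CSF signal is published, so these
defaults are a deliberately strong, tunable contrast — not a calibration
to clinical data. A master seed expands into per-patient substreams, so
enlarging a cohort never perturbs existing patients; intensities are
snapped to the 16-bit grid at generation so PNG round-trips are
bit-exact.

What the phantom does *not* model: CSF flow artifacts, scanner physics
and noise correlations, partial-volume effects, anatomy-shaped ROIs, or
3D structure. Passing the end-to-end tests therefore demonstrates that
the pipeline's plumbing, leakage control and learning dynamics are sound
and that it recovers class structure expressed through first-order and
texture statistics — not that clinical-grade performance transfers to
real MRI.

## Problem sizes used in the test suite

Unit and property tests run on micro configurations (8–32 px inputs,
4–96 channel widths) that exercise the identical code paths as the
full-scale model. The end-to-end recovery checks use 20 patients per
class, 32×32 network input with the compact backbone, and a shortened
two-phase schedule (lr 1e-3/1e-4, ≤20+4 epochs) — sizes chosen so the
whole suite completes in a couple of minutes on one CPU. The chance-level
(zero-contrast) check averages over three replicate cohorts and treats
the patient, not the ROI, as the binomial unit, since a patient's two
ROIs and a fold's decisions are correlated. The full-scale geometry
checks (1920/2560/1024-channel representations at 224×224) always run
against the complete architecture.

## Known limitations

- The numpy engine is single-threaded through BLAS and holds float64
  weights; the full 224×224 fusion model (~40M parameters) is practical
  for probing and short runs, not for long full-scale training.
- GLSZM/GLRLM matrices are trimmed to the observed maximum zone/run size
  per ROI; features are normalized counts, so this does not change
  values, but raw matrices from different ROIs have different widths.
- First-order Entropy/Uniformity reuse the same 32-bin discretization as
  the texture matrices rather than an independent binning.
- `discordance_rate` and the strict rule require exactly two ROIs per
  patient per region; cohorts with missing hemispheres are rejected
  rather than imputed.
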