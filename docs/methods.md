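# Methods

`rvtrack` quantifies right-ventricular (RV) longitudinal function from 2D
apical echo cine loops by tracking the tricuspid annulus automatically.
This note records the models, parameters, and design choices in enough
detail to reproduce or criticize them.

## Pipeline

1. **Standardization.** Each frame is resampled so its longer side matches
   the network input size (aspect ratio preserved), zero-padded square,
   and min–max rescaled to [0, 1] per frame. A constant frame rescales to
   all zeros rather than raising. The (scale, pad) geometry is retained so
   tracked positions can be mapped back to the source pixel grid, where
   the original pixel spacing applies.
2. **Segmentation.** A residual U-net labels every pixel as background
   (0), lateral annulus (1), or septal annulus (2). Three classes are used
   — rather than one annular class — so that the two annuli can be tracked
   separately by a single network.
3. **Tracking.** The annulus position in a frame is the unweighted centre
   of mass of all pixels carrying that class label. Frames with no
   labelled pixel are *missing*; they are never interpolated. By default
   all labelled pixels contribute (no connected-component filtering); a
   `keep_largest_component` option discards spurious secondary blobs.
4. **Smoothing.** Each coordinate time series is median-filtered
   (default window 3 frames). The window stays centred and shrinks
   symmetrically at the sequence ends — down to a single sample at the
   first and last frame. An asymmetric edge window would average the end
   frames with their neighbours and systematically shrink the measured
   excursion on short clips, which is why the symmetric policy was chosen.
   Missing frames are excluded from each window and remain missing.
5. **Indices.** Per annulus:
   * **LTAD** (linear tricuspid annular displacement) — the maximum
     displacement between any two positions occupied by the annulus, i.e.
     the maximum pairwise Euclidean distance over tracked frames. The
     "two positions" are deliberately not anchored at a cycle phase:
     the pairwise maximum is the only reading independent of phase
     labelling.
   * **CTAD** (circumferential tricuspid annular displacement) — the
     total bidirectional distance traversed: the sum of Euclidean steps
     between consecutive tracked frames. `CTAD >= LTAD` always.

   Indices are in cm only when the input carries pixel spacing; otherwise
   they are tagged `px` and never silently mislabelled. A run of missing
   frames longer than the smoothing window flags the case invalid
   (`valid=False`) instead of bridging unseen motion.

## Segmentation network and training

The network is a U-net whose convolution blocks are residual modules
(conv–BN–ReLU–conv–BN plus an identity shortcut, 1×1 projection when the
channel count changes), with 2×2 max-pooling on the contracting path,
stride-2 transposed convolutions on the expanding path, skip
concatenation between matching levels, and a 1×1 convolution head. It is
implemented directly in NumPy with explicit backward passes; convolutions
run as k² accumulated GEMMs over shifted views (channels-last), which
keeps a single-CPU training step at roughly 100 ms per 128-px frame.
Analytic gradients are verified against central finite differences in
float64 by the test suite.

Training minimizes a class-weighted softmax cross-entropy: per pixel with
logit vector x and true class i the loss is `-W[i] * ln(softmax(x)[i])`,
and the scalar loss is the plain mean of the weighted per-pixel terms
(not renormalized by the weight mass — this fixes the numeric scale of
reported losses). Default weights are 0.2 for background and 0.8 for each
annular class, counteracting the extreme pixel imbalance (annular pixels
are well under 1% of a frame). Optimization is RMSProp
(`v <- 0.99 v + 0.01 g²`), default learning rate 3e-3 for the compact
desk-scale configuration. Every source of randomness — weight
initialization, batch order, augmentation draws — derives from one seed,
so training is bit-reproducible; inference is single-pass (no test-time
augmentation), so quantification is exactly deterministic: repeated runs
agree with ICC 1.0 and zero Bland–Altman spread, and the test suite
asserts this.

Training-time augmentation (optional) applies one shared affine transform
(zoom 0.9–1.1, rotation ±15°, random crop, horizontal/vertical flips at
p = 0.5) to frame and mask — nearest-neighbour for the mask — plus
image-only Gaussian noise (σ = 0.01). A draw that removes every annular
pixel is re-drawn (≤5 attempts) rather than trained on.

## Cross-validation

Folds are formed at the **case** level (all frames of a clip share a
fold), sizes differing by at most one, deterministically under a seed. A
fresh model is trained per fold on the remaining folds and applied only
to held-out cases, so every case receives exactly one prediction. The
no-leakage condition is enforced as an assertion (`LeakageError`), not a
warning.

## Statistics

* **Bland–Altman**: mean difference and limits of agreement at
  mean ± 1.96 SD with the sample (n−1) SD.
* **ICC(2,1)**: two-way random effects, absolute agreement, single
  measurement — the standard inter-observer choice; the 95% CI is the
  F-based interval of McGraw & Wong. Zero between-case variance makes the
  coefficient undefined and it is reported as such. The implementation is
  checked against `pingouin` to 1e-6.
* **ROC/AUC**: Mann–Whitney rank formulation (equal to brute-force
  positive–negative pair enumeration, which the tests assert), DeLong
  confidence interval. Orientation: lower displacement indicates
  dysfunction (the positive class).
* **Operating point**: candidate cutoffs are midpoints between sorted
  unique scores; among candidates with sensitivity strictly above the
  floor (default 0.80) the one with maximal specificity is chosen, ties
  breaking toward higher sensitivity then the less aggressive cutoff.
  If no candidate attains the floor, the maximum-sensitivity cutoff is
  reported with a flag. The floor-then-maximize-specificity reading was
  chosen over "pick the maximum sensitivity" because it yields a
  well-defined unique point and reflects how screening cutoffs are used.
* **Group comparison**: two-sided unpaired Student's t test (pooled
  variance by default, Welch optional); tertile trends split at the
  empirical 33.3/66.7 percentiles of the stratifier with a one-way ANOVA
  across strata. No multiple-testing correction is applied; p values are
  reported raw at two-sided α = 0.05.

## Synthetic phantom

Clinical echo with annotated annuli cannot be redistributed, so the test
bed is a phantom: a wedge-shaped sector (default 75° opening) over
multiplicative unit-mean Rayleigh speckle on a smooth background, a
static bright band emulating the interventricular septum, and two
Gaussian landmarks (lateral and septal annulus) that move sinusoidally
along fixed directions (~20° off the long axis) with configurable peak
excursion. The excursion plays the role of the true annular displacement
— the quantity TAPSE estimates clinically. Ground-truth label maps are
uniform-radius disks rasterized at the nearest pixel (quantization error
≤ 0.5 px); sub-pixel truth positions are kept in floating point, so truth
LTAD/CTAD are exact up to trajectory discretization. Cohorts draw
dysfunctional cases (first `floor(n·fraction)` indices) from a low
amplitude range and normals from a high range; the default ranges
(0.8–1.4 vs 1.6–2.4 cm) are disjoint and bracket the clinical TAPSE
cutoff of 1.6 cm.

What the phantom does **not** emulate: anisotropic point-spread, shadowing
and dropout, valve leaflets and chamber walls, out-of-plane motion,
through-plane landmark disappearance, operator-dependent view variation.
Passing tests therefore demonstrate that the pipeline's machinery —
learning, tracking, index computation, statistics — is correct and exactly
reproducible, not that the network generalizes to clinical image quality.

## Desk-scale study conditions

The reference studies (`rvtrack.experiments`) run on one CPU core in
minutes and fix these sizes as the package's validation conditions:
128-px frames at 0.1 cm/px (12.8 cm field of view), 12 frames per cycle,
label radius 3 px, speckle SNR 4; network depth 3 with 6 base channels;
RMSProp lr 3e-3, batch 4, 15 epochs per fold; 3-fold case-level
cross-validation over 24 cases for parameter recovery, and a 20-case
cohort quantified twice (model trained on 10 disjoint cases) for
repeatability. At 12 frames per cycle the sinusoid's discretization and
the 3-frame median filter bound the recoverable excursion at ≈93–97% of
the configured amplitude, which the 15% recovery tolerance absorbs.

## Known limitations

* The segmenter distinguishes lateral from septal partly through the
  septum-band context; phantoms without such context would require
  positional encoding.
* Uniform circular labels make centre-of-mass tracking unbiased; real
  hand annotations vary in size and shape, adding annotation noise the
  phantom does not model.
* Median smoothing attenuates true single-frame extremes at low frame
  rates; at 30 frames per cycle (the generator default) the effect is
  ≈1%, at 12 frames it reaches a few percent.
* The NumPy trainer is practical at the desk scale only; clinical-scale
  training (256-px frames, thousands of clips) would need a GPU
  framework, though the pipeline's contracts would not change.
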