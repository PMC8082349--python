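# Methods

## Problem and model

The task is binary segmentation of the tumor core (enhancing rim plus
enclosed necrosis) from co-registered multi-channel 3D MRI in which the
post-contrast T1-weighted channel (T1c) is always present and any subset of
the secondary channels (T1w, T2w, FLAIR) may be missing. Missing channels
are materialized as zero-filled volumes of the common grid and flagged
unavailable; the flag — never an intensity heuristic — is the single source
of truth for missingness throughout the pipeline.

The segmentation model is a dual-pathway patch-based 3D CNN in the
DeepMedic family. For an input window of side `S` (divisible by the
downsample factor `f`), a *subsampled pathway* sees the whole window
mean-pooled by `f`, and a *normal pathway* sees a central full-resolution
crop. Both pathways are stacks of `L` valid 3×3×3 convolutions with ReLU
and separate weights; the subsampled features are upsampled by `f`
(nearest neighbor) and concatenated with the normal pathway's output,
followed by 1×1×1 hidden layers and a two-class voxelwise classifier.
Per axis:

    output = (S/f − L·(k−1)) · f,      hi-res crop = output + L·(k−1)

The `full` preset (S=57, f=3, L=8, k=3; feature maps
30,30,40,40,40,40,50,50; two 150-wide 1×1×1 layers) yields the 9³ output
patch and 11 weighted layers. The `tiny` preset (S=27, L=3; 8,8,16; one
32-wide 1×1×1 layer) obeys the same geometry rule (27³ → 9³) and trains in
about a minute per 500 iterations on one CPU. Geometry is validated at
construction; an inconsistent configuration cannot produce a runnable
network.

The network, its backpropagation and the Adam optimizer are implemented
directly in NumPy (channels-last layout; each valid convolution is an
accumulation of one BLAS matmul per kernel offset). At the patch sizes
used here this trains the tiny preset comfortably on a single CPU, and the
whole stack stays importable anywhere NumPy runs.

## Sparsified training

During training, each sampled patch stack passes through the augmentation:
every secondary channel is independently replaced by zeros with
probability `p` (default 0.2, approximating the missing-sequence frequency
of multi-hospital clinical cohorts); the primary channel is never zeroed.
Two placement decisions matter:

- **after normalization** — zeros are inserted post-whitening, so an
  augmented-missing channel is bit-identical to an originally-missing one
  from the network's point of view (both sit at the whitened mean of the
  available data);
- **per patch stack**, not per subject — the augmentation is a property of
  the sampling stream. The high-res and low-res stacks of one sample share
  a single draw, so a channel is never half-present.

Sparsification consumes a dedicated random stream: a seed-matched pair of
runs differing only in the `sparsified` flag shares initialization and the
exact patch sequence, so the comparison isolates the augmentation. With
`p=0` the sparsified run is bit-identical to the plain run.

## Training loop

Soft Dice loss on the foreground class, `1 − (2Σpy+ε)/(Σp+Σy+ε)` with
`ε=1e−5`, averaged over the batch; Adam (β₁=0.9, β₂=0.999); learning rate
0.001 halved every 5000 iterations up to 15 000 and every 1500 thereafter
(the tiny preset scales these steps to its shortened run: 150/300/75 over
500 iterations). 32 patches per iteration by default (16 in the tiny
preset); patch centers fall in the tumor core with probability 0.5, else
uniformly in the brain mask — standard practice for the extreme
foreground/background imbalance. The final-iteration weights are the
deliverable; validation data only monitor convergence, never select a
model. A non-finite loss aborts with a diagnostic rather than training
through NaNs.

Whole-volume inference tiles the subject with stride equal to the output
patch (the volume is conceptually padded to a stride multiple, so every
voxel is predicted exactly once) with zero-padded context at borders, then
takes the voxelwise argmax.

## Normalization

Nyúl-style percentile-landmark standardization with landmarks at
{1,10,20,…,90,99}. The standard scale per channel is the empirical-CDF
quantile (`inverted_cdf`) of the pooled brain-mask intensities of all
training subjects in which that channel is available — the empirical
quantile makes pooling invariant under duplicating subjects. At
normalization time a subject's own landmark percentiles are mapped
piecewise-linearly onto the standard scale (end segments extrapolate
linearly), then the channel is whitened to mean 0 / variance 1 over the
brain mask, so background air does not dominate the statistics. Channels
flagged missing skip both steps and remain exactly zero. Degenerate
channels (non-increasing landmarks, e.g. a constant volume) are rejected
with an explicit error. The histogram model is fit once, before any
augmentation, on the original data only.

## Metrics

- Dice `2·TP/(2·TP+FP+FN)`; two empty masks score 1.0 and are flagged.
- Sensitivity `TP/(TP+FN)`; undefined (NaN, flagged) for an empty manual
  mask.
- HD95: boundary voxels are mask voxels with at least one 6-neighbor
  outside the mask (or on the volume edge); directed distances between
  boundary voxel centers are computed in mm via k-d trees with anisotropic
  spacing; each directed set is reduced to its 95th percentile with linear
  interpolation between order statistics; the undirected value is the
  maximum of the two directed percentiles. A pooled-percentile variant
  (95th percentile of the union of both directed distance sets) is
  available via `method="pooled"`; percentile dialects and
  directed/undirected conventions differ across the literature, so the
  choice is explicit and tested against an all-pairs brute-force oracle.
  Undefined (NaN, flagged) if either mask is empty.

## Statistics

Two-sided Wilcoxon signed rank on paired Dice scores. Zero differences are
dropped (classic Wilcoxon; Pratt's zero-rank method is available behind
`zero_method="pratt"`). With ≤25 pairs and untied absolute differences the
exact null distribution of W⁺ is enumerated by dynamic programming over
the generating polynomial ∏ᵣ(1+xʳ)/2ⁿ; otherwise a normal approximation
with continuity and tie correction is used. Multiplicity is controlled by
one Bonferroni correction across the *entire* family of comparisons in a
run (multiply by the family size, cap at 1); the family size is written
into every output row so it is never implicit.

## Synthetic phantom cohort

Each phantom is an ellipsoidal brain (semi-axes 0.42 of the field of view)
of mid-gray tissue with a randomly placed, smoothly deformed spherical
tumor core (radius 5–9 mm by default, radial deformation ±15%), split into
an enhancing rim (outer 2 mm) and necrotic center. Default grid 48³ at
1 mm isotropic. Appearance (arbitrary units, tissue = 100): T1c rim 160 /
necrosis 60; FLAIR core 170 with a 140 halo; T2w core 125; T1w core 80.
Every channel renders the same latent geometry, so channels are partially
redundant and the core is in principle recoverable from T1c alone — the
property that makes missing-sequence robustness learnable. Each channel is
modulated by an independent smooth multiplicative bias field (±20%) and
additive Gaussian noise; the background outside the brain stays exactly
zero, as in skull-stripped MRI. Rician noise is not modeled.

The noise scale (`noise_sd`, as a fraction of the 60-unit rim–tissue
contrast, default 0.5 → sd 30) and the contrast magnitudes were calibrated
so the task sits in a moderate-difficulty regime: voxelwise SNR of order
1–2, where no single secondary channel is individually sufficient, the
FLAIR analog is the dominant cue (SNR ≈ 2.3 vs ≈ 0.7–0.8 for T1w/T2w), and
an unaugmented model therefore has something to lose when FLAIR is absent.
At low noise the phantom saturates (median Dice ≈ 0.97 under every channel
subset) and the robustness mechanism is unobservable by construction.

Missingness: with probability `missing_fraction` (default 0.5, matching a
cohort in which roughly half of patients lack ≥1 secondary sequence) a
non-empty subset of secondary channels is zero-filled, drawn from
configurable weights defaulting to T2w-only most common (0.50), then
T2w+FLAIR (0.25), with the remaining subsets rare — echoing the dominant
patterns reported for multi-hospital glioblastoma imaging. All randomness
derives from `(config.seed, subject_seed)`, so cohorts reproduce
file-by-file.

What the phantom does **not** emulate: anatomy (gyri, ventricles, multiple
tissue classes), scanner- and site-specific intensity distributions,
resolution heterogeneity, registration error, and Rician noise statistics.
Passing results therefore demonstrate the *mechanism* — that sparsified
training confers robustness to zero-filled channels when cross-channel
redundancy exists — not clinical-grade performance, and desk-scale Dice
values are not comparable to values reported on clinical cohorts.

## Problem sizes and numerical choices

The robustness experiment runs at desk scale by design: 48³ phantoms, 40
training / 20 test subjects, the tiny preset, 500 iterations, batch 16 —
about a minute of training per model on one CPU, so a seed-matched pair
with full 8-pattern evaluation completes in minutes. Both the training and
test cohorts of the model-pair comparison use complete imaging by default
(`complete_train` / `complete_test`): zero-filled channels then reach the
plain model only through the sparsified augmentation, so the comparison
isolates the method — training the pair on a cohort that already contains
naturally missing channels gives the plain model nearly the same
missing-channel exposure as the augmentation and washes out the contrast.
An optional data-variant grid (`data_variants=("complete", "all")`) trains
the pair on both cohort compositions in one run. Sparsification is applied
per sampled patch stack by default; `sparsify_scope="volume"` switches to
one draw per subject per iteration.
The experiment driver is deterministic: a master seed fixes the cohort,
initialization, patch sampling and augmentation streams, and two runs
produce byte-identical CSV outputs.

Other conventions: spacing compared with relative tolerance 1e-4 and
shapes exactly (inputs are assumed pre-registered; no resampling or
reorientation is performed); masks stored as unsigned 8-bit NIfTI;
foreground-center sampling falls back to brain voxels when a mask is
empty; `dice(∅,∅)=1`, sensitivity and HD95 carry NaN sentinels with flags
rather than raising in batch evaluation.

## Known limitations

- The full preset (57³ input, 30 000 iterations) is constructible
  and geometry-checked but impractical to train in NumPy on one CPU; all
  quantitative results in this package are tiny-preset results on
  phantoms.
- Only the binary tumor core is segmented; no multi-class subcompartments,
  CRF post-processing, or ensembling.
- Histogram standardization is the only intensity harmonization offered;
  cross-site domain shift is out of scope.
- The Wilcoxon exact path requires untied absolute differences; tied Dice
  scores (common at saturation) fall back to the tie-corrected normal
  approximation.
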