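# Methods

This note documents the models and procedures implemented in `mircos`,
the assumptions behind the synthetic-data generator, the numerical
choices, and the known limitations.

## The problem setting

Two classes of powdered plant material measured by ATR FT-MIR over
4000–450 cm⁻¹. Both classes share every absorption band — carbohydrate
C–O/C–C/C–O–H near 1014 cm⁻¹, phosphodiester/PO₂⁻ bands near 1220 and
1240 cm⁻¹, a broad CH₂/CH₃ composite over 1300–1500 cm⁻¹, amide I near
1635 cm⁻¹, aliphatic C–H near 2921 cm⁻¹, and the O–H/N–H envelope near
3276 cm⁻¹ — and differ only in band intensities. Classification must
therefore read relative intensity patterns, not peak positions.

## Synthetic-data generator

Real spectra of this kind are rarely shareable, so the generator is a
first-class, tested component that emulates the acquisition:

* **Clean class spectra** are sums of Gaussian bands at the positions
  above. The class effect is purely multiplicative per band
  (shape-preserving): the default table gives the second class a
  multiplier between 0.8 (carbohydrate band, depletion) and the
  configured contrast (default 1.5, amide I band), interpolated in fixed
  proportion across the remaining bands, so contrast = 1 is an exact
  null effect. A uniform multiplier on *all* bands would be removed by
  the per-map image autoscaling; band-dependent contrast is what real
  compositional differences look like.
* **Multiplicative scatter**: each recorded scan has its own gain,
  default range 0.8–1.2. A sample's replicate gains are, by default,
  jittered stratified draws over that range in random order
  (`scatter_model="stratified"`): every repack differs appreciably from
  the others, as manual repacking of a powder on an ATR crystal does.
  An iid mode is available; under it a sample's repacks can coincide by
  chance, which leaves that sample's correlation maps dominated by noise.
* **Additive baseline** (offset ±0.05 AU, slope ±2×10⁻⁵ AU/cm⁻¹) is
  drawn once per sample and shared by its replicate scans — baseline
  instability is slow instrument drift, so consecutive scans of one
  sample see the same baseline while different samples differ.
* **Noise**: iid Gaussian per point (default sd 0.01 AU ≈ 1% of the
  maximum band amplitude) plus a smaller per-replicate jitter
  (sd 0.002 AU). The noise model is homoscedastic; no detector
  wavelength dependence is simulated.
* **Defaults**: 109 + 63 samples, 3 replicate scans each, grid
  4000 → 450 cm⁻¹ at 2 cm⁻¹ spacing, seeded and fully deterministic.

What passing tests on this generator do **not** show: robustness to peak
shifts, ATR penetration-depth effects, water-vapor/CO₂ interference,
heteroscedastic detector noise, or instrument-to-instrument transfer.
The generator has a switch for small peak shifts only through custom
band tables.

## Preprocessing

SNV uses the sample (n−1) standard deviation; a constant record is an
error, not a silent pass-through. MSC fits x = a + b·ref by OLS and
returns (x − a)/b; the reference defaults to the mean of the fitted
(training) set and is frozen before held-out records are transformed, so
train and test pass through the identical operator. Savitzky–Golay uses
window 15, polynomial order 3; the chain names `1D`/`2D` select
derivative order 1/2 of that filter, `SG` alone is the smoother. The
phrase "third-order derivative, window 15" in the chemometric literature
this follows is read as polynomial order 3 — a literal third derivative
is used nowhere in the workflow, and first/second derivatives are listed
as separate methods. Derivatives are returned per cm⁻¹ with the sign of
the physical wavenumber axis regardless of storage direction.

## Kennard–Stone splitting

Selection is greedy maxmin on Euclidean distances, seeded by the
maximum-distance pair; all ties break toward the lowest canonical index
(records sorted by sample id), making selection invariant to record
order. The split is stratified per class — only per-class selection
reproduces the 76/44 train counts from 109/63 at 70% — with
floor(fraction × class size) training samples per class. Distances are
computed on raw averaged spectra by default (`space` selects a
preprocessing representation). Fractions that would round a class's test
set to empty are rejected. Replicates of one sample always travel
together because selection runs on per-sample averaged spectra.

## Chemometric models

PLS-DA regresses a centered one-column-per-class indicator matrix on
centered spectra (NIPALS partial least squares) and classifies by argmax
of predicted indicators — equivalent to a 0.5 threshold in two-class
coding. R²Y and RMSEE come from training residuals; Q² and RMSECV from
stratified k-fold cross-validation (default 7 folds) with per-fold
refit, Q² = 1 − PRESS/SS. RMSEP and test accuracy are computed once on
the held-out set. The permutation diagnostic refits on n (default 200)
label permutations, regresses R²Y/Q² on |corr(permuted, original)|
including the unpermuted model at abscissa 1, and flags overfitting when
the Q² intercept is nonnegative or any permuted model beats the
original.

The SVM is RBF-kernel with column-standardized features (training-set
mean/sd). The (c, g) grid is log₂-spaced (defaults span 2⁻¹⁰…2²⁰ ×
2⁻²⁰…2⁴ in the library; a coarser grid in the pipeline defaults);
selection is by k-fold CV accuracy with ties broken toward smaller c,
then smaller g, so results are deterministic.

PCA is plain mean-centered SVD; explained-variance ratios are σᵢ²/Σσ².

## Correlation maps

Dynamic spectra default to mean-centering over the perturbation series:
the synchronous diagonal is then the per-wavenumber variance, which is
what makes autopeaks interpretable. A raw-series mode (`reference=
"none"`) is kept for exact-equation comparison. Per-sample maps use each
sample's replicate scans as its perturbation series (m = 3 by default) —
the only construction that yields one map per sample from replicated
acquisition. With per-record gains g_k, the dynamic spectra are
approximately (g_k − ḡ)·clean(ν), so the synchronous map is close to a
rank-one outer product of the sample's clean spectrum with itself: the
map's *shape* carries the class's relative band intensities, which is
the signal the image classifier reads. A deviation mode (sample mean vs
global mean, m = 2) is provided as a fallback for unreplicated data; its
asynchronous map vanishes identically. The wavenumber grid is decimated
(pipeline default factor 16 → 111 × 111 maps) before the quadratic-cost
map computation; maps are held in memory and rendered transiently rather
than stored.

The integrated map is the elementwise product Φ∘Ψ (the defining
expression is pointwise in (ν₁, ν₂)), hence antisymmetric.

## Rendering and the image partition

Each map becomes a square surface image: intensity over the ν₁×ν₂ plane,
viridis palette, view (elev 30°, azim −60°), no axes, default 224 px in
the library and 64 px in the pipeline presets. Intensity autoscaling is
per map, making images invariant to the map's absolute amplitude — the
amplitude is quadratic (quartic for I) in absorbance scale and would
otherwise leak gain rather than composition; a shared-range option exists
for ablations. The surface mesh is capped at the output pixel count
(finer quads are invisible and dominate cost). Rendering is pure and
byte-deterministic. The train/test/external-validation partition
(default 84/36/52 on 172 samples) is a seed-controlled stratified random
assignment shared by all three map categories, with controlled rounding
that keeps every class-role cell within one sample of its proportional
share.

## Residual CNN

No deep-learning framework is required: the classifier is a small
residual network implemented directly on NumPy. Convolutions are im2col
matrix products; blocks are conv–BN–ReLU–conv–BN with identity shortcuts
(1×1 strided projection at width/resolution changes); a stride-2 stem,
three stages (default widths 16/32/64, two blocks each; the `TINY`
variant 8/16/32 × 1 used at desk scale), global average pooling, two-way
softmax head. Training is mini-batch Adam (lr 10⁻³, batch 16), default
46 epochs, no augmentation, no early stopping (histories stay
comparable). Per-channel normalization constants come from the training
role only; evaluation refuses roles whose sample ids overlap the
training role. Everything derives from one seed and is reproducible on a
single thread.

Scored metrics follow the confusion-matrix layer: Acc, Sen = TP/(TP+FN),
Spe = TN/(TN+FP), Eff = Sen×Spe, wild as the positive (adulteration
target) class. Note that Eff is the *product* — a classifier with
Sen = Spe = 0.6346 has Eff ≈ 0.403, not 0.6346; reports carry the
product. A majority-class predictor on a 33/19 role scores exactly
33/52 ≈ 63.46%, the null baseline any trained model must beat.

## Problem sizes and reproducibility

The acceptance script and the test suite run the image arm at 111 × 111
maps, 64 × 64 images and the `TINY` architecture — sizes chosen so the
full three-seed experiment completes in minutes on one CPU while leaving
the workflow's behavior unchanged in kind. The pipeline fans one global
seed out to per-stage seeds via a stable hash (`stage_seed`), so stages
can be rerun in isolation; identical configurations write byte-identical
reports. Under the default strong-contrast conditions the synchronous-map
classifier's external-validation accuracy is 100% on most seeds with
occasional single-sample misses (≈98%), the residue of borderline
repack-gain spreads; the asynchronous and integrated categories are
noisier targets, as their maps are dominated by noise cross-terms at
m = 3.

## Known limitations

* The generator's class effect is multiplicative and peak-aligned;
  workflows sensitive to peak shifts are not exercised.
* Q² pooling follows the plain k-fold PRESS/SS definition; commercial
  chemometric packages use proprietary variants, so Q² values are
  comparable in behavior, not digit-for-digit.
* The asynchronous map at m = 3 replicates estimates sequential order
  from three points; it is retained for completeness, not recommended as
  a primary classification input.
* Single-threaded CPU training limits the practical image budget to a
  few hundred small images; the architecture is sized accordingly.
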