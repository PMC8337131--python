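# Methods

This note records the model, the numerical choices, the synthetic data
conditions, and the limits of what the tests demonstrate.

## The registration model

The package fits a 6-parameter affine transform

    [x]   [r00 r01 tx] [x']
    [y] = [r10 r11 ty] [y']
    [1]   [0   0   1 ] [1 ]

mapping floating-image coordinates `(x', y')` (column, row, 0-based,
origin top-left, y down) to reference-image coordinates.  This direction
is fixed throughout: estimation consumes (floating point, reference
point) pairs, and warping uses the *inverse* transform so each output
pixel samples the floating image (inverse mapping; no holes).

Registration is feature-based and two-stage.  The coarse stage registers
the floating image F to a progressive image `M_l`; the fine stage
registers the coarse result to the reference R; the composed affine is
applied once to the original F, so the delivered image is resampled a
single time (no double interpolation blur).  The composition invariant
`composed = fine ∘ coarse` is asserted in tests.

### Progressive images

`M_0 = (F + R)/2`, then recursive averaging.  The recursion direction is
genuinely ambiguous as a matter of design — averaging the chain with R
or with F are both defensible — so both are implemented.  The default,
`toward_reference` (`M_{k+1} = (M_k + R)/2`, closed form
`M_l = 2^-(l+1) F + (1 - 2^-(l+1)) R`), is chosen because the coarse
stage registers F *to* `M_l` and the fine stage closes the remaining gap
to R; that layout wants `M_l` between F and R, nearer R as `l` grows.
The default level is `l = 7` (F carries weight 1/256 in `M_7`);
`select_level` / `fit_sweep` expose the data-driven choice, maximizing a
configurable metric (default NMI) over levels, failed levels skipped.

A practical note on low levels: `M_0` contains a half-contrast ghost of
F at F's own location, so the coarse stage can lock onto the ghost and
return a near-identity (or degenerate) transform.  Degenerate estimates
(|det| < 1e-6) are converted into stage failures; the sweep records such
levels as failed rather than aborting.

### SURF detector and descriptor

The detector follows the canonical configuration: integral image with an
exclusive zero first row/column (rectangle sums in 4 lookups, clipped at
the borders so out-of-bounds area contributes 0); box-filter
approximations of the Gaussian second derivatives with lobe `L/3`,
Dxy weight 0.9, responses normalized by the filter area `L^2`;
filter-size ladder 9, 15, 21, 27 / 15, 27, 39, 51 / 27, 51, 75, 99 /
51, 99, 147, 195 (start `9 + 6(2^o - 1)`, step `6 * 2^o`), scale
`sigma = 1.2 * size / 9`, all maps at full resolution (no stride
subsampling — determinism and exact testability were preferred to
speed, and the images here are ~200 px).  Keypoints are strict maxima
over the 26-point scale-space neighbourhood above a threshold (default
1e-4 on area-normalized responses under the [0, 1] intensity
convention), refined by a single 3-D quadratic fit and rejected if any
offset component exceeds 0.5 (plateaus are discarded by strictness; no
iterative re-localization, again for determinism).  The Laplacian sign
(bright/dark) is kept per keypoint.

Orientation is the dominant direction of Gaussian-weighted
(sigma = 2.5s) Haar responses on a 6s-radius disk sampled at step s
(`s = round(sigma)`), with a pi/3 sector slid in fixed pi/32 steps and
exact ties broken toward the smaller angle.  The descriptor is the
64-d vector of `(sum dx, sum dy, sum |dx|, sum |dy|)` over 4x4
subregions of a 20-sigma window aligned to the orientation (5x5 samples
per subregion, Haar half-width s, Gaussian weight sigma = 3.3s),
normalized to unit length.  Samples whose Haar window would cross the
image border are dropped entirely rather than clipped: a clipped window
has unequal halves and would silently break the descriptor's invariance
to affine intensity rescaling, which is asserted to 1e-3 in tests.
Keypoints whose orientation (8s) or descriptor (10s) margin leaves the
image are silently dropped by `extract`, which orders its output by
response descending, then y, then x.  An upright mode (skip orientation)
is available in `DetectorParams`.

Known boundary behaviour: the box approximation's effective scale is
slightly coarser than the nominal `1.2 * size / 9`, so an isolated
Gaussian blob of sigma ~2 px peaks along scale *below* the first
interior ladder level and is not a 26-neighbour maximum, although the
response maps still localize it exactly where a dense
Gaussian-derivative Hessian places it.  Blobs of sigma >= ~2.5 px are
detected outright.  On ideal noiseless blobs the operator also produces
weak shoulder maxima (two orders of magnitude below the peak); tests
treat detections above 10% of the top response as the salient set.

### Matching and estimation

Brute-force Euclidean nearest/next-nearest neighbour search (the
descriptor sets are small; exactness beats indexing), stable tie-break
toward the lower train index, and a ratio test with default threshold
0.7; a threshold of 1.0 reproduces raw first-NN matching (the CLI's
`--no-ratio-test`).  One match per query; many-to-one train matches are
representable deliberately — that failure mode is part of what the
two-stage design mitigates.

Affine estimation defaults to RANSAC (500 seeded minimal 3-point
samples, inlier = transfer error < 2 px, ties toward smaller inlier
error, least-squares refit on the consensus) with plain least squares
available.  Collinear or <3-point configurations raise estimation
errors.  With ~40 inliers and coordinate noise sigma, the refit
translation standard error is sigma/sqrt(n) in the best case — fitted
translations are accurate *relative to their magnitude*, not to
arbitrary absolute precision; the tests phrase translation accuracy
accordingly.

### Resampling and metrics

Warping uses the Keys bicubic kernel (a = -0.5), edge replication inside
the support, fill value 0 for samples more than 0.5 px outside the
source, and output clipped to [0, 1].  At integer coordinates the kernel
reproduces samples exactly and it is exact on linear ramps; both are
asserted.

The four similarity measures share one joint histogram: default 64
uniform bins on [0, 1] (common mutual-information-registration practice,
stable for 8-bit-origin data; configurable), log base 2 (entropies in
bits; NMI is base-invariant), `0 log 0 = 0` for empty bins.  All images
are min-max normalized to [0, 1] at load — a shared range is what makes
cross-modality averaging meaningful — with the original dtype/range kept
in metadata.  NCC is computed signed (the Pearson form); it is *not*
clamped to [0, 1].  Constant images make NMI/NCC undefined and raise
degenerate-input errors.

## Synthetic study conditions

`make_phantom` draws a head-like soft ellipse with a bright rim, ~30
Gaussian blobs of both polarities (sigma 2.5–8 px) inside it,
low-frequency cosine texture (amplitude 0.06) and additive Gaussian
noise (sigma 0.004), on a 181x217 grid matching typical MR slice
matrices; everything is deterministic under the spec seed.  Misaligned
pairs warp the phantom by the inverse of a known centre-anchored
similarity transform, so the registration target is exact and TRE is
measured against it on a 10x10 interior control grid (10% margin).
The study conditions are 40 pairs with |rotation| <= 10 degrees,
|translation| <= 15 px, scale in [0.9, 1.1].

The multimodal condition applies a monotone nonlinear remap
`v -> 0.08 + 0.82 v^0.55` to the floating image: geometry is preserved
while intensity conservation is broken (the property that defeats
optical-flow-style methods).  A polarity-inverting remap was considered
and rejected as the default: intensity inversion flips the detector's
bright/dark classification and permutes descriptor subregions, which is
a limitation of SURF itself rather than of the registration strategy
under study.

What the phantoms do *not* emulate: anatomy, partial-volume effects,
bias fields, independent sensor noise between the two images of a pair,
occlusion/missing structure, and non-affine deformation.  Passing tests
therefore demonstrate that the pipeline recovers affine misalignments of
blob-and-edge imagery under intensity remapping — not clinical-grade
performance on real MR/CT, where gold standards and preprocessing
dominate the reported numbers.

## Problem sizes and determinism

Simulation sizes were chosen to make every statement checkable on a
single CPU in minutes: 16x16 images for exhaustive/brute-force oracle
comparisons (all ~18k rectangles of the integral image are enumerated;
8-bit-quantized intensities make those sums exactly representable, so
exact equality is asserted rather than a tolerance), 96–192 px blob
images for detector localization, 200–1000 draws for affine recovery,
and 40 pairs per end-to-end condition.  All stochastic components
(RANSAC, phantom generation, pair parameters) are seeded; repeated runs
are bit-identical, and the acceptance script derives every sub-seed from
its single `--seed`.

## Known limitations

- 2-D only; no projective/B-spline/diffeomorphic transforms.
- Blobs below sigma ~2.5 px sit under the detector's scale ladder
  (see above).
- The per-level sweep is a full re-registration per level; it is linear
  in `max_level` and makes no attempt to share feature extraction.
- Standard errors in the results object are propagated from final
  correspondence residuals under an independent-noise assumption; they
  are indicative, not calibrated confidence intervals.
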