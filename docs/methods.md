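# Methods

## Overview

`irispipe` implements a classical iris-verification chain: locate the two
circular iris boundaries with a circular Hough transform, unwrap the annulus
between them to a fixed-size polar template with Daugman's rubber-sheet
model, compress the template with a one-level discrete wavelet transform
(keeping only the LL approximation band), project the flattened LL band onto
a PCA basis fitted at enrollment, and decide identity claims with one
soft-margin linear SVM per enrolled subject. A synthetic eye generator with
known ground-truth geometry makes the whole chain testable end to end.

## Segmentation

An edge map is built from centered finite differences of the (Gaussian
pre-smoothed, sigma 1.5 px) image; the binary mask keeps pixels whose
gradient magnitude is at or above a quantile (default 0.95) of the nonzero
magnitudes. The circular Hough accumulator uses an integer voting rule: an
edge pixel (y, x) votes for cell (yc, xc, r) exactly when
`rint(hypot(y - yc, x - xc)) == r` with round-half-to-even. This makes the
accumulator a well-defined combinatorial object — the test suite compares it
cell-for-cell against a brute-force per-cell counter — and fixes the
tie-break deterministically (smallest radius, then row-major center order).

Two passes:

* **Pupil pass** (isotropic gradients, radius search 12-40 px). The pupil is
  the darkest structure in an eye image, so edge pixels are restricted to a
  3-px dilation of the dark region (smoothed intensity < 80) and centers are
  searched within ±40 px of the dark-region centroid. Without this prior,
  fine iris-texture edges at larger radii can out-vote the short pupil
  perimeter on noisy images; with it the pass is also an order of magnitude
  faster. If the image contains no dark pixels the pass falls back to an
  unrestricted full-image search.
* **Limbic pass** (radius search 50-95 px, center constrained within 15 px
  of the found pupil center). The gradient's column-derivative component is
  multiplied by `vertical_weight` (default 4) before thresholding, which
  promotes the vertical left/right limbic arcs and demotes horizontally
  aligned eyelid edges. The weight value is a design choice: 4 reliably
  suppresses the synthetic occlusion bands without erasing the limbic arcs.

If the resulting pupil circle is not strictly inside the iris circle the
whole procedure is retried once with the threshold quantile halved (more
edge pixels); a second failure raises a segmentation error carrying both
candidate circles.

The radius search ranges are matched to the synthetic generator's geometry
and are plain config fields; real imagery would need ranges appropriate to
its capture scale.

## Normalization

Rubber-sheet unwrapping maps the annulus to a fixed `radial_res x
angular_res` grid (default 60 x 300). Column j samples angle
`theta_j = 2*pi*j/angular_res` (half-open, theta=0 along +x, increasing
toward increasing row index); row i samples the radial fraction
`t_i = i/(radial_res - 1)`, inclusive at both boundaries (row 0 on the pupil
circle, last row on the limbic circle — an explicit convention, since
half-open radial sampling would be equally defensible). Non-concentric
circles are handled by blending the two boundary points per angle,

    s(i, j) = (1 - t_i) * P(theta_j) + t_i * L(theta_j),

so the template degrades gracefully under pupil decentration. Intensities
are sampled with bilinear interpolation; samples that fall outside the image
(possible for jittered segmentations) are clamped to the border and counted
in the template metadata rather than raising.

## Feature extraction

One-level separable 2-D DWT (default Haar, periodized extension) splits the
template into LL/LH/HL/HH, each `ceil(m/2) x ceil(n/2)` — 30 x 150 for the
default template. Periodization keeps orthonormal wavelets exactly
energy-conserving and invertible, both asserted in tests. Only LL is kept
and flattened row-major (d = 4500).

PCA is fitted on the enrollment LL vectors using the scatter matrix
`C = Xz' Xz` of the mean-centered data **without** a 1/N factor; the
eigenvalues are therefore "unnormalized" (N times the usual variances),
which changes nothing downstream since eigenvectors and explained-variance
ratios are scale-free. Because d >> N, the eigenproblem is solved through
the N x N Gram matrix `Xz Xz'` (the snapshot / eigen-iris route) and mapped
back to d-space with renormalization; the nonzero spectra of the two routes
coincide, which the tests check at N=10, d=50. Determinism conventions:
eigenpairs sorted by descending eigenvalue, eigenvalues below a relative
tolerance of 1e-10 truncated as rank-deficient, each eigenvector's
largest-magnitude entry forced positive. The retained component count k
defaults to the smallest k explaining >= 95% of the eigenvalue mass, capped
at N-1; an integer config value fixes k directly.

## Matching

Verification is one-vs-rest: enrollment trains one soft-margin linear SVM
per subject (that subject's feature vectors against all others', penalty
C = 1.0 by default) through scikit-learn's libsvm binding, storing only the
hyperplane (w, b). A claim of identity s is accepted iff `w_s . f + b_s`
strictly exceeds the decision threshold (default 0). Error rates:

    FAR = impostor accepts / impostor trials * 100
    FRR = genuine rejects  / genuine trials  * 100
    accuracy = correct decisions / all trials * 100

The trial protocol pairs each test vector with one genuine claim and one
impostor claim whose wrong identity is drawn uniformly from the other
enrolled subjects. Impostor draws are assigned in a canonical content-sorted
order so that, for a fixed seed, the report is invariant to permutations of
the test set. These protocol conventions are the package's own: published
accuracy figures for iris systems rarely state their trial composition, so
FAR/FRR numbers are only comparable under an explicitly declared protocol.

## Synthetic data

The generator renders a dark pupil disc (level 30) inside a textured iris
annulus (level 130 ± texture) inside a bright sclera (level 220), on a
280 x 320 px canvas. The iris texture is a sum of 3-6 products of radial and
angular sinusoids (amplitudes 8-16, radial frequencies 0.08-0.30 cycles/px,
angular harmonics 2-12, seeded phases) plus a seeded smooth noise field,
clipped to ±60 — band-limited, cheap, and distinct per subject while
reproducible per (subject_id, texture_seed). Cohorts add per-capture
Gaussian pixel noise (sd 8 in the benchmark condition, roughly 6% of the
8-bit range) and a whole-eye center jitter of up to 3 px; geometry is drawn
per subject with pupil radius 15-35 px and iris radius 55-90 px. Optional
occlusion is a pair of plain horizontal bright bands covering a fraction of
the iris's vertical extent from above and below — a crude eyelid stand-in,
chosen because no principled degradation model was available.

What this emulates: stable per-subject texture, capture-to-capture noise
and misalignment, approximate eyelid occlusion, and recoverable circular
geometry. What it does not: photorealistic iris crypts and furrows,
specular highlights, off-axis gaze, pupil dilation between captures,
eyelashes, or sensor artifacts. Passing the synthetic benchmarks therefore
demonstrates the pipeline's internal consistency and robustness to additive
noise and jitter, not field performance on real iris imagery.

## Benchmark problem sizes

The segmentation-recovery benchmark uses 100 noisy eyes (20 subjects x 5
captures, noise sd 8) with a pass at <= 3 px center and radius error; the
end-to-end benchmark enrolls 20 subjects x 5 captures and tests on 5 held
out captures each (100 genuine + 100 impostor trials). These sizes mirror a
100-image enrollment regime while keeping a full run on one CPU in the
low minutes.

## Numerical and degenerate-input choices

* Edge mask threshold uses >= so a uniform-gradient edge is kept; a
  constant image yields an empty mask and, downstream, a segmentation error
  (fewer than 8 edge pixels).
* Identical PCA training vectors give a zero spectrum: the model is valid
  with k = 0 and produces empty feature vectors.
* A feature vector exactly on a subject's hyperplane is rejected (strict
  inequality).
* Evaluation with no impostor trials reports FAR as null rather than
  dividing by zero.
* Timings (classification stage, `bench` subcommand) are wall-clock and
  informational only; nothing is asserted on them.

## Known limitations

* Search ranges, the dark-pupil threshold (intensity 80), and the texture
  model are tuned to the synthetic image family; applying the pipeline to
  real captures requires revisiting the Hough config.
* No occlusion masking is carried into the template: occluded template rows
  simply contain eyelid intensity. Heavy occlusion (> ~0.3) degrades
  matching.
* The SVM stores only linear hyperplanes; nonlinear kernels would require
  keeping support vectors and are out of scope.
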