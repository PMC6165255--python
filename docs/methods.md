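# Methods

## Pipeline overview

The package classifies small histology tiles (nominally 300×300 px,
H&E-like) in three stages: local feature extraction with SIFT,
bag-of-features (BoF) encoding against a learned codebook, and a kernel
SVM over the encoded histograms.  Section- and patient-level summaries
(majority vote, recognition rate) sit on top of tile predictions.  The
design premise is that tumour subtypes differ in the local texture
statistics of their cell nuclei while nucleus *size* varies strongly
within a subtype, so the features must be scale- and
rotation-invariant.

## SIFT detector and descriptor

**Scale space.**  Octaves hold `s + 3 = 6` Gaussian images with scales
`σ₀·k^i`, `k = 2^(1/s)`, `s = 3`; blurring is incremental, and the next
octave starts from the `2σ₀` image downsampled by 2.  The input is
assumed to carry `0.5` px of acquisition blur, folded into the first
pre-smoothing.  The octave count defaults to
`floor(log2(min(h, w))) − 2` (6 for a 300×300 tile); an optional 2×
pre-upsampling of the first octave (off by default) roughly quadruples
keypoint yield at 4× cost.  Requesting more octaves than the image
supports logs a warning and clamps, rather than failing.

**Detection and rejection.**  Difference-of-Gaussians extrema are
strict maxima/minima over the 26-neighborhood, scanned only at interior
intervals and pixels.  Localization iterates the 3-D quadratic fit
(x, y, scale) up to 5 times, re-centering while any offset component
exceeds 0.5; candidates that leave the valid volume, hit a singular
Hessian, or fail to converge are dropped.  The contrast test
`|D(z)| < CC` uses the interpolated response on images scaled to [0, 1]
with **no** per-interval normalization of `CC` — the operating value
`CC = 0.04` is interpreted as a raw threshold, matching how the
parameter was tuned as a free constant.  The edge test uses
`Tr²/Det ≥ (CE+1)²/CE` on the 2×2 spatial Hessian (discard at equality,
and whenever `Det ≤ 0`), which is algebraically equivalent to the
eigenvalue-ratio formulation but avoids an explicit
eigendecomposition.

**Orientation.**  The 36-bin gradient-orientation histogram is built
from the Gaussian level nearest the keypoint's scale, with samples
weighted by gradient magnitude and a circular Gaussian of width
`1.5 σ` over a `±3·1.5σ` window.  The histogram is circularly smoothed
with the `[1,4,6,4,1]/16` kernel before peak-picking; every local peak
at ≥ 80% of the maximum emits a keypoint, its angle refined by
parabolic interpolation over the peak and its two neighbors.  An
all-zero-gradient region (possible only on degenerate inputs) yields
orientation 0 with a logged warning.

**Descriptor.**  Gradients are sampled bilinearly (components `dx`,
`dy`, then magnitude/angle — angles themselves cannot be interpolated
across the wrap) on a 16×16 grid scaled by the keypoint scale (each
4-sample sub-region spans `3σ`) and rotated by −orientation, then
accumulated into 4×4 spatial × 8 orientation bins with trilinear
interpolation and a Gaussian spatial weight (width = half the window).
The vector is normalized, clamped at 0.2, and renormalized; this gives
illumination robustness.  Note the final renormalization can lift
components above 0.2 again (to `0.2 / ‖clamped‖`, ≈ 0.3 in practice);
the clamp bounds the *pre-normalization* contribution of any single
bin.  Out-of-bounds samples contribute zero; a zero-gradient window
produces no descriptor.

Grayscale conversion of RGB inputs uses BT.601 luminance
(`0.299R + 0.587G + 0.114B`).  Coordinates are `(x, y) = (column,
row)`, 0-based, pixel centers at integers, reported at full input
resolution.

## Encoding

The codebook is k-means over training descriptors (k-means++
initialization, ≤ 300 iterations, best of 3 restarts, fixed seed); a
seeded uniform subsample caps clustering cost at 100 000 descriptors.
Encoding assigns each descriptor to the nearest centroid (Euclidean;
ties to the lowest index, making encoding deterministic) and
L1-normalizes the count vector.  L1 was chosen because the
histogram-intersection kernel presumes comparable masses.  The spatial
pyramid variant concatenates per-cell histograms over `2^l × 2^l` grids
(level `l = 0..L−1`, default 2 levels), each cell L1-normalized and
weighted by the standard pyramid-match weights (`1/2^(L−l)`, level 0
halved), with a final global L1 normalization; `levels=1` reduces
exactly to the flat encoding.

## Classification

One-vs-one soft-margin SVM (the common multiclass default).  The RBF
kernel uses the operating width γ = 0.004; the histogram-intersection
kernel is supplied as a precomputed Gram matrix, so the fitted model
retains its training histograms and computes the kernel row against
them at prediction time.  `C` defaults to 1.0 and is exposed in the
configuration and the tuning grid.  Per-class aggregated decision
values (one-vs-rest scores) are exposed for majority-vote
tie-breaking.

A practical note on the kernels: on L1-normalized histograms, pairwise
squared distances are ≪ 1, so the RBF kernel at γ = 0.004 is nearly
constant and separates weakly; the intersection kernel is
scale-appropriate for such histograms and is the configuration that
performs best — consistent with intersection-kernel rows being the
strongest in published comparisons of this pipeline.  The end-to-end
experiment protocol therefore reports both but uses intersection as the
primary configuration.

## Evaluation protocol

Tile-level: confusion matrix; per-class precision `TP/(TP+FP)` (0 with
a warning when a class is never predicted), recall `TP/(TP+FN)`,
F-measure (harmonic mean); weighted versions weight by actual-class
support, so weighted recall equals overall accuracy.  Method
comparisons use a two-sided paired t-test on per-trial F-measures
(significance level 5%); zero-variance differences are degenerate and
reported as p = 0 (means differ) or p = 1 (identical), flagged.
Section-level: plurality vote over sub-image predictions, ties broken
by the larger summed per-class decision score (classifier confidence),
then lexicographically, both logged.  Patient-level: recognition rate
`mean_P(Nrec_P / NP)`.

Splitting is stratified per class with rounded validation/test shares
and the remainder to training (defaults 0.6/0.2/0.2, matching
623/211/209 proportions on a 1043-image set within rounding).  An
optional patient-disjoint mode keeps all of a patient's images in one
subset; it is off by default to mirror image-level splitting protocols,
but provided because image-level splits can leak near-duplicate tiles.
Repeated-trial protocols re-split (not merely reshuffle) on each trial,
with per-trial seeds from named substreams of one master seed
(split / codebook / SVM / synthesis), so no stage's seed consumption
perturbs another's.

Hyper-parameter tuning sweeps one axis at a time in a fixed order —
σ₀ ∈ {0.1, 0.5, 0.9, 1.3, 1.7, 2.1}, then CC ∈ {0.02..0.06}, then
CE ∈ {5, 11, 17, 23, 29}, then codebook size ∈ {300..700} — freezing
the best value before the next axis; each cell is the mean accuracy
over repeated ~71/29 sub-splits of the validation set (the 150/61
pattern).  A full-factorial sweep is available behind a flag.  Grid
values that would produce no features on some images score those images
as errors instead of aborting the sweep.

## Synthetic data

The generator emulates what drives this classification problem:
texture classes distinguished by the size distribution and packing
density of roughly elliptical dark "cells" on a light background, with
strong within-class scale variation.  Cells are elliptical Gaussian
dips (Poisson-distributed count = density × area/10⁴ px²; radius
~ N(mean, sd), eccentricity and orientation per cell; amplitude jitter
0.8–1.0 of the class contrast), plus Gaussian pixel noise, clipped to
[0, 1].  One global scale multiplier per image, uniform on the class's
jitter range (default 0.7–1.4), creates the within-class size variation
that motivates scale-invariant features.

The five default classes — small-dense, small-sparse, large-dense,
large-sparse, mixed-size — use radii 3/3/8/8/5 px (sd
0.6/0.6/1.6/1.6/2.5), densities 10/3/6/2/5 cells per 10⁴ px²,
eccentricities 0.2/0.2/0.5/0.5/0.35, contrast 0.55 on background 0.85,
noise sd 0.02.  The sizes and densities bracket the
small-round-blue-cell extreme (many small nuclei) against sparse large
ganglion-like cells, with a deliberately ambiguous mixed class.
Parameter sets implying more than 50% expected blob coverage are
rejected as degenerate.  Images are grouped into pseudo-patients
(5 images) and pseudo-sections (10 images) so patient- and
section-level metrics can be exercised.

What this emulates — and what it does not: the generator produces
separable gradient-statistics classes with realistic scale variation,
which is what the feature pipeline needs to demonstrate scale-robust
classification end-to-end.  It does not model stain variability,
nuclear chromatin texture, tissue architecture, or imaging artifacts;
passing tests therefore demonstrate the pipeline's mechanics and its
scale/rotation robustness, not clinical-grade performance on real
slides.  Grayscale output is the default (the pipeline converts RGB to
grayscale anyway); an H&E-like purple/pink colorization exists solely
to exercise the RGB path.

## Experiment protocol and problem sizes

The standard study runs 5 classes × 50 tiles (40 per class for
training, 10 held out), k-means with k = 500 on the training
descriptors only (no leakage), committed master seed; repeated-trial
comparisons use 10 fresh splits with the codebook refit per trial and
both kernels fit on identical histograms (a paired design).  These
sizes keep a full run in the minutes range on one CPU while the default
classes remain separable at ≥ 0.9 held-out accuracy; within-class
scale jitter costs a few accuracy points (≤ 10) relative to
jitter-free data, quantifying the scale-robustness claim.

Invariance measurements: 90° rotations are lossless, so keypoints of
the rotated image are mapped back and matched within 1.5 px and one
scale interval; descriptor agreement is the fraction of matches with
cosine ≥ 0.9.  (Exact count equality is not expected: octave
downsampling keeps even-indexed pixels, and a 90° rotation shifts that
parity at coarse octaves.)  Scale robustness is the fraction of
keypoints recovered after 2× downscaling within 2 px and one interval —
restricted to keypoints whose halved scale remains inside the
pyramid's detectable band (`σ/2 ≥ σ₀√k`); finer keypoints fall below
the base of the scale space after halving and are unrecoverable by
construction for any detector on the same pyramid, so including them
would measure pyramid coverage rather than detector repeatability.

## Numerical choices and degenerate inputs

- Localization caps at 5 re-centering iterations; non-convergence
  rejects the candidate.  Singularity is declared at |det H| < 1e-30.
- Empty descriptor sets (featureless images) raise immediately at
  encoding time with the offending image identified.
- The k-means codebook requires at least k descriptors (error naming
  both counts).  Classes with fewer than 2 training examples are
  rejected by name.
- Histogram sums are exact to 1e-9; kernel Gram matrices are symmetric
  PSD up to −1e-8 in the smallest eigenvalue.
- Model archives store the exact training histograms, labels, kernel
  specification and seeds; loading refits the (deterministic) SVM, so a
  round-tripped model predicts identically to the original.

## Known limitations

- The descriptor samples a fixed 16×16 grid rather than every pixel of
  the scaled window; at very large keypoint scales this slightly
  undersamples the window relative to the classic formulation.
- RBF at γ = 0.004 is a weak configuration on L1-normalized histograms
  (see above); it is retained as the documented operating default and
  for kernel comparisons.
- The synthetic classes are a mechanics-and-invariance testbed, not a
  histological simulation; accuracy numbers on them do not transfer to
  real slide collections.
- Whole-slide formats, stain normalization, dense/affine SIFT variants
  and GPU execution are out of scope.
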