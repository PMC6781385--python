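# Methods

## The descriptor

A closed contour resampled to N uniformly spaced points is represented by
its normalized slope signal ẑ[n] = Δz[n]/‖Δz[n]‖ — the unit tangent
direction at each step — and its discrete Fourier transform
Z[k] = (1/N) Σ ẑ[n] e^(−j2πkn/N).  Working on slopes rather than
coordinates has three consequences that the tests pin down exactly:

* translation cancels in the differencing, and scale cancels in the
  normalization (given uniform resampling);
* rotation by θ multiplies every coefficient by e^(jθ) and a start-point
  shift by n₀ multiplies Z[k] by a pure phase, so coefficient magnitudes
  are invariant to both;
* because ‖ẑ[n]‖ = 1, the full spectrum always satisfies Σ|Z[k]|² = 1 —
  energy fractions are comparable across leaves with no extra
  normalization.

Slopes are computed with wraparound (N slopes for N points) so that a
closed polygon has a slope sum of exactly zero and Z[0] ≈ 0; the retained
band therefore excludes k = 0.  "22 harmonics" is read as the symmetric
signed band k ∈ {±1…±11}: the slope signal is complex, so negative
frequencies carry independent information.  A one-sided band {1…22} is
available as a configuration for comparison.

Reconstruction zero-fills the non-retained harmonics, inverts the
transform, renormalizes the slopes to unit modulus (truncation breaks it,
renormalization restores the arc-length reading), and integrates from the
stored start point.  Reconstruction error is reported as
100·RMS(‖p′−p‖)/R with R the centroid RMS radius of the original
contour — a scale-free percentage.

An optional canonical phase alignment (arg Z[±1] = π/2) removes the
rotation gauge and, up to a half-circuit ambiguity, the start-point
gauge.  It is off by default: the synthetic generator (like curated leaf
scans) produces consistently oriented contours that start at the blade
base, so phases are already comparable across samples.

## Morphospace and whitening

The q retained harmonics of n samples form Φ ∈ C^(q×n).  The default
embedding stacks real and imaginary parts (2q real features), centers
per feature, and takes the top d = 3 SVD components — a lossless,
invertible treatment of complex data that standard outline morphometrics
uses, and the one the axis-shape visualizations need (they map axis
points back to harmonic vectors and reconstruct contours).  A literal
complex-covariance mode (eigendecomposition of Φ̂Φ̂ᴴ/(n−1), real parts of
the complex scores) is kept for comparison but is not invertible.
Covariance uses the 1/(n−1) convention; the scale cancels in whitening.
Eigen-spectra are validated against dense eigensolver oracles, and
degenerate trailing directions yield zero eigenvalues and zero scores
rather than errors (rank-deficient collections are legitimate inputs).

Whitening is per-dimension standardization with the sample SD (n−1);
the transform is stored and inverted by the interpretability artifacts.

## Category discovery

Clusters are basins of attraction of a kernel density estimate.  The
adaptive variant assigns each sample the bandwidth
h_i = (1/k) Σ_{t=1}^{k} ‖u_i − u_i^{(t)}‖ over its k = 8 nearest
neighbors (sample-point estimator: each datum contributes with its own
h_i, weighted by h_i^{−(d+2)} in the shifted mean).  Defaults: Gaussian
kernel (a flat kernel is kept for hand-checkable fixtures), convergence
tolerance 1e−5 in whitened units, 300 iterations maximum, and converged
points merged into one mode when closer than min(h_i)/2.  The k = 8
default follows the source method's calibration on its six-species
reference set; it is a default, not a universal constant.  The
fixed-bandwidth variant defaults to the median of the h_i.  Clustering
contains no randomness: results are a deterministic function of the
input order, and a label-permutation test guards that the partition is
order-independent.

The sphere-overlap view assigns each sample a sphere of radius
ε_i = h_i/2; spheres that intersect (‖u_i−u_j‖ ≤ ε_i+ε_j) join into
connected components.  On well-separated data this reproduces the
mean-shift partition; on overlapping data it is a visualization aid, not
the clustering.  Prototypes are the members nearest their cluster
centroid (ties to the lowest index).

Evaluation uses the pairwise co-clustering F-measure by default
(precision/recall over all unordered sample pairs), with a weighted
best-match variant available; every report names the variant.  The
leave-one-out scheme re-runs the full embed → whiten → cluster chain n
times on n−1 samples — a deliberate choice of full re-clustering over
held-out projection.

## The synthetic generator

The generator emulates curated leaf datasets: six (blade family, margin
type) classes with 20–30 samples per class.  A blade is a width-profile
body: half-width w(t) along the main axis, mirrored about it.  Elliptic,
ovate and obovate blades share a sqrt-rounded base profile
2·√(t(1−t)) modulated by a smooth linear skew that moves the maximal
width toward the base (ovate) or apex (obovate) without sharpening
either tip; oblong blades use a superellipse (exponent 4) with flat
sides.  Rounded tips matter: a pointed tip is a tangent discontinuity
whose slope spectrum decays too slowly for a 22-harmonic budget, which
real entire leaves do not exhibit.

Margins are periodic modulations along the outward normal, with
amplitude proportional to the local half-width so teeth shrink toward
apex and base.  The waveforms are short Fourier series with unit
fundamental — crenate: sin θ (broad rounded lobes, 4–7 per circuit);
serrate: sin θ + 0.2 sin 2θ (many fine forward-leaning teeth, 7–10);
dentate: sin θ − sin 3θ/9 (intermediate outward teeth, 5–8).  Smooth
band-limited teeth are deliberate: real teeth are rounded, and the
margin must be representable inside the ±11 harmonic band for the
descriptor to be a faithful code (a discontinuous sawtooth would place
most of its energy outside any fixed band).  Serration amplitudes are
small fractions of the half-width (0.02–0.05) and crenation amplitudes
larger (0.04–0.08), matching their botanical appearance.

Within-class variation perturbs aspect ratio (6% relative), asymmetry
(±0.04), margin amplitude (12% relative) and adds per-vertex radial
noise (0.4% of blade length).  Teeth count is class-characteristic and
not perturbed by default: the descriptor is a line spectrum, and a ±1
change in integer teeth count relocates the margin's spectral lines to
neighboring harmonics — a gross change in descriptor space that no
linear embedding absorbs.  This is a genuine sensitivity of the
representation (the source method's hardest errors also involve
serration frequency content), not an artifact of the generator.

What the generator does **not** emulate: photographic texture, venation
and lighting; petioles (the descriptor treats whole closed outlines, and
a petiole only adds high-frequency content); broadband, irregular tooth
profiles.  Passing tests on synthetic data therefore demonstrate the
pipeline's correctness and its behavior under controlled factor
variation — not performance on any particular photographic dataset.

### Limitation: the margin-severity axis

On real leaf collections the first principal axis tends to order samples
from strongly serrated to entire, because natural serrations are
broadband and share harmonic support across species.  Periodic synthetic
teeth with distinct class-characteristic counts instead occupy mutually
orthogonal spectral lines, so the between-class margin scatter is a sum
of orthogonal rank-one directions: a principal axis aligns with one
margin class and places the others (and the entire class) near zero,
capping the rank correlation between any single axis and a margin
severity index around 0.5 on this generator.  The corresponding
interpretability assertion in the acceptance tests documents this gap
rather than papering over it.  The blade-shape axis does emerge exactly
as on real data: PC2 correlates with aspect ratio at |ρ| ≈ 0.9.

## Numerical choices

* Resampling: periodic cubic spline on cumulative chord length, followed
  by a fixed-point refinement that equalizes output chord lengths to
  ~1e−10 relative; a piecewise-linear mode exists for polygonal fixtures
  (a 4-knot spline overshoots at square corners — intrinsic to cubic
  interpolation, hence the dense-knot cross-mode test).
* Otsu's threshold is searched over a 256-bin histogram; the foreground
  is the side with higher mean saturation.  Saturation at black pixels
  is defined as 0.
* Boundary tracing is Moore-neighbor with Jacob's stopping criterion on
  the largest 8-connected component; output is canonically
  counter-clockwise in x-right/y-up coordinates (x = column,
  y = −row).
* Rasterization fills polygons by pixel-center sampling.  Round-trip
  fidelity (raster → extract within 2 px of the source contour) holds
  for geometry the raster can carry; sub-pixel jitter spikes and teeth
  below the 5-px closing element are legitimately lost.
* Problem sizes in the tests — 120-sample datasets, 60-contour fidelity
  fixtures, 150-point mixtures — are the generator's emulation of the
  evaluation designs the method targets (6 × 20–30 samples) and run the
  whole suite in well under a minute.
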