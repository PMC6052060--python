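# Methods

## Scope and model

`curvedcell` quantifies three things on closed, genus-0 triangulated cell
surfaces carrying a per-face fluorescence intensity: (i) how a
membrane-associated signal distributes with respect to local Gaussian
curvature, (ii) how uniform the cell's cylindrical body is, and (iii) how
changes in polymer-level features predict changes in that uniformity
across strains.  All coordinates are in μm, Gaussian curvature in μm⁻²,
polymer lengths in nm, and angles in degrees in [0, 90] relative to the
long cell axis.

## Discrete curvature

Gaussian curvature is estimated by the angle deficit: at each vertex,
K_v = (2π − Σ incident angles) / A_v with A_v the barycentric vertex area
(one third of the incident face area).  Face values are the mean of the
three vertex values.  This pairing is deliberate: with barycentric
weights, Σ_faces K_f·A_f telescopes to the total angle deficit, which is
exactly 4π on any closed genus-0 mesh, so the Gauss–Bonnet invariant used
throughout the tests holds to machine precision independent of mesh
quality.  Pointwise accuracy is the usual trade-off of deficit estimators:
mean absolute error on spheres falls roughly fourfold per mesh refinement,
while the worst single-face error decays slowly (it is dominated by
irregular-valence vertices); integrated and bin-averaged quantities — the
only ones the enrichment pipeline consumes — converge well.

## Enrichment profiles

Each cell is normalised by its own mean surface density I\* (total
intensity over total area) before any pooling, which makes the analysis
invariant to per-cell illumination and expression level.  The conditional
expectation E[I/I\* | K] per curvature bin is computed as the area-weighted
mean of I/I\* over the faces in that bin.  This is the limit of the
histogram/Bayes-rule formulation as the intensity bin width goes to zero;
we use the limit form because it preserves the law of total expectation
(Σ_K P(K)·E[I/I\*|K] = 1) exactly, whereas any finite intensity binning
would not.  The finite joint histogram is still available for inspection.
Defaults: curvature bins 0.25 μm⁻² wide spanning the pooled observed range
(a test checks halving the width moves profiles < 2%), 50 intensity bins
on [0, 4]·I\* with out-of-range faces assigned to edge bins.

The population profile is the **unweighted** mean across cells per bin
(cells are the statistical units; a bin a cell has no surface in is
absent, not zero, so the per-bin n varies), with SEM = SD/√n over the
contributing cells.  Smoothing uses a cubic smoothing spline weighted by
1/SEM² with its penalty chosen by generalized cross-validation; output is
reported only where the mean per-cell area probability of the bin exceeds
5·10⁻³, which removes curvatures so rare that the estimate is anecdotal.
The two scalar summaries (mean relative concentration below and above
2 μm⁻²) are computed per cell over the untruncated faces and then averaged
across cells, consistent with the per-cell-first convention of the
profile.

## Centerline and IDD

The centerline is the smoothed locus of cross-section centroids along the
first principal axis, computed in two passes: a first pass with planes
perpendicular to the principal axis yields centroids; smoothing splines
through them give local tangents; a second pass re-cuts perpendicular to
the local tangent, so bent rods report their true cross-sectional
diameter.  The diameter at a station is twice the length-weighted mean
distance of the section contour from its in-plane centroid.  Stations
within one median radius of either end are excluded — hemispherical caps
are not cylinder, and including them would dominate the variance.  Cells
with aspect ratio below 1.2 are flagged degenerate and measured on an
equatorial band only.

IDD is SD(diameter profile)/mean(diameter).  With a single (mean) diameter
per centerline position the per-position spread of repeated measurements
collapses, so this coefficient-of-variation form is the 3D estimator; it
is scale-invariant and insensitive to the sampling density (both tested).
Strain-level ΔIDD is the difference of unweighted per-cell means, with the
sign convention that positive means strain 1 is more irregular.

## Synthetic cells

The generator builds surfaces of revolution (rings plus pole fans) with
radius r(z) = r₀·(1 + a·sin(2πz/λ) + bumps), hemispherical caps matched to
the local end radius, and optional constant-curvature bending applied as a
rigid per-cross-section map.  Defaults mirror the measured organism:
r₀ = 0.5 μm, body length 3 μm (±20% per-cell jitter), target edge length
60 nm.  The sinusoidal mode gives a closed-form IDD of a/√2; the "bumpy"
irregular mode uses four equal-amplitude sinusoids with seeded random
wavelengths (0.8–2 μm) and phases, so the nominal radius CV equals the
requested RMS.  The wild-type-like and rodZ-deletion-like presets use
bump RMS 0.02 and 0.122, calibrated so their IDD difference is ≈ 0.1, the
published contrast between those strains; polymer counts are Poisson with
means 11.6 and 6.6 and exponential lengths with mean 315 nm, so the mean
of >200 nm polymers is ≈ 515 nm — the published per-strain values serve as
generator parameters, with recovery-from-simulation as the testable
property (the raw imaging data behind them is not reproducible here).

Painting draws I = g(K)·(1+η) per face with g normalised to an
area-weighted mean of exactly 1 per cell before the multiplicative noise η
(CV 0.2 by default).  The cytoplasmic (non-membrane) signal is carried as
a separate volumetric total; a membrane-fraction measurement integrates a
25 nm shell, capturing all surface signal plus the t·A/V slice of the
cytoplasm, so the painted fraction (e.g. 95% vs 90%) is recoverable to
±0.01.

Polymers are placed on the cylindrical body in the unwrapped (u, v) frame:
uniform positions, Gaussian angles (mean 80°, SD 15° — a choice, as no
distributional form is established for angles or counts; both are exposed
in the spec dataclasses), exponential lengths, axial clipping at the body
ends.  Rendering convolves each segment with an isotropic Gaussian PSF
(σ = 40 nm) in closed form (erf end-caps), so the image's half-maximum
axial crossing sits exactly at the true endpoints — the property the
segmentation's endpoint trim relies on, and the behaviour of a
diffraction-blurred filament image.

## Polymer segmentation

Images are thresholded at median + 5·1.4826·MAD (scale-invariant),
skeletonized, and short spur arms (< 6 px) pruned.  Component backbones
are the longest geodesic through the pixel graph (two Dijkstra sweeps),
which is robust to the dead-end walks and side bumps skeletonization
leaves.  Junctions split the skeleton into arms that are re-joined
pairwise by direction continuity (most antiparallel pairing, dot < −0.7),
so crossing filaments segment as two polymers.  Free ends are trimmed back
to half the streak's interior intensity (capped at 6 px); length is the
chord-resampled arc length (stride 5, suppressing the ~8% staircase bias
of 8-connected chains) plus a 3 px end correction for the residual
skeleton end erosion, times the pixel scale.  The error budget is 10% on
250–600 nm streaks at 15 nm/px; angles (intensity-weighted PCA, folded
into [0, 90]°) are accurate to a few degrees.  The azimuthal seam is
treated as non-periodic — a filament crossing it would be split — and
counts, not lengths, are reliable below ~150 nm; downstream stages
therefore also accept ground-truth polymer tables directly (the bypass
path), and population analyses support both paths.

## Thresholded-exponential length correction

Measured polymer lengths follow an exponential truncated at the 200 nm
detection floor.  By memorylessness, mean(L | L > θ) = θ + μ, so
μ̂ = mean(measurable) − 200 nm, and the measurable fraction is exp(−θ/μ)
(≈ 0.53 for μ = 315 nm; the observed fraction in the source data was
57–59%, and the package reports both without forcing agreement).  The
estimator is unbiased to < 2% at 10⁵ draws across μ = 150–500 nm.

## Shape model

The LASSO objective is (1/N)‖y − β₀ − Xβ‖₂² + λ‖β‖₁ with an unpenalised
intercept — the standard additive penalty (a subtracted penalty would be
unbounded).  Columns are scaled to unit variance without centering, so
swapping the strains of a comparison negates its row exactly; coefficients
are reported on both scales.  The solver is cyclic coordinate descent on
the Gram system with soft-thresholding (numba-accelerated when available;
pure numpy otherwise), verified in tests against ordinary least squares at
λ = 0, the closed-form soft threshold for one predictor, the KKT
conditions, and an independent implementation.  λ_max = 2·max|Xᵀỹ|/N zeroes
the solution exactly.  The λ grid is 100 log-spaced points over
[10⁻⁴·λ_max, λ_max], with the working values 0.02 and 0.022 inserted when
in range.

Cross-validation shuffles rows with a recorded seed and assigns contiguous
near-equal blocks; the CV curve is bit-reproducible given the seed, and
k = N reduces to leave-one-out.  The one-SE rule picks the largest λ whose
CV MSE is within one SEM (at the argmin) of the minimum.  Because
normalisation variants of one feature are strongly correlated and the
LASSO chooses among them unstably, the variant question is settled two
ways: the path solution at an elevated λ, and an exhaustive CV ranking of
every {number × length × enrichment} variant triple fitted by OLS,
including the check that the best triple beats every two-of-three plus any
single other column.  A leave-one-out diagnostic compares held-out to
in-sample MSE (with a numerical floor so exactly-interpolating fits on
noise-free data are not flagged).

The procedure is validated by simulation: comparison sets with 12 columns
in correlated families (within-family correlation 0.7), a true sparse
model using one variant from each of the three core families, N = 20 and
SNR ≈ 3 — conditions matching the real design's size.  The full procedure
recovers the true triple in ≥ 90% of 100 seeded replicates.

The bundled `table1.csv` carries the published 21 strain-pair comparisons
(20 training, 1 held-out test) with predicted and observed ΔIDD.
Recomputing the squared Pearson correlation from the printed 3-decimal
values gives 0.920 on the training rows (0.917 including the test row);
the published headline of 0.93 reflects the unrounded values, and the
0.92–0.93 band is the expected rounding loss.  r² is the square of the
Pearson correlation, not 1 − SSE/SST.

## What the synthetic data does and does not show

The generator produces the geometry, intensity statistics, and polymer
content the pipeline is designed to measure, with exact ground truth; it
does not emulate point-spread-function anisotropy, reconstruction error
from z-stacks, photobleaching, cell-cycle structure, or polymer dynamics.
Passing tests therefore demonstrate the estimators are correct and
well-calibrated on their stated model, not that the upstream 3D
reconstruction of real images is error-free (reconstruction from
experimental z-stacks is out of scope).  Per-strain published summary
statistics are generator inputs, not outputs; the testable claim is always
recovery of known truth from simulation.

## Problem sizes and numerical choices

Default test/script populations are 20–50 cells per strain at 60 nm mesh
resolution (~8,000 faces per cell) — sizes at which every sampling-error
bound in the tests has comfortable margin.  Degenerate inputs are handled
explicitly: open or non-manifold meshes are rejected naming the offending
edge; inconsistent winding is repaired once; near-spherical cells are
flagged and measured on an equatorial band; empty polymer sets, bins
without support, and cells with no faces beyond the curvature cutoff
propagate as absent (NaN) rather than zero.  All file indices are 0-based;
curvature bins are half-open [lo, hi); PLY is written with
double-precision vertices so meshes round-trip bit-identically.
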