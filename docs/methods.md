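# Methods

This note documents the models, estimators and numerical choices behind
`envmech`, and what the synthetic scenes do and do not emulate.

## Cell geometry and coordinate conventions

Cells are spherocylinders (capsules) of pole-to-pole length L and radius r
(L ≥ 2r), lying in the image plane. Image coordinates are row-major,
0-based, origin at the top-left pixel center, x along columns and y along
rows, values at pixel centers; all lengths are in nm except the
fluorescence module, which reports µm at its boundary. The axial cell
coordinate is the signed distance from the midpoint along the axis, poles
at ±L/2; axial binning uses the absolute value on [0, L/2] in half-open
bins (the last bin closes at the pole). Band areas are projected 2D
footprint areas — a rectangle slice in the cylindrical part plus circular
segments in the caps, both in closed form. Topography assumes the cell
rests on the substrate, so the surface height above it is
r + √(r² − d²) for axis distance d, with apex 2r.

## AFM image conditioning

Three levelling operators mirror standard AFM practice:

- **plane_level** fits a least-squares plane over background pixels and
  subtracts it everywhere. For large scans, pixels above
  median + 2 × robust SD (1.4826·MAD) are excluded from the fit so tall
  cells do not tilt the plane; the threshold is configurable.
- **align_rows** subtracts a per-row polynomial (order 0–2, default 2) fit
  on unmasked pixels; rows with fewer than order+1 usable pixels are left
  unchanged and logged.
- **flatten_base** iterates a plane-plus-row-offset background fit,
  reselecting background pixels within k·SD (default k = 1) of the current
  background. The scale is a robust SD (1.4826·MAD) over *all* unmasked
  residuals: a scale measured over the shrinking background set contracts
  geometrically on noise-only images and never converges, whereas the MAD
  over everything is stable against both protruding features and noise.
  Iteration stops when the background set stabilizes or its SD changes by
  <1% (max 10 iterations, then a logged warning). The symmetric ±k·SD cut
  keeps the background fit unbiased under Gaussian noise while excluding
  both protrusions and deep defects.

Smoothing is a normalized Gaussian kernel (sigma in pixels, reflective
boundaries). Of the conditioning operators, the levelling steps are
projections and hence idempotent (exactly for plane_level without the
high-pixel mask and for align_rows; to ~1% in RMS for flatten_base, whose
background reselection is data-dependent); smoothing is a linear filter
and deliberately not idempotent.

**RMS roughness** is measured on a crop after 2nd-order row alignment, as
the root mean square deviation from the crop mean. It is invariant to
constants and to any per-row quadratic contamination. Profiles use
bilinear interpolation (exact on linear fields); `feature_protrusion`
reports the profile maximum minus the median of the profile outside a
window around that maximum. Feature-height readouts are taken on
conditioned images (flatten base → 2nd-order row alignment → 1-pixel
Gaussian), over short profiles (±40 nm) centred on the feature: on longer
profiles the maximum is increasingly captured by corrugation rather than
the feature, biasing the readout upward.

## Corrugation model and amplitude calibration

Membrane corrugation is an isotropic Gaussian random field with Gaussian
spectrum, covariance exp(−d²/(2ℓ²)) with correlation length ℓ = 30 nm by
default, generated by Gaussian-filtering white noise (wrap-around
boundaries for stationarity) and normalizing the sample RMS.

The roughness a practitioner reports is protocol-defined: a 2nd-order
per-row polynomial fit removes a substantial, analytically computable
fraction of a smooth field's variance (for row covariance C and the
rank-3 polynomial projector P, the removed fraction is tr(PC)/tr(C); ~29%
for ℓ = 30 nm on a 500 nm row at 2 nm/px). The generator therefore
calibrates the corrugation amplitude so that the *standard measurement
protocol* reports the stated RMS in expectation (`calibration=
"conditioned"`, the default, using the closed-form retention factor
√(1 − tr(PC)/tr(C)) for the rendered row length); `calibration="raw"`
instead makes the field's own sample RMS equal the stated value. The
disruption presets encode measured roughnesses of 1.6 nm (pre) and 3.1 nm
(post), so they use the conditioned calibration.

## MAC rendering

MAC pores are rendered as annular (crater-shaped) protrusions: a Gaussian
ring of radial width σ_ring whose crest reaches exactly the rim height
(default 3 nm) at radius r_outer/2 − 1.5σ_ring, with outer diameter 22 nm.
σ_ring defaults to 3.5 nm — the *apparent* crest width, i.e. the
structural rim broadened by the finite AFM tip, which keeps the rendered
feature resolvable by the 1-pixel smoothing of the standard conditioning
chain at the 1 nm/px magnification of the membrane-patch preset. Larger
outer-membrane defects are smooth-edged (tanh) circular depressions,
default depth 4 nm (a membrane-thickness scale; the depth is a modelling
choice, widths 50–150 nm), recorded in a boolean defect mask. Scanline
artifacts add independent per-row quadratic offsets with configurable
amplitudes. All random draws derive from the scene seed; identical truth
and seed re-render bit-identically.

## Spatial statistics

The random-deposition null is exact-count CSR: each replicate draws the
observed number of points uniformly over the same region. g(r) uses ordered
pair counts per annulus divided by the CSR expectation
λ·Σᵢ area(annulus(pᵢ) ∩ region); the per-point annulus∩region areas are
evaluated by radial–angular quadrature of vectorized point-in-region tests
(4 sub-radii × 64 angles per bin by default), which is orders of magnitude
faster than polygon clipping and converges to the same areas. This
normalization makes the estimator integral-consistent: Σ g_k · expected_k
recovers the total pair count identically.

Nearest-neighbour distances use a k-d tree; an optional toroidal metric
supports comparison with the unbounded-Poisson closed form
E[d_NN] = 1/(2√λ). Chain analysis rasterizes points (default 10 nm/px),
dilates by a disk (default radius 25 nm, MAC scale), skeletonizes, and
reports per connected component the geodesic diameter of the skeleton
(8-connected, diagonal steps √2, double-sweep Dijkstra batched over
components). Isolated points give lengths near zero; results are invariant
to translation and 90° rotation up to rasterization tolerance.

`csr_compare` places each scalar statistic (mean NN distance, mean g at
small r, longest chain) within the null distribution with two-sided
empirical p-values using the (r+1)/(m+1) correction — exact under
exchangeability, so its type-I error is calibrated by construction, which
the 500-trial calibration test verifies end-to-end. Axial-bin counts are
tested against area-proportional expectation by χ² with n_bins − 1 df. The
study protocol's 5 replicates are the default; calibration uses 99.

## Force-curve processing and the Hertz fit

Approach curves are ordered far→near. The baseline is the mean force over
the far 10% of samples. Contact detection finds the first run of 5
samples exceeding 3× the baseline-tail SD, then walks back to the last
non-positive force sample: the raw threshold crossing is systematically
late by the distance at which the Hertz force reaches 3σ (≈12 nm at
50 kPa with a 10 pN noise floor), and the walk-back removes most of that
bias. Indentation is δ = contact_z − (z + F/k), which gives δ ≡ 0 on a
rigid surface and δ tracking the piezo at zero force.

The Hertz model F = (4/3)·E/(1−ν²)·√R·δ^{3/2} (ν = 0.5, R_tip = 65 nm —
the large-tip regime that senses overall surface mechanics rather than
individual pores) is linear in amplitude after the δ^{3/2} transform, so
the amplitude is solved in closed form over 0 < δ ≤ 200 nm. The contact
offset is refined within ±20 nm by minimizing the residual of a piecewise
model (zero force above contact, Hertz below) over a window extending one
refine-range above the detected contact: the near-contact samples
constrain the offset, while feasibility requires ≥10 samples below the
*detected* contact so that a rigid rise of 2–3 samples cannot be rescued
by shifting the contact into free air (a 5 nm margin absorbs detection
jitter). With the acquisition defaults (0.2 nN setpoint, 1200 nm ramp,
1024 samples/curve, k = 0.08 N/m, 10 pN noise) the estimator is median-
unbiased to <1% over E ∈ [20, 300] kPa with ~3–5% median relative error.
The ramp is simulated at 1024 samples because the setpoint terminates
contact after only δ_max + F/k nm of travel (≈16 nm at 300 kPa): coarser
sampling leaves too few in-contact samples to fit stiff surfaces at all.

QI maps run the chain per pixel. The substrate reference is a plane fit
through the lowest-quartile contact points; un-indented height is contact
minus that plane. A per-pixel quality gate discards fits whose residual
RMS exceeds 3× the curve's noise floor — a Hertz curve cannot reproduce a
cantilever-slope (rigid) rise, so such pixels are reported as having no
compliant contact rather than a spurious modulus. Failed pixels are
flagged, never interpolated; >50% failures abort the map.

Cell height per frame is read from profiles through the apex (row and
column lines; the one with the larger height contrast crosses the cell
transversally), background = median of the profile tails. Swelling and
stiffening are end/start ratios (configurable window); plateau detection
is an exhaustive two-segment piecewise-linear fit of E(t), declaring a
plateau when the post-breakpoint slope is within 10% of zero relative to
the pre-breakpoint slope (a globally flat series reports a plateau from
frame 0).

The time-series generator ramps the cell radius to (1+f)×initial and E to
E_end linearly up to the permeation frame, then holds both (the "dying"
preset: f = 0.07, the midpoint of the observed 5–10% band, E 100→150 kPa,
SYTOX positive from the permeation frame; "melittin": f = 0, flat E —
death without mechanical destabilization). Only the radius swells; the
length is held, since the height readout is the transverse diameter.

## Fluorescence morphometrics

Populations are non-overlapping capsules (pairwise capsule–capsule
clearance enforced; bounded retries, then an error reporting the placed
count) with widths drawn from the preset normal (1.17 µm untreated,
1.24 µm treated, SD 0.08 µm), lengths uniform on 2–4 µm, random
orientations. The membrane channel is the anti-aliased footprint blurred
with a Gaussian PSF (σ = 90 nm at 65 nm/px); the SYTOX channel adds the
per-cell intensity level (bimodal: 20 vs 400 AU) with Poisson shot noise
and Gaussian read noise over a 100 AU background.

Segmentation: Otsu threshold on the smoothed membrane channel, hole
filling, minimum-area filter, connected components. Because the rendered
edge is a symmetric blurred step, the mid-level threshold lands near the
true boundary. Width is the medial-axis distance-transform diameter:
2·EDT − 0.5 px, median over skeleton pixels with the polar 15% excluded
(ordered by the skeleton's principal axis). The −0.5 px term corrects two
half-pixel quantizations — the EDT measures to background pixel *centers*,
and the skeleton of an even-pixel-width rod sits half a pixel off the true
axis — making the diameter parity-unbiased (residual per-cell error
±0.5 px averages out over a population; measured population bias ≈ 3 nm).
Border-touching cells are excluded and logged; merged objects are flagged
by low solidity or implausible length, not silently split.

SYTOX calls: per-cell background-subtracted means, thresholded by an
*exact* two-class variance split (Otsu evaluated over all splits of the
sorted means rather than a binned histogram, which can bury a small
positive minority inside the dense negative mode); near-unimodal
populations are called collectively against the background noise scale.
Group comparison is Welch's unequal-variance two-tailed t test
(Satterthwaite df) via scipy, with the zero-variance-equal-means
degenerate case returning p = 1; both mean and median widths are reported
because both summaries are in common use.

## Workflow and reproducibility

Runs are YAML configs validated by an explicit schema check (scenario,
integer master seed, known stages, output directory). Per-stage seeds are
SHA-256 hashes of (master seed, stage index, stage name) reduced mod 2³¹;
no stage reads entropy elsewhere, so identical configs reproduce identical
artifact hashes, which the manifest records (SHA-256 per file). A stage
failure aborts with a partial manifest. The report renders manifests
section by section and degrades gracefully when stages or artifacts are
missing.

## Problem sizes

Defaults are chosen so a full demo run and the complete validation suite
execute on a single CPU in minutes: corrugation patches 500×500 nm at
2 nm/px (20 seeds per roughness estimate), membrane patches 300×300 nm at
1 nm/px, QI maps 12×12–32×32 pixels with 1024-sample curves, time series
of 10 frames, fluorescence fields of 2048×2048 px (133×133 µm) holding the
full 221/373-cell populations, and 500-trial × 99-replicate CSR
calibration with a lightened (but estimator-identical) g(r) quadrature.

## What the synthetic scenes do not emulate

The generator reproduces the *statistical structure* the analysis assumes,
not the physics behind it: no turgor or shell mechanics (swelling is
prescribed, not simulated), no MAC assembly kinetics or defect
propagation dynamics, no tip–sample convolution beyond the broadened rim
width, no adhesion or viscoelastic retract branch, no imaging feedback
artifacts (parachuting, creep), no optical PSF beyond a Gaussian, and no
cell curvature in the membrane-patch preset (high-magnification scans are
locally flat). Passing tests therefore demonstrate that the estimators
recover known inputs under realistic noise — not that real cells satisfy
the generative assumptions.

## Known limitations

- The flatten-base background model is a plane plus row offsets; strongly
  curved substrates would need a higher-order background.
- g(r) edge-correction quadrature is numerically, not analytically, exact;
  with the defaults the integral-consistency error is <1%.
- The contact-point walk-back assumes a noise-dominated zero-force line;
  long-range attractive forces (not modelled) would bias it.
- Width measurement assumes rod-shaped, mostly straight cells; strongly
  bent cells bias the medial-axis median and are only caught by the
  merged-object heuristic when solidity drops.
- The E of substrate-adjacent pixels mixes cell and support mechanics at
  the footprint edge; the cell-pixel mask for the series statistic uses a
  50%-of-apex height cut to avoid it.
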