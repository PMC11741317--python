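# Methods

`flowvasc` quantifies how endothelial cells respond to fluid shear
stress, at four levels: single-cell polarity in flow-exposed monolayers,
migration under flow, cell-population redistribution along the
vein–artery axis of the postnatal retina, and vessel regression during
plexus remodelling.  A synthetic-data module generates inputs with the
statistical structure each analysis assumes, so the whole pipeline is
testable without microscopy data.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Coordinate and angle conventions

Images use raster coordinates (x = column increasing right, y = row
increasing down).  A displacement `(dx, dy)` maps to the angle
`atan2(-dy, dx)`, i.e. the mathematical counter-clockwise convention
with 0 pointing along +x; rose diagrams therefore read like compass
plots.  All positions are converted to micrometres at read time.  The
flow direction is a unit vector in image coordinates; the default
`(1, 0)` means flow towards +x, so polarization *against* flow is an
angle near π and migration against flow is a negative parallel
velocity.  The sign convention (`positive v_par = with flow`) is
declared in output metadata because plots in the literature rarely
state it.

## Polarity and morphology

Each cell's front–rear axis is the vector from its nucleus centroid to
the intensity-weighted centroid of the Golgi channel within the cell
but outside the nucleus.  Intensity weighting makes the readout robust
to a fragmented Golgi without introducing a largest-fragment parameter.

Collective polarization of n angles θᵢ is summarised by
`C = mean cos θᵢ`, `S = mean sin θᵢ`:

* polarity index `PI = √(C² + S²)` ∈ [0, 1] — the mean resultant
  length; 1 means perfect alignment, 0 a uniform or symmetric
  distribution.  For a von Mises(μ, κ) population its expectation is
  the Bessel ratio I₁(κ)/I₀(κ), which the tests use as an independent
  oracle.
* signed polarity index (V-score) `V = mean cos(θᵢ − ref)` ∈ [−1, 1]
  relative to a reference direction.  The sources describing the
  V-score state only its range and meaning; the mean cosine is the
  unique smooth statistic on [−1, 1] consistent with "strength of
  polarization with respect to an assumed direction" and satisfies
  |V| ≤ PI algebraically (V = PI·cos(mean − ref)).

Orientation is axial: angles are doubled, statistics computed, and the
mean direction halved, so θ and θ + π are identified and the
orientation V-score maps flow-parallel → +1, perpendicular → −1.
Cells with elongation < 1.05 are excluded from orientation statistics
(near-isotropic orientation is numerical noise).  Orientation V-scores
are reported per image, because the image is the unit of comparison in
group statistics; pooled summaries are also available.

Shape features come from the second central moments of a cell's pixel
set with a 1/12 unit-square variance per pixel, so an axis-aligned
N×M rectangle has elongation exactly N/M.  Area is pixel count ×
pixel area.  Border-touching cells are flagged and excluded from shape
statistics but kept for nuclear/cytosolic intensity ratios, which are
insensitive to truncation.

## Migration under flow

Velocities are forward differences at the native 7.5-min frame
interval, with no smoothing (none is described for the assay this
emulates); gaps in a track divide by the actual time step.  Each step
velocity v is decomposed against the unit flow vector û:
`v_par = v·û`, `v_perp = √(speed² − v_par²)`.

Population curves average steps within each replicate and 1-h time
bin, then across replicates — the replicate (independent experiment)
is the unit of analysis, matching the n = 4 design — with 95% CIs from
bootstrapping replicates.  Whether to average within tracks first is
ambiguous in descriptions of such assays; both orders are implemented
and step-pooling within replicate is the default.  Tracks shorter than
10 frames are excluded: the threshold is not dictated by the assay but
short spurious tracks otherwise dominate step counts.

Trajectory ensembles follow the published design: 100 tracks resampled
with replacement per replicate, 4 replicates → 400 trajectories,
clipped to a time window (default the first 5 h), start-normalized to
(0, 0), and coloured by mean parallel velocity.

Mosaic (two-population) experiments require both dye channels in every
replicate; the contrast of replicate-wise time-averaged v_par and
speed between populations is estimated by bootstrap (below).

## Retina vein–artery coordinate analysis

For every labelled pixel, three numbers are computed from drawn masks:
Euclidean distance to the nearest vein (d_v), to the nearest artery
(d_a) — both via exact Euclidean distance transforms — and the radial
distance d_r to the optic-nerve centre (mask centroid if a mask is
supplied; a single point otherwise).  The relative arteriovenous
coordinate is φ = d_v/(d_v + d_a): 0 on veins, 1 on arteries, and
swapping the masks maps φ → 1 − φ identically.

Per retina, 5000 labelled ROI pixels are sampled without replacement
(the assay this emulates samples "x" pixels without stating x; 5000
resolves the distribution finely at typical retina sizes while keeping
per-retina variance low).  The (φ, d_r) distribution is summarised by:

* a 2D Gaussian KDE, implemented as a binned estimate (100×100 grid)
  smoothed with a Gaussian filter whose boundary mode reflects mass at
  the domain edges — φ = 0 and φ = 1 are hard anatomical boundaries
  and plain KDEs leak mass past them.  Bandwidths follow Scott's rule
  per axis (σ·n^(−1/6)), floored at one grid cell; the filter
  conserves mass, so the Riemann sum is 1.
* density histograms over φ, for the whole mount and for the
  remodelling plexus.  The plexus band is a configurable radial
  annulus, default 0.4–0.8 of the maximum radius; its bounds are an
  anatomical judgement call, not a published number.
* the arterial 90th percentile of φ per retina (linear-interpolation
  quantiles, declared in outputs), the scalar used for group
  comparisons of arterial accumulation.  Radial distance is kept in
  absolute µm; normalization to the sprouting front is an optional
  caller-side rescaling.

## Vessel regression

Both channels (CD31 = endothelium, ColIV = basement membrane) are
binary masks, 2D or 3D; segmentation is upstream.  Each channel is
skeletonized (medial axis, topology-preserving) and branching points
are skeleton voxels with ≥ 3 skeleton neighbours (8-/26-connectivity),
adjacent qualifying voxels merged into one point.

Candidate regression regions are ColIV voxels outside the CD31 mask
dilated by one voxel; the dilation absorbs ~1 px registration slack
between channels and suppresses sliver false positives.  Candidates
whose ColIV-skeleton footprint is below 5 voxels are discarded (human
scoring implies a visibility threshold; the value is configurable).
Stage assignment uses the raw (undilated) CD31 coverage of the
enclosing ColIV skeleton segment — the skeleton run between two
branch-point clusters:

* coverage 0, segment on an endothelialized network → **final**;
* coverage in (0, 0.5] → **intermediate** (the 50% boundary makes the
  qualitative "partial absence" operational);
* coverage 0 on a ColIV connected component that carries no CD31
  anywhere → **long-regressed** (an orphaned basement-membrane
  fragment);
* coverage above 50% → a staining gap, not an event.

Raw rather than dilated CD31 is used for coverage because the dilated
mask always reaches one voxel into a fully erased segment and would
misclassify final events as intermediate.

Headline statistics: regression frequency = 100 × events / CD31
branching points; CD31/ColIV ratios of branching-point density and
vessel density, normalized to the ROI volume ratio.  The normalization
multiplies the density ratio by ROI_CD31/ROI_ColIV, which cancels the
volume factors — identical channels quantified in different ROIs give
ratios of exactly 1.

## Estimation statistics

Group comparisons are estimation-first.  The bootstrap mean difference
resamples each group with replacement (default 5000 replicates,
seeded) and reports the observed difference `mean(a) − mean(b)` with a
percentile 95% CI; the percentile interval is the simplest seed-stable
choice where the CI flavour is otherwise unspecified, and BCa adds a
dependency on jackknife acceleration without changing any conclusion
at these group sizes.  Welch, Student and Mann-Whitney tests are thin
wrappers reported alongside.  The caller declares the unit of analysis
(image, replicate, animal); nothing here pools across units.

## Synthetic data: what it emulates and what it does not

* **Monolayer**: cells on a jittered hexagonal grid (deterministic
  density, no overlap-rejection failures), one disc nucleus and one
  Golgi locus per cell, polarity angles von Mises(μ, κ), marker
  channels realizing a set nuclear/cytosolic ratio plus optional
  Gaussian noise.  Defaults (400 cells, 25 µm spacing, μ = π, κ = 2,
  ratio 2) model a confluent monolayer moderately polarized against
  flow.  Not emulated: real cell shapes, junction geometry, PSF/noise
  statistics, segmentation errors — recovery tests show the estimators
  are correct on clean labels, not that segmentation is easy.
* **Tracks**: drift-diffusion, x(t+Δ) = x(t) + vΔ + N(0, 2DΔ) per
  axis; 48 h at 7.5 min by default, D = 15 µm²/h giving realistic
  ~20 µm/h instantaneous speeds.  No cell–cell interactions,
  persistence, or track-linking errors.
* **Retina**: alternating vein/artery rays from the optic nerve to the
  rim, labelled cells placed by the angular-fraction approximation
  within a sector (azimuth = vein angle + φ·sector width).  Because
  the Euclidean distance field of finite rays is not the angular
  fraction exactly, recovery of φ is assessed by rank correlation, not
  value equality; point masses at φ ∈ {0, 1} are snapped onto the ray
  masks so boundary identities hold exactly.  Real retinas have curved
  vessels, sprouting fronts and nonuniform plexus density.
* **Vessel fixture**: a square lattice (6×6 nodes, 40 px spacing,
  radius 2 px) as ColIV; CD31 equals ColIV except planted events —
  final = edge interior fully erased, intermediate = central half
  erased.  Planted edges are node-disjoint and connect branch-point
  nodes (corner nodes have degree 2 and are mere bends of a skeleton
  segment, which would dilute the coverage statistic).  The analytic
  branching-point count of an n×m lattice, (n−2)(m−2) + 2(n−2) +
  2(m−2), is emitted as ground truth.

Same seed → bit-identical outputs; downstream tests consume only the
generated rasters and tables, never the ground truth.

## Problem sizes and numerical notes

The test suite and the acceptance script run at desk scale: 5000-cell
monolayers for polarity recovery, 200 tracks per drift setting,
2000-cell retinas, 20 seeded vessel fixtures, 200 Monte-Carlo
repetitions for CI coverage — sizes at which the sampling error of
each check is several times smaller than its tolerance.  Degenerate
inputs fail loudly: empty masks, zero-variance KDE samples, empty
radial bands, single-point tracks, non-unit flow vectors.  Report CSVs
round-trip float64 exactly (repr on write, round-trip parsing on
read).

## Known limitations

* The V-score formula is fixed as the mean cosine; if an upstream
  toolbox defines it differently the numbers may differ even though
  range and interpretation match.
* Regression staging on maximum projections can merge events that are
  distinct in 3D; both 2D and 3D masks are accepted, but the synthetic
  fixtures are 2D.
* The retina generator's angular-fraction placement makes value-exact
  φ recovery impossible by construction; rank-based checks are the
  honest alternative.
* KDE boundary reflection is also applied at the radial extremes,
  which slightly flattens density at r = 0 and r = r_max.
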