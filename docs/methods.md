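# Methods

This note documents the models and procedures `volgrid` implements, the
choices made where the method left room, and what the synthetic-data
tests do and do not establish about real recordings.

## Coordinate and unit conventions

Positions in centimetres, times in seconds, rates in Hz. The spatial
origin is the environment's minimum corner with z up. Volumetric arrays
are indexed `[ix, iy, iz]`; voxel intervals are half-open; the lag-space
origin of an autocorrelation sits at the (odd-sided) array centre. A
plane through a volume is parametrised by the pitch of its tilt from
horizontal (0–90°) and the compass azimuth of that tilt (0–360°); with
pitch measured from horizontal every unoriented central plane appears
exactly once on this grid (tilting toward azimuth φ and φ+180° are
different planes, which is why the azimuth range must span the full
circle).

## Synthetic recordings

The generator provides the three ingredients of a session: a field
arrangement, a trajectory, and spikes.

**Arrangements.** Hexagonal layers have in-plane nearest-neighbour
distance S (drawn per cell from U[200, 600] mm in reference
simulations): points every S along x, rows √3·S/2 apart, alternate rows
offset S/2. Close-packed stacks place layers (√6/3)·S ≈ 0.816·S apart:
HCP alternates lateral offsets {0, +√3S/3} (ABA), FCC cycles
{0, +√3S/3, −√3S/3} (ABC; −√3S/3 ≡ +2√3S/3 modulo the lattice, giving
three distinct arrangements with period three). Columnar arrangements
repeat one layer at a fine z-step (S/25, within 1.5% of exact columns);
random arrangements draw as many uniform points as the matching HCP
contains. The rate volume is g(x) = exp(−½(x/σ)²) of the distance to
the nearest point with σ = 2 voxels. The bounding box is the 0.97 m
lattice maze scaled to the spacing (0.97 m at S = 400 mm), rendered at
41³ voxels, so arrangements of any S contain the same number of spatial
periods as the recorded maze did at its modal spacing; because σ is
fixed in voxels, the field-width-to-spacing ratio (≈0.12) matches
2.5 cm-voxel adaptive maps of a real-size maze at S = 400 mm. Requested rotations are
applied to the field points themselves (regenerated on a doubled box,
turned about the volume centre, cropped), so rotated volumes are sampled
exactly rather than resampled — the planar-symmetry rings read
few-degree-wide correlation peaks that trilinear resampling of the
volume visibly erodes.

**Trajectories.** Lattice sessions walk continuously along the
axis-aligned bars of a 6×6×6 climbing lattice (16.2 cm bar pitch at full
size), choosing the next bar with a horizontal-movement bias (default
weight 3) and a bottom-layer dwell bias (default 2) and avoiding
immediate backtracking; speeds jitter around 10 cm/s. These defaults
produce the qualitative coverage anisotropy of real rats (floor-heavy
dwell, horizontal-dominated headings) without claiming biomechanical
realism. Arena sessions are planar reflected random walks in the
1.2 m × 1.2 m open field; a free-volume walk is provided for
dense-coverage testing. No tracking noise is added: the analysis chain
is exercised on clean kinematics, and tests say nothing about tracking
artefacts.

**Spikes.** Inhomogeneous Poisson: the expected count in each tracking
interval is gain × map value at the position × dt, spike times uniform
within the interval.

Stochastic operations take explicit seeds; `subseed(master, *labels)`
derives stable per-operation seeds (SHA-256 of the label tuple, < 2³¹).

## Rate maps

The adaptive estimator expands a sphere around every 2.5 cm voxel in
1-voxel steps until r > α/(n√s) with α = 1600, n occupancy samples and
s ≥ 1 spikes inside (sphere membership by voxel-centre distance, clipped
at the volume boundary); the rate is (s/n) × 25 Hz. Voxels whose sphere
reaches half the volume diagonal without meeting the criterion keep rate
0. Periods below 5 cm/s are removed before any map. Histogram maps bin
dwell seconds and spikes and divide after smoothing both with the same
Gaussian (10 cm voxels / 2.5-bin σ for volumetric stability maps,
2.5 cm / 1-bin for planar maps, 2 cm / 2-voxel for information maps);
the visited mask is the pre-smoothing dwell support. Projections
collapse one axis by occupancy-weighted averaging over visited voxels.

Field detection operates on the full adaptive rate volume, not just
directly occupied voxels: adaptive binning deliberately assigns rates
wherever its sampling criterion is met, and masking by raw occupancy
fragments every field at realistic coverage. The trajectory-based
criteria (more than five visits, a visit being a maximal run of
in-field samples with ≥1 s gaps separating visits) remove the
extrapolation artefacts this can admit far from data.

## Autocorrelation statistics

r(τ) is the Pearson correlation between the map and its τ-shifted copy
over mutually visited voxels, computed exactly via six FFT
cross-correlations of the masked map (unvisited voxels are excluded
pairwise, never zero-filled). Lags with fewer than 20 overlapping pairs
or zero variance are undefined. Anisotropy correction thresholds at
0.25, takes the 26-connected central region, and rescales each axis
(cubic interpolation, at most 2× per axis) until the region's per-axis
extents equal their geometric mean. Field radius is the
equivalent-sphere radius of that region's volume. Grid spacing is the
first local maximum (prominence ≥ 0.01, radius ≥ 5 bins) of the median
correlation over spherical shells (|dist − r| ≤ 2 bins, radii up to
0.6× the maximum side); shells with fewer than 10 defined lags
contribute nothing, and cells without a qualifying peak get an undefined
spacing rather than an error. On generator arrangements the estimator
lands ~5% below S — the shell grid is discrete at the voxel pitch — so
the 10% recovery tolerance in the tests reflects discretisation, not
noise.

## Gridness and planar symmetry

The 2D scores threshold the autocorrelogram at 0.3, label 8-connected
components, and keep the seven component centroids nearest the centre;
the annulus spans [min ring distance − r_c, max ring distance + r_c]
with r_c the equal-area radius of the central component. Rotational
correlations are evaluated on annulus pixels valid in both the original
and the rotated copy; slices with fewer than seven components are
unscorable and contribute nothing anywhere downstream. The plane sweep
scores the central oblique slice on a 65 × 65 (pitch × azimuth) grid —
4,225 planes — with square slices of half-width min(28, what fits) at
the voxel pitch: 28 voxels covers the hexagonal six-peak annulus and
the diagonal peaks of square slices at the package's standard lattice
period (~17 voxels) while keeping the sweep a few seconds per cell. All
slices are extracted in one trilinear gather and scored in batch (one
shared bilinear rotation plan per offset angle).

Best-plane correction takes the maximal-HGS plane (ties toward the
lowest pitch), optionally refines it on a ±3° fine grid (the native
azimuth step, 5.5°, is coarser than the square-plane peaks read next),
rotates the autocorrelation so that plane is horizontal (cubic
interpolation), and re-expresses the score sphere in the new frame by
nearest-neighbour lookup on the sphere among *scorable* planes — an
unscorable direction inherits its nearest scored neighbour, which is
also how the 65×65 maps are interpolated to 128×128.

The structure scores follow the operational definitions: with rings read
at the sampled pitches nearest 72° (oblique hexagonal) and 50° (square)
— the nominal angles, kept even though ideal FCC geometry gives 70.5°
and 54.7° — and the hexagonal azimuth triple chosen as the 120°-spaced
triple at the 72° ring maximising summed HGS:

    χ_CP  = median({HGS at 72°} ∪ {SGS at 50°})
    χ_FCC = median SGS(hex ± 60°, 50°) − median SGS(hex, 50°)
    χ_HCP = median SGS(hex, 50°) − median SGS(hex, 72°)
    χ_COL = median HGS(pitch ≤ 60°) − median HGS(pitch > 60°)

In the full pipeline the three rings are re-scored natively on the
rotated volume (128 azimuths each; ring gaps filled circularly from the
nearest scorable azimuth) because the SGS peaks at the hexagonal
azimuths — the term that separates HCP from FCC — are only a few
degrees wide and do not survive nearest-neighbour regridding of a
coarsely sampled sphere; χ_COL, a broad-band median, comes from the
regridded sphere. Empirically (un-rotated, axis-aligned) both close
packings put their strong square planes at hex ± 60°; HCP is
distinguished by an additional weak square-symmetric family at the
hexagonal azimuths near 44–52° pitch and by SGS at (hex, 72°) being
deeply negative for any hexagonal plane — which is why χ_HCP is
moderately positive even for FCC and the classifier must compare the
full score vector.

χ scores are reported only when at least 5% of the sampled planes are
scorable. This gate is calibrated far from any boundary: uniform-random
reference arrangements score ≲ 2% of planes (their medians would be
junk spread from a handful of accidental slices), structured ones
≳ 70%. The argmax classifier labels a cell by its largest structured χ,
or random when all fall below 0.6 — the midpoint of the gap between
the generator's structured reference scores (argmax χ ≥ 1.1 over 20
seeds per kind with random S and 30° rotations) and the spurious
scores of random arrangements (≤ 0.9 before the gate, almost always
undefined after it). The hull classifier tests membership of
(χ_FCC, χ_HCP, χ_COL) in the convex hull of each reference cloud.

## Field statistics and shuffles

Field axes come from the eigendecomposition of the voxel-coordinate
covariance (P_i = 4√λ_i, the solid-ellipsoid convention; only ratios
are used downstream), elongation is P1/(0.5(P2+P3)) (P1/P2 in 2D), and
the equivalent diameter is (6·v_f/π)^⅓ of the convex-hull volume. The
elongation shuffle resprays the field's spikes from an isotropic
Gaussian at the centroid with σ = radius/1.8 — the width whose
~20%-of-peak threshold radius (√(2 ln 5) σ ≈ 1.8σ) equals the field's
equivalent radius, so the respray reproduces a spherical field of the
same equivalent diameter — snaps each spike to the nearest trajectory
point, rebuilds a local adaptive map, and z-scores the observed
elongation against 100 resprays (z > 1.96 → nonspherical). Note the
respray null is not centred on 1: even spherical fields measure ~1.6
under this estimator at realistic sampling, which is exactly why the
test is shuffle-referenced.

The field-position shuffle watershed-segments an oversmoothed copy
(σ = 3 bins, H-maxima 0.2 on the peak distance transform), moves each
field's peak bin to a uniform random visited position, then cycles the
fields, moving each remaining bin to the free visited position nearest
its ideal offset-from-peak in city-block distance (raster-order
tie-break). The output provably preserves the rate-value multiset, the
peak rate, and every unvisited bin's position.

Interfield local order uses 2 cm histogram maps (σ = 2.5 bins)
thresholded at 10% of peak, H-maxima (0.8 Hz) centroids merged
iteratively below 25 cm, and the CV of deduplicated 3-nearest-neighbour
distances; the null accepts circular spike-shift shuffles only when
their field count is within ±3 of the observed (target 1,000 accepted
of ≤ 10,000 attempts at full scale). Orientation tests count principal
axes within 30°-half-angle caps about each Cartesian axis (13.4% of the
sphere by area) against 1,000 uniform Monte-Carlo draws; layer tests
compare per-layer field proportions with uniform draws (chance 1/6 per
layer, 1st–99th percentile flags). Maze volume for fields-per-m³ is the
total volume of voxels with average dwell > 0.1 s.

## Information, stability, direction, temporal

Both Skaggs forms are computed — Σp_i(λ_i/λ)log₂(λ_i/λ) bits/spike and
Σp_iλ_ilog₂(λ_i/λ) bits/s (identically λ × the former) — along with
sparsity (Σp_iλ_i)²/Σp_iλ_i²; a silent map carries zero information by
convention. Shuffle standardisation is z = (obs − μ)/σ against 100
circular shifts (0.02 s grid, ≥ 20 s), with z > 1.96 read as exceeding
the shuffle 95th percentile (strictly the two-sided
97.5% point; the percentile itself is also exposed). Split-half
stability correlates half-session maps over mutually visited bins on a
shared grid; cross-cell chance pairs must come from different sessions —
sharing one trajectory leaks a large occupancy-smoothing artefact into
the null. Directional tuning uses 60 six-degree bins smoothed
circularly (σ = 3 bins); the Rayleigh vector length of the curve
measures directionality. The theta fit bounds a, b ≥ 0, c ∈ [0, 0.8],
ω ∈ [6, 12] Hz, τ2 ≤ 0.05 s, excludes the zero-lag bin, normalises to
the 100–150 ms maximum and drops values > 1, and multi-starts from five
ω values across the band; cells under 500 spikes are not fitted. The
speed score smooths the 20 ms spike histogram with a 260 ms Gaussian
window and fits an unweighted least-squares line to mean rate per
occupied 2 cm/s bin.

## Problem sizes in the test suite

The suite runs entirely on generated data at sizes chosen to mirror
realistic recording conditions while keeping the full run to minutes: 20 reference
simulations per arrangement kind for configuration recovery; 200
homogeneous-Poisson cells × 100 shuffles for the false-positive
calibration of the spike-shift null; 20 seeds per ω for theta recovery;
900–1,200 s sessions (the recordings ran 27–69 min); split-half null
pairs, interfield-CV shuffles and elongation resprays at tens rather
than the thousands a full study would use. Passing these tests shows
the estimators are correctly implemented and calibrated on clean,
well-sampled, stationary data; it does not certify behaviour under
tracking noise, non-stationary firing, cluster contamination, or the
coverage gaps of short real sessions.

## Known limitations

* The ≥7-peak scorability rule makes the plane sweep conservative on
  clean, sparse autocorrelations; real noisy maps score more planes,
  not fewer, so the 5% gate should be revisited before applying the
  classifier to data far cleaner or far noisier than the generator's.
* The operational 72°/50° ring pitches are kept from the method even
  though ideal close-packing geometry gives 70.5°/54.7°; the scores are
  contrasts, so the small systematic misplacement cancels to first
  order but does shrink margins.
* The adaptive estimator can assign rates in never-visited regions
  whose counting spheres eventually satisfy the criterion; downstream
  consumers should keep the visit-count criterion enabled.
* Histogram-map smoothing at 10 cm voxels in a ~1 m environment is
  near-global; correlations between such maps (including chance levels)
  are dominated by shared dwell structure whenever trajectories are
  shared.
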