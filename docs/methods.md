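# Methods

`somitekit` quantifies somite morphogenesis from 4D (x, y, z, t)
membrane-labelled fluorescence movies. Because no public raw data exist
for this kind of acquisition, every analysis stage is developed and
validated against a synthetic tissue simulator that produces both the
images and their exact ground truth. This note records the models, the
parameters that matter, and the design decisions taken where the
published description of each measurement left the procedure open.

## Coordinate and unit conventions

Arrays are ordered `(t, z, y, x)` with 0-based, half-open voxel
indexing. Default voxel geometry is 0.25 × 0.25 µm in-plane, 0.51 µm
axially, one stack per 20 minutes — the acquisition geometry of the
study the pipeline targets. Positions and lengths are in µm, volumes in
µm³, time in minutes, rates per hour. Simulated dorsal views map +x to
lateral→medial and +y to caudal→rostral; angles are counter-clockwise
from +x in degrees on (−180, 180]. The published track-angle plots do
not define a frame, so this one is fixed here to make directionality
testable; the rostro-medial quadrant is then the +x/+y quadrant and its
diagonal bearing is +45°.

## Synthetic tissue simulator

The simulator emulates membrane-GFP tissue: spheres packed by random
sequential addition (overlap at most 10 % of the smaller radius), each
rendered as a bright shell of ~0.5 µm thickness with a dark interior,
blurred by an isotropic Gaussian PSF (default σ = 0.3 µm) and corrupted
by Poisson shot noise plus Gaussian read noise. The noise model is
parameterized by a single peak SNR: unit-amplitude structure receives
`snr²` photons and read noise of SD `0.5/snr`. Motion is simulated in
the dorsal plane (the plane in which tracks are measured); step lengths
are Normal(mean_speed·dt, speed_sd·dt) truncated at zero — the simplest
two-parameter model matching reported mean ± SD speeds — and step
directions are uniform (`random`), a drift-weighted mixture of a unit
vector toward a sink and a uniform unit vector (`directed`), or the
same with the sink at the domain centre (`inward`). Cells reflect at
the domain boundary.

Divisions are a homogeneous Poisson process over the movie at a
field-level rate (events/hr). A dividing cell rounds up for 25 minutes
— rendered as a filled bright disk of 14 µm diameter so that the
detector's published gates (12 µm, 0.85) are genuinely exercised — and
then splits into two daughters of half volume. Two simulator choices
keep the rounding phase measurable and are deliberate realism
constraints, fixed in the generator rather than tuned per experiment:
events are carried by cells at least 8 µm from the lateral field edge
(a rounded cell is never half out of view), and simultaneous rounding
cells keep at least 1.5 rounded diameters apart (real mitoses are
spatially distinct; coincident rendered disks would merge into one
non-circular blob). Total true volume follows V₀ + g·t by uniform
radial growth, so volume is conserved exactly at division and the
linear-growth invariant holds to < 2 %.

What the simulator does **not** emulate: confluent epithelial packing
(cells are spheres with gaps, so an inverted image contains interstitial
spaces that look like extra "cells" to a blob detector), membrane
intensity heterogeneity, depth-dependent signal loss, optical-flow-like
collective deformation, and persistent (autocorrelated) random walks —
the study reports no autocorrelation data to model them from. Passing
tests therefore demonstrate correctness of the algorithms under
controlled conditions, not performance on real microscopy.

## Growth model

Somites and somitocoels are treated as spheres. The perimeter P of the
thresholded central slice (Gaussian smoothing, Otsu threshold, largest
connected component, sub-pixel iso-contour length) gives r = P/2π and
V = (4/3)πr³. The sub-pixel contour at the threshold level was chosen
over pixel-counting perimeters because V scales as P³: a 2 % perimeter
error is already a 6 % volume error, and contour length on the smoothed
grey-level image is accurate to well under 1 % for disks larger than
~10 px radius. Whether the original slice→sphere conversion went
through the perimeter or the area is not stated; both are implemented
(`sphere_volume_from_perimeter`, `sphere_volume_from_area`) and the
perimeter route is the default. One caveat of any Otsu-based
measurement applies here: the threshold level drifts with the object's
area fraction in the field of view, which can tilt a fitted growth
rate when the object grows appreciably relative to its canvas; keeping
a generous margin around the object (or fixing the threshold)
suppresses the effect.

Growth rates are ordinary least-squares slopes of volume against time,
converted to µm³/hr, with the slope SD from the residual variance. The
proliferation-only division rate is `round(g / v_c)`; with the measured
g = 19 µm³ hr⁻¹ this yields 3 cells hr⁻¹ only if the "average cell
size of 6 µm" is read as a cell *volume* of 6 µm³, so that reading is
adopted (the diameter reading, ~113 µm³, contradicts the printed
result). The decomposition `min(1, observed_rate·v_c/g)` attributes the
remainder of growth to cell-size increase. The absolute volume scale of
the study (somite volumes of order 10²–10³ µm³) is anatomically small
for real somites; all printed values are taken at face value and the
unit question is flagged, not resolved.

## Morphology correlation

Change between two time points is the Pearson correlation over all
pixel pairs of two slices, computed on raw, unregistered slices exactly
as the overlay measurement describes (no drift correction by default; a
mask argument exists for somite-restricted comparison). Depths are
specified as fractions of the z extent (default 0.25/0.5/0.75 →
dorsal/centre/ventral) because no absolute depths are published.
r is symmetric, invariant under positive affine intensity maps, 1 for
identical images, and decreases monotonically with true cell
displacement on simulated sequences.

## Division detection

Per z slice: median filter (3 px), light Gaussian smoothing (1 px),
Otsu threshold, then grey-level opening with a 2 µm disk. The opening
removes thin membrane outlines while preserving filled rounded cells;
its radius and the smoothing were chosen on simulated movies to keep
the boundary of a true rounded disk smooth enough that discretization
and noise do not push its circularity below the published 0.85 gate
(an ideal disk measures ~0.95–1.0 after digitization; a ragged one can
drop below 0.85). Regions pass with equivalent diameter
2√(Area/π) ≥ 12 µm and circularity 4π·Area/P² ≥ 0.85, with P the
sub-pixel contour length; raw circularity values up to 1.1 (a
discretization artifact) are clipped to 1. Detections in consecutive
frames (one missing frame allowed) within 6 µm are merged into one
event, since a 25-minute rounding phase spans 1–2 frames at 20-minute
sampling; 6 µm covers per-frame cell displacement plus centroid jitter
while staying below typical inter-event distances. Rate =
events · 60 / duration_min, reported per analyzed volume.

## Tracking

The pipeline mirrors the published ImageJ/TrackMate workflow on a
single dorsal slice. Preprocessing: intensity inversion (membrane
images have dark cell interiors), difference-of-Gaussians band-pass
(default σ = 2 and 16 px), and rolling-ball background subtraction
(radius 20 px, the published value); output clipped to ≥ 0. Detection:
Laplacian-of-Gaussian blobs at a scale matched to the expected cell
diameter, an intensity-weighted centroid refinement, and a merge of
detections closer than 0.6 diameters (multi-scale duplicates).
Linking: per consecutive frame pair, a Jaqaman-style augmented linear
assignment problem over squared distances with non-link cost equal to
the squared maximum link distance, solved exactly with the Hungarian
algorithm; no merge or split costs (the "simple" tracker), optional
single-frame gap closing, off by default. The default maximum link
distance in the movie-level driver is deliberately generous (~3× the
expected per-frame displacement) because truncating the step-length
tail biases speeds downward.

Per track: the mean direction is the circular mean of per-step heading
angles (the Methods speak of averaging directions; the net-displacement
bearing is available behind a flag), net displacement |last − first|,
path length Σ|steps|, and mean speed path/elapsed-minutes. Length-vs-
angle plots use net displacement, since directedness is the quantity of
interest. Population directionality is the mean resultant length
R = |Σ u(θ̄_k)|/N ∈ [0, 1]; the unnormalized sum used in the original
plots is R·N. Tracks shorter than 3 frames are excluded from
directionality statistics (configurable). Under uniform random angles
E[R] = √π/2/√N ≈ 0.886/√N, which the tests verify by Monte Carlo.

## Domain segmentation

Counting and sizing cells in the fixed 32 × 41 × 20 µm medial/lateral
boxes (65–85 µm deep for early, 85–105 µm for mid-stage somites) uses a
membrane-based seeded 3D watershed: Otsu membrane mask, slice-wise hole
filling (xy rings close reliably even where the axial sampling is
coarse near cell poles), connected dark interiors as seeds, watershed
over membrane intensity. Label volumes are measured to the membrane
mid-surface by stripping voxels closer to the outside of the filled
mask than half the *apparent* membrane thickness, which is estimated
from the mask's own distance transform (4 × its median) because the PSF
widens the membrane well beyond its 0.5 µm physical thickness. Labels
below 2 µm³ are discarded; cells clipped by the box are counted by the
centroid rule. This component is a documented stand-in for the RACE
cell-shape extractor: it is validated only against synthetic ground
truth, and equivalence to RACE is not claimed.

Cell-size structure is assessed by 1- vs 2-component Gaussian mixtures
on log volume (volumes are positive and right-skewed), decided by BIC;
component means are reported as geometric means.

## Statistics and reporting

Group comparisons are two-tailed Welch t-tests with Satterthwaite
degrees of freedom (via scipy, cross-checked in the tests against
statsmodels). No multiple-testing correction is applied, matching the
original analysis; reports carry the raw p-values with a note. The
packaged three-stage scenario (random 0.14 µm/min + 1.7 hr⁻¹ →
directed 0.21 µm/min + 4.4 hr⁻¹ → inward 0.06 µm/min + 0.3 hr⁻¹)
reproduces the qualitative orderings — directionality and speed and
proliferation all peaking at mid stage — and its sample unit for the
t-tests is the per-track mean speed, stated in the output. The
mid-stage sink is placed far outside the field so the directed flow is
quasi-parallel; a sink inside the field makes cells pile up at a point,
which is neither biological nor trackable.

## Problem sizes and determinism

All stochastic components consume explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical images,
ground truth and reports. The packaged validation runs use scaled-down
scenes chosen to exercise every code path at realistic density: 2D
tracking fields of 40–100 cells over 8–10 frames, division movies of
100 × 100 µm over 180 simulated minutes, and full-resolution 3D boxes
(128 × 164 × 39 voxels) for segmentation. Batch checks (growth-rate
bias, division-rate bias) average 100 independent seeds.

## Known limitations

* The simulator's sparse sphere packing creates interstitial spaces
  that an inverted-image blob detector partly mistakes for cells;
  transient false tracks are suppressed by the 3-frame minimum length,
  but slow-motion speed estimates retain a small upward bias from
  localization jitter.
* Volume measurements for cells a few voxels across (r ≈ 1.5 µm at
  0.51 µm axial sampling) are strongly discretization-limited; counts
  are reliable there, absolute volumes are not.
* Tracking is strictly 2D in a single slice; cells leaving the plane
  terminate tracks.
* The division detector is per-slice 2D with cross-frame merging, as in
  the original object-detector workflow; a true 3D detector would
  behave differently near slice boundaries.
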