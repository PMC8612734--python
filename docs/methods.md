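# Methods

This package quantifies how a flat epithelial placode funnels its cells
through an eccentric invagination pit to bud a narrow tube, from tracked
apical cell meshes.  All computations operate on a `TrackedTissue`: an
ordered list of frames, each holding per-cell apical polygons (µm,
counter-clockwise) keyed by persistent track ids, the cell-cell adjacency
graph with shared-interface lengths, placode membership, and the subset of
cells on the boundary cable.  Time zero is the frame just before the first
sign of tissue bending.

## Mobile radial coordinate system

The pit origin is specified once at t = 0 and tracked through all frames.
Two signals drive the tracking:

1. a linear displacement field fitted to the 10 placodal cells nearest the
   current origin, evaluated *at* the origin.  This is exact under bulk
   translation and neutral under a radially symmetric inflow (the
   converging components cancel in the fit rather than advecting the origin
   into the pit, which a plain mean displacement would do);
2. an anchor on the observable definition of the pit — the sink where
   tracks end.  When tracks end within ±3 frames and two cell diameters of
   the estimate, the origin is blended 70% toward their mean final
   centroid.  Without this, the estimate degrades late in invagination,
   when the dorsal-posterior supply is exhausted and all material arrives
   from the anterior side, so the purely kinematic fit extrapolates a
   curved (1/r) flow from a one-sided sample.

Each cell carries `r` (distance to the origin), `theta` (angle from the
posterior direction, anti-clockwise for left-side placodes and clockwise
for right-side ones so mirrored placodes overlay), and `D`, the distance
from the origin to the placode boundary polygon along the cell's own ray
(placodes are not circles, so a single radius would misclassify cells).
The near region is `r <= 0.33 D`, boundary inclusive; cohorts and radial
stripes (default 10, spanning [0, max D]) are fixed at t = 0 by track id.

## Strain-rate decomposition

Deformation is measured on domains of a focal cell plus its first corona of
neighbours over a window of ~3 min (nearest whole number of frames, centred
where possible).  Three symmetric 2×2 tensors in proportion/min:

* **Total tissue strain rate T** — the symmetric part of the least-squares
  velocity-gradient tensor fitted to member centroid displacements.  The
  antisymmetric part (rigid rotation) is recorded as a diagnostic and
  excluded from all strain outputs.
* **Cell-shape strain rate C** — per cell, the best-fit (equivalent-moment)
  ellipse at the window start is mapped to the ellipse at the end by the
  minimal-rotation stretch: axes are paired major-with-major, the axial
  rotation is wrapped into (−π/2, π/2], and the log-stretch
  diag(ln a₁/a₀, ln b₁/b₀) is expressed in the mid-orientation frame.
  This is additive over consecutive windows, gives exactly zero for rigid
  rotations, and reduces to the closed-form log-ratio for coaxial scaling.
  Domain C is the area-weighted mean over members (large cells contribute
  proportionally to tissue deformation).  Near-circular ellipses borrow the
  partner frame's orientation; if both are circular the strain is isotropic
  and the orientation moot.
* **Intercalation strain rate I = T − C** — the residual sliding of cells
  past one another.  The identity is exact by construction; what the tests
  check is *attribution*: on a generated pure-constriction flow ≥95% of |T|
  lands in C, on a rigid-shape shear flow ≥95% lands in I.

Tensors are projected on the local radial/circumferential axes as quadratic
forms (ûᵀMû).  Scalar rates accumulate multiplicatively:
cumulative(t) = exp(Σ rate·Δt) − 1, so constant −0.01/min over 10 min gives
−0.95%, not −10%; gaps split the accumulation and flag later points.
Per-cell apical area-change rate is Δln(area)/Δt (pp/min).  The projected
aspect ratio is the ellipse half-width along û_r over the half-width along
û_c (>1 = radially elongated).

## Neighbor exchanges

A T1 event is the quartet (pair losing contact between t and t+1, pair
gaining it), matched by requiring both gaining cells to share both losing
cells as neighbours at t; rosette-like multi-exchanges decompose pairwise.
Adjacency series are cleaned with one frame of hysteresis (single-frame
gaps filled, single-frame appearances dropped) to suppress pixel-noise
flicker around the contact threshold.  Gains are circumferential when the
gaining pair's centroid-centroid axis lies within 45° (inclusive) of the
local circumferential direction at the pair midpoint, else radial.  The
per-step rate is net circumferential gain over half the tracked interfaces,
divided by the tracked-interface fraction when coverage is incomplete;
its running sum is the cumulative proportion of productive gains.

## Fluorescence

Label and intensity pages must be congruent.  Junctional pixels of a cell
are those within 2 px of its boundary in the Euclidean distance transform
(edge pixels sit at distance 1, so the band is `dist <= 3`); medial pixels
are the rest, flagged undefined when the band swallows the cell.
Background is estimated per frame from the 1st percentile of pixel values
with a Gaussian-tail correction (σ read off the p1–p5 spread, 0.681σ for a
normal floor; the correction vanishes for noise-free images).  Per-cell
means are normalised by the frame's 98th percentile (linear-interpolation
definition), which removes embryo-to-embryo staining scale and leaves
polarity amplitudes unchanged.

Medial traces are detrended by subtracting a centred 6-min boxcar (chosen
above the longest expected cycle; truncated windows at the edges).  Cycle
detection builds the alternating peak/trough sequence and iteratively
merges the weakest adjacent pair whose amplitude falls below 0.2 trace SD
(the skip rule for very-small-amplitude cycles; configurable).  Cycle length is the
peak-to-peak interval, amplitude the mean |peak − trough|, and strength
amplitude/median cycle length.  For recovery against a programmed sinusoid
the package also provides a debiased strength: peak-to-trough amplitudes on
a boxcar-detrended, discretely sampled trace are scaled by the boxcar
high-pass gain |1 − H| at the cycle frequency and by sinc(dt/P), the
expected extremum attenuation at uniformly random sampling phase; both have
closed forms and are divided out, with the period taken as the mean cycle
length (the median is quantised to multiples of dt).  Cycle recovery is
meaningful only with at least ~3 samples per cycle; at dt ≥ P/2 the cycle
aliases and between P/3 and P/2 the peak-to-peak quantisation dominates any
estimator — recovery tests therefore cover the acquisition grid with
dt ≤ P/3.

Junctional polarity treats the perimeter intensity as a periodic signal in
the angle about the centroid: trapezoidal Fourier projection gives mode-1
(unipolarity) and mode-2 (bipolarity) amplitudes as proportions of the mean
perimeter fluorescence, with phases the enrichment direction/axis.  From
images, the perimeter is sampled at 64 equal arc-length points with
bilinear interpolation; an optional inward inset keeps samples inside the
cell's own junctional band instead of straddling the neighbour's.
Boundary-cable cells are excluded by the caller.

## Corona model

The idealized placode is a triangular lattice (spacing d) clipped to a disk
of radius R; the corona index is the adjacency-graph distance from the pit
cell set (neighbour shells, not Euclidean annuli).  A central single-cell
pit collects 6k cells in shell k until the disk clips; a boundary pit's
shells saturate at the chord width, keeping counts low with a smaller
coefficient of variation; an enlarged pit starts large and stays large.
Series are classified steady / increasing / large-then-steady by the fitted
slope over coronae ≥1 (|slope| < 0.5 cells/corona = steady) with a
corona-0 excess of 1.5× the tail mean marking large-then-steady.  Observed
coronae in tracked tissues take the earliest-disappearing cells as the
seed and assign every internalized cell its shell distance on the first
frame's mesh; with a point-like pit the first shells necessarily ramp up
and the last is truncated by the movie end, so steadiness is a statement
about the interior coronae.

## Synthetic placode generator

The generator realizes prescribed kinematics without mechanics.  Cells are
Voronoi regions of Lloyd-relaxed seed points in a disk, advected by the
scenario flow; each polygon is rescaled about its centroid so its area
follows the per-cell program exactly, which makes area-based ground truth
exact rather than approximate.  Defaults describe the wild-type-like
condition: 100 cells, placode extent 47 µm at t = 0, 1-min frames from −40
to +70 min, pixel size 0.22 µm, eccentric pit at 0.68 R dorsal-posterior
with 5 µm radius.

The sink flow has radial speed v(r) = drift + (k_area/2)·r inside the
constriction-onset radius (13.7 µm, the near-region extent), i.e. area
divergence −(k_area + drift/r), strongest at the pit; outside it is
incompressible (v ∝ 1/r), so far cells drift inward at constant area until
they cross the onset radius — the programmed behaviour switch whose onset
frame is recorded per cell.  With k_area = 0.02/min and drift = 0.6 µm/min
the inflow flux (~63 µm²/min, about one cell per 1.5 min) internalizes most
of the placode by +70 min, as in the real tissue; the disk is seeded
correspondingly larger at −40 min so its extent is ~47 µm at t = 0.  Cells
entering the pit radius collapse (area ×0.3 per frame for two frames) and
the track ends.  Two oracle flows bypass the sink: `uniform` (v = −k x on
points, boundary and tessellation alike — every strain measure is exactly
−k, Voronoi commutes with similarity transforms) and `shear_rigid` (pure
shear point motion under rigid polygon templates — C ≡ 0, I = T).

Scripted T1 exchanges are generated on a static hexagonal lattice where
adjacency is edited explicitly (the diagonal of a distinct quartet flips at
a scheduled frame; reversals flip back two frames later), giving an exact
event list; quartets are accepted only when their gain axis is clearly
(>15° margin) circumferential or radial about the lattice centre, so truth
classes never depend on the classifier's own tie rule.

Medial signals are sinusoids (period 3.5 min for cells near the pit at
t = 0, 5.5 min far — inside the 3–6 min range), amplitude 30 a.u. on a base
of 100 with a 1 a.u./min linear drift to exercise detrending, plus Gaussian
noise (SD 1).  Junctional polarity is programmed with unipolar amplitude
0.1 pointing at the pit and bipolar amplitude 0.3 along the circumferential
axis.  Rendering rasterizes polygons to uint16 label pages (value =
track id + 1) and float32 intensity pages (medial value inside the cell,
junctional Fourier modes on the 2-px edge band, constant background 20,
noise SD 2).  Everything is keyed by one integer seed and bit-reproducible.

### What the generator does and does not emulate

It reproduces the geometry, flow topology, region structure, exchange
bookkeeping and signal statistics of the study system, so passing tests
show the *measurement pipeline* recovers known kinematics and signals under
realistic sampling.  It does not model mechanics (no force balance, no
junctional tension), curvature (2D apical view only), segmentation error
beyond rasterization, z-projection artefacts, or biological variability in
constriction rates; recovery on real movies would additionally face
tracking noise that is only partially emulated by the adjacency hysteresis
and quality filters.

## Numerical choices and degenerate inputs

Coordinates are µm with y increasing dorsally and x anteriorly→posteriorly;
image pixel (row, col) maps to (x, y) = (col·px, row·px) at pixel centres.
Polygons from label images are boundaries of pixel-square unions, so pixel
mass is conserved exactly.  Adjacency from images requires ≥2 shared
boundary pixels (suppresses four-fold-vertex contacts).  Ellipses are
equivalent-moment ellipses (semi-axes 2√eigenvalues of the polygon
covariance).  Eigenvalue ties set the orientation to 0.  A cell at the
origin has r = 0 and an undefined angle (NaN) and is excluded from
projections.  Quality filters (lineage ≥3 frames, area 1–200 µm², aspect
≤8, relative velocity ≤10 µm/min — package defaults, all overridable)
remove whole tracks and are idempotent.  Analysis problem sizes in the
tests and drivers (60–100 cells, runs of 10–111 frames) are the package's
default study conditions; the oracle flows use short runs because their
statistics are stationary.

## Known limitations

* The origin tracker assumes the pit is either surrounded by tracked cells
  or marked by ongoing internalization; a movie with neither (e.g. long
  pre-constriction phases with heavy tracking loss near the pit) would
  drift.
* Cell-shape strain pairs ellipse axes major-with-major; cells rotating
  faster than ~45° per window would be mis-paired.
* Pairwise decomposition of rosettes counts each gained interface as one
  event and makes no claim about rosette topology.
* The debiased oscillation strength assumes a locally sinusoidal signal;
  strongly asymmetric pulses would need a different amplitude model.
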