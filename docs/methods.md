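# Methods

## Helical lattice geometry

A helical polymer is generated by a single symmetry operator: axial rise
Δz (Å) and azimuthal twist Δφ (degrees) per subunit.  Twists are stored
reduced to (−180°, 180°].  Connecting every k-th subunit yields the
k-start family with azimuthal step per connection
`step(k) = reduce(k·Δφ)`; its handedness follows the sign of the reduced
step in a z-up right-handed frame (positive step = right-handed).  The
deposited twist values are used verbatim; this convention reproduces the
published handedness of the 4-, 5-, 14-, 17-, 19- and 21-start families
of all four refined Vipp1 lattices, so no sign juggling is applied.

Inter-strand axial spacing of a family is `360·Δz/|step(k)|` and the
strand pitch is k times that.  On the cylinder unrolled at radius r the
k-connection is the planar vector `(r·step(k) in radians, k·Δz)`; the two
shortest such vectors over k = 1..k_max are the lattice's
nearest-neighbour directions and correspond (up to sign) to the dominant
Bessel orders of the diffraction pattern.

*Defaults.* k_max = 25 (visible start count is bounded by circumference
over minimum subunit spacing, ≈ 2π·122 Å / 30 Å for the widest filament
here).  Evaluation radius defaults to the mid-wall radius
(r_lumen + r_outer)/2; the principal-vector ordering flips near the
outer wall, and mid-wall reproduces the published Bessel pairs (17/−4
and 14/−5).  Ties in length or step comparisons break toward smaller k
with a 1e−9 absolute tolerance.

*4-start "pitch".*  The printed 44 Å pitch of the 4-start helix is
ambiguous between the strand pitch divided by k (the inter-stripe axial
spacing, 43.13 Å from the refined parameters) and the pre-refinement
particle-extraction overlap (44 Å).  Both `strand_pitch_A` (172.5 Å) and
`axial_spacing_A` (43.13 Å) are reported with explicit names.

## Diffraction

Layer lines follow the helical selection rule
`Z = (n·Δφ/360 + m)/Δz`.  Only positions are modelled; Bessel-function
amplitude modulation depends on the unmodelled subunit shape and is out
of scope.  The candidate-symmetry grid search inverts pairs of indexed
reflections (Z, n): for each pair and each integer assignment
(m_i, m_j) in the m-search window the two linear selection-rule
equations are solved exactly for (rise, twist); solutions are kept
inside physical bounds, deduplicated within (0.005 Å, 0.01°) and ranked
by RMS residual over all reflections with per-reflection best-m
assignment.  Defaults: m ∈ [−6, 6], rise ∈ [1, 10] Å, twist ∈ (−180,
180]° — the m-window and bounds are this package's choice (plausible
subunit packing); the source analysis does not state its grid.

Simulated power spectra place Gaussian pseudo-subunits (σ = 4 Å) on the
1-start helix, project along the view axis, apply a Hann window and
return the origin-centred amplitude spectrum.  The seed randomises only
the azimuthal phase; spectra are bit-reproducible per seed.

## Cylindrical projection (unrolling)

Convention: azimuth origin on the +x axis, wrap to [0, 2π), y increases
with z.  Map unrolling averages trilinear interpolations over
`n_shells = 5` radial samples across a shell of thickness 2 voxels by
default (mean, not max), with azimuthal sampling at least Nyquist for
the voxel size.  The projection radius for a given map is a user choice
(default mid-wall) since the source does not state one.

Line-family spacings of an unrolled point lattice are measured, not
copied from the closed form: the family direction is the median wrapped
k-step displacement, points are projected on the unit normal, clustered
by gap (threshold 0.3 × the areal-density estimate of the inter-line
spacing), and the median adjacent-cluster gap is the perpendicular
spacing; axial spacing = perpendicular / cos(tilt).  On noiseless
lattices this agrees with `360·Δz/|step|` to well under 0.5%.

## Curvature-limit model

The filament substructure is a set of rigid parallel ridges
(hairpin columns) with relaxed spacing s0 = 54 Å, compressible to
s_min ≈ 41 Å and stretchable to s_max ≈ 61 Å (bounds measured across
ring rungs; they carry a "~").  Bending a filament of width w = 134 Å in
the plane with centerline radius R rescales the spacing linearly with
local radius: `s_edge = s0·(R ± w/2)/R`, i.e. spacing is referenced to
the centerline (symmetric treatment of the compress/stretch bounds; an
inner-edge-relaxed variant would change only the bookkeeping).  The
bounds give `R ≥ s0·(w/2)/(s_max − s0)` (stretch) and
`R ≥ s0·(w/2)/(s0 − s_min)` (compression); the larger, here the stretch
bound, yields a minimum planar centerline diameter of 103.4 nm.
`requires_tilt` is inclusive-feasible at the boundary.  Sensitivity: ±2 Å
on each bound moves the limit between roughly 80 and 145 nm — the
qualitative conclusion (37 nm rings are far below any planar limit) is
insensitive.  The relation between the ~1 nm ring protrusion and a tilt
angle is not quantified here; no tilt-angle operation is offered.

C_N ring rungs satisfy `π·D = N·s` exactly; `ring_geometry` round-trips
diameter ↔ subunit arc.  Protofilament count is the rounded ratio of
filament width to the 32.5 Å lateral protofilament spacing (minimum 1).

## Spiral fitting

Traces are fit in polar coordinates about a centre optimised jointly
with the shape parameters: nested least squares (Levenberg–Marquardt on
the centre; the inner (a, b) fit is linear — directly for the
Archimedean form, in log-r for the exponential form, with residuals
always evaluated in r).  θ is unwrapped along the trace order; traces
must span ≥ 1.5 turns and be monotone (up to 10% of steps may jitter
backwards before a trace error is raised, tolerating digitisation
noise).  "auto" selects by AIC under a Gaussian residual likelihood;
both models have four free parameters (a, b, centre), so AIC reduces to
the smaller residual sum — stated explicitly for reproducibility.

## Synthetic AFM generator

The generator emulates the measured statistics of membrane-bound
polymers; every default is the published mean/s.d. and every parameter
is overridable:

| quantity | default |
|---|---|
| membrane height offset | 5.5 nm |
| ridge period / seam period | 54 Å / 122 Å |
| ridge / seam modulation amplitude | 0.3 / 0.15 nm |
| filament width | N(13.4, 0.9) nm |
| spiral outer diameter | N(82.7, 37.8) nm, floor 30 nm |
| ring (high-salt) diameter, height | N(35.5, 2.9) nm, N(9.6, 2.2) nm |
| central-ring protrusion | 1.0 nm above the spiral plateau |
| growth velocity | N(24, 19.6) nm/s, floor 0 |
| noise | additive Gaussian, σ = 0.1 nm |
| pixel size | 0.7 nm (sheet, filaments), 1.0 nm (fields) |

Distribution families are a generator assumption: the sources report
means ± s.d. only (the spiral-diameter s.d. being nearly half the mean
suggests skew that a normal cannot capture).  Floors are applied by
*clipping* to the floor, not rejection-resampling: resampling would
inflate the configured means (≈ +7% for diameters, ≈ +17% for
velocities), contradicting the stated statistics the generator is meant
to reproduce; clipping leaves them within ~2 and ~4% respectively and
has a physical reading (a stalled filament, a smallest resolvable
curl).  One named RNG substream per object class keeps truth tables
stable when another class's object count changes.

*Spiral rendering.*  Spirals curl anticlockwise as inward-decaying
Archimedean centerlines with turn pitch = filament width + 10 nm
membrane gap (turns are clearly separated in the imaged spirals; a
zero-gap pitch would merge all turns into a disk).  A decaying spiral
touches its nominal outer radius at a single angle, so the centerline is
rendered from r_out + pitch/4, making the object's minimal enclosing
circle equal the drawn diameter.  Spirals too small to complete ~0.9
turns at the default pitch shrink the pitch; if that leaves a membrane
channel narrower than 4 nm the turns are rendered merged (pitch = 0.9 ×
width, curled to a filled core) — geometrically, a 13.4 nm filament
cannot wind 1.5 turns below a ~50 nm outer diameter, and the imaged
sub-50 nm objects are exactly such fully-curled, lumen-free curls.
Central rings (when a spiral is large enough to host one, ≥ ~104 nm)
are detached annuli at the spiral centre protruding 1 nm above the
spiral plateau.  Rejection sampling places bounding circles without
overlap (error after 10⁴ attempts).

*Not simulated* (documented limitations): tip convolution, scanner
drift, tapping-mode/phase physics, membrane mechanics, vendor file
formats.  Green recovery tests therefore establish that the measurement
pipeline inverts this generator's idealised imaging model — not that it
is calibrated against instrument physics.

## Measurement pipeline

Background is the modal height (0.1 nm bins); objects are connected
components above background + 2 nm, minimum 300 nm².  Classification:

1. **ring** — the mask encloses a hole (≥ 4 px), and the filled region
   contains no other, smaller component;
2. **spiral (ring-hosting)** — encloses a hole *and* a smaller component
   (the detached central ring);
3. **sheet** — local width (2 × mean skeleton-to-edge distance) > 40 nm
   and area ≥ 2×10⁴ nm²;
4. **spiral** — skeleton net tangent turning ≥ 0.75 turn, or a compact
   disk-filling object (enclosing diameter ≤ 75 nm, mask ≥ 45% of its
   enclosing circle): the maximal-curl regime whose skeleton is too
   blob-like to resolve a curl.  The 0.75-turn threshold replaces a
   1.5-turn criterion deliberately: 1.5 turns is geometrically
   impossible below ~50 nm at the measured filament width, and would
   misclassify every small spiral;
5. **filament** — everything else.

Diameter is the minimal enclosing circle of the mask boundary
(documented convention; the measurement the sources used is not
defined).  Width is twice the mean Euclidean distance transform at
skeleton pixels; the EDT's half-pixel overshoot and the skeleton's
off-centerline wobble cancel empirically to < 0.5% across pixel sizes,
so no correction is applied.  Height offset is mean object height minus
the background mode.  Skeleton arc length uses 6-pixel chords to
suppress the up-to-8% chain-code overestimate of digital line length.
Growth velocities are reported per frame interval (matching how growth
was measured), tracked by nearest centroid (safe at the generator's
object separations); lost tracks are flagged and excluded from
summaries.  Ridge periodicity is the strongest non-DC peak of the
Hann-windowed 2D FFT after 3×3 amplitude smoothing (without smoothing,
the extreme-value tail of white noise exceeds any fixed
multiple-of-median threshold), with log-parabolic sub-pixel
interpolation; a peak below 3 × its radial-annulus median amplitude is
a no-periodicity signal, returned as `None` rather than an error.

## Determinism and units

All generators and writers are bit-reproducible per (seed, parameters)
on a fixed platform; file payloads carry no timestamps.  Lattice and
reciprocal quantities are Å, AFM-scale quantities nm; CSV/JSON fields
carry unit suffixes (`_A`, `_nm`, `_invA`, `_deg`).
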