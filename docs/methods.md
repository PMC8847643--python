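# Methods

## The planning problem

Rotational radiotherapy (VMAT) of a mediastinal target — typified by
esophageal cancer — trades conformity for a low-dose bath: as the gantry
sweeps 360 degrees, nearly all lung tissue receives some dose, and the
relative lung volume receiving at least 5 Gy (lung V5) is a known risk
factor for radiation pneumonitis. Restricting the gantry to anterior and
posterior sectors spares the lateral lungs, but the right total span
differs per patient. `opaplan` implements a volume-based algorithm that
converts a handful of geometric measurements into a personalized total
arc span, and everything needed to exercise and evaluate that choice on
a digital phantom.

## The arc-angle model

Inputs (units cm / cm^3 / fraction):

| symbol | meaning | how obtained |
|---|---|---|
| T | transverse thorax diameter | axial slice through the PTV centroid |
| E | PTV width (left-right) | same axial slice |
| Lt | PTV cranio-caudal length | coronal plane through the centroid |
| V_W | whole-lung volume | voxel counting |
| V_OW | lung volume outside the cranio-caudal field slab | voxel counting |
| expected_V5 | lung-V5 goal | user input, default 0.55 |

The lateral "restricted" lung region on one side has radius

    R = (T - E - m) / 2,          m = total lateral margin, default 4 cm

and the unirradiated lung is modeled as a partial circular cylinder of
radius R and length Lt + m spanning the angular complement of the arc,
plus V_OW. Setting it equal to the lung volume that must stay below
5 Gy gives the balance

    pi R^2 (360 - theta_A)/360 (Lt + m) + V_OW = V_W (1 - expected_V5)

solved in closed form:

    theta_A = 360 [1 - (V_W (1 - expected_V5) - V_OW) / (pi R^2 (Lt + m))]

With the default expected_V5 = 0.55 the right-hand factor is the
customary 0.45. The solver classifies rather than guesses outside the
domain: a non-positive required restriction is `NEEDS_FULL_ARC`
(theta clamped to 360, the pipeline falls back to the full-arc
baseline); a requirement exceeding the whole cylinder is `INFEASIBLE`
(theta clamped to 0, the pipeline raises). `achieved_geometric_v5`
reports the V5 implied by the clamped angle under the same model.

## Arc sequencing

C-arm linacs cannot rotate through the 180/-180 meridian, so theta_A is
split into six partial arcs with q = theta_A/4:

    CW : 180 -> 180+q,   -q -> q,   180-q -> 179
    CCW: 179 -> 180-q,    q -> -q,  180+q -> 180

i.e. an anterior sector (-q, q) and a posterior sector (180-q, 180+q),
each delivered in both rotation senses, with a 1-degree sentinel short
of 180 (the `sentinel_gap` parameter). Per rotation sense the covered
measure is exactly theta_A - sentinel_gap. The full-arc baseline is two
359-degree arcs, CW 180 -> 179 then CCW 179 -> 180, the second with a
5-degree collimator offset to wash out tongue-and-groove effects; in
partial-arc plans the offset is applied to the CCW set. Angles are kept
exact in memory and rounded to 0.1 degree only at serialization.
`theta_A <= 4 * sentinel_gap` is rejected: the third clockwise arc would
degenerate. Every constructed arc is validated never to traverse the
meridian mid-arc.

## The digital thorax phantom

All structures are analytic solids so measurements have closed-form
oracles: an elliptic body cylinder (constant axial cross-section), two
lateral ellipsoidal lungs, a central elliptic-cylinder PTV of width E
and length Lt, an ellipsoidal heart and a cylindrical cord. Defaults
(body 30 x 20 cm, lungs 11 x 15 x 26 cm at +/-8 cm lateral offset, PTV
6 x 6 x 16 cm) give a whole-lung volume of about 4.5 L and tumor lengths
configurable across the clinically reported 6-25 cm span. Optional
seeded Gaussian jitter of structure centers emulates placement
variability while staying bit-reproducible. Voxel convention: x runs
patient left to right, y posterior to anterior, z inferior to superior;
extents are measured center-to-center plus one voxel pitch, accurate to
one pitch and converging as the lattice refines.

What the phantom does *not* emulate: CT intensities, tissue
heterogeneity, concave or off-axis targets, breathing motion. Passing
tests therefore demonstrate the algorithmic pipeline and its internal
consistency, not clinical dosimetry.

A second, deliberately artificial *idealized cylinder phantom* realizes
the arc-angle model's own geometry: circular body of diameter T, central
PTV cylinder, and lung filling the annulus between the beam-corridor
half-width w = E/2 + margin and the skin. Its annulus satisfies
r_out^2 - r_in^2 = R^2 by construction, which makes the model's
restricted-volume bookkeeping nearly exact (see below).

## The dose simulator

A deliberately simple forward model in place of a commercial inverse
optimizer — every dose-level conclusion drawn from it is ordinal or
property-based, never a value match against clinical tables:

* parallel (non-divergent) beams, one per control point, sampled at the
  4-degree gantry spacing with trapezoidal weights so an irregular final
  step is weighted by the arc length it represents (doubling the control
  point density changes structure mean doses by well under 1%);
* aperture = the beam's-eye-view PTV projection dilated by a circular
  2 cm margin (the same margin the angle formulas assume);
* primary dose only: exp(-mu * depth) in a homogeneous unit-density
  body, mu = 0.05 /cm (megavoltage order); no scatter, so tissue outside
  every aperture receives exactly zero;
* global normalization so the PTV mean (or optionally D95) equals the
  45 Gy / 25 fraction prescription.

Parallel beams keep the never-irradiated region exactly cylindrical,
matching the solver's premise. The simulator requires a z-uniform body
cross-section (the phantom guarantees it) so entry depths are computed
once per gantry angle on the axial plane.

`geometric_unirradiated_fraction` counts lung voxels crossed by no
aperture — the voxel-level counterpart of the model's restricted volume
over V_W.

### How closely does the cylinder model hold?

On the idealized phantom the voxel-counted unirradiated fraction matches
the analytic expression to about 1 pp at 3 mm voxels for mid-range
angles. The residual is the corridor-width blur: a corridor of
half-width w widens each irradiated wedge by arcsin(w/r) at radius r,
while the model's sector accounting overestimates the un-swept area;
the two effects cancel near theta ~ 125 degrees and the acceptance
fixture solves there (expected_V5 = 2/3). For extreme spans
(theta below ~95 or above ~165 degrees) the model's error exceeds 5 pp
for any realistic corridor — and on the anthropomorphic phantom, whose
lungs sit well inside the blur zone, the model's restricted volume is a
substantial overestimate. This is a faithful property of the published
model, not of the implementation: clinically it functions as a
calibrated heuristic, with apertures conformal rather than
corridor-wide. Consequently the self-consistency check (spared fraction
meets 1 - expected_V5 within 5 pp) is asserted on the idealized
geometry only, and all realistic-phantom claims are ordinal (partial
arcs never increase simulated lung V5; V5 is monotone in theta).

## Plan metrics

* Cumulative DVH in uniform 0.05 Gy bins; value at d = % of structure
  volume receiving >= d.
* V_x by linear interpolation between bin edges; D_x as the largest
  dose at which coverage is still >= x%, interpolated into the crossing
  bin — so D_100 is the minimum structure dose to within one bin.
* HI = D5/D95 (acceptable 1.00-1.40); a D95 below one bin width is
  treated as zero and HI is refused rather than returned as a huge
  number.
* CI = (volume receiving >= the prescription) / PTV volume (acceptable
  0.9-2, tolerable 2-2.5), reference isodose at 100% of prescription.
* Constraint table: cord max < 45 Gy; mean heart dose < 34 Gy, heart
  V40 < 50%; mean lung dose < 20 Gy and V20/V15/V10/V5 <= 20/30/50/55%
  for whole, right and left lung. Comparators are exactly as stated
  (strict for cord/heart/mean doses, inclusive for lung V-levels); a
  missing metric raises instead of silently passing.

## Gamma index

Global-normalization gamma (criterion dose as % of the reference
maximum), 3%/3mm by default, 10% low-dose cutoff, 95% passing
threshold. The minimization over the evaluated distribution samples
displacements on a lattice of pitch DTA/10 inside a sphere of 3 x DTA,
with linear interpolation of the evaluated grid, visiting displacements
in order of increasing radius and retiring points whose running minimum
can no longer improve (the identical-field case terminates after one
batch). Singleton axes are squeezed, so planar fields work unchanged.
Reported gamma values are capped at the search radius. The test suite
checks the implementation against an exhaustive windowed search on an
upsampled lattice; on fields with clinically plausible gradients the
two agree exactly, and the implementation is bit-exact against a
same-lattice exhaustive search. Note that for fields whose dose
gradient is large relative to the dose criterion the pass boundary in
displacement space becomes razor-thin and *any* two discretizations of
the continuous search can disagree on borderline points.

## Reproducibility

`run_pipeline` executes phantom -> measurement -> solve -> sequencing ->
simulation (FA and OPA) -> metrics and writes plan JSON, DVH CSVs, a
comparison table and a `report.json` whose bytes are identical across
reruns of the same configuration (no timestamps; provenance is a hash
of the scientific configuration plus the package version). All
randomness (phantom jitter) flows from explicit seeds.

Problem sizes used by the automated checks: unit tests run phantoms at
4-6 mm voxels; the acceptance-grade geometry checks use 3 mm (about
0.5 M lung voxels on the idealized phantom) and a ten-phantom sweep at
4 mm spanning tumor lengths 6.3-25.2 cm; the solver-vs-root-finder
comparison uses 1000 randomized geometries. These sizes were chosen so
every result is stable at the stated tolerances while the whole suite
stays interactive.

## Known limitations

* The dose model has no scatter, divergence, heterogeneity or MLC
  modulation; absolute DVH values are not comparable to clinical plans.
* Inverse optimization, monitor units and delivery-time prediction are
  out of scope; machine settings (maximum seconds per arc, leaf-motion
  constraint) are carried as configuration provenance only.
* E/Lt/T measurement uses maximal extents on centroid planes; for
  concave targets a global bounding-box mode is provided
  (`extent_mode="bbox"`) but no contour-based measurement exists.
* The restricted-volume model itself overestimates sparing at extreme
  arc spans (see above); the solver reports, and the package tests,
  exactly what the model claims.
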