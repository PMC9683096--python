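# Methods

This note records the models, numerical choices and limitations behind
tandemflow, in the order the pipeline runs them.

## Scope and assumptions

The package post-processes already-segmented vessel wall surfaces,
skeletons (centerlines), and CFD field series. Blood is assumed
incompressible and Newtonian (defaults: dynamic viscosity 0.0035 Pa·s,
density 1066 kg/m³) with rigid no-slip walls; these constants are carried
in `Config` for provenance and unit bookkeeping — no flow is solved here.
Geometry is stored in the unit it was read in (mm for clinical meshes);
`Config.length_unit_scale` (default 10⁻³) converts to SI where physics
needs it. Field series follow the convention of 100 uniformly spaced
instants over one cardiac cycle; any uniform sampling ≥ 2 is accepted.

## Vascular restoration

An aneurysmal segment is defined by two arc-length positions `s_in < s_out`
on the skeleton. Cut planes are normal to the skeleton tangent (the
conventional reading of a vessel "cross-section"). The restoration:

1. measures both cross-sections: the mesh–plane intersection loop nearest
   the plane origin, its enclosed planar area `A`, and the equivalent
   diameter `d = 2√(A/π)`;
2. clips away all wall strictly between the planes (plane slicing with
   triangle splitting; each cut must yield exactly one closed loop);
3. lofts an open tube along the skeleton with diameter **linear in arc
   length** from `d_in` to `d_out` — the simplest reading of a "uniformly
   changing" diameter — with rings oriented by **rotation-minimizing
   (double-reflection) frames**. Frenet frames are deliberately not used:
   they flip at inflection points and would twist the tube;
4. stitches each tube end ring to its cut loop with a greedy "zipper"
   triangulation between the two closed polylines (orientation aligned by
   projected signed area, start correspondence by nearest point). End
   stations are inset by 10⁻⁴ of the segment length so ring and loop
   vertices can never coincide and produce zero-area triangles;
5. optionally applies Taubin (λ/μ = 0.5/−0.53, volume-preserving)
   smoothing restricted to a 2-ring band around the junction seams
   (default 5 passes; the demo uses 3), then verifies watertightness.

Vertices outside the clipped region are bit-identical to the input, which
is what makes Model A's restored segments vertex-identical to the
corresponding segments of Models P and D. `build_model_variants` sorts the
two segments by arc length, so argument order is immaterial; Model A is
produced by restoring the distal segment of Model P. The loft refuses
stations where the local skeleton curvature radius drops below the tube
radius (self-intersection). Restoration at bifurcations with more than two
branch stubs is out of scope.

## Region-of-interest localisation

The only annotation is the aneurysm neck: a plane plus a closed 3D curve
around the ostium (≥ 8 points, not necessarily planar). Wall points are
projected **orthogonally along the neck-plane normal** into a fixed
in-plane basis; a point is inside the inception region when the neck curve
winds ≥ 360° − tol around its projection (default tol = 1°, since discrete
curves rarely close the angle exactly). Two disambiguations are needed
because a tube has two walls projecting inside the neck curve:

* a candidate band — only vertices within 2 neck diameters of the plane on
  the vessel side are tested;
* a normal filter — the vertex's outward normal must face the neck plane
  (the far wall faces away).

Triangles join the patch when **all three** vertices qualify (conservative;
`triangle_rule="any"` is available). The ROI area is then a slight lower
bound of the true footprint.

## Surface indicators

All cycle integrals use the trapezoidal rule on the periodically extended
uniform series, which reduces to the sample mean; the quadrature error on
smooth integrands is O(1/n²) in the number of time points.

* **TAWSS** is the cycle mean of |τ| per vertex.
* **AFI** at an instant is the cosine between τ(t) and the cycle-mean
  vector τ_av. Where |τ(t)||τ_av| < 10⁻¹², the angle is undefined; the
  value is set to 1 and the vertex flagged. A *pure* sine reversal has
  τ_av ≡ 0 exactly and is therefore entirely flagged — the `reversing`
  generator takes a `bias` parameter to exercise AFI on a field whose
  direction still flips but whose mean is nonzero (there AFI = −1 exactly
  during reversal). `min_afi` gives the pointwise cycle minimum.
* **GON** needs the in-surface WSS gradient `G = (∂f_p/∂p, ∂f_q/∂q)`:
  per-vertex tangent frames (p, q, n) are built once — n as the
  area-weighted face-normal average, p as the tangential projection of a
  global reference axis (fallback axis when near-parallel), q = n × p —
  and τ is decomposed into (f_p, f_q). Gradients are per-face linear
  (hat-function) gradients, area-averaged to vertices; only the two
  diagonal derivative components enter G. Where the cycle integral of |G|
  is below 10⁻¹⁴ the vertex is flagged and GON set to 0 (e.g. end-cap
  apexes of a phantom where τ has no tangential component). GON is
  clipped to [0, 1] against rounding. Note that G depends on the tangent
  frame convention; frames must rotate with the geometry for GON to be
  rigid-motion invariant, which `gon(series, frames)` supports explicitly.

The oscillatory shear index is intentionally absent: it is strongly
collinear with AFI and would not add an independent vote.

## Q-criterion and vortex cores

Per-tetrahedron velocity gradients come from linear shape functions
(exact for affine fields, hence the solid-rotation/shear/strain benchmarks
hold to rounding error). `Q = ½(‖Ω‖²_F − ‖S‖²_F)`; positive Q means
rotation dominates strain. Cores are built by thresholding at a fraction
(default 0.08) of the **positive peak Q at peak systole** (peak systole =
argmax of the inflow waveform) and grouping tets by shared-face
connectivity; components are sorted by volume. Q values positive only at
rounding level — below 10⁻¹² of the squared velocity-gradient scale — are
treated as non-positive, so analytically shear-only flows (Poiseuille)
yield an empty core set rather than noise components. An empty set is a
valid result.

## Morphology

Skeletons from segmentations are noisy, so curvature is never taken from
finite differences of raw points: `resample_centerline` fits a cubic
smoothing spline (residual budget ≈ 0.1 of the resampling step per point)
and resamples uniformly in arc length; `curvature_profile` differentiates
an interpolating cubic spline of the resampled points. For analytically
clean curves the smoothing budget itself is the dominant error source, so
closed-form validations (circle, helix) pass `smoothing=0`. Summary
statistics exclude the first and last two samples, where spline
derivatives are unreliable. If the interior maximum curvature is below
10⁻⁹ mm⁻¹ the curve is reported as having **no** curvature maximum rather
than an arbitrary argmax (a straight or constant-curvature skeleton has no
meaningful one). DM is the endpoint chord over the arc length; a closed
loop returns the boundary value 0 with a warning.

## Grading and voting

Triangle indicator value = mean of its three vertex values (optional
sub-triangulation refinement is not implemented; the triangle areas of the
patch are the "fragments"). The pre and post ROI values are pooled and the
pooled min..max split into 4 equal-width grades, making pre and post areas
directly comparable. The risk grade is the top grade for TAWSS and GON and
the bottom grade for AFI (strongly negative AFI is the risk factor). When
the pre risk area is < 10⁻⁶ of the patch area the ratio is computed
against that floor and flagged `degenerate` — this happens legitimately
when the retained aneurysm pushes the post field beyond the entire pre
range, as the demo's AFI does (AFI's cosine saturates near 1, so its pre
spread is naturally tiny). A constant pooled field is ungradeable and
raises. The vote is strict majority over {TAWSS, AFI, GON}: larger ratio
wins an indicator (ties within 10⁻⁹ are surfaced as ties, not resolved);
≥ 2 votes call the model, otherwise the case is indeterminate.

## Synthetic phantoms and fields

The phantom is a tube of radius r(s) (constant or linearly tapered) swept
along a line / circular-arc / seeded-spline centerline with
rotation-minimizing frames, capped with end fans to be watertight.
Each aneurysm is an outward radial bump

    d(s, φ) = A · f(q),   f(q) = exp(k(1 − 1/(1−q²))),  q < 1,  k = 0.5,

with q the elliptic coordinate √(Δs² + (rΔφ)²)/w for width w. The bump is
C∞ and **compactly supported**, so clean and diseased meshes are identical
outside the support; the ground-truth inception footprint (triangles
displaced by > 10⁻⁶·r) and the neck curve (the 5%-of-amplitude level set,
resampled to 64 points) are then nearby nested level sets — with a
Gaussian bump the 10⁻⁶ footprint would be several times larger than any
practical neck, making footprint-overlap validation meaningless. Bulge
supports may not overlap (tandem, not fused). Default grid m = 48 rings of
n = 140 stations (~11.5k triangles) keeps the full demo under ten seconds;
ROI-overlap validations use m = 64, n = 200, where the conservative
triangle rule costs a one-to-two-triangle rim and the measured Jaccard
against ground truth is ≈ 0.82–0.87 (the analytic ceiling from the two
level-set radii is ≈ 0.89).

Analytic WSS kinds (steady, pulsating magnitude, reversing with optional
bias, rotating-in-tangent-plane) have closed-form TAWSS/AFI/GON values;
optional spatial modulation (linear gradient, Gaussian hotspots) gives the
fields structure. Velocity kinds (solid rotation, pure shear, planar
strain, Poiseuille, Lamb–Oseen) have known ∇u structure; tet meshes come
from a Kuhn-subdivided box lattice (face-compatible across cubes, so
face-connectivity is meaningful), optionally carved to a cylinder. The
cardiac waveform is a positive, periodic, single-peaked von-Mises-shaped
pulse — a stand-in defining peak systole (argmax) and mid-diastole
(argmin), not a calibrated physiological waveform.

The demo flow field is phenomenological: a pulsatile axial WSS with an
axially modulated magnitude plus a cross-flow oscillation whose strength
decays with distance to the apex of any *retained* aneurysm (influence
width 10 mm). What passing tests show is that the geometric and indicator
machinery is correct; they do not validate any physiological claim about
real tandem-aneurysm hemodynamics, which would require patient-specific
CFD.

## Determinism and report

`run_case` is deterministic given the config: the only randomness (spline
centerlines) is seeded, and reports are written with sorted keys and
floats rounded to 9 digits, so reruns are byte-identical. Stage failures
raise a stage-tagged error after writing a partial manifest. Problem sizes
used by the test-suite and the acceptance script (phantom grids up to
m = 64 × n = 200, tet lattices up to ~3·10⁴ cells, 100 time points) were
chosen as the smallest sizes at which the discretization errors sit well
inside the validated tolerances.

## Known limitations

* Restoration handles exactly two cut loops; bifurcation stubs beyond two
  major branches are unsupported.
* The neck plane/curve is an input annotation; no automatic neck detection.
* The winding criterion plus band/normal filters can still mis-select wall
  on extremely tortuous or self-touching vessels.
* GON depends on the printed two-component gradient convention, not the
  full surface-gradient tensor; values are comparable within this package
  but not necessarily across implementations.
* The four-grade binning uses the pooled pre+post range; results differ
  from per-surface binning when the two ranges differ strongly.
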