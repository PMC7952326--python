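# Methods

This note documents the models, conventions, defaults and numerical
choices behind `eamkit`, and what the synthetic fixtures do and do not
establish about behaviour on clinical data.

## Study model and units

A study (`UserData`) holds a chamber surface, a per-point electrical
record and optional ablation data.  Units are the clinical conventions
throughout: mm for positions, ms for times, mV for voltages, Hz for
sampling, m/s (≡ mm/ms) for conduction velocity; areas and volumes are
reported in cm²/cm³ (mm²/100, mm³/1000).  Missing scalars are NaN;
derived surface fields carry an explicit per-vertex validity mask.

Annotation times are absolute on the trace clock (sample 0 at t = 0 ms);
the window of interest is stored relative to the reference annotation and
every activation annotation must fall inside it.  The relative LAT of a
point is `map_annot − ref_annot`.  Unipolar channel order is fixed as
(distal, proximal) and the bipolar sign convention is distal − proximal.
Points tagged "Location only" carry positions but no usable electrogram
and are excluded from every map computation; all metrics are invariant to
adding such points (regression-tested).

## Exchange container

One zip per study: `manifest.json` plus one CSV per array.  The design
goals are a single file (no per-point file-system overhead), no
redundancy (each unique electrogram trace is stored once and referenced
by index — the shared reference channel collapses to one row), and a
language-agnostic bit-exact text encoding: comma separation, header row,
`NaN` for missing, UTF-8, LF, floats at 17 significant digits.  Readers
must use correctly-rounded float parsing (`float_precision='round_trip'`
in pandas) — the default fast parser loses ulps.  The manifest declares
schema version, units, and every array's shape; shape mismatches raise an
integrity error naming the array, unknown arrays warn and are skipped
(forward compatibility), and unsupported schema versions are refused
outright rather than guessed at.

## Clinical-export dialect

The proprietary export schemas are not public.  The dialect read by
`parse_clinical_export` is therefore a *documented stand-in* with the
same shape as clinical exports — study-level XML, one XML + one trace CSV
per point, a mesh file, optional visitag CSVs — and is exactly the format
`emit_clinical_export` writes, so `parse(emit(study))` is the identity
bit-for-bit.  Triangle indices are 0-based; a tree declaring
`index_base="1"` is converted on read.  Per-point trace files carry the
channels reference/bipolar/two unipolars; the reference (and optionally
an ECG) column name is selectable at parse time.

## Geometry

**Boundary loops.**  Free edges (one incident triangle) are traced into
closed cycles; each loop reports perimeter, centroid, and an enclosed-area
estimate by fan triangulation to its centroid.  Non-manifold edges (≥3
incident triangles) are a topology error.

**Hole filling** caps each loop with a fan to one new centroid vertex:
deterministic, linear-time, and exact for planar rims, which clinical
valve/vein rims approximate.  All loops are filled by default; a subset
can be passed explicitly (an open flat patch has an outer rim one usually
wants to keep).

**Area** is the triangle sum of the open (`nofill`) or capped (`fill`)
mesh.  **Volume** caps the mesh, repairs winding by breadth-first
propagation across shared edges (non-orientable input is an error), and
sums signed tetrahedron volumes; the magnitude is reported, so the result
is orientation- and translation-invariant (vertices are centered first to
keep the cancellation well-conditioned; the invariance is tested to
1e-9 relative).

**Point status** classifies catheter points against the capped mesh by
ray-crossing parity, with a majority vote over three seeded ray
directions so a ray grazing an edge cannot flip the answer; the minimum
point-to-surface distance (exact point-triangle distances) is reported
alongside.

## Surface interpolation

Default scheme: Gaussian RBF with kernel width σ = 2× the mean
nearest-neighbour spacing of the sample points and ridge
λ = 1e-8·trace(Φ)/p.  The expansion is augmented with a constant + linear
polynomial tail under the standard orthogonality constraint
(`Pᵀc = 0`): a bare RBF expansion cannot reproduce even an affine field,
whereas with the tail constants and linear fields are reproduced to
rounding — the property the conduction-velocity gradient and the
linear-recovery tests rely on.  The saddle system falls back to a
minimum-norm least-squares solution when the polynomial block is
rank-deficient (coplanar sites, e.g. a flat sheet).  A pure expansion is
available (`InterpolatorSpec(poly=False)`), as are multiquadric,
inverse-distance and nearest-neighbour schemes; the non-RBF schemes obey
the data range (no overshoot) but are not differentiable.

λ = 0 requests exact interpolation; duplicate sample positions then make
the system singular and trigger an automatic fall-back to the default λ
with a warning.  Distances for the color-fill mask are Euclidean 3D
chords (matching the clinical display convention of a spatial fill
threshold, default 10 mm); geodesic masking is a possible extension.

## Activation metrics

Six TAT methods = {point annotations, clinical vertex map, re-interpolated
map} × {range, central percentile span}.  The percentile convention is
linear interpolation between closest order statistics (numpy's default),
stated here so ports agree; default q = 2.5 gives a central 95% span,
robust to isolated mis-annotations on high-density maps.  The earliest
site is the arg-min location (ties broken by lowest index) for the plain
methods; the percentile variant returns the centroid of the cohort with
LAT ≤ P_q projected back onto the surface — a deliberate design choice
where several geometric readings are defensible; the cohort centroid is
robust to a single early outlier.

## Conduction velocity

The LAT samples are fit with the differentiable RBF interpolant; at each
vertex the analytic gradient is projected onto the tangent plane (vertex
normals are area-weighted incident-triangle normals) and speed is the
reciprocal tangential slowness.  Gradient magnitudes below 1e-6 ms/mm
(plateaus, e.g. constant LAT) mark the vertex invalid rather than
producing infinite speed; speeds outside the analysis clamp (default
0–10 m/s) are clamped and flagged; the display convention is 0–2 m/s.
The CV histogram assigns each fully-valid triangle's area to the bin of
its mean vertex speed (values clamped to the outer edges so bins conserve
the total valid area) and reports area-weighted median and mean.

A caution that shapes the fixtures: for a 3D-planar wavefront crossing a
curved chamber, the *apparent* surface speed is v/sin θ ≥ v (θ the angle
between wavefront normal and surface), so on a sphere the median apparent
speed of a 1 m/s wave is ≈1.15 m/s — a property of the physics, not an
estimator error.  Quantitative speed-recovery tests therefore run on a
flat sheet (`make_planar_sheet`), where apparent and true speeds
coincide and recovery is exact to rounding; the curved-chamber pipeline
is exercised separately for invariances (LAT scaling, shifts, rigid
rotations).

## Voltage metrics

Mean chamber voltage is the area-weighted mean over triangles whose three
vertices are valid.  Low-voltage area treats the per-vertex values as a
piecewise-linear field and clips the sub-threshold region exactly within
each triangle (0, 1 or 2 isoline crossings), making the area continuous
in the threshold wherever the field has no constant region at that exact
value, and mesh-resolution independent to first order.  The strict
convention is area{v < thr}: a triangle constant at exactly the threshold
contributes nothing.  Triangles with any invalid vertex are excluded from
numerator *and* denominator of the low-voltage fraction.  The voltage
histogram uses the same kernel as cumulative differences between edges,
with values clamped to the outer edges so the bins always sum to the
considered area; the top bin is closed from above so a triangle clamped
to the upper edge is not dropped.  Defaults follow clinical convention:
threshold 0.5 mV, fill threshold 10 mm.

## Ablation

Sites carry position, surface-projected position, a *named*
lesion-quality index (platforms disagree on semantics, so the name
travels with the value), contact force (g), power (W), temperature (°C),
impedance (Ω) and duration (s), plus an optional raw grid.  Ablated area
marks every triangle whose centroid is within the influence radius
(default 5 mm ≈ a typical radiofrequency lesion radius; always an
explicit parameter) of any projected site — union semantics, so
duplicated or overlapping lesions count once, and the area is monotone in
radius and site count.  Distance is Euclidean, consistent with the
color-fill convention.

## Synthetic fixtures

The generator emulates a left-atrium-scale study: a subdivided icosphere
(default r = 30 mm, subdivision 3, ≈1280 triangles before cutting) scaled
to an ellipsoid, optionally jittered, with five angular cut-outs (one
valve-like, four vein-like) whose rims become the anatomical-structure
loops.  Activation is either 3D-planar (closed-form affine LAT) or focal
(Dijkstra shortest paths over the edge graph at speed v; edge-graph
geodesics slightly overestimate true surface distance, so planar waves
are used for quantitative CV recovery and focal waves for earliest-site
recovery).  Default wave speed 1.0 m/s, offset t0 = 40 ms.

Electrograms use a Gaussian-derivative unipolar template
`u(t) = −A·((t−t*)/τ)·exp(−(t−t*)²/2τ²)` (A = 1 mV, τ = 5 ms) whose
steepest negative slope falls exactly at t*, the conventional LAT marker;
the proximal unipole is delayed by Δ = 3 ms, the bipolar trace is their
difference plus optional seeded Gaussian noise, and the point bipolar
voltage is the noiseless peak-to-peak.  Sampling is 1 kHz.  The reference
annotation is pinned to the trace origin so the stored relative LAT
equals the imposed field value bit-exactly — which is what lets the
point-based TAT tests assert exact equality with truth.

Voltage patches are geodesic discs at a low level (default 0.2 mV on a
2.0 mV background).  Patch rim vertices are blended to the midpoint level
so that at the midpoint threshold the sub-level set is exactly
triangle-aligned and the generator can state the true sub-threshold area
in closed form (`rim='level'` gives a hard two-valued step instead).
Ablation sites draw from physiologic ranges (index 300–550, force
5–40 g, power 25–50 W, temperature 25–45 °C, impedance 80–120 Ω,
duration 10–60 s).

Same spec + seed ⇒ bit-identical fixtures.  What the fixtures do *not*
emulate: fibrosis texture, anisotropic conduction, reentry, far-field
contamination, mapping-catheter geometry, or annotation error.  Passing
tests therefore establish correctness of the computations and formats,
not clinical accuracy of any derived metric; published comparisons of
similar pipelines against clinical systems report good but imperfect
agreement, and this package documents its own definitions (e.g. which
mesh the volume uses) rather than matching any vendor's.

## Problem sizes and determinism

The default test fixtures use subdivision-3 chambers (≈600 vertices),
120–200 mapping points, 160–256-sample traces and a 21×21 flat sheet;
`scripts/acceptance.py` additionally runs one 500-point study for the
round-trip and storage checks.  All randomness flows from explicit seeds
(`numpy.random.default_rng`); the CLI's `--seed` makes whole pipelines
reproducible, and same-seed runs produce bit-identical containers and
metrics.

## Known limitations

- LAT re-annotation from raw electrograms is out of scope: activation
  times are taken as annotated by the source system (or the generator).
- Only the RBF-gradient CV method is implemented; triangulation,
  omnipole, cosine-fit and polynomial-fit methods are not.
- No bit-compatible parsing of proprietary vendor exports; the dialect is
  a stand-in with the same structure.
- Geodesic variants of the color-fill mask and ablation distance are not
  implemented (Euclidean chords throughout).
- 12-lead ECG storage, fractionation indices, late potentials and
  segmental analysis are not modelled.
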