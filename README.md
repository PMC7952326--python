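# eamkit

Electroanatomic-mapping (EAM) systems guide catheter ablation procedures by
pairing a triangulated chamber geometry with spatially localized
intracardiac electrograms.  The data these systems export is scientifically
rich — activation times, bipolar voltages, ablation-lesion parameters — but
locked in sprawling proprietary file trees that are hard to parse and
wasteful to store.  `eamkit` is a Python toolkit for electrophysiology
researchers that provides:

- **A compact exchange container** — one `*.openep.zip` per study holding a
  JSON manifest plus CSV arrays (17-significant-digit floats, so read-back
  is bit-exact).  Identical electrogram traces are stored once and indexed,
  and the whole study lives in a single file.
- **A parser for a documented clinical-export-style dialect** — a study
  descriptor XML, a mesh XML, per-point XML + trace CSV files and optional
  ablation (visitag) CSVs.  This dialect mirrors the *structure* of clinical
  exports; it is a documented simplification, not a bit-compatible reader
  for any vendor format.
- **An analysis suite** covering chamber geometry, activation mapping,
  conduction velocity, voltage mapping, electrogram display and ablation
  quantification.
- **A synthetic-study generator** producing chamber shells, wavefronts,
  voltage fields and electrograms with known ground truth, so every
  analysis stage is testable without clinical data.

## The quantities at the core

For a chamber surface with vertices X and triangles T, and per-point local
activation times (LAT) `t_i = map_annot_i - ref_annot_i` and bipolar
voltages `v_i`:

- **Surface area / volume** — triangle-area sums on the open mesh
  (`nofill`) or after capping each free-boundary rim with a centroid fan
  (`fill`); volume by the divergence theorem, `V = |Σ det[a,b,c]/6|`, after
  breadth-first winding repair.
- **Total activation time (TAT)** — `max − min` (or the central
  `P_{100−q} − P_q` percentile span, default q = 2.5) of the LAT population,
  taken from the points, the clinical surface map, or a re-interpolated map
  (six methods in all).
- **Surface interpolation** — a Gaussian radial-basis-function interpolant
  `s(x) = Σ c_i φ(‖x − x_i‖) + d_0 + d·x` with `(Φ + λI)c + Pd = y`,
  `Pᵀc = 0`; vertices farther than a color-fill threshold (default 10 mm)
  from every mapping point are masked.
- **Conduction velocity** — `CV = 1/‖∇s − (∇s·n̂)n̂‖` from the analytic RBF
  gradient projected onto the local tangent plane (mm/ms ≡ m/s), with a
  plateau guard and a physiologic clamp; display convention 0–2 m/s.
- **Low-voltage area** — surface area with interpolated bipolar voltage
  below a threshold (default 0.5 mV, the conventional atrial scar
  surrogate), computed exactly per triangle by isoline clipping of the
  linear field.
- **Ablation area** — union of triangles whose centroids lie within an
  influence radius (default 5 mm) of any projected lesion site.

## Worked example

Generate a synthetic left-atrium-scale study (planar wavefront at 1 m/s, a
low-voltage patch, 20 ablation sites), emit it as a clinical-dialect tree,
import it into a container, and quantify it:

```sh
$ eamkit synth --preset planar --seed 42 --visitag-sites 20 \
    -o export_tree --container study.openep.zip
$ eamkit info study.openep.zip
system: synthetic
mapping points: 100 (+0 location-only)
trace: 1000 samples @ 1000 Hz
mesh: 607 vertices, 1146 triangles, fields ['act', 'bip']
ablation sites: 20 (AblationIndex)

$ eamkit metrics study.openep.zip --area --volume --tat ptbased \
    --mean-voltage map --lva map --ablation-area
area_nofill_cm2: 100.441
area_fill_cm2: 112.939
volume_cm3: 111.057
tat_ptbased_ms: 58.7049
mean_voltage_map_mv: 1.95768
low_voltage_area_map_cm2: 0.989035
low_voltage_fraction_map_pct: 0.984695
ablation_area_cm2: 12.5009
```

Reading the numbers: the open chamber (valve + vein cut-outs left open)
measures 100.4 cm²; capping the five rims raises it to 112.9 cm², close to
the 113.1 cm² of the underlying 30 mm sphere, and encloses 111.1 cm³.  The
point-based TAT of 58.7 ms is exactly the spread of the generator's
activation annotations across the sampled points.  Mean bipolar voltage
sits just below the 2.0 mV background because of the low-voltage patch,
which occupies ~1% of the surface; the 20 lesions cover 12.5 cm².

Maps and electrograms render to image files:

```sh
eamkit map study.openep.zip --type act --orientation ap -o act.png
eamkit map study.openep.zip --type cv --color-axis 0,2 -o cv.png
eamkit map study.openep.zip --visitags --color-by index_value -o lesions.png
```

The same operations are available as library functions
(`eamkit.get_area`, `eamkit.total_activation_time`,
`eamkit.compute_conduction_velocity`, `eamkit.low_voltage_area`,
`eamkit.get_ablation_area`, ...), all operating on the `UserData` study
record.

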