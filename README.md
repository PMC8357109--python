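# airwaykit

Preoperative prediction of upper-airway geometry changes for
maxillomandibular advancement (MMA) planning.

MMA surgery moves the maxilla and mandible forward to enlarge the pharyngeal
airway in obstructive sleep apnea treatment. Planning it benefits from a
quantitative preview: given a preoperative CT-derived STL surface of the
nasal cavity and pharynx, how will the airway lumen change, and does the
predicted geometry make sense against follow-up imaging and rhinomanometric
measurements? `airwaykit` provides that pipeline for oral surgeons and CFD
engineers:

* **STL geometry I/O** — ASCII/binary read/write, validation, Taubin
  smoothing that does not shrink the lumen.
* **Pivotal-plane deformation** — a C1-smooth displacement field controlled
  by three horizontal planes. The geometry is fixed above the top plane and
  behind the spine-side wall; the middle and lower planes each carry an
  anteroposterior enlargement `dY` and a half-to-peak lateral widening
  `dX` supplied from surgical experience.
* **Cross-section dimensioning** — closed contours on any horizontal plane
  with `Ys` (spine-side extreme), `Yc` (anterior extreme on the mid-sagittal
  line), width, depth and area, plus pre/post comparison and plot-ready
  export.
* **Target fitting** — iteratively choose `dY`/`dX` so the predicted
  sections reproduce postoperative widths or areas ("follow-up prediction").
* **Respiratory metrics** — anterior-rhinomanometry resistance
  `R = (P1 - P2)/F` per naris, parallel-circuit total
  `R_L R_R / (R_L + R_R)`, grid-refinement convergence assessment, and CFD
  case metadata export (mass-flow inlet / static-pressure outlet, ambient
  1.013e5 Pa, 25 °C, viscosity 1.822e-5 Pa·s).
* **Synthetic airway** — a parametric two-naris/one-pharynx surrogate with
  analytically known elliptical cross-sections, so the whole pipeline is
  testable without patient data.

## The deformation model

Coordinates follow the CT patient frame: x right-to-left, y face-to-back,
z foot-to-head, lengths in mm. For each controlled plane `i` at height
`z_i`, a piecewise-quadratic C1 axial profile `B_i(z)` equals 1 at `z_i`,
reaches 0 with zero slope at the top plane, and extends as a constant below
the lower plane. The displacement at a point `(x, y, z)` is

```
Δy = -dY(z) · ((y - Ys(z)) / (Yc(z) - Ys(z)))²        for y < Ys(z), else 0
Δx =  dX(z) · sign(x - x_c) · min(((x - x_c)/w_half)², 1) · G(y)
Δz =  0
```

with `dY(z) = Σ B_i(z) dY_i`, `dX(z) = Σ B_i(z) dX_i`, per-plane anatomy
(`Ys`, `Yc`, mid-sagittal `x_c`, half-width `w_half`) measured from the
preoperative mesh and interpolated quadratically in z, and `G(y)` a C1
smoothstep that releases the lateral push near the fixed spine side. The
field is C1 everywhere, zero on the fixed regions, linear in the four
parameters, and exact at the control planes: the achieved depth increase at
a controlled plane equals `dY` and the width increase equals `2·dX`.

## Worked example

```python
from airwaykit import (DeformationConfig, PivotalPlaneSpec, SyntheticAirwaySpec,
                       compare_sections, deform_mesh, generate_airway, slice_mesh)

mesh = generate_airway(SyntheticAirwaySpec())      # surrogate airway
config = DeformationConfig(
    top_plane=PivotalPlaneSpec(z=-566.0, label="fixed"),
    middle_plane=PivotalPlaneSpec(z=-587.0, label="tip of soft palate",
                                  dY=4.0, dX_half=1.0),
    lower_plane=PivotalPlaneSpec(z=-610.0, label="tip of epiglottis",
                                 dY=6.0, dX_half=2.0),
)
predicted = deform_mesh(mesh, config)
result = compare_sections(slice_mesh(mesh, -587.0), slice_mesh(predicted, -587.0))
print(f"achieved dY = {result.achieved_dY:.3f} mm, "
      f"dX total = {result.achieved_dX_total:.3f} mm, "
      f"area ratio = {result.area_ratio:.3f}")
```

prints

```
achieved dY = 4.000 mm, dX total = 2.000 mm, area ratio = 1.430
```

i.e. at the soft-palate plane the anteroposterior diameter grew by the
requested 4 mm, the width by twice the half-to-peak 1 mm, and the section
area by 43%.

The same workflow is scriptable from the shell:

```
airwaykit synth --out airway.stl
airwaykit deform airway.stl --config config.json --out predicted.stl
airwaykit slice predicted.stl -z -587 -z -610
airwaykit refine refinement.csv --tolerance 0.10
airwaykit resist pressure_flow.csv
```

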