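# Methods

## Problem setting

Maxillomandibular advancement enlarges the pharyngeal airway; the toolkit
predicts that enlargement on the preoperative CT-derived STL surface. All
geometry lives in the DICOM patient frame (x right-to-left, y face-to-back,
z foot-to-head; mm). The anterior airway wall is therefore the low-y side
and the spine-side wall the high-y side, and "horizontal" planes are
constant-z planes.

## Pivotal-plane deformation

Three horizontal control planes bound the deformation: a top plane
(z maximum) above which the geometry is fixed, and a middle and a lower
plane that each carry two surgeon-supplied parameters — `dY`, the increase
of the anteroposterior airway diameter, and `dX`, the half-to-peak lateral
widening. Points at or behind the spine-side wall (y ≥ Ys at their height,
minus an optional `spine_fix_margin`) never move; `Δz = 0` everywhere.

**Axial profile.** Each parameter is carried along z by a piecewise-
quadratic profile f with f(z_lower) = d_lower, f(z_middle) = d_middle,
f(z_top) = 0, f′(z_top) = 0, and f′(z_lower) = 0 so the constant extension
below the lower plane (which keeps the outlet section shape consistent) is
C1. The span from top to middle is a single quadratic with a double root at
the top plane; the lower-to-middle span needs four boundary conditions
(value and slope at both ends), one more than a single quadratic carries,
so it is built from two quadratic pieces joined C1 at the span midpoint.
The profile is linear in (d_lower, d_middle), so the whole field is linear
in the four parameters.

**In-plane weights.** The anterior push is `-dY(z)·Wy(y)` with
`Wy = ((y − Ys)/(Yc − Ys))²`: weight 1 at the anterior extreme Yc, fading
to zero with zero slope at Ys. The lateral push is antisymmetric about the
mid-sagittal x: `dX(z)·sign(x − x_c)·min(((x − x_c)/w_half)², 1)`, zero
with zero slope at x_c (both one-sided derivatives vanish) and full
strength at the lateral walls. Because the stated fixed region is a
constraint on the *whole* displacement vector, the lateral component is
additionally gated by a C1 quadratic smoothstep in y that is 1 at the
height of the section's widest point and decays to zero with zero slope at
Ys; this was a genuinely open design point, and the gate was chosen so that
the width achieved at the widest point is untouched while the spine-side
zero set is exact.

**Anatomy interpolation.** Per-plane anatomy (Ys, Yc, x_c, w_half, and the
widest-point height) is measured from the preoperative mesh at each pivotal
plane (largest-area contour when a slice yields several, e.g. at nasal
levels) unless supplied explicitly, and interpolated between planes by the
unique quadratic through the three plane values — smooth in z, exact at the
planes. The model is intended for the single-lumen pharyngeal region below
the nasal confluence.

**Consequences.** The field is C1 in x, y and z everywhere except at the
clamp level |x − x_c| = w_half of the lateral weight (a deliberate bound on
how far the widening extrapolates); it vanishes identically above the top
plane and behind the spine-side wall; with non-negative parameters every
cross-section mapping is expansive, so section areas never shrink; and the
achieved enlargement at a controlled plane equals the input exactly — the
depth grows by dY and the width by 2·dX. That exactness at the control
point is a deliberate formulation choice (it also makes the fitter's update
rule a unit-gain step); a formulation that trades control-point exactness
for other smoothness properties could undershoot the input by a few
percent without violating any of the stated constraints.

## Cross-section dimensioning

Plane-mesh intersection and contour chaining are delegated to trimesh; the
plane is nudged by 1e-9 mm so vertices exactly on it fall on a consistent
side. Contours must close within 1e-6 mm; an open chain (surface not
watertight at that height) is an error reporting the gap. Area is the
shoelace formula summed over contours; Ys, width and depth come from the
union of contour points. Yc is the minimum y among points within ±0.5 mm of
the mid-sagittal x — the midline is only defined up to discretisation, and
a 0.5 mm band keeps the estimate on the midline without being hostage to
one vertex. x_c is the midpoint of the x-extremes of the (largest)
contour; nothing in the formulation depends on a centroid.

## Target fitting

Follow-up prediction inverts the model: given postoperative section widths
or areas at the controlled planes, find the parameters. Width targets use
an undamped difference step (`dY += target_depth − achieved_depth`,
`dX += (target_width − achieved_width)/2`) — exact in one step because the
field responds linearly with unit gain at the control planes, so
convergence takes one productive iteration plus one verification pass.
Area targets respond nonlinearly, so the step is multiplicative and
0.5-damped: both parameters grow by `0.5·(√(target/achieved) − 1)` times
the current section dimensions. Parameters are clamped at zero (the model
only enlarges); both planes are fitted simultaneously (their control-plane
responses are decoupled by construction: each plane's basis vanishes at the
other controlled plane); non-convergence within `max_iterations` is
reported in the result, never raised.

## Respiratory metrics

Per-naris resistance is `R = (P1 − P2)/F` (Pa·s/cm³) from the anterior
rhinomanometric method, in which the contralateral naris is plugged and
serves as a static-pressure tap for P2. The total nasal resistance is the
parallel-circuit combination `R_L R_R/(R_L + R_R)`. When reading a
resistance off a measured pressure–flow curve, flow is linearly
interpolated at a reference Δp of 100 Pa (the international
anterior-rhinomanometry convention; the reference is a parameter), and
extrapolation outside the measured range is refused.

Grid-refinement assessment takes a series of (cell count, Δp) pairs from
repeated CFD solves of the same case and recommends the smallest mesh
whose Δp lies within a relative tolerance (default 10%) of the finest
mesh's — a plateau criterion, not a Richardson extrapolation, matching how
such series are read in practice. CFD itself is out of scope; the toolkit
only exports case metadata (ambient 1.013e5 Pa, 25 °C, air viscosity
1.822e-5 Pa·s, mass-flow inlet, static-pressure outlet, residual < 1e-6 or
mass-flow imbalance < 0.5%, near-wall y+ in 2–5) for an external solver.

## Synthetic airway

The surrogate is a pharyngeal tube with elliptical sections — semi-axes
a(z), b(z) and centre offset c(z) given as polynomials — that splits at a
confluence plane into two circular nasal branches, closed by end caps and
a flat confluence shoulder. The shoulder (an ellipse with two circular
holes) is triangulated by cutting along the mid-sagittal chord and zipping
each half between its boundary loops by angular merge, which keeps every
edge shared by exactly two facets. Defaults emulate an adult pharynx in
the patient frame: z from −620 to −560 mm, a = 10 mm, b = 6 mm,
c = −16 mm, nasal radius 3.5 mm at ±6 mm, one ring per mm, 64 vertices per
ring (a multiple of 4, so the x- and y-extreme vertices lie exactly on the
axes and dimensioning checks are sharp).

The elliptical part has closed-form section metrics (area πab, Ys = c + b,
Yc = c − b), used as the slicing oracle: an inscribed n-gon underestimates
the ellipse area by ~(2π²/3)/n², i.e. 0.16% at 64 vertices per ring and
0.01% at 256, which is what the precision tests assert against. The seed
only drives optional radial surface noise for smoothing tests; the
geometry itself is deterministic.

What the surrogate does **not** emulate: turbinates, paranasal sinuses,
mucosal texture, non-convex pharyngeal outlines, or oblique airway axes.
Tests passing on it validate the geometric machinery (slicing, field
construction, fitting), not the clinical accuracy of a prediction on real
anatomy — the spine-side wall shape in particular is known to be the
model's weakest feature.

## Numerical choices and problem sizes

Vertex-merge tolerance 1e-6 mm on STL read; contour closure 1e-6 mm;
plane nudge 1e-9 mm; degenerate-facet area threshold 1e-12 mm²; fitting
tolerances 0.05 mm (widths) and 0.5% (area) with at most 50 iterations;
Taubin smoothing uses λ = 0.5·strength with the 0.1-pass-band μ. Test and
acceptance runs use the default 64-vertex/ring surrogate (~11k facets) and
a 256-vertex/ring variant for the high-precision slicing checks; the
parameter-recovery study draws (dY, dX) uniformly over [0, 8] × [0, 4] mm.

## Known limitations

The lateral weight is clamped at full strength beyond the measured
half-width, so the field is only C0 across that clamp; anatomy
interpolation is a global quadratic and can degrade if the three planes'
anatomy is wildly non-monotone; the deformation assumes a single lumen
between the pivotal planes; and the fitter's symmetric lateral split cannot
represent asymmetric (left/right-unequal) widening.
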