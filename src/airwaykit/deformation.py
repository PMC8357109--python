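"""Pivotal-plane deformation of the pharyngeal airway.

The model enlarges the pharyngeal lumen between three horizontal control
("pivotal") planes, emulating the soft-tissue response to
maxillomandibular advancement.  z runs foot-to-head, y runs
face-to-back, so the anterior airway wall is the low-y side and the
spine-side wall is the high-y side.

* Above the **top** plane (z maximum) the geometry is fixed.
* The **middle** and **lower** planes each carry two surgeon-supplied
  parameters: ``dY`` (increase of the anteroposterior diameter, applied as a
  forward/-y push of the anterior wall) and ``dX_half`` (half-to-peak
  lateral widening, applied symmetrically about the mid-sagittal x).
* Points on or behind the spine-side wall (y >= Ys at their height) never
  move.

All blending uses piecewise-quadratic functions with matched first
derivatives, so the displacement field is C1 in x, y and z and the deformed
wall stays uniformly smooth.  The field is built so the enlargement achieved
at a control plane's anterior extreme equals ``dY`` exactly (and the width
gain at the widest point equals ``2 * dX_half`` exactly), and it is linear
in the four parameters — which is what makes iterative target fitting
converge in a couple of steps.

Axial profile
-------------
Each parameter d is interpolated along z through (z_lower, d_lower),
(z_middle, d_middle), (0 at z_top with zero slope).  The top span is a
single quadratic; the lower span uses two quadratic pieces joined C1 at the
span midpoint so that the profile also has zero slope at the lower plane,
making the constant extension below it (which keeps the outlet section
shape consistent) C1 as well.

In-plane weights
----------------
The anterior push is ``-dY(z) * Wy(y)`` with ``Wy = ((y - Ys)/(Yc - Ys))^2``
for y < Ys and 0 beyond: weight 1 at the anterior extreme Yc, fading with
zero slope into the fixed spine side.  The lateral push is
``dX(z) * S(x) * G(y)`` where ``S = sign(x - x_c) * min(((x - x_c)/w_half)^2, 1)``
(zero with zero slope at the mid-sagittal x, full strength at the lateral
walls) and ``G`` is a quadratic smoothstep in y that is 1 at the height of
the widest point and fades to 0 with zero slope at Ys, so the lateral
component also vanishes on the fixed spine side.

Per-plane anatomy (Ys, Yc, mid-sagittal x, half-width, widest-point y) is
taken from the preoperative mesh when not supplied, and interpolated
between the planes by the quadratic through the three plane values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .cross_section import slice_mesh
from .errors import ParameterError, SliceRangeError
from .geometry_io import TriangleMesh


class PivotalPlaneSpec(BaseModel):
    """One control plane: height, wall anatomy and enlargement parameters.

    ``Ys``/``Yc`` mirror the planning table convention (maximum y of the
    pharynx wall; minimum y on the mid-sagittal line).  ``x_c``, ``w_half``
    and ``y_wide`` complete the lateral anatomy and are normally estimated
    from the preoperative mesh.
    """

    z: float
    label: str = ""
    Ys: float | None = None
    Yc: float | None = None
    dY: float = Field(default=0.0, ge=0.0)
    dX_half: float = Field(default=0.0, ge=0.0)
    x_c: float | None = None
    w_half: float | None = None
    y_wide: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "PivotalPlaneSpec":
        if self.Ys is not None and self.Yc is not None and not self.Yc < self.Ys:
            raise ParameterError(f"plane z={self.z:g}: Yc must be < Ys")
        if self.w_half is not None and self.w_half <= 0:
            raise ParameterError(f"plane z={self.z:g}: w_half must be positive")
        return self

    @property
    def anatomy_complete(self) -> bool:
        return None not in (self.Ys, self.Yc, self.x_c, self.w_half, self.y_wide)


class DeformationConfig(BaseModel):
    """Three pivotal planes plus the spine-side fixing margin.

    The top plane is the fixed boundary and must carry zero parameters;
    planes must be ordered ``lower.z < middle.z < top.z`` (z foot-to-head).
    """

    top_plane: PivotalPlaneSpec
    middle_plane: PivotalPlaneSpec
    lower_plane: PivotalPlaneSpec
    spine_fix_margin: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "DeformationConfig":
        if not self.lower_plane.z < self.middle_plane.z < self.top_plane.z:
            raise ParameterError(
                "pivotal planes must satisfy lower.z < middle.z < top.z "
                f"(got {self.lower_plane.z:g}, {self.middle_plane.z:g}, "
                f"{self.top_plane.z:g})"
            )
        if self.top_plane.dY != 0.0 or self.top_plane.dX_half != 0.0:
            raise ParameterError("the top (fixed) plane must have dY = dX_half = 0")
        return self

    @property
    def planes(self) -> tuple[PivotalPlaneSpec, PivotalPlaneSpec, PivotalPlaneSpec]:
        """Bottom-to-top ordering (lower, middle, top)."""
        return (self.lower_plane, self.middle_plane, self.top_plane)


@dataclass
class PlaneAnatomy:
    """Wall anatomy measured on one horizontal plane."""

    Ys: float
    Yc: float
    x_c: float
    w_half: float
    y_wide: float


def estimate_plane_anatomy(mesh: TriangleMesh, z: float) -> PlaneAnatomy:
    """Measure (Ys, Yc, x_c, w_half, y_wide) from the airway contour at z.

    When the slice yields several contours (nasal level) the largest-area
    contour is used; the deformation model itself is intended for the
    single-lumen pharyngeal region below the confluence.
    """
    section = slice_mesh(mesh, z)
    if section.is_empty:
        raise SliceRangeError(f"slicing at z={z:g} mm yields no contour")
    contour = section.largest_contour()[:-1]
    x, y = contour[:, 0], contour[:, 1]
    x_min, x_max = float(x.min()), float(x.max())
    x_c = 0.5 * (x_min + x_max)
    w_half = 0.5 * (x_max - x_min)
    ys = float(y.max())
    band = np.abs(x - x_c) <= 0.5
    yc = float(y[band].min()) if band.any() else float(y.min())
    y_wide = float(y[int(np.argmax(x))])
    return PlaneAnatomy(Ys=ys, Yc=yc, x_c=x_c, w_half=w_half, y_wide=y_wide)


def resolve_anatomy(mesh: TriangleMesh, config: DeformationConfig) -> DeformationConfig:
    """Fill any missing per-plane anatomy from the preoperative mesh.

    User-supplied values (e.g. a planning-table Ys/Yc) take precedence;
    only ``None`` fields are estimated.
    """
    planes = {}
    for name in ("top_plane", "middle_plane", "lower_plane"):
        plane: PivotalPlaneSpec = getattr(config, name)
        if plane.anatomy_complete:
            planes[name] = plane
            continue
        est = estimate_plane_anatomy(mesh, plane.z)
        planes[name] = plane.model_copy(
            update={
                "Ys": plane.Ys if plane.Ys is not None else est.Ys,
                "Yc": plane.Yc if plane.Yc is not None else est.Yc,
                "x_c": plane.x_c if plane.x_c is not None else est.x_c,
                "w_half": plane.w_half if plane.w_half is not None else est.w_half,
                "y_wide": plane.y_wide if plane.y_wide is not None else est.y_wide,
            }
        )
    return config.model_copy(update=planes)


# ---------------------------------------------------------------------------
# axial profile: piecewise-quadratic, C1, exact at the control planes


def _axial_profile(
    z: np.ndarray, z_l: float, z_m: float, z_t: float, d_l: float, d_m: float
) -> np.ndarray:
    """Evaluate the C1 piecewise-quadratic parameter profile along z.

    f(z_l) = d_l with f'(z_l) = 0, f(z_m) = d_m, f(z_t) = 0 with
    f'(z_t) = 0; constant d_l below z_l, identically zero at and above z_t.
    """
    z = np.asarray(z, dtype=np.float64)
    out = np.zeros_like(z)

    # top span: single quadratic with a double root at z_t
    u = (z - z_t) / (z_m - z_t)
    s_m = 2.0 * d_m / (z_m - z_t)  # slope of the top span at z_m (<= 0)

    # lower span: two quadratics joined C1 at the midpoint
    z_mid = 0.5 * (z_l + z_m)
    half = 0.5 * (z_m - z_l)
    a = (d_m - d_l - 0.5 * s_m * half) / (2.0 * half**2)
    b = (s_m - 2.0 * a * half) / (2.0 * half)

    top = (z >= z_m) & (z < z_t)
    out[top] = d_m * u[top] ** 2
    upper_half = (z >= z_mid) & (z < z_m)
    t = z[upper_half] - z_m
    out[upper_half] = d_m + s_m * t + b * t**2
    lower_half = (z >= z_l) & (z < z_mid)
    out[lower_half] = d_l + a * (z[lower_half] - z_l) ** 2
    out[z < z_l] = d_l
    # z >= z_t stays exactly zero
    return out


def _quad_through(z_pts: np.ndarray, values: np.ndarray):
    """Coefficients of the quadratic through three (z, value) pairs."""
    return np.polyfit(z_pts, values, 2)


def _smoothstep_quad(t: np.ndarray) -> np.ndarray:
    """C1 quadratic smoothstep: 1 for t <= 0, 0 for t >= 1, zero slope at both."""
    t = np.clip(t, 0.0, 1.0)
    return np.where(t <= 0.5, 1.0 - 2.0 * t**2, 2.0 * (1.0 - t) ** 2)


class DisplacementField:
    """Evaluates the deformation displacement at arbitrary points (mm).

    Built by :func:`build_displacement_field`; call with an ``(n, 3)`` array
    of points to get ``(n, 3)`` displacements.  Linear in the four
    enlargement parameters; exactly zero for z >= top plane and for
    y >= the plane-interpolated Ys.
    """

    def __init__(self, config: DeformationConfig):
        for plane in config.planes:
            if not plane.anatomy_complete:
                raise ParameterError(
                    f"plane z={plane.z:g} is missing anatomy (Ys/Yc/x_c/w_half/"
                    "y_wide); run resolve_anatomy(mesh, config) first"
                )
        self.config = config
        lo, mid, top = config.planes
        self.z_l, self.z_m, self.z_t = lo.z, mid.z, top.z
        z_pts = np.array([lo.z, mid.z, top.z])
        margin = config.spine_fix_margin
        self._c_Ys = _quad_through(z_pts, np.array([p.Ys - margin for p in config.planes]))
        self._c_Yc = _quad_through(z_pts, np.array([p.Yc for p in config.planes]))
        self._c_xc = _quad_through(z_pts, np.array([p.x_c for p in config.planes]))
        self._c_wh = _quad_through(z_pts, np.array([p.w_half for p in config.planes]))
        self._c_yw = _quad_through(z_pts, np.array([p.y_wide for p in config.planes]))
        self.dY = (lo.dY, mid.dY)
        self.dX = (lo.dX_half, mid.dX_half)

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in (*self.dY, *self.dX))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        disp = np.zeros_like(pts)
        if self.is_identity:
            return disp

        dY_z = _axial_profile(z, self.z_l, self.z_m, self.z_t, *self.dY)
        dX_z = _axial_profile(z, self.z_l, self.z_m, self.z_t, *self.dX)
        ys = np.polyval(self._c_Ys, z)
        yc = np.polyval(self._c_Yc, z)
        x_c = np.polyval(self._c_xc, z)
        w_half = np.polyval(self._c_wh, z)
        y_wide = np.polyval(self._c_yw, z)

        movable = (z < self.z_t) & (y < ys)

        # anterior (-y) push, weight 1 at Yc fading to 0 with zero slope at Ys
        wy = np.zeros_like(y)
        wy[movable] = ((y[movable] - ys[movable]) / (yc[movable] - ys[movable])) ** 2
        disp[:, 1] = -dY_z * wy

        # lateral push, antisymmetric about the mid-sagittal x, gated in y
        u = np.zeros_like(x)
        u[movable] = (x[movable] - x_c[movable]) / w_half[movable]
        s = np.sign(u) * np.minimum(u**2, 1.0)
        gate = np.zeros_like(y)
        span = ys[movable] - y_wide[movable]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(span > 0, (y[movable] - y_wide[movable]) / np.where(span > 0, span, 1.0), 1.0)
        gate[movable] = _smoothstep_quad(t)
        disp[:, 0] = dX_z * s * gate
        return disp


def build_displacement_field(config: DeformationConfig) -> DisplacementField:
    """Build the smooth displacement field for a fully specified config."""
    return DisplacementField(config)


def deform_mesh(mesh: TriangleMesh, config: DeformationConfig) -> TriangleMesh:
    """Apply the pivotal-plane deformation vertex-wise.

    Missing plane anatomy is estimated from ``mesh`` first.  Topology is
    unchanged and the result is deterministic.  A mesh entirely above the
    top (fixed) plane is returned unchanged with a warning.
    """
    if mesh.n_faces == 0:
        raise ParameterError("cannot deform an empty mesh")
    if mesh.bounds[0, 2] >= config.top_plane.z:
        warnings.warn(
            "mesh lies entirely above the top pivotal plane; returning it unchanged",
            stacklevel=2,
        )
        return mesh.copy()
    resolved = resolve_anatomy(mesh, config)
    field = build_displacement_field(resolved)
    out = mesh.copy()
    if field.is_identity:
        return out
    out.vertices = out.vertices + field(out.vertices)
    return out


def plane_params_from_expansion(
    forward_expansion_mm: float, lateral_expansion_mm: float
) -> tuple[float, float]:
    """Convert a surgeon's estimated section expansion to plane parameters.

    The forward (anteroposterior, y) expansion is the diameter increase and
    maps directly to ``dY``; the lateral (x) expansion is a total width
    increase applied symmetrically, so ``dX_half`` is half of it.
    """
    if forward_expansion_mm < 0 or lateral_expansion_mm < 0:
        raise ParameterError("expansion estimates must be non-negative")
    return forward_expansion_mm, lateral_expansion_mm / 2.0
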