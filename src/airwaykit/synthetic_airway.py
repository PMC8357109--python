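"""Parametric airway surrogate with analytically known cross-sections.

Patient airway surfaces cannot be redistributed, so every downstream stage
is exercised on a synthetic stand-in: a single pharyngeal tube with smoothly
varying elliptical cross-sections that splits, above a confluence plane,
into two circular nasal branches (left and right nasal passages).  The
elliptical part has exact closed-form section metrics, which makes it the
oracle for the slicing and deformation machinery.

Geometry is deterministic for a fixed spec; the seed only drives optional
radial surface noise used by smoothing tests.  Default dimensions follow a
typical adult pharynx in the CT patient frame (z foot-to-head, around
z = -560..-620 mm): lateral semi-axis 10 mm, anteroposterior semi-axis
6 mm, section centre at y = -16 mm.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .cross_section import CrossSection
from .errors import ParameterError, SliceRangeError
from .geometry_io import TriangleMesh


class SyntheticAirwaySpec(BaseModel):
    """Parameters of the surrogate airway (all lengths in mm).

    The semi-axis and centre-offset profiles are polynomials in
    ``zeta = z - pharynx_z_range[0]`` with coefficients in increasing order,
    e.g. ``a_coeffs=[10.0]`` is a constant 10 mm lateral semi-axis.
    """

    pharynx_z_range: tuple[float, float] = (-620.0, -560.0)
    a_coeffs: list[float] = Field(default_factory=lambda: [10.0])
    b_coeffs: list[float] = Field(default_factory=lambda: [6.0])
    c_coeffs: list[float] = Field(default_factory=lambda: [-16.0])
    nasal_radius: float = 3.5
    nasal_separation: float = 6.0
    nasal_height: float = 25.0
    vertices_per_ring: int = 64
    rings_per_mm: float = 1.0
    noise_mm: float = 0.0
    seed: int = 0

    # -- profile evaluation -------------------------------------------------
    def _poly(self, coeffs: list[float], z) -> np.ndarray:
        zeta = np.asarray(z, dtype=np.float64) - self.pharynx_z_range[0]
        return np.polynomial.polynomial.polyval(zeta, np.asarray(coeffs))

    def a(self, z):
        """Lateral (x) semi-axis at height z."""
        return self._poly(self.a_coeffs, z)

    def b(self, z):
        """Anteroposterior (y) semi-axis at height z."""
        return self._poly(self.b_coeffs, z)

    def c(self, z):
        """Section centre y-offset at height z."""
        return self._poly(self.c_coeffs, z)

    @property
    def confluence_z(self) -> float:
        """Height where the two nasal branches meet the pharyngeal tube."""
        return self.pharynx_z_range[1]

    @model_validator(mode="after")
    def _check(self) -> "SyntheticAirwaySpec":
        z_lo, z_hi = self.pharynx_z_range
        if not z_lo < z_hi:
            raise ParameterError("pharynx_z_range must be (low, high) with low < high")
        if self.vertices_per_ring < 8 or self.vertices_per_ring % 4:
            raise ParameterError("vertices_per_ring must be a multiple of 4, >= 8")
        if self.rings_per_mm < 0.2:
            raise ParameterError("rings_per_mm must be >= 0.2")
        zs = np.linspace(z_lo, z_hi, 65)
        if np.any(self.a(zs) <= 0) or np.any(self.b(zs) <= 0):
            raise ParameterError("semi-axes a(z), b(z) must stay positive")
        if self.nasal_height > 0:
            a_c, b_c = float(self.a(z_hi)), float(self.b(z_hi))
            r, d = self.nasal_radius, self.nasal_separation
            if r <= 0 or d <= 0:
                raise ParameterError("nasal radius and separation must be positive")
            if d + r >= a_c or r >= b_c:
                raise ParameterError("nasal branches must fit inside the confluence ellipse")
            if d - r <= 0.25:
                raise ParameterError("nasal branches must leave a mid-sagittal gap")
        if self.noise_mm < 0:
            raise ParameterError("noise_mm must be >= 0")
        return self


def analytic_cross_section(spec: SyntheticAirwaySpec, z: float) -> CrossSection:
    """Exact elliptical section of the pharyngeal tube at height z.

    Area is the closed form pi*a(z)*b(z); Ys = c + b, Yc = c - b.  The
    attached contour is a dense polyline for plotting, but the metric fields
    are exact, which is what makes this the slicing oracle.
    """
    z_lo, z_hi = spec.pharynx_z_range
    if not z_lo <= z <= z_hi:
        raise SliceRangeError(
            f"z={z:g} mm outside the pharyngeal range [{z_lo:g}, {z_hi:g}]"
        )
    a, b, c = float(spec.a(z)), float(spec.b(z)), float(spec.c(z))
    theta = np.linspace(0.0, 2.0 * np.pi, 241)
    contour = np.column_stack([a * np.cos(theta), c + b * np.sin(theta)])
    contour[-1] = contour[0]
    return CrossSection(
        z=float(z),
        contours=[contour],
        area=np.pi * a * b,
        Ys=c + b,
        Yc=c - b,
        width_x=2.0 * a,
        depth_y=2.0 * b,
        contour_areas=[np.pi * a * b],
    )


# ---------------------------------------------------------------------------
# mesh assembly helpers


def _ring(spec: SyntheticAirwaySpec, z: float, n: int) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    a, b, c = float(spec.a(z)), float(spec.b(z)), float(spec.c(z))
    return np.column_stack(
        [a * np.cos(theta), c + b * np.sin(theta), np.full(n, z)]
    )


def _circle_ring(cx: float, cy: float, r: float, z: float, n: int) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [cx + r * np.cos(theta), cy + r * np.sin(theta), np.full(n, z)]
    )


def _tube_faces(rings: list[np.ndarray], base: int, n: int) -> list[tuple[int, int, int]]:
    """Quad-strip side walls between consecutive CCW rings (outward normals)."""
    faces = []
    for i in range(len(rings) - 1):
        lo = base + i * n
        hi = base + (i + 1) * n
        for k in range(n):
            k1 = (k + 1) % n
            faces.append((lo + k, lo + k1, hi + k1))
            faces.append((lo + k, hi + k1, hi + k))
    return faces


def _fan(center: int, ring: list[int], upward: bool) -> list[tuple[int, int, int]]:
    """Cap fan over a CCW ring; ``upward`` picks the +z normal."""
    n = len(ring)
    faces = []
    for k in range(n):
        k1 = (k + 1) % n
        if upward:
            faces.append((center, ring[k], ring[k1]))
        else:
            faces.append((center, ring[k1], ring[k]))
    return faces


def _monotone_angles(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Unwrapped CCW angles of a loop around ``center`` (must be star-shaped)."""
    d = points - center
    ang = np.arctan2(d[:, 1], d[:, 0])
    out = ang.copy()
    for i in range(1, len(out)):
        while out[i] <= out[i - 1]:
            out[i] += 2.0 * np.pi
    if out[-1] - out[0] >= 2.0 * np.pi:
        raise ParameterError("loop is not star-shaped around the given centre")
    return out


def _zip_loops(
    outer: list[int],
    inner: list[int],
    vertices: np.ndarray,
    center: tuple[float, float],
) -> list[tuple[int, int, int]]:
    """Triangulate the planar annulus between two CCW loops (shared z).

    Both loops are walked in order of increasing angle around ``center``;
    triangles are emitted CCW in the plane (+z normals).  Every boundary
    edge is used exactly once, so the cap stitches watertight onto the tube
    walls that share the loop vertices.
    """
    ctr = np.asarray(center, dtype=np.float64)
    ao = _monotone_angles(vertices[outer][:, :2], ctr)
    ai_raw = _monotone_angles(vertices[inner][:, :2], ctr)
    # rotate the inner loop so it starts at the first angle >= outer start
    shift = (ai_raw - ao[0]) % (2.0 * np.pi)
    start = int(np.argmin(shift))
    inner = list(inner[start:]) + list(inner[:start])
    ai = _monotone_angles(vertices[inner][:, :2], ctr)
    ai = ai - ai[0] + ao[0] + float(shift[start])

    no, ni = len(outer), len(inner)
    io = ii = 0
    faces: list[tuple[int, int, int]] = []
    while io < no or ii < ni:
        next_o = ao[io + 1] if io + 1 < no else ao[0] + 2.0 * np.pi
        next_i = ai[ii + 1] if ii + 1 < ni else ai[0] + 2.0 * np.pi
        if io < no and (ii == ni or next_o <= next_i):
            faces.append((outer[io % no], outer[(io + 1) % no], inner[ii % ni]))
            io += 1
        else:
            faces.append((outer[io % no], inner[(ii + 1) % ni], inner[ii % ni]))
            ii += 1
    return faces


def generate_airway(spec: SyntheticAirwaySpec) -> TriangleMesh:
    """Build the watertight surrogate surface described by ``spec``.

    Pharyngeal tube rings run from the bottom of the z-range up to the
    confluence; two circular branches continue upward from there.  The
    confluence shoulder (the flat region between the wide pharyngeal outline
    and the two branch inlets) is triangulated by splitting it along the
    mid-sagittal chord and zipping each half between its boundary loops.
    """
    z_lo, z_hi = spec.pharynx_z_range
    n = spec.vertices_per_ring
    m = max(16, (n // 2) - (n // 2) % 4)
    n_seg = max(2, int(round((z_hi - z_lo) * spec.rings_per_mm)))
    zs = np.linspace(z_lo, z_hi, n_seg + 1)

    vertices: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []

    # pharyngeal tube
    pharynx_rings = [_ring(spec, z, n) for z in zs]
    vertices.extend(pharynx_rings)
    faces.extend(_tube_faces(pharynx_rings, 0, n))
    top_ring = [n_seg * n + k for k in range(n)]

    # optional radial noise on interior pharynx rings (seeded, smoothing tests)
    if spec.noise_mm > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.uniform(-spec.noise_mm, spec.noise_mm, size=(n_seg - 1, n))
        for i in range(1, n_seg):
            ring = vertices[i]
            centre = np.array([0.0, float(spec.c(zs[i]))])
            radial = ring[:, :2] - centre
            radial /= np.linalg.norm(radial, axis=1)[:, None]
            ring[:, :2] += noise[i - 1][:, None] * radial

    verts = np.vstack(vertices)

    def add_vertex(p) -> int:
        nonlocal verts
        verts = np.vstack([verts, np.asarray(p, dtype=np.float64)])
        return len(verts) - 1

    # bottom cap (fan, -z normal)
    bottom_centre_idx = add_vertex([0.0, float(spec.c(z_lo)), z_lo])
    faces.extend(_fan(bottom_centre_idx, list(range(n)), upward=False))

    if spec.nasal_height <= 0:
        # single tube: close the top with a fan
        top_centre = add_vertex([0.0, float(spec.c(z_hi)), z_hi])
        faces.extend(_fan(top_centre, top_ring, upward=True))
        return TriangleMesh(verts, np.asarray(faces, dtype=np.int64))

    # nasal branches
    r, sep = spec.nasal_radius, spec.nasal_separation
    cy = float(spec.c(z_hi))
    n_bseg = max(2, int(round(spec.nasal_height * spec.rings_per_mm)))
    bzs = np.linspace(z_hi, z_hi + spec.nasal_height, n_bseg + 1)
    branch_bottom: dict[str, list[int]] = {}
    for side, cx in (("right", sep), ("left", -sep)):
        base = len(verts)
        rings = [_circle_ring(cx, cy, r, z, m) for z in bzs]
        verts = np.vstack([verts] + rings)
        faces.extend(_tube_faces(rings, base, m))
        branch_bottom[side] = [base + k for k in range(m)]
        top_centre = add_vertex([cx, cy, bzs[-1]])
        faces.extend(
            _fan(top_centre, [base + n_bseg * m + k for k in range(m)], upward=True)
        )

    # confluence shoulder: split along the mid-sagittal chord
    b_c = float(spec.b(z_hi))
    k_chord = max(3, int(round(2.0 * b_c * spec.rings_per_mm)))
    chord_y = np.linspace(cy + b_c, cy - b_c, k_chord + 2)[1:-1]  # top -> bottom
    chord = [add_vertex([0.0, y, z_hi]) for y in chord_y]

    # ellipse vertices n/4 and 3n/4 sit exactly at (0, c +/- b): chord endpoints
    left_arc = top_ring[n // 4 : 3 * n // 4 + 1]
    right_arc = top_ring[3 * n // 4 :] + top_ring[: n // 4 + 1]

    left_outer = left_arc + chord[::-1]         # arc top->bottom, chord bottom->top
    right_outer = right_arc + chord             # arc bottom->top, chord top->bottom
    faces.extend(_zip_loops(left_outer, branch_bottom["left"], verts, (-sep, cy)))
    faces.extend(_zip_loops(right_outer, branch_bottom["right"], verts, (sep, cy)))

    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
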