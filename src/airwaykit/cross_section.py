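"""Horizontal-plane slicing and airway cross-section dimensioning.

A cross-section at height z collects the closed contours where the airway
wall meets the plane, and the dimensioning quantities used for surgical
planning:

* ``Ys`` — maximum y of the wall (the spine-side extreme),
* ``Yc`` — minimum y on the mid-sagittal line (the anterior extreme),
* ``width_x`` / ``depth_y`` — lateral width and anteroposterior depth,
* ``area`` — enclosed area (shoelace formula, summed over contours).

Yc is taken over contour points within a +/-0.5 mm band around the
mid-sagittal x, which keeps it robust to contour discretisation while
staying on the midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, SliceAssemblyError
from .geometry_io import TriangleMesh

#: contour endpoints closer than this (mm) count as closed
CLOSURE_TOLERANCE_MM = 1e-6

#: half-width (mm) of the mid-sagittal band used for Yc
MIDSAGITTAL_BAND_MM = 0.5

#: planes are nudged by this much (mm) so vertices exactly on the plane
#: fall on a consistent side (standard simulation-of-simplicity convention)
PLANE_EPS_MM = 1e-9


def shoelace_area(contour: np.ndarray) -> float:
    """Unsigned area (mm^2) of a closed planar polyline given as (k, 2)."""
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _close(contour: np.ndarray) -> np.ndarray:
    if np.linalg.norm(contour[0] - contour[-1]) > CLOSURE_TOLERANCE_MM:
        contour = np.vstack([contour, contour[0]])
    else:
        contour = contour.copy()
        contour[-1] = contour[0]
    return contour


@dataclass
class CrossSection:
    """Closed contours at a horizontal plane plus dimensioning metrics."""

    z: float
    contours: list[np.ndarray]  # each (k, 2), closed: first == last
    area: float
    Ys: float
    Yc: float
    width_x: float
    depth_y: float
    contour_areas: list[float] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.contours) == 0

    @classmethod
    def empty(cls, z: float) -> "CrossSection":
        return cls(z, [], 0.0, float("nan"), float("nan"), 0.0, 0.0)

    @classmethod
    def from_contours(cls, z: float, contours: list[np.ndarray]) -> "CrossSection":
        """Build a section, deriving every metric from the contour points."""
        if not contours:
            return cls.empty(z)
        closed = [_close(np.asarray(c, dtype=np.float64)) for c in contours]
        for c in closed:
            if len(np.unique(np.round(c[:-1], 9), axis=0)) < 3:
                raise ParameterError("contour needs >= 3 distinct points")
        areas = [shoelace_area(c) for c in closed]
        pts = np.vstack([c[:-1] for c in closed])
        x, y = pts[:, 0], pts[:, 1]
        x_min, x_max = float(x.min()), float(x.max())
        x_c = 0.5 * (x_min + x_max)
        ys = float(y.max())
        band = np.abs(x - x_c) <= MIDSAGITTAL_BAND_MM
        yc = float(y[band].min()) if band.any() else float(y.min())
        return cls(
            z=float(z),
            contours=closed,
            area=float(sum(areas)),
            Ys=ys,
            Yc=yc,
            width_x=x_max - x_min,
            depth_y=ys - yc,
            contour_areas=areas,
        )

    def largest_contour(self) -> np.ndarray:
        if self.is_empty:
            raise ParameterError("empty section has no contours")
        return self.contours[int(np.argmax(self.contour_areas))]

    def to_dict(self) -> dict:
        return {
            "z": self.z,
            "n_contours": len(self.contours),
            "area": self.area,
            "Ys": self.Ys,
            "Yc": self.Yc,
            "width_x": self.width_x,
            "depth_y": self.depth_y,
            "contour_areas": self.contour_areas,
        }


@dataclass
class SectionComparison:
    """Pre/post differences of the planning quantities at one plane."""

    achieved_dY: float
    achieved_dX_total: float
    area_ratio: float

    def to_dict(self) -> dict:
        return {
            "achieved_dY": self.achieved_dY,
            "achieved_dX_total": self.achieved_dX_total,
            "area_ratio": self.area_ratio,
        }


def slice_mesh(mesh: TriangleMesh, z: float) -> CrossSection:
    """Intersect the mesh with the horizontal plane at height z (mm).

    Plane-triangle intersection segments are chained into closed loops; a
    plane outside the bounding box yields an empty section.  Open chains
    (a surface that is not watertight at z) raise
    :class:`~airwaykit.errors.SliceAssemblyError` reporting the gap size.
    """
    lo, hi = mesh.bounds[:, 2]
    if not lo <= z <= hi:
        return CrossSection.empty(z)
    path = mesh.to_trimesh().section(
        plane_origin=[0.0, 0.0, z + PLANE_EPS_MM], plane_normal=[0.0, 0.0, 1.0]
    )
    if path is None:
        return CrossSection.empty(z)
    contours: list[np.ndarray] = []
    for entity in path.entities:
        loop = path.vertices[entity.points]
        gap = float(np.linalg.norm(loop[0] - loop[-1]))
        if gap > CLOSURE_TOLERANCE_MM:
            raise SliceAssemblyError(
                f"slice at z={z:g} mm left an open chain with a {gap:.3g} mm gap "
                "(mesh not watertight at this height)"
            )
        if len(loop) < 4:  # closed triangle needs 3 distinct + repeat
            continue
        contours.append(loop[:, :2])
    return CrossSection.from_contours(z, contours)


def compare_sections(pre: CrossSection, post: CrossSection) -> SectionComparison:
    """Achieved enlargement between two sections on the same plane."""
    if abs(pre.z - post.z) > 1e-3:
        raise ParameterError(
            f"sections are on different planes (z={pre.z:g} vs {post.z:g} mm)"
        )
    if pre.is_empty or post.is_empty:
        raise ParameterError("cannot compare empty sections")
    return SectionComparison(
        achieved_dY=post.depth_y - pre.depth_y,
        achieved_dX_total=post.width_x - pre.width_x,
        area_ratio=post.area / pre.area,
    )


def export_section(section: CrossSection, path: str | Path) -> Path:
    """Write contours as plot-ready whitespace-delimited ``x y`` columns.

    Contours are blank-line separated, each written closed (the first point
    repeated at the end), so the file plots directly with e.g. gnuplot.
    """
    if section.is_empty:
        raise ParameterError("refusing to export an empty section")
    path = Path(path)
    blocks = []
    for contour in section.contours:
        blocks.append(
            "\n".join(f"{x:.9g} {y:.9g}" for x, y in contour)
        )
    path.write_text("\n\n".join(blocks) + "\n")
    return path


def read_section_export(path: str | Path) -> list[np.ndarray]:
    """Re-read a file written by :func:`export_section` (round-trip helper)."""
    text = Path(path).read_text()
    contours = []
    for block in text.strip().split("\n\n"):
        rows = [[float(v) for v in line.split()] for line in block.splitlines() if line.strip()]
        contours.append(np.asarray(rows))
    return contours
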