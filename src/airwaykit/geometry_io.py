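"""Read, validate, smooth and write STL airway surfaces.

Surfaces live in the CT-derived patient frame: x runs right-to-left, y
face-to-back (so the spine side is +y), z foot-to-head.  All lengths are in
millimetres.  STL facets are stored independently on disk; on read,
coincident vertices are merged into shared indices so that connectivity-based
operations (smoothing, slicing) see a single surface.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import trimesh.smoothing

from .errors import EmptyMeshError, ParameterError, StlFormatError

#: vertices closer than this (mm) are considered the same point
MERGE_TOLERANCE_MM = 1e-6

#: facets with area below this (mm^2), or with a repeated vertex index,
#: are reported as degenerate
DEGENERATE_AREA_MM2 = 1e-12


@dataclass
class TriangleMesh:
    """A triangulated airway surface in the patient frame (mm).

    Parameters
    ----------
    vertices
        ``(n, 3)`` float array of vertex positions.
    faces
        ``(m, 3)`` integer array of vertex indices, counter-clockwise when
        viewed from outside the surface.
    normals
        Optional ``(m, 3)`` per-facet unit normals.  Treated as advisory:
        normals are recomputed from the vertex winding on write.
    source_is_binary
        Set by :func:`read_stl` to record the dialect of the source file.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    source_is_binary: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ParameterError("mesh vertices contain non-finite coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ParameterError("mesh facet indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """``(2, 3)`` array of per-axis (min, max) in mm."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.normals is None else self.normals.copy(),
            self.source_is_binary,
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` without reprocessing."""
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class MeshReport:
    """Summary statistics from :func:`validate_mesh` (JSON-serialisable)."""

    facet_count: int
    degenerate_facets: int
    bounding_box: dict[str, list[float]]
    is_binary_source: bool | None = None

    def to_dict(self) -> dict:
        return {
            "facet_count": self.facet_count,
            "degenerate_facets": self.degenerate_facets,
            "bounding_box": self.bounding_box,
            "is_binary_source": self.is_binary_source,
        }


def _detect_binary(data: bytes, path: str) -> bool:
    """Classify an STL byte stream, raising on structurally broken binaries."""
    if len(data) < 15:
        raise StlFormatError(f"{path}: too short ({len(data)} bytes) to be an STL file")
    head = data[:512]
    looks_ascii = head.lstrip()[:5] == b"solid" and b"facet" in data[:4096]
    if looks_ascii:
        return False
    if len(data) < 84:
        raise StlFormatError(
            f"{path}: binary STL needs at least 84 bytes of header, got {len(data)}"
        )
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if expected != len(data):
        raise StlFormatError(
            f"{path}: binary header at byte 80 declares {count} facets "
            f"({expected} bytes) but the file holds {len(data)} bytes"
        )
    return True


def read_stl(path: str | Path) -> TriangleMesh:
    """Load an ASCII or binary STL surface, merging duplicate vertices.

    The dialect is auto-detected.  Vertices coincident within
    ``MERGE_TOLERANCE_MM`` are merged into shared indices.

    Raises
    ------
    StlFormatError
        For truncated or unparseable files (the message names the byte or
        line where the structure breaks).
    EmptyMeshError
        For a syntactically valid file that contains no facets.
    """
    path = Path(path)
    data = path.read_bytes()
    is_binary = _detect_binary(data, str(path))
    try:
        raw = trimesh.load_mesh(
            io.BytesIO(data), file_type="stl", process=True, validate=False
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise StlFormatError(f"{path}: unparseable STL ({exc})") from exc
    if raw.faces.shape[0] == 0:
        raise EmptyMeshError(f"{path}: STL contains no facets")
    return TriangleMesh(
        np.asarray(raw.vertices, dtype=np.float64),
        np.asarray(raw.faces, dtype=np.int64),
        source_is_binary=is_binary,
    )


def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "binary") -> Path:
    """Write a mesh as STL.

    ``dialect`` is ``"binary"`` (80-byte header, uint32 count, 50-byte
    records) or ``"ascii"``.  Facet normals are recomputed from the vertex
    winding; stored normals are not trusted.
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write a mesh with zero facets")
    if dialect not in ("binary", "ascii"):
        raise ParameterError(f"unknown STL dialect {dialect!r}")
    path = Path(path)
    tm = mesh.to_trimesh()
    from trimesh.exchange import stl as stl_io

    if dialect == "binary":
        path.write_bytes(stl_io.export_stl(tm))
    else:
        path.write_text(stl_io.export_stl_ascii(tm))
    return path


def validate_mesh(mesh: TriangleMesh) -> MeshReport:
    """Report facet count, degenerate (zero-area) facets and the bounding box.

    Pure: the input mesh is never mutated.
    """
    v = mesh.vertices
    f = mesh.faces
    degenerate = 0
    if len(f):
        repeated = (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        )
        tri = v[f]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        degenerate = int(np.count_nonzero(repeated | (0.5 * area2 < DEGENERATE_AREA_MM2)))
    lo = v.min(axis=0) if len(v) else np.zeros(3)
    hi = v.max(axis=0) if len(v) else np.zeros(3)
    return MeshReport(
        facet_count=mesh.n_faces,
        degenerate_facets=degenerate,
        bounding_box={"min": lo.tolist(), "max": hi.tolist()},
        is_binary_source=mesh.source_is_binary,
    )


def smooth_mesh(mesh: TriangleMesh, iterations: int, strength: float = 1.0) -> TriangleMesh:
    """Taubin-smooth a surface without shrinking the airway lumen.

    Two-step neighbour averaging: each iteration applies a positive
    (shrinking) Laplacian step of weight ``lambda = 0.5 * strength`` followed
    by a negative (inflating) back-step, Taubin's classic lambda/mu pair with
    a 0.1 pass band.  This keeps cross-section areas stable where plain
    Laplacian smoothing would bias them low.  Topology (vertex and facet
    counts) is unchanged; ``iterations=0`` returns an identical copy.
    """
    if not 0.0 <= strength <= 1.0:
        raise ParameterError(f"smoothing strength must be in [0, 1], got {strength}")
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0 or strength == 0.0 or mesh.n_faces == 0:
        return out
    lamb = 0.5 * strength
    nu = lamb / (1.0 - 0.1 * lamb)  # |mu| slightly above lambda: volume-preserving
    tm = out.to_trimesh()
    trimesh.smoothing.filter_taubin(tm, lamb=lamb, nu=nu, iterations=iterations)
    out.vertices = np.asarray(tm.vertices, dtype=np.float64)
    return out
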