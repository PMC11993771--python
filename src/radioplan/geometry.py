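"""Triangle-mesh and rigid-transform primitives.

Conventions used throughout the package:

* all lengths are millimetres,
* angles are degrees at API boundaries (radians internally),
* transforms are serialised as 4x4 row-major homogeneous matrices,
* planes are serialised as ``{"point": [...], "normal": [...]}``.

STL files are read in both binary and ASCII dialects.  On read, vertices
repeated per facet are welded by *exact* coordinate match, so the welding is
deterministic and needs no tolerance parameter.
"""

from __future__ import annotations

import json
import logging
import re
import struct
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptySelectionError,
    MeshValidationError,
    StlParseError,
    TransformValidationError,
)

log = logging.getLogger(__name__)

_ORTHO_TOL = 1e-7
_AREA_EPS = 1e-12


class TriangleMesh:
    """Indexed triangle surface mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex-index triplets.  Faces with repeated indices are rejected.
    """

    def __init__(self, vertices, faces):
        vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
        faces = np.ascontiguousarray(faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(vertices).all():
            raise MeshValidationError("mesh vertices contain non-finite coordinates")
        if faces.size:
            if faces.min() < 0 or faces.max() >= len(vertices):
                raise MeshValidationError("face index out of range")
            degen = (
                (faces[:, 0] == faces[:, 1])
                | (faces[:, 1] == faces[:, 2])
                | (faces[:, 0] == faces[:, 2])
            )
            if degen.any():
                raise MeshValidationError(
                    f"{int(degen.sum())} faces have repeated vertex indices"
                )
        self.vertices = vertices
        self.faces = faces

    # -- basic properties ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates per face."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_normals(self) -> np.ndarray:
        t = self.triangles
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        n = np.linalg.norm(c, axis=1)
        n = np.where(n > 0, n, 1.0)
        return c / n[:, None]

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        t = self.triangles
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # 2*area*normal
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], c)
        n = np.linalg.norm(vn, axis=1)
        n = np.where(n > 0, n, 1.0)
        return vn / n[:, None]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if not len(self.vertices):
            raise MeshValidationError("empty mesh has no bounds")
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def is_empty(self) -> bool:
        return self.n_faces == 0

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_triangle_soup(cls, triangles) -> "TriangleMesh":
        """Weld a (m, 3, 3) triangle soup by exact coordinate match."""
        triangles = np.asarray(triangles, dtype=np.float64).reshape(-1, 3, 3)
        if not len(triangles):
            return cls(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        flat = triangles.reshape(-1, 3)
        uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
        faces = inverse.reshape(-1, 3)
        keep = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        mesh = cls(uniq, faces[keep])
        return mesh

    @classmethod
    def concatenate(cls, *meshes: "TriangleMesh") -> "TriangleMesh":
        verts, faces, off = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + off)
            off += m.n_vertices
        return cls(np.vstack(verts), np.vstack(faces))

    def transformed(self, transform: "RigidTransform") -> "TriangleMesh":
        """Apply a rigid (possibly improper) transform.

        Improper transforms mirror the geometry, so the face winding is
        flipped to keep outward normals outward.
        """
        v = transform.apply(self.vertices)
        f = self.faces if transform.proper else self.faces[:, [0, 2, 1]]
        return TriangleMesh(v, f)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def __repr__(self):  # pragma: no cover
        return f"TriangleMesh(n_vertices={self.n_vertices}, n_faces={self.n_faces})"


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation; ``proper=False`` marks a mirroring.

    The rotation matrix must be orthogonal; the ``proper`` flag is derived
    from its determinant (+1 proper, -1 mirroring).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.ascontiguousarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        if not (np.isfinite(r).all() and np.isfinite(t).all()):
            raise TransformValidationError("non-finite transform entries")
        if np.abs(r.T @ r - np.eye(3)).max() > _ORTHO_TOL:
            raise TransformValidationError("rotation matrix is not orthogonal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @property
    def proper(self) -> bool:
        return bool(np.linalg.det(self.rotation) > 0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation_about(cls, rotation, point) -> "RigidTransform":
        """Rotation about an arbitrary fixed point."""
        rotation = np.asarray(rotation, dtype=np.float64)
        point = np.asarray(point, dtype=np.float64)
        return cls(rotation, point - rotation @ point)

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=np.float64))

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (``other`` applied first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        m = np.asarray(matrix, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(json.loads(text)["matrix"])

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.abs(self.rotation - other.rotation).max() < atol
            and np.abs(self.translation - other.translation).max() < atol
        )


@dataclass(frozen=True)
class Plane:
    """Oriented plane; ``normal`` is normalised on construction."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.ascontiguousarray(self.point, dtype=np.float64).reshape(3)
        n = np.ascontiguousarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise MeshValidationError("plane normal must be nonzero and finite")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return (points - self.point) @ self.normal

    def to_json(self) -> str:
        return json.dumps({"point": self.point.tolist(), "normal": self.normal.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Plane":
        d = json.loads(text)
        return cls(np.asarray(d["point"]), np.asarray(d["normal"]))


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

_BINARY_HEADER = struct.Struct("<80sI")
_FACET_DTYPE = np.dtype(
    [("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
)
_ASCII_FLOAT = r"[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?"
_VERTEX_RE = re.compile(
    rf"vertex\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})"
)


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a welded :class:`TriangleMesh`."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) >= _BINARY_HEADER.size:
        _, count = _BINARY_HEADER.unpack_from(raw, 0)
        expected = _BINARY_HEADER.size + count * _FACET_DTYPE.itemsize
        if len(raw) == expected:
            facets = np.frombuffer(raw, dtype=_FACET_DTYPE, count=count, offset=84)
            return TriangleMesh.from_triangle_soup(facets["v"].astype(np.float64))
    if raw.lstrip()[:5].lower() == b"solid":
        return _read_stl_ascii(raw)
    if len(raw) >= _BINARY_HEADER.size:
        _, count = _BINARY_HEADER.unpack_from(raw, 0)
        expected = _BINARY_HEADER.size + count * _FACET_DTYPE.itemsize
        raise StlParseError(
            f"binary STL declares {count} facets, expected file size {expected} "
            f"but got {len(raw)}",
            byte_offset=min(len(raw), expected),
        )
    raise StlParseError("file too short to be an STL", byte_offset=len(raw))


def _read_stl_ascii(raw: bytes) -> TriangleMesh:
    try:
        text = raw.decode("ascii", errors="strict")
    except UnicodeDecodeError as exc:
        raise StlParseError("ASCII STL contains non-ASCII bytes", exc.start) from exc
    coords = np.array(_VERTEX_RE.findall(text), dtype=np.float64)
    n_facets = text.count("facet normal")
    if len(coords) != 3 * n_facets:
        raise StlParseError(
            f"ASCII STL has {n_facets} facets but {len(coords)} vertex lines"
        )
    if n_facets == 0:
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    return TriangleMesh.from_triangle_soup(coords.reshape(-1, 3, 3))


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL (``dialect`` in {"binary", "ascii"})."""
    if dialect == "binary":
        facets = np.zeros(mesh.n_faces, dtype=_FACET_DTYPE)
        facets["normal"] = mesh.face_normals().astype(np.float32)
        facets["v"] = mesh.triangles.astype(np.float32)
        with open(path, "wb") as fh:
            fh.write(_BINARY_HEADER.pack(b"radioplan binary STL", mesh.n_faces))
            fh.write(facets.tobytes())
    elif dialect == "ascii":
        normals = mesh.face_normals()
        lines = ["solid radioplan"]
        for nrm, tri in zip(normals, mesh.triangles):
            lines.append(f"  facet normal {nrm[0]:.9g} {nrm[1]:.9g} {nrm[2]:.9g}")
            lines.append("    outer loop")
            for v in tri:
                lines.append(f"      vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid radioplan")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown STL dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Plane cutting and mirroring
# ---------------------------------------------------------------------------


def _clip_polygon(poly, dist, keep_positive):
    """Sutherland-Hodgman clip of a polygon against one halfspace.

    ``poly`` is a list of 3D points, ``dist`` their signed plane distances.
    """
    sign = 1.0 if keep_positive else -1.0
    out = []
    n = len(poly)
    for i in range(n):
        j = (i + 1) % n
        di, dj = sign * dist[i], sign * dist[j]
        if di >= 0:
            out.append(poly[i])
        if (di > 0 and dj < 0) or (di < 0 and dj > 0):
            t = di / (di - dj)
            out.append(poly[i] + t * (poly[j] - poly[i]))
    return out


def _fan_triangulate(poly):
    return [(poly[0], poly[i], poly[i + 1]) for i in range(1, len(poly) - 1)]


def cut_with_plane(
    mesh: TriangleMesh, plane: Plane, eps: float = 1e-9
) -> tuple[TriangleMesh, TriangleMesh]:
    """Split ``mesh`` into (positive-side, negative-side) open surfaces.

    Triangles straddling the plane are split along the intersection line; no
    cap surface is added.  A plane that misses the mesh entirely yields one
    empty part and logs a warning.
    """
    dist = plane.signed_distance(mesh.vertices)
    fd = dist[mesh.faces]
    all_pos = (fd >= -eps).all(axis=1)
    all_neg = (fd <= eps).all(axis=1)
    on_plane = all_pos & all_neg
    straddle = ~(all_pos | all_neg)

    tris = mesh.triangles
    pos_soup = [tris[all_pos & ~on_plane], tris[on_plane]]
    neg_soup = [tris[all_neg & ~on_plane]]
    for fi in np.nonzero(straddle)[0]:
        poly = [tris[fi, k] for k in range(3)]
        d = fd[fi]
        p_part = _clip_polygon(poly, d, keep_positive=True)
        n_part = _clip_polygon(poly, d, keep_positive=False)
        if len(p_part) >= 3:
            pos_soup.append(np.asarray(_fan_triangulate(p_part)))
        if len(n_part) >= 3:
            neg_soup.append(np.asarray(_fan_triangulate(n_part)))

    def _build(soups):
        soups = [s.reshape(-1, 3, 3) for s in soups if len(s)]
        if not soups:
            return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        soup = np.vstack(soups)
        areas = 0.5 * np.linalg.norm(
            np.cross(soup[:, 1] - soup[:, 0], soup[:, 2] - soup[:, 0]), axis=1
        )
        return TriangleMesh.from_triangle_soup(soup[areas > _AREA_EPS])

    positive, negative = _build(pos_soup), _build(neg_soup)
    if positive.is_empty() or negative.is_empty():
        log.warning("cut_with_plane: plane misses the mesh; one part is empty")
    return positive, negative


def mirror_transform(plane: Plane) -> RigidTransform:
    """Improper transform reflecting across ``plane``."""
    n = plane.normal
    r = np.eye(3) - 2.0 * np.outer(n, n)
    t = 2.0 * (plane.point @ n) * n
    return RigidTransform(r, t)


def mirror(mesh: TriangleMesh, plane: Plane) -> TriangleMesh:
    """Reflect ``mesh`` across ``plane``, re-flipping face winding."""
    return mesh.transformed(mirror_transform(plane))


def select_side(points, plane: Plane, side: str, margin: float = 0.0) -> np.ndarray:
    """Boolean mask of ``points`` lying on one side of ``plane``.

    ``side`` is "positive"/"distal" or "negative"/"proximal" (the package
    convention orients osteotomy-plane normals distally).  ``margin`` is a
    dead zone excluded around the plane.
    """
    d = plane.signed_distance(points)
    if side in ("positive", "distal"):
        return d > margin
    if side in ("negative", "proximal"):
        return d < -margin
    raise ValueError(f"unknown side {side!r}")


def restrict_vertices(
    mesh: TriangleMesh, plane: Plane, side: str, margin: float = 2.0
) -> np.ndarray:
    """Vertices of ``mesh`` strictly beyond ``margin`` on one side of ``plane``."""
    mask = select_side(mesh.vertices, plane, side, margin)
    if not mask.any():
        raise EmptySelectionError(
            f"no vertices on side {side!r} of plane beyond {margin} mm margin"
        )
    return mesh.vertices[mask]
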