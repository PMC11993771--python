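"""Rigid surface registration.

Two routes are provided on purpose: :func:`kabsch` solves the orthogonal
Procrustes problem in closed form for *known* point pairings and acts as the
oracle for :func:`icp`, which iterates nearest-point correspondences on the
fixed surface (point-to-triangle, since moving and fixed tessellations are
generally unrelated).

Trimming dialect: ``trim_mode="auto_threshold"`` excludes, at every
iteration, correspondences farther than mean + 2 SD of the current
correspondence distances.  The residual metric is the RMS point-to-surface
distance of the retained correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    RegistrationError,
    TrimmingCollapseError,
)
from .geometry import Plane, RigidTransform, TriangleMesh, select_side

__all__ = [
    "IcpParams",
    "RegistrationResult",
    "SurfaceProximity",
    "kabsch",
    "icp",
    "sample_surface",
    "restrict_to_region",
]


@dataclass(frozen=True)
class IcpParams:
    """ICP controls; defaults sit well below optical-scan noise (~0.05 mm)."""

    max_iterations: int = 100
    convergence_tol: float = 1e-4
    sample_count: int = 500
    trim_mode: str = "none"  # "none" | "auto_threshold"
    metric: str = "point_to_point"  # or "point_to_plane"
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.sample_count < 3:
            raise ValueError("sample_count must be >= 3")
        if self.trim_mode not in ("none", "auto_threshold"):
            raise ValueError(f"unknown trim_mode {self.trim_mode!r}")
        if self.metric not in ("point_to_point", "point_to_plane"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    mean_residual: float
    iterations_run: int
    converged: bool
    retained_fraction: float
    residual_history: list = field(default_factory=list)


def kabsch(moving_points, fixed_points) -> RigidTransform:
    """Closed-form least-squares rigid alignment of paired points.

    Returns the proper rigid transform T minimising
    ``sum ||T(moving_i) - fixed_i||^2`` (orthogonal Procrustes with
    determinant constraint).
    """
    m = np.asarray(moving_points, dtype=np.float64).reshape(-1, 3)
    f = np.asarray(fixed_points, dtype=np.float64).reshape(-1, 3)
    if len(m) != len(f):
        raise ValueError("paired point sets must have equal length")
    if len(m) < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    cm, cf = m.mean(axis=0), f.mean(axis=0)
    h = (m - cm).T @ (f - cf)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-9 * max(s[0], 1e-30):
        raise DegenerateGeometryError("point configuration is (near-)collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cf - r @ cm)


def sample_surface(mesh: TriangleMesh, count: int, seed: int = 0) -> np.ndarray:
    """Deterministic area-weighted point sample of a mesh surface."""
    areas = mesh.face_areas()
    total = areas.sum()
    if mesh.is_empty() or total <= 0:
        raise EmptySelectionError("cannot sample an empty or zero-area mesh")
    rng = np.random.default_rng(seed)
    fi = rng.choice(mesh.n_faces, size=count, p=areas / total)
    r1 = np.sqrt(rng.random(count))
    r2 = rng.random(count)
    a, b, c = (mesh.triangles[fi, k] for k in range(3))
    return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


def _closest_point_on_triangles(p, a, b, c):
    """Vectorised closest point on triangles (Ericson's region method).

    All inputs broadcast to (..., 3); returns closest points of same shape.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    def safe_div(num, den):
        den = np.where(np.abs(den) < 1e-300, 1e-300, den)
        return num / den

    # interior (default)
    denom = va + vb + vc
    v = safe_div(vb, denom)[..., None]
    w = safe_div(vc, denom)[..., None]
    out = a + ab * v + ac * w
    # edge bc
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    t = safe_div(d4 - d3, (d4 - d3) + (d5 - d6))[..., None]
    out = np.where(m[..., None], b + t * (c - b), out)
    # edge ac
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = safe_div(d2, d2 - d6)[..., None]
    out = np.where(m[..., None], a + t * ac, out)
    # vertex c
    m = (d6 >= 0) & (d5 <= d6)
    out = np.where(m[..., None], c, out)
    # edge ab
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = safe_div(d1, d1 - d3)[..., None]
    out = np.where(m[..., None], a + t * ab, out)
    # vertex b
    m = (d3 >= 0) & (d4 <= d3)
    out = np.where(m[..., None], b, out)
    # vertex a
    m = (d1 <= 0) & (d2 <= 0)
    out = np.where(m[..., None], a, out)
    return out


def _refine_soup(tris: np.ndarray, parents: np.ndarray, max_rounds: int = 8):
    """Longest-edge bisection until element sizes are near uniform.

    Mixed triangle sizes (shaft quads next to cap fans) defeat a plain
    centroid KD-tree: a query near a huge triangle may see only the small
    neighbours among its k candidates.  Bisecting oversized triangles keeps
    every centroid close to its own surface patch; the children lie on the
    same surface, so closest-point queries stay exact.
    """
    edges = np.stack(
        [
            np.linalg.norm(tris[:, 1] - tris[:, 2], axis=1),
            np.linalg.norm(tris[:, 2] - tris[:, 0], axis=1),
            np.linalg.norm(tris[:, 0] - tris[:, 1], axis=1),
        ],
        axis=1,
    )
    thr = max(2.5 * float(np.median(edges)), 1e-9)
    for _ in range(max_rounds):
        longest = edges.max(axis=1)
        split = longest > thr
        if not split.any():
            break
        keep_t, keep_p = tris[~split], parents[~split]
        t, p = tris[split], parents[split]
        j = edges[split].argmax(axis=1)  # longest-edge opposite-vertex index
        rows = np.arange(len(t))
        a = t[rows, j]
        b = t[rows, (j + 1) % 3]
        c = t[rows, (j + 2) % 3]
        mid = 0.5 * (b + c)
        child1 = np.stack([a, b, mid], axis=1)
        child2 = np.stack([a, mid, c], axis=1)
        tris = np.concatenate([keep_t, child1, child2])
        parents = np.concatenate([keep_p, p, p])
        edges = np.stack(
            [
                np.linalg.norm(tris[:, 1] - tris[:, 2], axis=1),
                np.linalg.norm(tris[:, 2] - tris[:, 0], axis=1),
                np.linalg.norm(tris[:, 0] - tris[:, 1], axis=1),
            ],
            axis=1,
        )
    return tris, parents


class SurfaceProximity:
    """Closest-point queries against a fixed triangle mesh.

    Oversized triangles are internally bisected into a near-uniform element
    soup (geometry unchanged), then candidates are the k nearest element
    centroids and the exact point-to-triangle projection is evaluated on
    each.  Face indices reported back always refer to the *original* mesh.
    """

    def __init__(self, mesh: TriangleMesh, k: int = 16):
        if mesh.is_empty():
            raise EmptySelectionError("cannot build proximity query on empty mesh")
        self._normals = mesh.face_normals()
        tris, parents = _refine_soup(
            mesh.triangles, np.arange(mesh.n_faces, dtype=np.int64)
        )
        self._tri = tris
        self._parents = parents
        centroids = tris.mean(axis=1)
        self._centroid_tree = cKDTree(centroids)
        # certification bound: farthest centroid-to-vertex distance
        self._radius_bound = float(
            np.linalg.norm(tris - centroids[:, None, :], axis=2).max()
        )
        self._k = min(k, len(tris))

    def query(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest_points, distances) for each query point."""
        cp, dist, _ = self.query_faces(points)
        return cp, dist

    def _evaluate(self, pts, idx):
        cand = self._tri[idx]  # (n, k, 3, 3)
        cp = _closest_point_on_triangles(
            pts[:, None, :], cand[:, :, 0], cand[:, :, 1], cand[:, :, 2]
        )
        d2 = np.sum((cp - pts[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(pts))
        return cp[rows, best], np.sqrt(d2[rows, best]), idx[rows, best]

    def query_faces(self, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, distances, original-mesh face indices).

        The candidate set is certified: whenever the k-th candidate-centroid
        distance does not exceed ``d_best + radius_bound`` (so a farther,
        unevaluated element could still contain a closer surface point —
        e.g. the many slivers crowding a fan apex), the affected points are
        re-queried with a larger k until the bound is met.  Queries are
        therefore exact, not approximate.
        """
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        n_elem = len(self._tri)
        k = self._k
        dist_c, idx = self._centroid_tree.query(pts, k=k)
        if k == 1:
            dist_c, idx = dist_c[:, None], idx[:, None]
        cp, dist, elem = self._evaluate(pts, idx)
        pending = (
            np.zeros(len(pts), dtype=bool)
            if k >= n_elem
            else dist_c[:, -1] < dist + self._radius_bound
        )
        while pending.any():
            k = min(4 * k, n_elem)
            sub = np.nonzero(pending)[0]
            dist_c_s, idx_s = self._centroid_tree.query(pts[sub], k=k)
            cp_s, dist_s, elem_s = self._evaluate(pts[sub], idx_s)
            cp[sub], dist[sub], elem[sub] = cp_s, dist_s, elem_s
            if k >= n_elem:
                break
            pending[sub] = dist_c_s[:, -1] < dist_s + self._radius_bound
        return cp, dist, self._parents[elem]

    def face_normal(self, face_indices) -> np.ndarray:
        return self._normals[face_indices]


def _point_to_plane_step(cur, cp, normals) -> RigidTransform:
    """One linearized point-to-plane update (small rotation assumption).

    Minimises ``sum(((p + w x p + t - q) . n)^2)`` over the twist (w, t)
    and returns the corresponding incremental rigid transform.  Converges
    far faster than the point-to-point step in tangential sliding modes.
    """
    from scipy.spatial.transform import Rotation

    a = np.hstack([np.cross(cur, normals), normals])  # (n, 6)
    b = -np.sum((cur - cp) * normals, axis=1)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    rot = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(rot, x[3:])


def _trim_mask(dist: np.ndarray) -> np.ndarray:
    """mean + 2 SD auto-threshold; degenerates to keep-all when the
    threshold would not separate anything."""
    thr = dist.mean() + 2.0 * dist.std()
    if thr <= dist.min() + 1e-12:
        return np.ones(len(dist), dtype=bool)
    return dist < thr


def icp(
    moving,
    fixed: TriangleMesh,
    init: RigidTransform | None = None,
    params: IcpParams = IcpParams(),
) -> RegistrationResult:
    """Iterative closest point registration of ``moving`` onto ``fixed``.

    ``moving`` may be a :class:`TriangleMesh` (area-weighted samples are
    drawn with ``params.seed``) or an (n, 3) point array used as-is.  The
    returned transform maps the *original* moving coordinates onto the fixed
    surface (it is re-estimated from scratch each iteration, not chained
    incrementally).
    """
    if isinstance(moving, TriangleMesh):
        pts0 = sample_surface(moving, params.sample_count, params.seed)
    else:
        pts0 = np.asarray(moving, dtype=np.float64).reshape(-1, 3)
    if len(pts0) < 3:
        raise RegistrationError("need at least 3 moving points")
    prox = SurfaceProximity(fixed)

    transform = init if init is not None else RigidTransform.identity()
    history: list[float] = []
    keep = np.ones(len(pts0), dtype=bool)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        cur = transform.apply(pts0)
        cp, dist, fid = prox.query_faces(cur)
        keep = _trim_mask(dist) if params.trim_mode == "auto_threshold" else np.ones(
            len(dist), dtype=bool
        )
        if keep.sum() < 3:
            raise TrimmingCollapseError(
                f"only {int(keep.sum())} correspondences survived trimming"
            )
        if params.metric == "point_to_point":
            transform = kabsch(pts0[keep], cp[keep])
        else:
            transform = _point_to_plane_step(
                cur[keep], cp[keep], prox.face_normal(fid[keep])
            ).compose(transform)
        residual = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(residual)
        if len(history) >= 2 and abs(history[-2] - residual) < params.convergence_tol:
            converged = True
            break

    # final evaluation at the returned transform
    cp, dist = prox.query(transform.apply(pts0))
    keep = _trim_mask(dist) if params.trim_mode == "auto_threshold" else np.ones(
        len(dist), dtype=bool
    )
    residual = float(np.sqrt(np.mean(dist[keep] ** 2)))
    return RegistrationResult(
        transform=transform,
        mean_residual=residual,
        iterations_run=iterations,
        converged=converged,
        retained_fraction=float(keep.mean()),
        residual_history=history,
    )


def restrict_to_region(
    mesh: TriangleMesh, plane: Plane, side: str, margin: float = 2.0
) -> np.ndarray:
    """Vertices of ``mesh`` on the requested side of ``plane``.

    A dead zone of ``margin`` mm around the plane is excluded so that the
    cut edge itself never drives a registration.
    """
    mask = select_side(mesh.vertices, plane, side, margin)
    if not mask.any():
        raise EmptySelectionError(f"region selection (side={side!r}) is empty")
    return mesh.vertices[mask]
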