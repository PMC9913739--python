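"""Triangle-mesh and landmark data model, IO, and elementary surface geometry.

The types here are the plumbing every later stage relies on: a cleaned
:class:`TriangleMesh`, an ordered :class:`LandmarkSet` whose order is the
correspondence key across specimens, on-surface points expressed in
barycentric coordinates (:class:`SurfacePoint`), and the semilandmark
template that couples a mesh, its anatomical landmarks and an evenly
sampled set of surface semilandmarks.

Mesh files are read through :mod:`trimesh` (PLY ASCII/binary and OBJ);
nearest-point queries and k-means surface sampling are implemented here
because downstream code depends on their exact determinism guarantees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "LandmarkSet",
    "SurfacePoint",
    "SemilandmarkTemplate",
    "load_mesh",
    "save_mesh",
    "nearest_point_on_surface",
    "closest_points",
    "kmeans_surface_sample",
    "triangle_areas",
    "centroid_size",
    "load_landmarks",
    "save_landmarks",
    "load_semilandmark_template_csv",
    "save_semilandmark_template_csv",
]


class MeshValidationError(ValueError):
    """Mesh violates a structural invariant (too few vertices, bad faces...)."""


@dataclass(frozen=True)
class TriangleMesh:
    """An indexed triangle surface: ``vertices`` (V,3) float, ``faces`` (F,3) int.

    Face indices are 0-based. All faces must reference distinct, valid
    vertices and have strictly positive area (enforced at construction;
    use :func:`load_mesh` to clean raw files first).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (V,3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError(f"faces must be (F,3), got {f.shape}")
        if v.shape[0] < 4:
            raise MeshValidationError(f"mesh needs >=4 vertices, got {v.shape[0]}")
        if f.shape[0] < 1:
            raise MeshValidationError("mesh needs >=1 face")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise MeshValidationError("face index out of range")
        if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
            raise MeshValidationError("face with repeated vertex index")
        areas = _raw_areas(v, f)
        if (areas <= 0.0).any():
            raise MeshValidationError("zero-area face present; clean with load_mesh")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def diameter(self) -> float:
        """Bounding-box diagonal — the mesh's characteristic length scale."""
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def face_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.vertices[self.faces[:, 0]],
                self.vertices[self.faces[:, 1]],
                self.vertices[self.faces[:, 2]])

    def areas(self) -> np.ndarray:
        return _raw_areas(self.vertices, self.faces)

    def face_normals(self) -> np.ndarray:
        a, b, c = self.face_corners()
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length)."""
        a, b, c = self.face_corners()
        fn = np.cross(b - a, c - a)  # magnitude = 2*area: area weighting for free
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return vn / norms

    def edges_unique(self) -> np.ndarray:
        """(E,2) sorted unique undirected edges."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology, new vertex positions."""
        return TriangleMesh(np.asarray(vertices, dtype=float), self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


def _raw_areas(v: np.ndarray, f: np.ndarray) -> np.ndarray:
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered, uniquely labelled 3D landmarks. Order is the correspondence key."""

    labels: tuple[str, ...]
    points: np.ndarray

    def __post_init__(self):
        labels = tuple(str(s) for s in self.labels)
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n,3), got {pts.shape}")
        if len(labels) != pts.shape[0]:
            raise ValueError("labels and points length mismatch")
        if len(set(labels)) != len(labels):
            raise ValueError("landmark labels must be unique")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.labels)

    def check_matches(self, other: "LandmarkSet") -> None:
        if self.labels != other.labels:
            raise ValueError("landmark label sets/order do not correspond")


@dataclass(frozen=True)
class SurfacePoint:
    """A point on a specific face, stored as barycentric weights."""

    face_index: int
    barycentric: np.ndarray  # (3,) nonnegative, sums to 1
    point: np.ndarray        # (3,) cartesian

    def __post_init__(self):
        b = np.asarray(self.barycentric, dtype=float)
        p = np.asarray(self.point, dtype=float)
        if abs(b.sum() - 1.0) > 1e-12 or (b < -1e-12).any():
            raise ValueError("barycentric weights must be nonnegative and sum to 1")
        object.__setattr__(self, "barycentric", b)
        object.__setattr__(self, "point", p)


def surface_points_to_arrays(pts: list[SurfacePoint]):
    """(faces (k,), bary (k,3), xyz (k,3)) from a SurfacePoint list."""
    faces = np.array([p.face_index for p in pts], dtype=np.int64)
    bary = np.array([p.barycentric for p in pts], dtype=float)
    xyz = np.array([p.point for p in pts], dtype=float)
    return faces, bary, xyz


def arrays_to_surface_points(mesh: TriangleMesh, faces: np.ndarray,
                             bary: np.ndarray) -> list[SurfacePoint]:
    xyz = barycentric_to_cartesian(mesh, faces, bary)
    return [SurfacePoint(int(f), b, p) for f, b, p in zip(faces, bary, xyz)]


def barycentric_to_cartesian(mesh: TriangleMesh, faces: np.ndarray,
                             bary: np.ndarray) -> np.ndarray:
    tri = mesh.vertices[mesh.faces[np.asarray(faces, dtype=np.int64)]]  # (k,3,3)
    return np.einsum("kj,kjd->kd", np.asarray(bary, dtype=float), tri)


@dataclass(frozen=True)
class SemilandmarkTemplate:
    """Reference mesh + anatomical landmarks + k on-surface semilandmarks."""

    mesh: TriangleMesh
    landmarks: LandmarkSet
    semilandmarks: tuple[SurfacePoint, ...]
    density_label: int = field(default=0)

    def __post_init__(self):
        semis = tuple(self.semilandmarks)
        k = len(semis)
        label = self.density_label or k
        if label != k:
            raise ValueError(f"density_label {label} != semilandmark count {k}")
        for sp in semis:
            if not (0 <= sp.face_index < self.mesh.n_faces):
                raise ValueError("semilandmark face index outside template mesh")
        object.__setattr__(self, "semilandmarks", semis)
        object.__setattr__(self, "density_label", label)

    @property
    def k(self) -> int:
        return len(self.semilandmarks)

    def semilandmark_points(self) -> np.ndarray:
        return np.array([sp.point for sp in self.semilandmarks])

    def configuration_points(self) -> np.ndarray:
        """Landmarks stacked above semilandmarks: the template configuration."""
        return np.vstack([self.landmarks.points, self.semilandmark_points()])


# ---------------------------------------------------------------- mesh IO

def load_mesh(path: str | Path) -> TriangleMesh:
    """Load a PLY or OBJ triangle mesh, dropping degenerate and duplicate faces.

    Degenerate means repeated vertex indices or zero area. Unreferenced
    vertices are removed. Removal counts are logged at INFO level.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    tm = trimesh.load(str(path), file_type=path.suffix.lstrip(".").lower(),
                      process=False, force="mesh")
    v = np.asarray(tm.vertices, dtype=float)
    f = np.asarray(tm.faces, dtype=np.int64)
    if f.ndim != 2 or f.shape[1] != 3:
        raise MeshValidationError(f"{path}: not a pure triangle mesh")

    n0 = f.shape[0]
    # repeated-index faces
    keep = ~((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2]))
    f = f[keep]
    # zero-area faces (distinct indices but collinear corners)
    if f.shape[0]:
        f = f[_raw_areas(v, f) > 0.0]
    # duplicate faces irrespective of winding
    if f.shape[0]:
        _, idx = np.unique(np.sort(f, axis=1), axis=0, return_index=True)
        f = f[np.sort(idx)]
    dropped = n0 - f.shape[0]
    if dropped:
        logger.info("%s: dropped %d degenerate/duplicate faces", path.name, dropped)

    # drop unreferenced vertices, remap indices
    used = np.unique(f)
    if used.size < v.shape[0]:
        logger.info("%s: dropped %d unreferenced vertices", path.name,
                    v.shape[0] - used.size)
        remap = -np.ones(v.shape[0], dtype=np.int64)
        remap[used] = np.arange(used.size)
        v, f = v[used], remap[f]

    if v.shape[0] < 4:
        raise MeshValidationError(f"{path}: fewer than 4 vertices after cleaning")
    return TriangleMesh(v, f)


def save_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write PLY (ASCII) or OBJ, chosen by extension."""
    path = Path(path)
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
    elif path.suffix.lower() == ".obj":
        path.write_text(trimesh.exchange.obj.export_obj(tm))
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")


# ------------------------------------------------- nearest point on surface

def closest_points(mesh: TriangleMesh, queries: np.ndarray,
                   chunk: int = 4_000_000):
    """Exact closest points on a triangle mesh for a batch of queries.

    Evaluates the point-to-triangle distance against *every* face
    (vectorised Ericson closest-point-on-triangle) and takes, per query,
    the minimum distance with ties resolved to the lowest face index.

    Returns ``(points (q,3), face_idx (q,), bary (q,3), dist (q,))``.
    """
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    a, b, c = mesh.face_corners()
    nq, nf = q.shape[0], a.shape[0]
    rows = max(1, chunk // max(nf, 1))

    out_p = np.empty((nq, 3))
    out_f = np.empty(nq, dtype=np.int64)
    out_b = np.empty((nq, 3))
    out_d = np.empty(nq)
    for lo in range(0, nq, rows):
        hi = min(lo + rows, nq)
        p, f, w, d = _closest_block(q[lo:hi], a, b, c)
        out_p[lo:hi], out_f[lo:hi], out_b[lo:hi], out_d[lo:hi] = p, f, w, d
    return out_p, out_f, out_b, out_d


def _closest_block(q, a, b, c):
    """Closest point of each query (m,3) against all triangles (f,3)."""
    s, t = _closest_point_triangle_params(q[:, None, :], a[None], b[None], c[None])
    u = 1.0 - s - t
    pts = u[..., None] * a[None] + s[..., None] * b[None] + t[..., None] * c[None]
    d2 = np.einsum("mfd,mfd->mf", pts - q[:, None, :], pts - q[:, None, :])
    fidx = np.argmin(d2, axis=1)  # first (lowest-index) minimum
    m = np.arange(q.shape[0])
    bary = np.stack([u[m, fidx], s[m, fidx], t[m, fidx]], axis=1)
    # clip tiny negatives from roundoff, renormalise
    bary = np.clip(bary, 0.0, None)
    bary /= bary.sum(axis=1, keepdims=True)
    return pts[m, fidx], fidx, bary, np.sqrt(d2[m, fidx])


def _closest_point_triangle_params(p, a, b, c):
    """Ericson's closest-point-on-triangle, vectorised; returns (s,t) with
    closest = a + s*(b-a) + t*(c-a)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...d,...d->...", ab, ap)
    d2 = np.einsum("...d,...d->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...d,...d->...", ab, bp)
    d4 = np.einsum("...d,...d->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...d,...d->...", ab, cp)
    d6 = np.einsum("...d,...d->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom_v = vb + vc + va

    s = np.zeros(np.broadcast(d1, d2).shape)
    t = np.zeros_like(s)
    done = np.zeros(s.shape, dtype=bool)

    # vertex A region
    m = (d1 <= 0) & (d2 <= 0)
    done |= m
    # vertex B region
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    s[m] = 1.0
    done |= m
    # vertex C region
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    t[m] = 1.0
    done |= m
    # edge AB
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_ab = d1 / (d1 - d3)
    s[m] = s_ab[m]
    done |= m
    # edge AC
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_ac = d2 / (d2 - d6)
    t[m] = t_ac[m]
    done |= m
    # edge BC
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    s[m] = 1.0 - w_bc[m]
    t[m] = w_bc[m]
    done |= m
    # interior
    m = ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        s_in = vb / denom_v
        t_in = vc / denom_v
    s[m] = s_in[m]
    t[m] = t_in[m]
    return s, t


def nearest_point_on_surface(mesh: TriangleMesh, query: np.ndarray) -> SurfacePoint:
    """Exact closest on-surface point to ``query`` (ties -> lowest face index)."""
    p, f, b, _ = closest_points(mesh, np.asarray(query, dtype=float)[None, :])
    return SurfacePoint(int(f[0]), b[0], p[0])


# ----------------------------------------------------------- surface sampling

def sample_surface_dense(mesh: TriangleMesh, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Area-weighted uniform random points on the surface (n,3)."""
    areas = mesh.areas()
    fidx = rng.choice(mesh.n_faces, size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    u, v, w = 1.0 - r1, r1 * (1.0 - r2), r1 * r2
    a, b, c = mesh.face_corners()
    return (u[:, None] * a[fidx] + v[:, None] * b[fidx] + w[:, None] * c[fidx])


def kmeans_surface_sample(mesh: TriangleMesh, k: int, seed: int,
                          oversample: int = 50) -> list[SurfacePoint]:
    """k surface points spread as evenly as possible, via k-means.

    Runs k-means++ (fixed ``seed``) on an area-weighted dense sampling of
    ``oversample * k`` random surface points, then projects each centroid
    back onto the surface. Deterministic for a given (mesh, k, seed).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > mesh.n_vertices:
        raise ValueError(f"k={k} exceeds vertex count {mesh.n_vertices}")
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    dense = sample_surface_dense(mesh, oversample * k, rng)
    km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                random_state=int(seed) % (2**31), max_iter=300)
    km.fit(dense)
    _, faces, bary, _ = closest_points(mesh, km.cluster_centers_)
    return arrays_to_surface_points(mesh, faces, bary)


# ------------------------------------------------------------- measurements

def triangle_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-face areas: half the cross-product norm of two edge vectors."""
    return mesh.areas()


def centroid_size(points: np.ndarray) -> float:
    """√(Σ‖xᵢ − x̄‖²): the standard size variable of geometric morphometrics."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 points")
    d = pts - pts.mean(axis=0)
    cs = float(np.sqrt((d * d).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points identical")
    return cs


# ------------------------------------------------------------- landmark IO

def load_landmarks(path: str | Path) -> LandmarkSet:
    """Read `label,x,y,z` CSV."""
    df = pd.read_csv(path)
    required = ["label", "x", "y", "z"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: expected header label,x,y,z")
    return LandmarkSet(tuple(df["label"].astype(str)),
                       df[["x", "y", "z"]].to_numpy(dtype=float))


def save_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    pd.DataFrame({"label": lms.labels, "x": lms.points[:, 0],
                  "y": lms.points[:, 1], "z": lms.points[:, 2]}).to_csv(
        path, index=False)


def save_semilandmark_template_csv(template: SemilandmarkTemplate,
                                   path: str | Path) -> None:
    """Serialise semilandmarks as `index,face,b0,b1,b2`."""
    faces, bary, _ = surface_points_to_arrays(list(template.semilandmarks))
    pd.DataFrame({"index": np.arange(len(faces)), "face": faces,
                  "b0": bary[:, 0], "b1": bary[:, 1], "b2": bary[:, 2]}).to_csv(
        path, index=False)


def load_semilandmark_template_csv(mesh: TriangleMesh, landmarks: LandmarkSet,
                                   path: str | Path) -> SemilandmarkTemplate:
    df = pd.read_csv(path)
    faces = df["face"].to_numpy(dtype=np.int64)
    bary = df[["b0", "b1", "b2"]].to_numpy(dtype=float)
    semis = arrays_to_surface_points(mesh, faces, bary)
    return SemilandmarkTemplate(mesh, landmarks, tuple(semis))
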