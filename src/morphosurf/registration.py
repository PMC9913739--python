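"""Rigid and non-rigid registration of a template mesh to a specimen.

Three layers, matching the registration steps the semilandmarking
methods are built from:

* :func:`similarity_fit` — closed-form least-squares (LS) similarity /
  rigid alignment of two corresponding landmark sets (Umeyama), never
  returning a reflection.
* :func:`icp_refine` — iterative closest point refinement of a rigid
  transform, alternating nearest-point correspondences on the specimen
  surface with a rigid least-squares update (scale frozen at the initial
  value, because ICP here "rigidly" refits an already LS-scaled template).
* :func:`nicp_register` — optimal-step non-rigid ICP: one 3x4 affine per
  template vertex, a stiffness term over mesh edges relaxed through a
  decreasing schedule, a landmark term, and normal/distance pruning of
  nearest-point correspondences. Solved as a sparse linear least-squares
  problem at each inner iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import LandmarkSet, TriangleMesh, closest_points

logger = logging.getLogger(__name__)

__all__ = ["SimilarityTransform", "NICPParams", "DenseCorrespondence",
           "similarity_fit", "icp_refine", "nicp_register",
           "average_correspondences"]


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * (x @ rotation.T) + translation, det(rotation)=+1."""

    rotation: np.ndarray    # (3,3) proper orthonormal
    translation: np.ndarray  # (3,)
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, dtype=float) @ self.rotation.T) \
            + self.translation

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)


def similarity_fit(source: LandmarkSet, target: LandmarkSet,
                   with_scale: bool = True) -> SimilarityTransform:
    """Least-squares similarity (or rigid) fit of labelled landmark sets.

    Closed-form Umeyama/orthogonal-Procrustes solution; the rotation is
    always proper, so mirrored targets give a positive residual rather
    than a reflection.
    """
    source.check_matches(target)
    X = source.points
    Y = target.points
    n = X.shape[0]
    if n < 3:
        raise ValueError("similarity fit needs at least 3 landmarks")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1e-300):
        raise ValueError("landmarks are collinear: rotation is undetermined")
    C = Yc.T @ Xc / n
    u, d, vt = np.linalg.svd(C)
    s = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s[-1] = -1.0
    R = (u * s) @ vt
    if with_scale:
        var_x = (Xc * Xc).sum() / n
        scale = float((d * s).sum() / var_x)
    else:
        scale = 1.0
    t = my - scale * (R @ mx)
    return SimilarityTransform(R, t, scale)


def icp_refine(template_anchor_points: np.ndarray, target_mesh: TriangleMesh,
               init: SimilarityTransform, max_iters: int = 50,
               tol: float = 1e-8,
               fixed_indices: np.ndarray | None = None,
               fixed_targets: np.ndarray | None = None) -> SimilarityTransform:
    """ICP refinement of a rigid alignment (scale frozen at ``init.scale``).

    Anchors are the template landmarks plus semilandmark points. If
    ``fixed_indices``/``fixed_targets`` are given, those anchors keep a
    label-matched target instead of a nearest-point correspondence.
    Stops when the RMS improvement drops below ``tol`` (relative to mesh
    diameter) or after ``max_iters``. The objective is non-increasing by
    construction.
    """
    P = np.asarray(template_anchor_points, dtype=float)
    if P.size == 0:
        raise ValueError("anchor point set is empty")
    scale = init.scale
    R, t = init.rotation, init.translation
    diam = target_mesh.diameter
    prev_rms = np.inf
    it = 0
    for it in range(max_iters):
        cur = scale * (P @ R.T) + t
        corr, _, _, dist = closest_points(target_mesh, cur)
        if fixed_indices is not None:
            corr = corr.copy()
            corr[fixed_indices] = fixed_targets
            dist = np.linalg.norm(cur - corr, axis=1)
        rms = float(np.sqrt((dist**2).mean()))
        if prev_rms - rms < tol * diam:
            prev_rms = min(prev_rms, rms)
            break
        prev_rms = rms
        # rigid update with frozen scale: minimise ||s R P + t - corr||
        Ps = scale * P
        mp, mq = Ps.mean(axis=0), corr.mean(axis=0)
        C = (corr - mq).T @ (Ps - mp)
        u, _, vt = np.linalg.svd(C)
        s3 = np.ones(3)
        if np.linalg.det(u) * np.linalg.det(vt) < 0:
            s3[-1] = -1.0
        R = (u * s3) @ vt
        t = mq - R @ mp
    else:
        it += 1  # pragma: no cover
    logger.debug("icp_refine: %d iterations, terminal RMS %.3e", it, prev_rms)
    return SimilarityTransform(R, t, scale)


@dataclass(frozen=True)
class NICPParams:
    """Optimal-step NICP controls.

    ``stiffness_schedule`` is the strictly decreasing sequence of edge
    stiffness weights α; ``gamma`` weights the skew/translation part of
    each per-vertex affine in the stiffness norm; ``landmark_weights``
    (same length as the schedule, padded with zeros) weight the landmark
    term at each outer step. Correspondences are pruned when surface
    normals disagree by more than ``prune_angle_deg`` or the closest
    point is farther than ``prune_distance_frac`` of the specimen
    diameter.
    """

    stiffness_schedule: tuple[float, ...] = (50.0, 20.0, 5.0, 2.0, 0.8, 0.5,
                                             0.35, 0.2)
    gamma: float = 1.0
    landmark_weights: tuple[float, ...] = (5.0, 2.0, 0.5, 0.0)
    inner_tol: float = 1e-4
    max_inner_iters: int = 15
    prune_angle_deg: float = 60.0
    prune_distance_frac: float = 0.1

    def __post_init__(self):
        sched = tuple(float(a) for a in self.stiffness_schedule)
        if len(sched) < 1:
            raise ValueError("stiffness schedule must be non-empty")
        if any(a <= 0 for a in sched):
            raise ValueError("stiffness values must be positive")
        if any(b >= a for a, b in zip(sched, sched[1:])):
            raise ValueError("stiffness schedule must be strictly decreasing")
        if self.inner_tol <= 0 or self.max_inner_iters < 1:
            raise ValueError("tolerances must be positive")
        lw = tuple(float(w) for w in self.landmark_weights)
        if any(w < 0 for w in lw):
            raise ValueError("landmark weights must be nonnegative")
        lw = lw + (0.0,) * max(0, len(sched) - len(lw))
        object.__setattr__(self, "stiffness_schedule", sched)
        object.__setattr__(self, "landmark_weights", lw[:len(sched)])

    @classmethod
    def from_dict(cls, d: dict) -> "NICPParams":
        kwargs = {}
        for key in ("stiffness_schedule", "landmark_weights"):
            if key in d:
                kwargs[key] = tuple(float(x) for x in d[key])
        for key in ("gamma", "inner_tol", "prune_angle_deg",
                    "prune_distance_frac"):
            if key in d:
                kwargs[key] = float(d[key])
        if "max_inner_iters" in d:
            kwargs["max_inner_iters"] = int(d["max_inner_iters"])
        return cls(**kwargs)


@dataclass(frozen=True)
class DenseCorrespondence:
    """NICP output: the deformed template and per-vertex matches on the
    specimen (with a validity mask from correspondence pruning)."""

    deformed_template: TriangleMesh
    target_points: np.ndarray   # (V,3) closest specimen points
    target_faces: np.ndarray    # (V,)
    target_bary: np.ndarray     # (V,3)
    validity_mask: np.ndarray   # (V,) bool
    iterations: int = 0


def nicp_register(template: TriangleMesh, specimen: TriangleMesh,
                  template_landmarks: LandmarkSet,
                  specimen_landmarks: LandmarkSet,
                  params: NICPParams | None = None) -> DenseCorrespondence:
    """Optimal-step non-rigid ICP of an (already coarsely aligned) template.

    Unknowns are one 3x4 affine per template vertex, stacked in X
    ((4V,3)). Each outer step fixes a stiffness α and iterates: find
    pruned nearest-point correspondences of the current vertices on the
    specimen, then solve

        min ‖W(DX − U)‖² + α‖(M⊗G)X‖² + β‖D_L X − U_L‖²

    where D places the original template vertices, M is the node-arc
    incidence matrix over template edges, G = diag(1,1,1,γ), and the
    landmark rows tie the template vertices nearest each template
    landmark to the specimen landmarks.
    """
    if params is None:
        params = NICPParams()
    template_landmarks.check_matches(specimen_landmarks)

    V = template.n_vertices
    edges = template.edges_unique()
    E = edges.shape[0]
    # connectivity check: stiffness term must tie all vertices together
    import scipy.sparse.csgraph as csgraph
    adj = sp.coo_matrix((np.ones(E), (edges[:, 0], edges[:, 1])), shape=(V, V))
    ncomp, _ = csgraph.connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError(f"template mesh has {ncomp} connected components; "
                         "NICP stiffness system would be singular")

    # D: (V, 4V) sparse, row v = [vx vy vz 1] in columns 4v..4v+3
    verts = template.vertices
    cols = (4 * np.arange(V)[:, None] + np.arange(4)[None, :]).ravel()
    rows = np.repeat(np.arange(V), 4)
    vals = np.hstack([verts, np.ones((V, 1))]).ravel()
    D = sp.csr_matrix((vals, (rows, cols)), shape=(V, 4 * V))

    # stiffness matrix M ⊗ G
    Mi = sp.coo_matrix(
        (np.hstack([np.ones(E), -np.ones(E)]),
         (np.hstack([np.arange(E), np.arange(E)]),
          np.hstack([edges[:, 0], edges[:, 1]]))), shape=(E, V))
    G = sp.diags([1.0, 1.0, 1.0, params.gamma])
    MG = sp.kron(Mi.tocsr(), G, format="csr")

    # landmark rows: each template landmark expressed barycentrically over
    # its closest template face, so the term is exact for on-face landmarks
    _, lm_faces, lm_bary, _ = closest_points(template,
                                             template_landmarks.points)
    nl = lm_faces.shape[0]
    lrows, lcols, lvals = [], [], []
    for li in range(nl):
        for corner, bw in zip(template.faces[lm_faces[li]], lm_bary[li]):
            lrows.extend([li] * 4)
            lcols.extend(4 * corner + np.arange(4))
            lvals.extend(bw * np.array([*verts[corner], 1.0]))
    DL = sp.csr_matrix((lvals, (lrows, lcols)), shape=(nl, 4 * V))
    UL = specimen_landmarks.points

    spec_fnormals = specimen.face_normals()
    tmpl_vnormals = template.vertex_normals()
    diam = specimen.diameter
    cos_prune = np.cos(np.deg2rad(params.prune_angle_deg))

    # X init: per-vertex identity
    X = np.zeros((4 * V, 3))
    X[0::4, 0] = 1.0
    X[1::4, 1] = 1.0
    X[2::4, 2] = 1.0

    total_inner = 0
    for alpha, beta in zip(params.stiffness_schedule, params.landmark_weights):
        for _ in range(params.max_inner_iters):
            current = D @ X
            corr, cfaces, cbary, cdist = closest_points(specimen, current)
            w = np.ones(V)
            w[cdist > params.prune_distance_frac * diam] = 0.0
            cosang = np.einsum("vd,vd->v", tmpl_vnormals,
                               spec_fnormals[cfaces])
            w[cosang < cos_prune] = 0.0

            Wd = sp.diags(w)
            blocks = [MG * alpha, Wd @ D]
            rhs = [np.zeros((4 * E, 3)), w[:, None] * corr]
            if beta > 0:
                blocks.append(DL * beta)
                rhs.append(beta * UL)
            A = sp.vstack(blocks, format="csr")
            B = np.vstack(rhs)
            AtA = (A.T @ A).tocsc()
            AtB = A.T @ B
            X_new = spla.spsolve(AtA, AtB)
            total_inner += 1
            change = np.linalg.norm(X_new - X) / np.sqrt(V)
            X = X_new
            if change < params.inner_tol * (1.0 + diam):
                break

    deformed = template.with_vertices(D @ X)
    corr, cfaces, cbary, cdist = closest_points(specimen, deformed.vertices)
    w = np.ones(V, dtype=bool)
    w &= cdist <= params.prune_distance_frac * diam
    cosang = np.einsum("vd,vd->v", deformed.vertex_normals(),
                       spec_fnormals[cfaces])
    w &= cosang >= cos_prune
    logger.debug("nicp_register: %d inner solves, %d/%d valid correspondences",
                 total_inner, int(w.sum()), V)
    return DenseCorrespondence(deformed, corr, cfaces, cbary, w, total_inner)


def average_correspondences(
        correspondences: list[DenseCorrespondence]) -> TriangleMesh:
    """Mean mesh from per-specimen dense correspondences.

    The per-specimen matched point sets (all in template topology) are
    GPA-aligned using the vertices valid in every specimen, and the mean
    is the per-vertex arithmetic average of the aligned matched points,
    excluding invalid vertices per specimen. Faces are copied from the
    template.
    """
    if not correspondences:
        raise ValueError("no correspondences to average")
    faces0 = correspondences[0].deformed_template.faces
    for c in correspondences[1:]:
        if not np.array_equal(c.deformed_template.faces, faces0):
            raise ValueError("correspondences do not share template topology")

    pts = np.stack([c.target_points for c in correspondences])   # (n,V,3)
    masks = np.stack([c.validity_mask for c in correspondences])  # (n,V)
    if len(correspondences) == 1:
        return correspondences[0].deformed_template.with_vertices(pts[0])

    common = masks.all(axis=0)
    if common.sum() < 4:
        raise ValueError("too few commonly valid vertices to align")
    from .shape_stats import gpa
    sample = gpa(pts[:, common, :])
    # re-apply each specimen's similarity transform to its full vertex set
    aligned_full = np.empty_like(pts)
    for i in range(pts.shape[0]):
        src = pts[i, common, :]
        mu = src.mean(axis=0)
        cs = np.sqrt(((src - mu)**2).sum())
        # recover the rotation GPA used from the aligned sub-configuration
        from .shape_stats import optimal_rotation
        R = optimal_rotation(sample.aligned[i], (src - mu) / cs)
        aligned_full[i] = ((pts[i] - mu) / cs) @ R

    counts = masks.sum(axis=0)[:, None].astype(float)
    counts[counts == 0] = 1.0
    mean_v = (aligned_full * masks[:, :, None]).sum(axis=0) / counts
    return correspondences[0].deformed_template.with_vertices(mean_v)
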