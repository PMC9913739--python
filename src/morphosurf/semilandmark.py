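"""The three landmark-driven semilandmarking methods and the slider.

Every method transfers the template's semilandmarks onto a specimen
surface, anchored by the anatomical landmarks:

* ``sliding_tps`` — TPS-warp the template semilandmarks to the specimen
  through the landmarks, project onto the surface, then slide them in
  their local tangent planes to minimise the bending energy of the TPS
  from the template configuration to the slid configuration.
* ``ls_icp`` — least-squares similarity fit on landmarks, rigid ICP
  refinement with landmarks + semilandmarks as anchors, then nearest-
  point projection of the registered semilandmarks (no sliding).
* ``tps_nicp`` — TPS-warp the whole template mesh to the specimen
  through the landmarks, refine with non-rigid ICP, then carry each
  semilandmark through its barycentric coordinates on the deformed
  template and project onto the specimen surface.

All three return the specimen's landmarks verbatim (fixed points)
followed by k on-surface semilandmarks in template order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import (LandmarkSet, SemilandmarkTemplate, SurfacePoint,
                   TriangleMesh, arrays_to_surface_points,
                   barycentric_to_cartesian, centroid_size, closest_points,
                   surface_points_to_arrays)
from .registration import NICPParams, icp_refine, nicp_register, similarity_fit
from .tps import bending_energy_matrix, tps_apply, tps_fit

logger = logging.getLogger(__name__)

__all__ = ["Configuration", "SlidingResult", "project_template_semilandmarks",
           "slide_semilandmarks", "semilandmark_specimen", "METHODS"]

METHODS = ("sliding_tps", "ls_icp", "tps_nicp")


@dataclass(frozen=True)
class Configuration:
    """One specimen's landmark + semilandmark coordinates.

    The first ``n_fixed`` points are anatomical landmarks (fixed role),
    the remaining k are semilandmarks (sliding role), in template order.
    ``surface_faces``/``surface_bary`` optionally record where each
    semilandmark sits on its specimen mesh.
    """

    points: np.ndarray  # (L+k, 3)
    n_fixed: int
    surface_faces: np.ndarray | None = field(default=None, compare=False)
    surface_bary: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (p,3)")
        if not 0 <= self.n_fixed <= pts.shape[0]:
            raise ValueError("n_fixed out of range")
        object.__setattr__(self, "points", pts)

    @property
    def n_sliding(self) -> int:
        return self.points.shape[0] - self.n_fixed

    @property
    def roles(self) -> np.ndarray:
        return np.array(["fixed"] * self.n_fixed + ["sliding"] * self.n_sliding)

    @property
    def fixed_points(self) -> np.ndarray:
        return self.points[:self.n_fixed]

    @property
    def sliding_points(self) -> np.ndarray:
        return self.points[self.n_fixed:]


@dataclass(frozen=True)
class SlidingResult:
    configuration: Configuration
    bending_energy_trace: np.ndarray  # energy before each recorded state
    iterations_run: int


def project_template_semilandmarks(semis: np.ndarray,
                                   specimen: TriangleMesh) -> list[SurfacePoint]:
    """Project k (already registered/deformed) semilandmarks onto the
    specimen by exact nearest-point search, order preserved."""
    _, faces, bary, _ = closest_points(specimen, np.asarray(semis, dtype=float))
    return arrays_to_surface_points(specimen, faces, bary)


def _tangent_bases(mesh: TriangleMesh, faces: np.ndarray,
                   bary: np.ndarray) -> np.ndarray:
    """(k,3,2) orthonormal tangent bases from barycentrically interpolated
    area-weighted vertex normals."""
    vn = mesh.vertex_normals()
    n = np.einsum("kj,kjd->kd", bary, vn[mesh.faces[faces]])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    n = n / norms
    # stable perpendicular: cross with the axis least aligned with n
    helper = np.zeros_like(n)
    helper[np.arange(n.shape[0]), np.argmin(np.abs(n), axis=1)] = 1.0
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(n, t1)
    return np.stack([t1, t2], axis=2)


def slide_semilandmarks(reference: Configuration,
                        specimen_config: Configuration,
                        specimen_mesh: TriangleMesh,
                        max_iters: int = 3, tol: float = 1e-4) -> SlidingResult:
    """Slide semilandmarks along the specimen surface to minimise the TPS
    bending energy relative to the reference configuration.

    Each iteration (i) builds a tangent plane for every sliding point
    from interpolated vertex normals, (ii) solves the generalised
    least-squares step that minimises trace(YᵀBₑY) with fixed points
    immobile and each slider confined to its plane, and (iii) re-projects
    onto the surface. A step-halving backtrack keeps the recorded energy
    trace non-increasing despite the curvature error of re-projection.
    """
    if reference.points.shape != specimen_config.points.shape \
            or reference.n_fixed != specimen_config.n_fixed:
        raise ValueError("reference and specimen configurations must match in "
                         "length and roles")
    L = specimen_config.n_fixed
    k = specimen_config.n_sliding
    Y = specimen_config.points.copy()
    faces = specimen_config.surface_faces
    bary = specimen_config.surface_bary
    if faces is None or bary is None:
        _, faces, bary, dist = closest_points(specimen_mesh, Y[L:])
        if k and dist.max() > 1e-6 * specimen_mesh.diameter:
            raise ValueError("sliding points do not lie on the specimen mesh")
    faces = np.asarray(faces, dtype=np.int64)
    bary = np.asarray(bary, dtype=float)

    Be = bending_energy_matrix(reference.points)
    cs = centroid_size(Y)

    def energy(cfg: np.ndarray) -> float:
        return float(np.einsum("id,ij,jd->", cfg, Be, cfg))

    trace = [energy(Y)]
    iters = 0
    if k == 0:
        max_iters = 0
    for iters in range(1, max_iters + 1):
        T = _tangent_bases(specimen_mesh, faces, bary)  # (k,3,2)
        # GLS step: Y_new = Y + S t, S places tangent displacements.
        # Per coordinate d, S_d (p x 2k) has row (L+i) = T[i, d, :].
        p = Y.shape[0]
        A = np.zeros((2 * k, 2 * k))
        rhs = np.zeros(2 * k)
        BeY = Be @ Y  # (p,3)
        Bess = Be[L:, L:]  # (k,k)
        for d in range(3):
            Td = T[:, d, :]  # (k,2)
            # (S_dᵀ Be S_d)[(i,a),(j,b)] = Td[i,a] Be[L+i,L+j] Td[j,b]
            A += np.einsum("ia,ij,jb->iajb", Td, Bess, Td).reshape(2 * k, 2 * k)
            rhs -= (Td * BeY[L:, d][:, None]).reshape(2 * k)
        A += 1e-12 * np.trace(A) / max(2 * k, 1) * np.eye(2 * k)
        try:
            t_step = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            t_step, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        disp = np.einsum("kdt,kt->kd", T, t_step.reshape(k, 2))

        # backtrack so projection onto the curved surface never raises energy
        step = 1.0
        accepted = False
        for _ in range(6):
            cand = Y[L:] + step * disp
            proj, pf, pb, _ = closest_points(specimen_mesh, cand)
            Y_new = Y.copy()
            Y_new[L:] = proj
            if energy(Y_new) <= trace[-1] * (1 + 1e-9) + 1e-300:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            iters -= 1
            break
        change = np.linalg.norm(Y_new - Y) / np.sqrt(Y.shape[0])
        Y, faces, bary = Y_new, pf, pb
        trace.append(min(energy(Y), trace[-1]))
        if change < tol * cs:
            break

    cfg = Configuration(Y, L, surface_faces=faces, surface_bary=bary)
    return SlidingResult(cfg, np.array(trace), iters)


def semilandmark_specimen(template: SemilandmarkTemplate,
                          specimen: TriangleMesh,
                          specimen_landmarks: LandmarkSet,
                          method: str = "sliding_tps",
                          nicp_params: NICPParams | None = None,
                          slide_iters: int = 3, slide_tol: float = 1e-4,
                          icp_iters: int = 50,
                          with_scale: bool = True) -> Configuration:
    """Transfer the template's semilandmarks onto one specimen."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    template.landmarks.check_matches(specimen_landmarks)
    L = len(template.landmarks)
    tmpl_semis = template.semilandmark_points()

    if method == "sliding_tps":
        warp = tps_fit(template.landmarks.points, specimen_landmarks.points)
        moved = tps_apply(warp, tmpl_semis)
        sps = project_template_semilandmarks(moved, specimen)
        faces, bary, xyz = surface_points_to_arrays(sps)
        cfg0 = Configuration(
            np.vstack([specimen_landmarks.points, xyz]), L,
            surface_faces=faces, surface_bary=bary)
        ref = Configuration(template.configuration_points(), L)
        result = slide_semilandmarks(ref, cfg0, specimen,
                                     max_iters=slide_iters, tol=slide_tol)
        return result.configuration

    if method == "ls_icp":
        init = similarity_fit(template.landmarks, specimen_landmarks,
                              with_scale=with_scale)
        anchors = np.vstack([template.landmarks.points, tmpl_semis])
        xform = icp_refine(anchors, specimen, init, max_iters=icp_iters,
                           fixed_indices=np.arange(L),
                           fixed_targets=specimen_landmarks.points)
        moved = xform.apply(tmpl_semis)
        sps = project_template_semilandmarks(moved, specimen)
        faces, bary, xyz = surface_points_to_arrays(sps)
        return Configuration(np.vstack([specimen_landmarks.points, xyz]), L,
                             surface_faces=faces, surface_bary=bary)

    # tps_nicp
    warp = tps_fit(template.landmarks.points, specimen_landmarks.points)
    warped_mesh = template.mesh.with_vertices(tps_apply(warp,
                                                        template.mesh.vertices))
    warped_landmarks = LandmarkSet(template.landmarks.labels,
                                   specimen_landmarks.points)
    corr = nicp_register(warped_mesh, specimen, warped_landmarks,
                         specimen_landmarks, nicp_params)
    sfaces, sbary, _ = surface_points_to_arrays(list(template.semilandmarks))
    on_deformed = barycentric_to_cartesian(corr.deformed_template, sfaces, sbary)
    sps = project_template_semilandmarks(on_deformed, specimen)
    faces, bary, xyz = surface_points_to_arrays(sps)
    return Configuration(np.vstack([specimen_landmarks.points, xyz]), L,
                         surface_faces=faces, surface_bary=bary)
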