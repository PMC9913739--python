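"""Synthetic mesh populations with known ground truth.

Real cranial/head datasets are rarely redistributable, so every pipeline
stage here is exercised on simulated populations built from a smooth
base shape: an icosphere, an "ellipsoid head" (sphere with nose/brow/
chin bumps and a landmark-free scalp hemisphere), or a "crested
cranium" (ellipsoid with a sagittal ridge and brow bumps). A template
carries landmarks at geometrically identifiable bump apices plus evenly
k-means-sampled semilandmarks.

Each simulated specimen is the template deformed by

    x  ->  x + (lnCS_i − E[lnCS]) · A(x) + R_i(x),   then scaled by exp(u_i)

where A is a fixed smooth allometric displacement field (a TPS driven by
a few control displacements) and R_i is an independent zero-mean smooth
random TPS field. Landmark and configuration points are transported
through their barycentric coordinates on the deformed faces, so they lie
exactly on the (pre-noise) specimen surface and landmark correspondence
is exact by construction. I.i.d. Gaussian vertex noise is added *after*
ground truth is recorded, so recovery error is attributable.

``vertex_noise_sd`` and the deformation scales are fractions of the
normalised centroid size CS/√p (the RMS distance of vertices from the
centroid) and of the bounding-box diameter respectively — both natural,
point-count-free length scales of the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh import (LandmarkSet, SemilandmarkTemplate, TriangleMesh,
                   centroid_size, closest_points, kmeans_surface_sample,
                   sample_surface_dense, arrays_to_surface_points,
                   barycentric_to_cartesian)
from .shape_stats import AllometricModel, optimal_rotation, procrustes_distance
from .tps import tps_apply, tps_fit

__all__ = ["PopulationSpec", "SyntheticPopulation", "make_base_template",
           "simulate_population", "evaluate_against_truth",
           "project_out_similarity", "field_angle_deg"]

BASE_KINDS = ("icosphere", "ellipsoid-head", "crested-cranium")


# ------------------------------------------------------------- base shapes

def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit directions (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def _bump(dirs: np.ndarray, center: np.ndarray, amp: float,
          width: float) -> np.ndarray:
    """Radial Gaussian bump amplitude per unit direction."""
    c = center / np.linalg.norm(center)
    ang = np.arccos(np.clip(dirs @ c, -1.0, 1.0))
    return amp * np.exp(-(ang / width) ** 2)


_HEAD_BUMPS = [  # (direction, amplitude, width): nose, brows, chin, cheeks
    (np.array([1.0, 0.0, -0.15]), 0.18, 0.22),
    (np.array([0.85, 0.32, 0.38]), 0.08, 0.20),
    (np.array([0.85, -0.32, 0.38]), 0.08, 0.20),
    (np.array([0.85, 0.0, -0.55]), 0.10, 0.25),
    (np.array([0.75, 0.55, -0.15]), 0.06, 0.28),
    (np.array([0.75, -0.55, -0.15]), 0.06, 0.28),
]

_CRANIUM_BUMPS = [  # brow ridges and occipital bun
    (np.array([0.9, 0.35, 0.25]), 0.09, 0.25),
    (np.array([0.9, -0.35, 0.25]), 0.09, 0.25),
    (np.array([-1.0, 0.0, 0.1]), 0.10, 0.35),
]


def _base_mesh(kind: str, subdivisions: int) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(ico.vertices, dtype=float)
    f = np.asarray(ico.faces, dtype=np.int64)
    dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
    if kind == "icosphere":
        return TriangleMesh(v, f)
    if kind == "ellipsoid-head":
        r = np.ones(len(v))
        for c, a, w in _HEAD_BUMPS:
            r += _bump(dirs, c, a, w)
        v = dirs * r[:, None] * np.array([0.95, 0.85, 1.05])
        return TriangleMesh(v, f)
    if kind == "crested-cranium":
        r = np.ones(len(v))
        for c, a, w in _CRANIUM_BUMPS:
            r += _bump(dirs, c, a, w)
        # sagittal crest: ridge along the y=0 great circle, upper half
        crest = 0.15 * np.exp(-(dirs[:, 1] / 0.12) ** 2) \
            * np.clip(dirs[:, 2], 0.0, None) ** 2
        r += crest
        v = dirs * r[:, None] * np.array([1.25, 0.9, 1.0])
        return TriangleMesh(v, f)
    raise ValueError(f"unknown base kind {kind!r}; choose from {BASE_KINDS}")


def make_base_template(kind: str = "ellipsoid-head", subdivisions: int = 3,
                       n_landmarks: int = 16, k_semilandmarks: int = 100,
                       seed: int = 0) -> SemilandmarkTemplate:
    """Deterministic base mesh + landmarks at identifiable extrema +
    k-means semilandmarks.

    For the ellipsoid head, landmarks are confined to the "face"
    hemisphere (x > 0), emulating datasets whose scalp carries no
    identifiable landmarks; for the other shapes they cover the whole
    surface.
    """
    if n_landmarks < 5:
        raise ValueError("need at least 5 landmarks")
    mesh = _base_mesh(kind, subdivisions)

    apices = []
    if kind == "ellipsoid-head":
        apices = [c for c, _, _ in _HEAD_BUMPS]
        pool = _fibonacci_directions(max(8 * n_landmarks, 64))
        pool = pool[pool[:, 0] > 0.15]  # face hemisphere only
    elif kind == "crested-cranium":
        apices = [c for c, _, _ in _CRANIUM_BUMPS] + [np.array([0.0, 0.0, 1.0])]
        pool = _fibonacci_directions(max(4 * n_landmarks, 64))
    else:
        apices = [np.array(d) for d in
                  ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
                   [0, 0, -1])]
        pool = _fibonacci_directions(max(4 * n_landmarks, 64))

    dirs = [a / np.linalg.norm(a) for a in apices]
    for d in pool:
        if len(dirs) >= n_landmarks:
            break
        if all(np.arccos(np.clip(d @ e, -1, 1)) > 0.25 for e in dirs):
            dirs.append(d)
    dirs = np.array(dirs[:n_landmarks])
    if len(dirs) < n_landmarks:
        raise ValueError(f"could not place {n_landmarks} well-separated "
                         f"landmarks on {kind}")
    lm_pts, _, _, _ = closest_points(mesh, dirs * 2.0)
    labels = tuple(f"L{i:02d}" for i in range(n_landmarks))
    landmarks = LandmarkSet(labels, lm_pts)
    semis = kmeans_surface_sample(mesh, k_semilandmarks, seed)
    return SemilandmarkTemplate(mesh, landmarks, tuple(semis))


# ------------------------------------------------------------- populations

@dataclass(frozen=True)
class PopulationSpec:
    """Conditions of a simulated study population."""

    base_kind: str = "ellipsoid-head"
    subdivisions: int = 3
    n_landmarks: int = 16
    k_semilandmarks: int = 100
    n_specimens: int = 50
    deformation_scale: float = 0.015     # fraction of diameter
    n_deformation_controls: int = 8
    allometry_scale: float = 0.05        # fraction of diameter per unit lnCS
    n_allometry_controls: int = 10
    lncs_distribution: str = "uniform"   # uniform | skewed (toward the max)
    lncs_halfwidth: float = 0.15         # log-size offsets span ±this
    vertex_noise_sd: float = 0.01        # fraction of CS/√p (RMS radius)
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens < 2 or self.n_landmarks < 5:
            raise ValueError("need >=2 specimens and >=5 landmarks")
        for name in ("deformation_scale", "allometry_scale", "vertex_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.lncs_distribution not in ("uniform", "skewed"):
            raise ValueError("lncs_distribution must be 'uniform' or 'skewed'")


@dataclass(frozen=True)
class SyntheticPopulation:
    template: SemilandmarkTemplate
    specimens: tuple  # of (TriangleMesh, LandmarkSet)
    true_configs: np.ndarray          # (n, L+k, 3), pre-noise
    noisy_configs: np.ndarray         # (n, L+k, 3), truth + measurement noise
    true_mean_mesh: TriangleMesh
    true_allometric_field: np.ndarray  # (V,3) per unit lnCS
    true_config_field: np.ndarray      # (L+k,3) field at configuration points
    lncs_offsets: np.ndarray           # (n,) draws of the log-size offset
    spec: PopulationSpec

    @property
    def n(self) -> int:
        return len(self.specimens)


def _smooth_field(mesh: TriangleMesh, n_controls: int, scale: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-vertex smooth displacement field: TPS interpolating random
    control displacements of RMS magnitude ``scale`` (absolute units)."""
    controls = sample_surface_dense(mesh, n_controls, rng)
    disp = rng.normal(0.0, scale / np.sqrt(3), size=(n_controls, 3))
    warp = tps_fit(controls, controls + disp)
    return tps_apply(warp, mesh.vertices) - mesh.vertices


def simulate_population(template: SemilandmarkTemplate,
                        spec: PopulationSpec) -> SyntheticPopulation:
    """Draw a population of deformed, sized, noisy copies of the template."""
    rng = np.random.default_rng(spec.seed)
    mesh = template.mesh
    V = mesh.n_vertices
    diam = mesh.diameter
    rms_radius = centroid_size(mesh.vertices) / np.sqrt(V)

    # configuration points as (face, barycentric) on the template
    _, lm_faces, lm_bary, _ = closest_points(mesh, template.landmarks.points)
    sl_faces = np.array([s.face_index for s in template.semilandmarks])
    sl_bary = np.array([s.barycentric for s in template.semilandmarks])
    cfg_faces = np.concatenate([lm_faces, sl_faces])
    cfg_bary = np.vstack([lm_bary, sl_bary])

    # fixed allometric field (zero if allometry_scale == 0)
    if spec.allometry_scale > 0:
        allo = _smooth_field(mesh, spec.n_allometry_controls,
                             spec.allometry_scale * diam, rng)
    else:
        allo = np.zeros((V, 3))
    allo_cfg = np.einsum("kj,kjd->kd", cfg_bary, allo[mesh.faces[cfg_faces]])

    # log-size offsets: uniform, or skewed toward the maximum (left tail
    # of small specimens, as in observed size distributions)
    lo, hi = -spec.lncs_halfwidth, spec.lncs_halfwidth
    if spec.lncs_distribution == "uniform":
        u = rng.uniform(lo, hi, size=spec.n_specimens)
        u_mean = 0.0
    else:
        u = lo + (hi - lo) * rng.beta(5.0, 2.0, size=spec.n_specimens)
        u_mean = lo + (hi - lo) * (5.0 / 7.0)

    L = len(template.landmarks)
    specimens = []
    true_configs = np.empty((spec.n_specimens, L + template.k, 3))
    noisy_configs = np.empty_like(true_configs)
    for i in range(spec.n_specimens):
        dv = (u[i] - u_mean) * allo
        if spec.deformation_scale > 0:
            dv = dv + _smooth_field(mesh, spec.n_deformation_controls,
                                    spec.deformation_scale * diam, rng)
        scale = np.exp(u[i])
        verts = (mesh.vertices + dv) * scale
        cfg = np.einsum("kj,kjd->kd", cfg_bary,
                        verts[mesh.faces[cfg_faces]])
        true_configs[i] = cfg
        lms = LandmarkSet(template.landmarks.labels, cfg[:L])
        noise_sd = spec.vertex_noise_sd * rms_radius * scale
        if noise_sd > 0:
            verts = verts + rng.normal(0.0, noise_sd, size=(V, 3))
            noisy_configs[i] = cfg + rng.normal(0.0, noise_sd, size=cfg.shape)
        else:
            noisy_configs[i] = cfg
        specimens.append((TriangleMesh(verts, mesh.faces.copy()), lms))

    return SyntheticPopulation(
        template=template, specimens=tuple(specimens),
        true_configs=true_configs, noisy_configs=noisy_configs,
        true_mean_mesh=mesh,
        true_allometric_field=allo, true_config_field=allo_cfg,
        lncs_offsets=u, spec=spec)


# ------------------------------------------------------------- evaluation

def project_out_similarity(field: np.ndarray, shape: np.ndarray) -> np.ndarray:
    """Remove the similarity-transform tangent components of a displacement
    field at ``shape`` (translations, uniform scaling, infinitesimal
    rotations) — the directions GPA quotients out."""
    X = shape - shape.mean(axis=0)
    p = X.shape[0]
    basis = []
    for d in range(3):
        e = np.zeros((p, 3))
        e[:, d] = 1.0
        basis.append(e)
    basis.append(X)
    gens = [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0.0]]),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0.0]]),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0.0]])]
    basis.extend(X @ g.T for g in gens)
    B = np.stack([b.ravel() for b in basis], axis=1)
    q, _ = np.linalg.qr(B)
    f = field.ravel()
    return (f - q @ (q.T @ f)).reshape(field.shape)


def field_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two flattened displacement fields, in degrees."""
    fa, fb = a.ravel(), b.ravel()
    denom = np.linalg.norm(fa) * np.linalg.norm(fb)
    if denom == 0:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(fa @ fb / denom, -1.0, 1.0))))


def evaluate_against_truth(population: SyntheticPopulation,
                           estimated) -> dict:
    """Error report for an estimated mean surface or allometric model.

    * EstimatedSurface (or TriangleMesh): vertex Procrustes distance to
      the true mean mesh.
    * AllometricModel fitted to configuration points: angle (degrees)
      between the recovered slope field and the true allometric field at
      the configuration points, after rotating the model into the
      template frame and projecting the similarity components out of the
      truth.
    """
    from .surface_compare import EstimatedSurface

    if isinstance(estimated, AllometricModel):
        tmpl_cfg = population.template.configuration_points()
        if estimated.mean_shape.shape != tmpl_cfg.shape:
            raise ValueError("model was not fitted to this population's "
                             "configuration points")
        X0 = tmpl_cfg - tmpl_cfg.mean(axis=0)
        X0 = X0 / np.linalg.norm(X0)
        M = estimated.mean_shape - estimated.mean_shape.mean(axis=0)
        M = M / np.linalg.norm(M)
        R = optimal_rotation(X0, M)
        slope_in_template_frame = estimated.slope_field @ R
        truth = project_out_similarity(population.true_config_field, tmpl_cfg)
        fitted = project_out_similarity(slope_in_template_frame, X0)
        return {
            "allometry_angle_deg": field_angle_deg(fitted, truth),
            "true_field_norm": float(np.linalg.norm(truth)),
            "fitted_field_norm": float(np.linalg.norm(fitted)),
        }

    mesh = estimated.mesh if isinstance(estimated, EstimatedSurface) else estimated
    if not np.array_equal(mesh.faces, population.true_mean_mesh.faces):
        raise ValueError("estimated surface does not share the population's "
                         "template topology")
    return {"vertex_procrustes_to_true_mean": procrustes_distance(
        mesh.vertices, population.true_mean_mesh.vertices)}
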