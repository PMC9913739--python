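"""Warping surfaces to estimated configurations and comparing them.

An :class:`EstimatedSurface` is the template mesh TPS-warped to an
estimated landmark + semilandmark configuration (a Procrustes mean, an
allometric extreme, or a landmark-only target). Because different
semilandmarking methods and densities place semilandmarks — and hence
warped mesh vertices — in different surface locations even when the
underlying surface shapes agree, surfaces are made comparable by the
re-semilandmarking + re-warping protocol: semilandmark the estimated
surface afresh with one fixed method (sliding TPS), then re-warp the
template to the original landmarks plus the new semilandmarks. Vertex
Procrustes distances, PCA of vertex sets, and registration-free
per-triangle area-difference maps then compare surface shape rather
than mesh geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh import (LandmarkSet, SemilandmarkTemplate, TriangleMesh,
                   centroid_size, triangle_areas)
from .semilandmark import Configuration, semilandmark_specimen
from .shape_stats import gpa, procrustes_distance
from .tps import tps_apply, tps_fit

__all__ = ["EstimatedSurface", "FaceScalarMap", "warp_surface_to_configuration",
           "resemilandmark_and_rewarp", "vertex_procrustes_distance",
           "area_difference_map", "scale_to_common_size",
           "estimate_mean_surface", "landmark_only_surface",
           "compare_across_densities", "save_face_map_csv",
           "save_face_map_ply"]


@dataclass(frozen=True)
class EstimatedSurface:
    """A warped template surface plus the provenance needed to reuse it.

    ``landmarks`` are the fixed-landmark positions of the configuration
    the surface was warped to (the TPS images of the template landmarks),
    carried through so the surface can be re-semilandmarked later.
    """

    mesh: TriangleMesh
    landmarks: np.ndarray                 # (L,3)
    method: str = "unknown"
    density: int = 0
    target: str = "mean"                  # mean | allometry-min | allometry-max | landmark-only
    reference_id: str = "template"
    provenance: dict = field(default_factory=dict, compare=False)

    def describe(self) -> str:
        return f"{self.method}/k={self.density}/{self.target}@{self.reference_id}"


@dataclass(frozen=True)
class FaceScalarMap:
    """Per-triangle area-difference ratios between topology-identical meshes."""

    values: np.ndarray
    reference_id: str = ""
    target_id: str = ""


def _check_topology(a: TriangleMesh, b: TriangleMesh) -> None:
    if not np.array_equal(a.faces, b.faces):
        raise ValueError("meshes are not topology-identical")


def warp_surface_to_configuration(template_mesh: TriangleMesh,
                                  template_config: Configuration,
                                  target_config: Configuration,
                                  **meta) -> EstimatedSurface:
    """TPS-warp all template vertices so the template configuration lands
    exactly on the target configuration (λ=0)."""
    if template_config.points.shape != target_config.points.shape:
        raise ValueError("configurations must have the same length/order")
    warp = tps_fit(template_config.points, target_config.points)
    verts = tps_apply(warp, template_mesh.vertices)
    return EstimatedSurface(
        mesh=template_mesh.with_vertices(verts),
        landmarks=target_config.fixed_points.copy(),
        **meta)


def resemilandmark_and_rewarp(template: SemilandmarkTemplate,
                              estimated: EstimatedSurface,
                              method: str = "sliding_tps",
                              **method_kwargs) -> EstimatedSurface:
    """Make an estimated surface comparison-ready.

    (i) Semilandmark the estimated surface from the template (sliding
    TPS by default — the most widely used method); (ii) warp the
    template mesh to [original landmarks + new semilandmarks].
    """
    _check_topology(template.mesh, estimated.mesh)
    lms = LandmarkSet(template.landmarks.labels, estimated.landmarks)
    new_config = semilandmark_specimen(template, estimated.mesh, lms,
                                       method=method, **method_kwargs)
    tmpl_config = Configuration(template.configuration_points(),
                                len(template.landmarks))
    out = warp_surface_to_configuration(
        template.mesh, tmpl_config, new_config,
        method=estimated.method, density=estimated.density,
        target=estimated.target, reference_id=estimated.reference_id,
        provenance={**estimated.provenance, "rewarped": True,
                    "rewarp_method": method})
    return out


def vertex_procrustes_distance(a: EstimatedSurface | TriangleMesh,
                               b: EstimatedSurface | TriangleMesh) -> float:
    """Partial Procrustes distance between full vertex sets."""
    ma = a.mesh if isinstance(a, EstimatedSurface) else a
    mb = b.mesh if isinstance(b, EstimatedSurface) else b
    _check_topology(ma, mb)
    return procrustes_distance(ma.vertices, mb.vertices)


def area_difference_map(reference: EstimatedSurface | TriangleMesh,
                        target: EstimatedSurface | TriangleMesh) -> FaceScalarMap:
    """Registration-free per-triangle map: (A_target − A_ref) / A_ref."""
    mr = reference.mesh if isinstance(reference, EstimatedSurface) else reference
    mt = target.mesh if isinstance(target, EstimatedSurface) else target
    _check_topology(mr, mt)
    values = triangle_areas(mt) / triangle_areas(mr) - 1.0
    rid = reference.describe() if isinstance(reference, EstimatedSurface) else ""
    tid = target.describe() if isinstance(target, EstimatedSurface) else ""
    return FaceScalarMap(values, rid, tid)


def scale_to_common_size(surfaces: list[EstimatedSurface]) -> list[EstimatedSurface]:
    """Center each surface's vertex set and scale it to unit centroid size
    (needed before area maps across densities: vertex-set centroid size
    depends inversely on semilandmark density)."""
    if not surfaces:
        raise ValueError("empty surface list")
    out = []
    for s in surfaces:
        v = s.mesh.vertices
        cs = centroid_size(v)
        scaled = (v - v.mean(axis=0)) / cs
        out.append(replace(s, mesh=s.mesh.with_vertices(scaled),
                           landmarks=(s.landmarks - v.mean(axis=0)) / cs))
    return out


def estimate_mean_surface(template: SemilandmarkTemplate,
                          configs: list[Configuration],
                          method_label: str = "unknown",
                          density: int | None = None) -> EstimatedSurface:
    """GPA the configurations, then warp the template to the Procrustes
    mean (unit centroid size)."""
    pts = np.stack([c.points for c in configs])
    n_fixed = configs[0].n_fixed
    if any(c.n_fixed != n_fixed or c.points.shape != pts[0].shape
           for c in configs):
        raise ValueError("configurations disagree in length or roles")
    sample = gpa(pts)
    mean_cfg = Configuration(sample.mean_shape, n_fixed)
    tmpl_cfg = Configuration(template.configuration_points(), n_fixed)
    k = density if density is not None else configs[0].n_sliding
    return warp_surface_to_configuration(
        template.mesh, tmpl_cfg, mean_cfg, method=method_label, density=k,
        target="mean", provenance={"n_specimens": len(configs)})


def landmark_only_surface(reference_mesh: TriangleMesh,
                          reference_landmarks: LandmarkSet,
                          target_landmarks: np.ndarray,
                          reference_id: str = "template",
                          target: str = "mean") -> EstimatedSurface:
    """Warp a reference surface using the anatomical landmarks alone.

    Any reference surface is supported (the template, the individual
    nearest the mean, ...): the choice changes where in shape space the
    estimate lands.
    """
    target_landmarks = np.asarray(target_landmarks, dtype=float)
    if target_landmarks.shape != reference_landmarks.points.shape:
        raise ValueError("target landmarks must match the reference set")
    warp = tps_fit(reference_landmarks.points, target_landmarks)
    verts = tps_apply(warp, reference_mesh.vertices)
    return EstimatedSurface(
        mesh=reference_mesh.with_vertices(verts), landmarks=target_landmarks,
        method="landmark_only", density=0, target=target,
        reference_id=reference_id)


def compare_across_densities(surfaces_by_density: dict[int, EstimatedSurface],
                             max_density: int | None = None):
    """Convergence of estimated surfaces with semilandmark density.

    Computes the vertex Procrustes distance from each lower-density
    surface to the maximum-density one, plus area-difference maps with
    the max-density surface as reference (after common-size scaling).

    Returns ``(table: DataFrame, maps: dict[int, FaceScalarMap])``.
    """
    if max_density is None:
        max_density = max(surfaces_by_density)
    ref = surfaces_by_density[max_density]
    lower = sorted(d for d in surfaces_by_density if d != max_density)
    rows, maps = [], {}
    scaled = dict(zip([max_density] + lower, scale_to_common_size(
        [ref] + [surfaces_by_density[d] for d in lower])))
    for d in lower:
        dist = vertex_procrustes_distance(ref, surfaces_by_density[d])
        rows.append({"density": d, "max_density": max_density,
                     "vertex_procrustes_distance": dist})
        maps[d] = area_difference_map(scaled[max_density], scaled[d])
    return pd.DataFrame(rows), maps


# ---------------------------------------------------------------- exports

def save_face_map_csv(fmap: FaceScalarMap, path) -> None:
    pd.DataFrame({"face_index": np.arange(len(fmap.values)),
                  "value": fmap.values}).to_csv(path, index=False)


def save_face_map_ply(fmap: FaceScalarMap, mesh: TriangleMesh, path) -> None:
    """ASCII PLY with a per-face float property ``quality`` holding the
    area-difference ratio (readable by standard mesh viewers)."""
    v, f = mesh.vertices, mesh.faces
    lines = ["ply", "format ascii 1.0",
             f"element vertex {len(v)}",
             "property float x", "property float y", "property float z",
             f"element face {len(f)}",
             "property list uchar int vertex_indices",
             "property float quality", "end_header"]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in v]
    lines += [f"3 {a} {b} {c} {q:.9g}"
              for (a, b, c), q in zip(f, fmap.values)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
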