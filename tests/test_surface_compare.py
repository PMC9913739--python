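import numpy as np
import pytest

from morphosurf import (Configuration,
                        area_difference_map, compare_across_densities,
                        estimate_mean_surface, landmark_only_surface,
                        resemilandmark_and_rewarp, scale_to_common_size,
                        vertex_procrustes_distance,
                        warp_surface_to_configuration)
from morphosurf.mesh import centroid_size
from morphosurf.surface_compare import save_face_map_csv, save_face_map_ply
from morphosurf.tps import tps_apply, tps_fit


def _warp_to(template, target_points, **meta):
    cfg0 = Configuration(template.configuration_points(),
                         len(template.landmarks))
    cfg1 = Configuration(target_points, cfg0.n_fixed)
    return warp_surface_to_configuration(template.mesh, cfg0, cfg1, **meta)


# ---------------------------------------------------------------- warping

def test_warp_hits_target_configuration(small_template, rng):
    target = small_template.configuration_points() + rng.normal(
        size=small_template.configuration_points().shape) * 0.05
    surf = _warp_to(small_template, target, method="test")
    warp = tps_fit(small_template.configuration_points(), target)
    assert np.allclose(surf.mesh.vertices,
                       tps_apply(warp, small_template.mesh.vertices),
                       atol=1e-12)
    assert np.array_equal(surf.landmarks, target[:len(small_template.landmarks)])


def test_warp_identity_is_exact(small_template):
    surf = _warp_to(small_template, small_template.configuration_points())
    assert np.abs(surf.mesh.vertices - small_template.mesh.vertices).max() \
        < 1e-9


# ------------------------------------------------------------- area maps

def test_area_map_self_comparison_is_zero(sphere2):
    fmap = area_difference_map(sphere2, sphere2)
    assert np.array_equal(fmap.values, np.zeros(sphere2.n_faces))


def test_area_map_uniform_scale(sphere2):
    s = 1.37
    scaled = sphere2.with_vertices(sphere2.vertices * s)
    fmap = area_difference_map(sphere2, scaled)
    assert np.abs(fmap.values - (s**2 - 1.0)).max() < 1e-9


def test_area_map_single_vertex_perturbation_is_local(sphere2):
    v = sphere2.vertices.copy()
    vi = 37
    v[vi] = v[vi] * 1.1
    bumped = sphere2.with_vertices(v)
    fmap = area_difference_map(sphere2, bumped)
    incident = (sphere2.faces == vi).any(axis=1)
    assert (np.abs(fmap.values[~incident]) < 1e-15).all()
    assert (np.abs(fmap.values[incident]) > 1e-6).all()


def test_area_map_requires_shared_topology(sphere1, sphere2):
    with pytest.raises(ValueError):
        area_difference_map(sphere1, sphere2)


# ---------------------------------------------------------------- rewarp

def test_rewarp_near_fixed_point_and_idempotent_on_template(small_template):
    # the template warped to its own configuration should survive the
    # re-semilandmark/re-warp loop almost unchanged, and a second pass
    # should change next to nothing
    surf = _warp_to(small_template, small_template.configuration_points(),
                    method="test")
    re1 = resemilandmark_and_rewarp(small_template, surf)
    assert vertex_procrustes_distance(surf, re1) < 1e-3
    re2 = resemilandmark_and_rewarp(small_template, re1)
    assert vertex_procrustes_distance(re1, re2) < 1e-4


def test_rewarp_contracts_on_deformed_surface(small_template, rng):
    # on a genuinely deformed surface repeated rewarping is a (slow)
    # contraction: each pass changes the shape less than the one before,
    # because sliding re-minimises bending energy on the changed surface
    target = small_template.configuration_points() + rng.normal(
        size=small_template.configuration_points().shape) * 0.03
    surf = _warp_to(small_template, target, method="test")
    re1 = resemilandmark_and_rewarp(small_template, surf)
    re2 = resemilandmark_and_rewarp(small_template, re1)
    assert vertex_procrustes_distance(re1, re2) \
        < vertex_procrustes_distance(surf, re1)


def test_rewarp_records_provenance(small_template):
    surf = _warp_to(small_template, small_template.configuration_points(),
                    method="m", density=30, target="mean")
    out = resemilandmark_and_rewarp(small_template, surf)
    assert out.provenance["rewarped"] is True
    assert out.method == "m"


# ------------------------------------------------------------- estimation

def test_estimate_mean_surface_of_identical_configs(small_template):
    cfg = Configuration(small_template.configuration_points(),
                        len(small_template.landmarks))
    surf = estimate_mean_surface(small_template, [cfg, cfg, cfg],
                                 method_label="x")
    # mean of identical configs is the (unit-size) template shape
    assert vertex_procrustes_distance(surf, small_template.mesh) < 1e-6
    assert surf.density == small_template.k
    assert surf.provenance["n_specimens"] == 3


def test_estimate_mean_surface_rejects_mixed_configs(small_template):
    cfg = Configuration(small_template.configuration_points(),
                        len(small_template.landmarks))
    bad = Configuration(cfg.points, cfg.n_fixed - 1)
    with pytest.raises(ValueError):
        estimate_mean_surface(small_template, [cfg, bad])


def test_landmark_only_surface_matches_landmark_warp(small_template, rng):
    lms = small_template.landmarks
    target = lms.points + rng.normal(size=lms.points.shape) * 0.05
    surf = landmark_only_surface(small_template.mesh, lms, target)
    warp = tps_fit(lms.points, target)
    assert np.allclose(surf.mesh.vertices,
                       tps_apply(warp, small_template.mesh.vertices),
                       atol=1e-12)
    assert surf.method == "landmark_only"


# ------------------------------------------------------------ common size

def test_scale_to_common_size(small_template, rng):
    surfs = []
    for scale in (1.0, 3.0):
        target = small_template.configuration_points() * scale
        surfs.append(_warp_to(small_template, target))
    scaled = scale_to_common_size(surfs)
    for s in scaled:
        assert centroid_size(s.mesh.vertices) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(s.mesh.vertices.mean(axis=0), 0.0, atol=1e-12)
    assert np.abs(scaled[0].mesh.vertices - scaled[1].mesh.vertices).max() \
        < 1e-9


def test_compare_across_densities_table(small_template, rng):
    base = small_template.configuration_points()
    surfaces = {}
    for k in (10, 20, 30):
        target = base + rng.normal(size=base.shape) * 0.02
        surfaces[k] = _warp_to(small_template, target, method="t", density=k)
    table, maps = compare_across_densities(surfaces)
    assert list(table["density"]) == [10, 20]
    assert (table["max_density"] == 30).all()
    assert set(maps) == {10, 20}
    assert (table["vertex_procrustes_distance"] > 0).all()


# ---------------------------------------------------------------- exports

def test_face_map_exports_roundtrip(tmp_path, sphere1):
    scaled = sphere1.with_vertices(sphere1.vertices * 1.2)
    fmap = area_difference_map(sphere1, scaled)
    csv_path = tmp_path / "map.csv"
    save_face_map_csv(fmap, csv_path)
    import pandas as pd
    back = pd.read_csv(csv_path)
    assert np.allclose(back["value"], fmap.values, atol=1e-12)

    ply_path = tmp_path / "map.ply"
    save_face_map_ply(fmap, sphere1, ply_path)
    text = ply_path.read_text().splitlines()
    assert text[0] == "ply"
    n_v = sphere1.n_vertices
    header_end = text.index("end_header")
    face_lines = text[header_end + 1 + n_v:]
    assert len(face_lines) == sphere1.n_faces
    last_vals = np.array([float(line.split()[-1]) for line in face_lines])
    assert np.allclose(last_vals, fmap.values, atol=1e-6)
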