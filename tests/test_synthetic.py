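import dataclasses

import numpy as np
import pytest

from morphosurf.mesh import centroid_size, closest_points
from morphosurf.synthetic import (BASE_KINDS, PopulationSpec,
                                  evaluate_against_truth, field_angle_deg,
                                  make_base_template, project_out_similarity,
                                  simulate_population)

SMALL_SPEC = PopulationSpec(subdivisions=2, n_landmarks=12,
                            k_semilandmarks=30, n_specimens=6,
                            n_deformation_controls=6,
                            n_allometry_controls=6, seed=7)


@pytest.fixture(scope="module")
def small_pop():
    tmpl = make_base_template("ellipsoid-head", subdivisions=2,
                              n_landmarks=12, k_semilandmarks=30)
    return simulate_population(tmpl, SMALL_SPEC)


# ---------------------------------------------------------------- templates

@pytest.mark.parametrize("kind", BASE_KINDS)
def test_base_template_is_deterministic(kind):
    a = make_base_template(kind, subdivisions=2, n_landmarks=8,
                           k_semilandmarks=20)
    b = make_base_template(kind, subdivisions=2, n_landmarks=8,
                           k_semilandmarks=20)
    assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
    assert np.array_equal(a.landmarks.points, b.landmarks.points)
    assert np.array_equal(a.semilandmark_points(), b.semilandmark_points())


def test_template_landmarks_are_separated_and_on_surface():
    t = make_base_template("ellipsoid-head", subdivisions=2, n_landmarks=16,
                           k_semilandmarks=30)
    pts = t.landmarks.points
    _, _, _, dist = closest_points(t.mesh, pts)
    assert dist.max() < 1e-9
    d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    np.fill_diagonal(d, np.inf)
    assert d.min() > 0.1  # no near-duplicate landmarks


def test_head_landmarks_confined_to_face_hemisphere():
    t = make_base_template("ellipsoid-head", subdivisions=2, n_landmarks=16,
                           k_semilandmarks=30)
    assert (t.landmarks.points[:, 0] > 0).all()


def test_template_rejects_bad_requests():
    with pytest.raises(ValueError):
        make_base_template(n_landmarks=3)
    with pytest.raises(ValueError):
        make_base_template("klein-bottle")
    with pytest.raises(ValueError):
        # far more separated landmarks than the hemisphere can hold
        make_base_template("ellipsoid-head", subdivisions=2, n_landmarks=200)


# --------------------------------------------------------------------- spec

def test_population_spec_validation():
    with pytest.raises(ValueError):
        PopulationSpec(n_specimens=1)
    with pytest.raises(ValueError):
        PopulationSpec(vertex_noise_sd=-0.1)
    with pytest.raises(ValueError):
        PopulationSpec(lncs_distribution="gaussian")


# --------------------------------------------------------------- simulation

def test_simulation_is_deterministic(small_pop):
    again = simulate_population(small_pop.template, SMALL_SPEC)
    assert np.array_equal(again.true_configs, small_pop.true_configs)
    assert np.array_equal(again.noisy_configs, small_pop.noisy_configs)
    assert np.array_equal(again.lncs_offsets, small_pop.lncs_offsets)
    for (m1, l1), (m2, l2) in zip(again.specimens, small_pop.specimens):
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(l1.points, l2.points)


def test_population_shapes_and_metadata(small_pop):
    n = SMALL_SPEC.n_specimens
    p = SMALL_SPEC.n_landmarks + SMALL_SPEC.k_semilandmarks
    assert small_pop.n == n
    assert small_pop.true_configs.shape == (n, p, 3)
    assert small_pop.noisy_configs.shape == (n, p, 3)
    assert small_pop.true_config_field.shape == (p, 3)
    assert small_pop.lncs_offsets.shape == (n,)
    V = small_pop.template.mesh.n_vertices
    assert small_pop.true_allometric_field.shape == (V, 3)


def test_true_configs_lie_on_prenoise_surfaces():
    # with noise off, configuration points sit exactly on each specimen
    spec = dataclasses.replace(SMALL_SPEC, vertex_noise_sd=0.0)
    pop = simulate_population(
        make_base_template("ellipsoid-head", subdivisions=2, n_landmarks=12,
                           k_semilandmarks=30), spec)
    for (mesh, lms), cfg in zip(pop.specimens, pop.true_configs):
        _, _, _, dist = closest_points(mesh, cfg)
        assert dist.max() < 1e-9 * mesh.diameter
        assert np.array_equal(lms.points, cfg[:12])
    assert np.array_equal(pop.noisy_configs, pop.true_configs)


def test_noise_level_matches_specification(small_pop):
    tmpl = small_pop.template
    rms_radius = centroid_size(tmpl.mesh.vertices) / np.sqrt(
        tmpl.mesh.n_vertices)
    resid = small_pop.noisy_configs - small_pop.true_configs
    for i in range(small_pop.n):
        expected = SMALL_SPEC.vertex_noise_sd * rms_radius * np.exp(
            small_pop.lncs_offsets[i])
        observed = resid[i].std()
        assert 0.5 * expected < observed < 1.8 * expected


def test_lncs_offsets_uniform_within_bounds(small_pop):
    hw = SMALL_SPEC.lncs_halfwidth
    assert (np.abs(small_pop.lncs_offsets) <= hw).all()


def test_lncs_offsets_skewed_toward_maximum():
    spec = dataclasses.replace(SMALL_SPEC, lncs_distribution="skewed",
                               n_specimens=200)
    pop = simulate_population(
        make_base_template("ellipsoid-head", subdivisions=2, n_landmarks=12,
                           k_semilandmarks=30), spec)
    u = pop.lncs_offsets
    hw = spec.lncs_halfwidth
    assert (u >= -hw).all() and (u <= hw).all()
    # Beta(5,2): mean above the midpoint, left tail of small specimens
    assert u.mean() > 0.1 * hw
    from scipy.stats import skew
    assert skew(u) < 0.0


def test_specimen_size_tracks_lncs_offset(small_pop):
    tmpl_cs = centroid_size(small_pop.template.mesh.vertices)
    for (mesh, _), u in zip(small_pop.specimens, small_pop.lncs_offsets):
        cs = centroid_size(mesh.vertices)
        assert cs == pytest.approx(tmpl_cs * np.exp(u), rel=0.1)


def test_zero_scales_reproduce_template():
    spec = dataclasses.replace(SMALL_SPEC, deformation_scale=0.0,
                               allometry_scale=0.0, vertex_noise_sd=0.0,
                               lncs_halfwidth=0.0)
    pop = simulate_population(
        make_base_template("ellipsoid-head", subdivisions=2, n_landmarks=12,
                           k_semilandmarks=30), spec)
    for mesh, _ in pop.specimens:
        assert np.abs(mesh.vertices - pop.template.mesh.vertices).max() < 1e-12
    assert np.all(pop.true_allometric_field == 0.0)


# --------------------------------------------------------------- evaluation

def test_project_out_similarity_kills_similarity_fields(rng):
    shape = rng.normal(size=(25, 3))
    # translation + scaling + infinitesimal rotation
    X = shape - shape.mean(axis=0)
    g = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0.0]])
    fields = [np.tile([1.0, -2.0, 0.5], (25, 1)), 0.3 * X, X @ g.T]
    for f in fields:
        out = project_out_similarity(f, shape)
        assert np.abs(out).max() < 1e-10
    # a generic field survives (and is idempotent)
    f = rng.normal(size=(25, 3))
    out = project_out_similarity(f, shape)
    assert np.linalg.norm(out) > 0.5 * np.linalg.norm(f)
    assert np.allclose(project_out_similarity(out, shape), out, atol=1e-10)


def test_field_angle_deg_basics(rng):
    a = rng.normal(size=(10, 3))
    # arccos loses precision near ±1, hence the loose absolute tolerance
    assert field_angle_deg(a, a) == pytest.approx(0.0, abs=1e-4)
    assert field_angle_deg(a, -a) == pytest.approx(180.0, abs=1e-4)
    assert field_angle_deg(a, 3.7 * a) == pytest.approx(0.0, abs=1e-4)
    assert field_angle_deg(a, np.zeros_like(a)) == 0.0


def test_evaluate_mean_surface_zero_on_truth(small_pop):
    report = evaluate_against_truth(small_pop, small_pop.true_mean_mesh)
    assert report["vertex_procrustes_to_true_mean"] < 1e-12


def test_evaluate_rejects_foreign_inputs(small_pop, sphere1):
    with pytest.raises(ValueError):
        evaluate_against_truth(small_pop, sphere1)
    from morphosurf.shape_stats import AllometricModel
    bad = AllometricModel(np.zeros((4, 3)), np.zeros((4, 3)), 0.0, -1.0, 1.0)
    with pytest.raises(ValueError):
        evaluate_against_truth(small_pop, bad)


def test_evaluate_allometric_model_on_exact_fit(small_pop):
    """A model whose slope equals the true configuration field scores a
    near-zero angle."""
    from morphosurf.shape_stats import AllometricModel
    tmpl_cfg = small_pop.template.configuration_points()
    X0 = tmpl_cfg - tmpl_cfg.mean(axis=0)
    X0 = X0 / np.linalg.norm(X0)
    model = AllometricModel(mean_shape=X0,
                            slope_field=small_pop.true_config_field,
                            lncs_mean=0.0, lncs_min=-0.1, lncs_max=0.1)
    report = evaluate_against_truth(small_pop, model)
    assert report["allometry_angle_deg"] < 1e-6
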