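import numpy as np
import pytest

from morphosurf import (LandmarkSet, SemilandmarkTemplate, TriangleMesh,
                        centroid_size, kmeans_surface_sample, load_landmarks,
                        load_mesh, nearest_point_on_surface, save_landmarks,
                        save_mesh, triangle_areas)
from morphosurf.mesh import (MeshValidationError, SurfacePoint,
                             barycentric_to_cartesian, closest_points,
                             load_semilandmark_template_csv,
                             sample_surface_dense,
                             save_semilandmark_template_csv)

from conftest import icosphere


# ------------------------------------------------------------- validation

def test_mesh_rejects_too_few_vertices():
    with pytest.raises(MeshValidationError):
        TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))


def test_mesh_rejects_bad_face_index():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    with pytest.raises(MeshValidationError):
        TriangleMesh(v, np.array([[0, 1, 4]]))


def test_mesh_rejects_repeated_index_face():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    with pytest.raises(MeshValidationError):
        TriangleMesh(v, np.array([[0, 1, 1]]))


def test_mesh_rejects_zero_area_face():
    v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 0, 1.0]])
    with pytest.raises(MeshValidationError):
        TriangleMesh(v, np.array([[0, 1, 2]]))


def test_landmarks_require_unique_labels():
    with pytest.raises(ValueError):
        LandmarkSet(("a", "a"), np.zeros((2, 3)))


def test_surface_point_barycentric_checked():
    with pytest.raises(ValueError):
        SurfacePoint(0, np.array([0.5, 0.2, 0.2]), np.zeros(3))


# ------------------------------------------------------------- geometry

def test_euler_characteristic_icosphere(sphere2):
    v, f = sphere2.n_vertices, sphere2.n_faces
    e = sphere2.edges_unique().shape[0]
    assert (v, f) == (162, 320)
    assert v - e + f == 2


def test_vertex_normals_point_outward_on_sphere(sphere2):
    vn = sphere2.vertex_normals()
    assert np.allclose(np.linalg.norm(vn, axis=1), 1.0)
    radial = sphere2.vertices / np.linalg.norm(sphere2.vertices, axis=1,
                                               keepdims=True)
    assert (np.einsum("ij,ij->i", vn, radial) > 0.9).all()


def test_triangle_areas_match_heron(sphere2, rng):
    areas = triangle_areas(sphere2)
    a, b, c = sphere2.face_corners()
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    s = 0.5 * (la + lb + lc)
    heron = np.sqrt(s * (s - la) * (s - lb) * (s - lc))
    assert np.allclose(areas, heron, rtol=1e-10)


def test_centroid_size_definition(rng):
    pts = rng.normal(size=(17, 3))
    expected = np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum())
    assert centroid_size(pts) == pytest.approx(expected, rel=1e-14)
    with pytest.raises(ValueError):
        centroid_size(np.ones((5, 3)))


# ---------------------------------------------------------- closest points

def _brute_force_closest(mesh, q):
    """Per-query scan of every face with an independent scalar projector."""
    best_d = np.inf
    best = None
    for fi, (i, j, k) in enumerate(mesh.faces):
        a, b, c = mesh.vertices[i], mesh.vertices[j], mesh.vertices[k]
        # exhaustive candidate set: interior solve clipped to the triangle
        e0, e1 = b - a, c - a
        A = np.array([[e0 @ e0, e0 @ e1], [e0 @ e1, e1 @ e1]])
        rhs = np.array([e0 @ (q - a), e1 @ (q - a)])
        s, t = np.linalg.solve(A, rhs)
        candidates = [(s, t)] if (s >= 0 and t >= 0 and s + t <= 1) else []
        for (p0, p1) in [(a, b), (a, c), (b, c)]:
            e = p1 - p0
            u = np.clip((q - p0) @ e / (e @ e), 0.0, 1.0)
            pt = p0 + u * e
            d = np.linalg.norm(q - pt)
            if d < best_d - 1e-15:
                best_d, best = d, (fi, pt)
        for (s, t) in candidates:
            pt = a + s * e0 + t * e1
            d = np.linalg.norm(q - pt)
            if d < best_d - 1e-15:
                best_d, best = d, (fi, pt)
    return best_d, best


def test_closest_points_match_brute_force(sphere1, rng):
    queries = np.vstack([rng.normal(size=(40, 3)) * 1.5,
                         sphere1.vertices[:10] * 1.0])
    pts, faces, bary, dist = closest_points(sphere1, queries)
    for qi, q in enumerate(queries):
        d_ref, _ = _brute_force_closest(sphere1, q)
        assert dist[qi] == pytest.approx(d_ref, abs=1e-12)
        rec = barycentric_to_cartesian(sphere1, faces[qi:qi + 1],
                                       bary[qi:qi + 1])[0]
        assert np.linalg.norm(rec - pts[qi]) < 1e-12


def test_closest_points_barycentric_valid(sphere2, rng):
    q = rng.normal(size=(200, 3)) * 2.0
    _, _, bary, _ = closest_points(sphere2, q)
    assert np.allclose(bary.sum(axis=1), 1.0, atol=1e-12)
    assert (bary >= 0).all()


def test_closest_points_tie_breaks_to_lowest_face(sphere2):
    # a query exactly at a vertex is equidistant to all incident faces
    for vi in (0, 7, 33):
        incident = np.where((sphere2.faces == vi).any(axis=1))[0]
        _, f, _, d = closest_points(sphere2, sphere2.vertices[vi][None] * 1.2)
        assert d[0] > 0
        assert f[0] == incident.min()


def test_nearest_point_on_surface_roundtrip(sphere2):
    sp = nearest_point_on_surface(sphere2, np.array([2.0, 0.1, -0.3]))
    rec = barycentric_to_cartesian(sphere2, np.array([sp.face_index]),
                                   sp.barycentric[None])[0]
    assert np.linalg.norm(rec - sp.point) < 1e-12
    assert np.linalg.norm(sp.point) == pytest.approx(1.0, abs=0.01)


# ---------------------------------------------------------------- sampling

def test_sample_surface_dense_on_surface(sphere2, rng):
    pts = sample_surface_dense(sphere2, 100, rng)
    _, _, _, dist = closest_points(sphere2, pts)
    assert dist.max() < 1e-12


def test_kmeans_sample_deterministic_and_on_surface(sphere2):
    s1 = kmeans_surface_sample(sphere2, 20, seed=4)
    s2 = kmeans_surface_sample(sphere2, 20, seed=4)
    assert len(s1) == 20
    for a, b in zip(s1, s2):
        assert a.face_index == b.face_index
        assert np.array_equal(a.barycentric, b.barycentric)
    _, _, _, dist = closest_points(sphere2, np.array([p.point for p in s1]))
    assert dist.max() < 1e-9


def test_kmeans_sample_rejects_bad_k(sphere2):
    with pytest.raises(ValueError):
        kmeans_surface_sample(sphere2, 0, seed=0)
    with pytest.raises(ValueError):
        kmeans_surface_sample(sphere2, sphere2.n_vertices + 1, seed=0)


# --------------------------------------------------------------------- IO

@pytest.mark.parametrize("ext", ["ply", "obj"])
def test_mesh_io_roundtrip(tmp_path, sphere1, ext):
    path = tmp_path / f"m.{ext}"
    save_mesh(sphere1, path)
    back = load_mesh(path)
    assert np.allclose(back.vertices, sphere1.vertices, atol=1e-6)
    assert np.array_equal(back.faces, sphere1.faces)


def test_load_mesh_cleans_degenerate_faces(tmp_path):
    # hand-written PLY: one good tetrahedron + repeated-index, zero-area
    # and duplicate faces, plus an unreferenced vertex
    ply = "\n".join([
        "ply", "format ascii 1.0", "element vertex 6",
        "property float x", "property float y", "property float z",
        "element face 6", "property list uchar int vertex_indices",
        "end_header",
        "0 0 0", "1 0 0", "0 1 0", "0 0 1", "2 0 0", "9 9 9",
        "3 0 1 2", "3 0 1 3", "3 1 2 3", "3 1 1 2", "3 0 1 4", "3 1 0 2",
    ]) + "\n"
    path = tmp_path / "dirty.ply"
    path.write_text(ply)
    mesh = load_mesh(path)
    # repeated-index, zero-area and duplicate faces dropped; the (2,0,0)
    # vertex (only in the zero-area face) and (9,9,9) become unreferenced
    assert mesh.n_vertices == 4
    assert mesh.n_faces == 3


def test_landmark_csv_roundtrip(tmp_path, rng):
    lms = LandmarkSet(("a", "b", "c"), rng.normal(size=(3, 3)))
    path = tmp_path / "lms.csv"
    save_landmarks(lms, path)
    back = load_landmarks(path)
    assert back.labels == lms.labels
    assert np.allclose(back.points, lms.points, atol=1e-12)


def test_landmark_csv_header_checked(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("name,x,y,z\nfoo,0,0,0\n")
    with pytest.raises(ValueError):
        load_landmarks(path)


def test_template_csv_roundtrip(tmp_path, small_template):
    path = tmp_path / "semis.csv"
    save_semilandmark_template_csv(small_template, path)
    back = load_semilandmark_template_csv(small_template.mesh,
                                          small_template.landmarks, path)
    assert back.k == small_template.k
    assert np.allclose(back.configuration_points(),
                       small_template.configuration_points(), atol=1e-12)


def test_template_validates_face_indices(small_template):
    bad = SurfacePoint(small_template.mesh.n_faces + 3,
                       np.array([1.0, 0.0, 0.0]), np.zeros(3))
    with pytest.raises(ValueError):
        SemilandmarkTemplate(small_template.mesh, small_template.landmarks,
                             (bad,))
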