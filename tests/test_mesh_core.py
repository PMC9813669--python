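"""Mesh I/O, correspondence, surface-distance metrics, volumes and mass."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cardiomesh import mesh_core as mc
from cardiomesh import synthetic_population as sp
from cardiomesh.errors import (
    DataLeakageError,
    EmptyInputError,
    InvalidAnatomyError,
    MeshParseError,
    UnsupportedTopologyError,
)


# ---------------------------------------------------------------------------
# Independent scalar oracle for point-to-triangle distance
# ---------------------------------------------------------------------------

def _oracle_point_triangle(p, a, b, c):
    """Scalar closest-distance oracle: plane projection with 2D inclusion test,
    falling back to the three edge segments.  Independent of the vectorised
    region-based implementation."""
    p, a, b, c = (np.asarray(x, dtype=float) for x in (p, a, b, c))
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    best = math.inf
    if nn > 1e-14:
        n = n / nn
        proj = p - np.dot(p - a, n) * n
        # barycentric inclusion via areas
        def area2(u, v, w):
            return np.dot(np.cross(v - u, w - u), n)
        full = area2(a, b, c)
        w0 = area2(proj, b, c) / full
        w1 = area2(a, proj, c) / full
        w2 = area2(a, b, proj) / full
        if w0 >= -1e-12 and w1 >= -1e-12 and w2 >= -1e-12:
            best = np.linalg.norm(p - proj)
    for u, v in ((a, b), (b, c), (c, a)):
        d = v - u
        t = np.clip(np.dot(p - u, d) / np.dot(d, d), 0.0, 1.0)
        best = min(best, np.linalg.norm(p - (u + t * d)))
    return best


def _oracle_directed(points, mesh):
    tris = mesh.triangle_coordinates()
    return np.array([min(_oracle_point_triangle(p, *t) for t in tris) for p in points])


def test_point_triangle_distances_match_scalar_oracle():
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(40, 3))
    tris = rng.normal(size=(25, 3, 3))
    sq = mc.point_triangle_distances(pts, tris)
    for i in range(len(pts)):
        for j in range(len(tris)):
            expect = _oracle_point_triangle(pts[i], *tris[j])
            assert math.sqrt(sq[i, j]) == pytest.approx(expect, abs=1e-9)


def test_directed_distance_pruning_equals_brute_force(icosphere, small_icosphere):
    # icosphere has >256 faces -> pruned path; compare against full evaluation
    rng = np.random.default_rng(3)
    pts = rng.normal(scale=12.0, size=(50, 3))
    pruned = mc.directed_surface_distance(pts, icosphere)
    brute = np.sqrt(mc.point_triangle_distances(pts, icosphere.triangle_coordinates()).min(axis=1))
    np.testing.assert_allclose(pruned, brute, atol=1e-12)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ext", ["ply", "obj", "off"])
def test_mesh_round_trip(tmp_path, tetra, ext):
    path = tmp_path / f"tetra.{ext}"
    mc.write_mesh(tetra, path)
    back = mc.read_mesh(path)
    # PLY/OBJ/OFF interop stores float32 coordinates
    np.testing.assert_allclose(back.vertices, tetra.vertices, rtol=1e-6, atol=1e-9)
    np.testing.assert_array_equal(back.faces, tetra.faces)


def test_label_sidecar_round_trip(tmp_path, small_template):
    path = tmp_path / "lv.ply"
    mc.write_mesh(small_template, path)
    back = mc.read_mesh(path)
    np.testing.assert_array_equal(back.vertex_labels, small_template.vertex_labels)


def test_off_quad_face_rejected(tmp_path):
    path = tmp_path / "quad.off"
    path.write_text("OFF\n4 1 0\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n")
    with pytest.raises((UnsupportedTopologyError, MeshParseError)):
        mc.read_mesh(path)


def test_malformed_file_raises_parse_error(tmp_path):
    path = tmp_path / "bad.ply"
    path.write_text("this is not a ply file\n")
    with pytest.raises(MeshParseError):
        mc.read_mesh(path)


def test_template_ply_has_2450_vertices(tmp_path):
    tpl = sp.build_template()
    path = mc.write_mesh(tpl, tmp_path / "template.ply")
    assert mc.read_mesh(path).n_vertices == 2450


# ---------------------------------------------------------------------------
# Correspondence
# ---------------------------------------------------------------------------

def test_correspondence_identical_copies_pass(small_template):
    ds = mc.MeshDataset([small_template.copy() for _ in range(3)], ["a", "b", "c"])
    assert mc.validate_correspondence(ds).passed


def test_correspondence_face_order_sensitive(small_template):
    other = small_template.copy()
    other.faces[[0, 1]] = other.faces[[1, 0]]
    ds = mc.MeshDataset([small_template, other], ["ok", "swapped"])
    report = mc.validate_correspondence(ds)
    assert not report.passed
    assert report.failures[0][0] == "swapped"


def test_correspondence_cohort_passes(small_cohort):
    assert mc.validate_correspondence(small_cohort.ed).passed
    assert mc.validate_correspondence(small_cohort.es).passed


def test_correspondence_empty_dataset_raises():
    with pytest.raises(EmptyInputError):
        mc.validate_correspondence(mc.MeshDataset([], []))


# ---------------------------------------------------------------------------
# MSD / Hausdorff
# ---------------------------------------------------------------------------

def _planar_grid(n, offset_z=0.0, size=10.0):
    xs = np.linspace(0, size, n)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, offset_z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return mc.Mesh(verts, np.asarray(faces))


def test_msd_identity_zero(small_template):
    assert mc.mean_surface_distance(small_template, small_template) == 0.0
    assert mc.hausdorff_distance(small_template, small_template) == 0.0


def test_msd_parallel_planes_closed_form():
    # Large parallel grids offset along the normal: every vertex projects
    # onto the other plane's interior, so MSD is exactly the offset.
    x = _planar_grid(12, 0.0)
    y = _planar_grid(12, 2.0)
    assert mc.mean_surface_distance(x, y) == pytest.approx(2.0, abs=1e-12)


def test_hausdorff_translated_convex_shape(small_icosphere):
    moved = small_icosphere.with_vertices(small_icosphere.vertices + np.array([3.0, 0, 0]))
    assert mc.hausdorff_distance(small_icosphere, moved) == pytest.approx(3.0, abs=1e-9)


def test_distance_metric_properties_on_random_pairs(small_cohort):
    rng = np.random.default_rng(5)
    meshes = small_cohort.ed.meshes
    for _ in range(20):
        i, j = rng.integers(len(meshes), size=2)
        x, y = meshes[i], meshes[j]
        msd_xy = mc.mean_surface_distance(x, y)
        msd_yx = mc.mean_surface_distance(y, x)
        hd = mc.hausdorff_distance(x, y)
        assert msd_xy == pytest.approx(msd_yx, abs=1e-12)  # symmetric
        assert hd == pytest.approx(mc.hausdorff_distance(y, x), abs=1e-12)
        assert msd_xy >= 0
        assert hd >= msd_xy - 1e-12  # sup >= mean
        if i == j:
            assert msd_xy == 0.0


def test_msd_hd_agree_with_brute_force_oracle(small_icosphere):
    rng = np.random.default_rng(1)
    x = small_icosphere  # 80 faces
    y = small_icosphere.with_vertices(small_icosphere.vertices * 1.1 + rng.normal(scale=0.3, size=(small_icosphere.n_vertices, 3)))
    dx = mc.directed_surface_distance(x.vertices, y)
    dy = mc.directed_surface_distance(y.vertices, x)
    np.testing.assert_allclose(dx, _oracle_directed(x.vertices, y), atol=1e-9)
    np.testing.assert_allclose(dy, _oracle_directed(y.vertices, x), atol=1e-9)
    msd = mc.mean_surface_distance(x, y)
    assert msd == pytest.approx(0.5 * (dx.mean() + dy.mean()), abs=1e-12)


def test_empty_mesh_distance_raises(small_template):
    empty = mc.Mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    with pytest.raises(EmptyInputError):
        mc.mean_surface_distance(small_template, empty)


# ---------------------------------------------------------------------------
# Volume and mass
# ---------------------------------------------------------------------------

def test_icosphere_volume_within_half_percent(icosphere):
    analytic = 4.0 / 3.0 * math.pi * 1000.0 / 1000.0  # mL
    vol = mc.enclosed_volume(icosphere)
    assert abs(vol - analytic) / analytic < 0.005


def test_sphere_volume_error_decreases_with_subdivision():
    import trimesh

    analytic = 4.0 / 3.0 * math.pi
    errors = []
    for sub in (1, 2, 3, 4):
        ico = trimesh.creation.icosphere(subdivisions=sub, radius=10.0)
        vol = mc.enclosed_volume(mc.Mesh(np.asarray(ico.vertices), np.asarray(ico.faces)))
        errors.append(abs(vol - analytic))
    assert all(e1 > e2 for e1, e2 in zip(errors, errors[1:]))


def test_hemisphere_cup_capped_at_equator():
    # Open hemispherical cup of radius 10 mm whose boundary ring lies exactly
    # on the equator; the centroid-fan cap closes it, giving the half-ball
    # volume 2.0944 mL within 0.5%.
    verts = sp._surface_points((10.0, 10.0, 10.0), n_rings=70, n_circ=72, apex_pointedness=0.0, mid_bulge_mm=0.0)
    faces = sp._surface_faces(n_rings=70, n_circ=72, offset=0, flip=False)
    cup = mc.Mesh(verts, faces)
    vol = mc.enclosed_volume(cup)
    half_ball = 0.5 * 4.0 / 3.0 * math.pi  # mL at r=10mm
    assert abs(vol - half_ball) / half_ball < 0.005


def test_flat_patch_zero_volume():
    patch = _planar_grid(4)
    assert mc.enclosed_volume(patch) == pytest.approx(0.0, abs=1e-12)


def test_template_endo_epi_volumes(template):
    v_endo = mc.enclosed_volume(template, "endocardial")
    v_epi = mc.enclosed_volume(template, "epicardial")
    a, b, c = sp.DEFAULT_ENDO_SEMI_AXES
    analytic_endo = 0.5 * 4.0 / 3.0 * math.pi * a * b * c / 1000.0
    assert v_epi > v_endo > 0
    assert abs(v_endo - analytic_endo) / analytic_endo < 0.02  # tessellation tolerance


def test_half_ellipsoid_template_closed_form():
    tpl = sp.build_template(endo_semi_axes=(20.0, 20.0, 60.0), wall_thickness_mm=8.0)
    vol = mc.enclosed_volume(tpl, "endocardial")
    analytic = 0.5 * 4.0 / 3.0 * math.pi * 20 * 20 * 60 / 1000.0  # 50.27 mL
    assert abs(vol - analytic) / analytic < 0.02


@pytest.mark.parametrize(
    "wall_ml,expect_g", [(100.0, 105.0), (0.0, 0.0), (1.0, 1.05)]
)
def test_lv_mass_density_constant(wall_ml, expect_g):
    assert mc.lv_mass(wall_ml + 50.0, 50.0) == pytest.approx(expect_g, abs=1e-12)


def test_lv_mass_linear_slope_is_density():
    walls = np.linspace(0.0, 300.0, 7)
    masses = np.array([mc.lv_mass(w + 10.0, 10.0) for w in walls])
    slopes = np.diff(masses) / np.diff(walls)
    np.testing.assert_allclose(slopes, 1.05, atol=1e-12)


def test_negative_wall_volume_raises():
    with pytest.raises(InvalidAnatomyError):
        mc.lv_mass(50.0, 100.0)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def test_standardization_round_trip(small_cohort):
    stats = mc.fit_standardization(small_cohort.ed)
    x = small_cohort.ed.meshes[0].vertices
    np.testing.assert_allclose(stats.invert(stats.apply(x)), x, rtol=1e-9)


def test_standardized_train_set_zero_mean_unit_sd(small_cohort):
    stats = mc.fit_standardization(small_cohort.ed)
    train = small_cohort.ed.split_subset("train")
    std = np.stack([stats.apply(m.vertices) for m in train.meshes])
    np.testing.assert_allclose(std.mean(axis=0), 0.0, atol=1e-9)
    floored = stats.sd <= mc.StandardizationStats.SD_FLOOR
    np.testing.assert_allclose(std.std(axis=0)[~floored], 1.0, atol=1e-9)


def test_identical_meshes_sd_floored(small_template):
    meshes = [small_template.copy() for _ in range(4)]
    stats = mc.fit_standardization(meshes)
    assert (stats.sd == mc.StandardizationStats.SD_FLOOR).all()
    np.testing.assert_allclose(stats.apply(small_template.vertices), 0.0, atol=1e-12)


def test_non_train_split_statistics_rejected(small_cohort):
    with pytest.raises(DataLeakageError):
        mc.fit_standardization(small_cohort.ed, split="test")
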