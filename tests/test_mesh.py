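"""Geometric primitives: geodesics, smoothing, resampling, volume projection."""

import numpy as np
import pytest

from sulcmorph.mesh import (
    LabelSet,
    ScalarField,
    TriangleMesh,
    UnreachableVertexError,
    VolumeGrid,
    fwhm_to_sigma,
    gaussian_smooth_volume,
    geodesic_distances,
    icosphere,
    pairwise_geodesics,
    resample_nearest,
    smooth_on_mesh,
    surface_to_volume,
)


# ---------------------------------------------------------------------- mesh


def test_mesh_validation_rejects_bad_faces():
    with pytest.raises(ValueError):
        TriangleMesh(vertices=np.zeros((3, 3)), faces=np.array([[0, 1, 5]]))
    with pytest.raises(ValueError):
        TriangleMesh(vertices=np.eye(3), faces=np.array([[0, 1, 2]]),
                     sphere_coords=2 * np.eye(3))


def test_icosphere_is_connected_unit_sphere(ico3):
    assert ico3.is_connected()
    assert np.allclose(np.linalg.norm(ico3.sphere_coords, axis=1), 1.0, atol=1e-9)
    assert np.allclose(np.linalg.norm(ico3.vertices, axis=1), 100.0, atol=1e-6)


# ----------------------------------------------------------------- geodesics


def test_geodesic_single_edge_and_chain(chain_mesh):
    d = geodesic_distances(chain_mesh, 0, [0, 1, 2])
    assert d[0] == 0.0
    assert d[1] == pytest.approx(1.0)
    assert d[2] == pytest.approx(3.0)


def test_geodesic_symmetry(chain_mesh, ico3):
    assert geodesic_distances(chain_mesh, 2, [0])[0] == pytest.approx(3.0)
    rng = np.random.default_rng(0)
    for _ in range(5):
        a, b = rng.integers(0, ico3.n_vertices, size=2)
        dab = geodesic_distances(ico3, int(a), [int(b)])[0]
        dba = geodesic_distances(ico3, int(b), [int(a)])[0]
        assert dab == pytest.approx(dba, rel=1e-12)


def test_geodesic_unreachable_raises():
    # two disconnected triangles
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [10, 0, 0], [11, 0, 0], [10, 1, 0]], dtype=float)
    f = np.array([[0, 1, 2], [3, 4, 5]])
    m = TriangleMesh(vertices=v, faces=f)
    with pytest.raises(UnreachableVertexError):
        geodesic_distances(m, 0, [4])


def test_icosphere_geodesic_matches_great_circle(ico4):
    """Near-antipodal graph geodesic within 2% of the closed-form arc length."""
    u = ico4.sphere_coords
    j = int(np.argmin(u @ u[0]))
    d = geodesic_distances(ico4, 0, [j])[0]
    gc = 100.0 * np.arccos(np.clip(u[0] @ u[j], -1.0, 1.0))
    assert abs(d - gc) / gc < 0.02


def test_icosphere_geodesic_error_decreases_with_subdivision():
    errs = []
    for sub in (2, 3, 4):
        m = icosphere(sub, radius=100.0)
        u = m.sphere_coords
        j = int(np.argmin(u @ u[0]))
        d = geodesic_distances(m, 0, [j])[0]
        gc = 100.0 * np.arccos(np.clip(u[0] @ u[j], -1.0, 1.0))
        errs.append(abs(d - gc) / gc)
    assert errs[0] > errs[1] > errs[2]


def test_triangle_inequality_on_random_triples(ico3):
    rng = np.random.default_rng(1)
    idx = rng.choice(ico3.n_vertices, size=9, replace=False)
    D = pairwise_geodesics(ico3, idx)
    for i in range(9):
        for j in range(9):
            for k in range(9):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


def test_pairwise_geodesics_properties(chain_mesh, ico3):
    D = pairwise_geodesics(chain_mesh, [0, 1, 2])
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)
    # hand-enumerated pairs: {1, 2, 3} -> median 2
    iu = np.triu_indices(3, k=1)
    assert sorted(D[iu]) == [1.0, 2.0, 3.0]
    assert np.median(D[iu]) == 2.0
    # 20 points -> 190 unique pairs
    idx = np.random.default_rng(2).choice(ico3.n_vertices, 20, replace=False)
    D20 = pairwise_geodesics(ico3, idx)
    assert len(np.triu_indices(20, k=1)[0]) == 190
    with pytest.raises(ValueError):
        pairwise_geodesics(chain_mesh, [0])
    assert np.all(pairwise_geodesics(ico3, [5, 5, 5]) == 0.0)


# ----------------------------------------------------------------- smoothing


def test_smooth_constant_field_is_fixed_point(ico3):
    f = ScalarField(values=np.full(ico3.n_vertices, 3.7))
    out = smooth_on_mesh(ico3, f, fwhm=10.0)
    assert np.allclose(out.values, 3.7, atol=1e-9)


def test_smooth_delta_keeps_max_and_nonnegative(ico3):
    delta = np.zeros(ico3.n_vertices)
    delta[17] = 1.0
    out = smooth_on_mesh(ico3, delta, fwhm=2.0 * ico3.mean_edge_length())
    assert out.values.argmax() == 17
    assert (out.values >= 0).all()


def test_smooth_delta_matches_explicit_kernel(ico3):
    """Smoothed delta equals the direct normalised-Gaussian computation."""
    fwhm = 2.0 * ico3.mean_edge_length()
    sigma = fwhm_to_sigma(fwhm)
    src = 101
    delta = np.zeros(ico3.n_vertices)
    delta[src] = 1.0
    out = smooth_on_mesh(ico3, delta, fwhm).values
    # oracle: per-vertex weight of src within the <=3 sigma neighbourhood,
    # normalised over each vertex's own neighbourhood
    expected = np.zeros(ico3.n_vertices)
    for v in range(ico3.n_vertices):
        d = geodesic_distances(ico3, v)
        nb = d <= 3.0 * sigma
        w = np.exp(-0.5 * (d[nb] / sigma) ** 2)
        if nb[src]:
            expected[v] = np.exp(-0.5 * (d[src] / sigma) ** 2) / w.sum()
    assert np.allclose(out, expected, atol=1e-9)


def test_smoothing_operators_are_linear(ico3):
    rng = np.random.default_rng(3)
    x = rng.normal(size=ico3.n_vertices)
    y = rng.normal(size=ico3.n_vertices)
    a, b = 2.5, -1.25
    sx = smooth_on_mesh(ico3, x, 5.0).values
    sy = smooth_on_mesh(ico3, y, 5.0).values
    sxy = smooth_on_mesh(ico3, a * x + b * y, 5.0).values
    assert np.allclose(sxy, a * sx + b * sy, atol=1e-9)
    vol = VolumeGrid(data=rng.normal(size=(8, 8, 8)), affine=np.eye(4))
    vol2 = VolumeGrid(data=rng.normal(size=(8, 8, 8)), affine=np.eye(4))
    g = gaussian_smooth_volume
    lhs = g(vol.copy_with(a * vol.data + b * vol2.data), 2.0).data
    rhs = a * g(vol, 2.0).data + b * g(vol2, 2.0).data
    assert np.allclose(lhs, rhs, atol=1e-9)


# ---------------------------------------------------------------- resampling


def test_resample_identity_and_rotation(toy_sphere_mesh):
    rng = np.random.default_rng(4)
    vals = rng.normal(size=toy_sphere_mesh.n_vertices)
    out = resample_nearest(toy_sphere_mesh, vals, toy_sphere_mesh)
    assert np.array_equal(out, vals)
    # rotated copy of the mesh with identically rotated field -> recovered
    ang = 0.3
    R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
    rot = TriangleMesh(vertices=toy_sphere_mesh.vertices @ R.T, faces=toy_sphere_mesh.faces,
                       sphere_coords=toy_sphere_mesh.sphere_coords @ R.T)
    back = resample_nearest(rot, vals, rot)
    assert np.array_equal(back, vals)


def test_resample_matches_brute_force():
    src = icosphere(2, radius=1.0)  # 162 vertices
    tgt = icosphere(1, radius=1.0)
    rng = np.random.default_rng(5)
    vals = rng.normal(size=src.n_vertices)
    out = resample_nearest(src, vals, tgt)
    # exhaustive nearest neighbour in the great-circle metric
    ang = np.arccos(np.clip(tgt.sphere_coords @ src.sphere_coords.T, -1, 1))
    expected = vals[np.argmin(ang, axis=1)]
    assert np.allclose(out, expected)


def test_resample_requires_sphere_coords(toy_sphere_mesh):
    flat = TriangleMesh(vertices=toy_sphere_mesh.vertices, faces=toy_sphere_mesh.faces)
    with pytest.raises(ValueError):
        resample_nearest(flat, np.zeros(flat.n_vertices), toy_sphere_mesh)


# ------------------------------------------------------------ surface/volume


def _toy_grid(shape=(8, 8, 8), vox=1.0, origin=(-4.0, -4.0, -4.0)):
    affine = np.eye(4) * vox
    affine[3, 3] = 1.0
    affine[:3, 3] = origin
    return VolumeGrid(data=np.zeros(shape, dtype=np.float32), affine=affine)


def test_surface_to_volume_single_vertex_and_empty():
    v = np.array([[0.0, 0.0, 0.0], [50.0, 50.0, 50.0], [50.0, 50.0, 51.0]])
    f = np.array([[0, 1, 2]])
    mesh = TriangleMesh(vertices=v, faces=f)
    grid = _toy_grid()
    labels = LabelSet(values=np.array([1, 0, 0]), hemisphere="left")
    vols = surface_to_volume(mesh, labels, grid, segments=["cs_1"], max_distance=0.4)
    got = vols["cs_1"].data
    ijk = np.argwhere(got > 0)
    assert len(ijk) == 1 and np.allclose(grid.voxel_to_world(ijk[0])[0], [0, 0, 0])
    empty = surface_to_volume(mesh, LabelSet(values=np.zeros(3, int)), grid, segments=["cs_1"])
    assert empty["cs_1"].data.sum() == 0


def test_surface_to_volume_matches_brute_force():
    rng = np.random.default_rng(6)
    v = rng.uniform(-3, 3, size=(10, 3))
    f = np.array([[i, (i + 1) % 10, (i + 2) % 10] for i in range(8)])
    mesh = TriangleMesh(vertices=v, faces=f)
    labels = LabelSet(values=rng.integers(0, 3, size=10).astype(np.int32))
    grid = _toy_grid()
    cap = 2.0 * mesh.mean_edge_length()
    vols = surface_to_volume(mesh, labels, grid, segments=["cs_1", "cs_2"])
    centers = grid.voxel_centers_world()
    for seg, sid in (("cs_1", 1), ("cs_2", 2)):
        expected = np.zeros(len(centers))
        for i, c in enumerate(centers):
            d = np.linalg.norm(v - c, axis=1)
            j = int(np.argmin(d))  # lowest index wins ties
            if d[j] <= cap and labels.values[j] == sid:
                expected[i] = 1.0
        assert np.array_equal(vols[seg].data.ravel(), expected)


def test_gaussian_smooth_volume_mass_and_profile():
    grid = _toy_grid(shape=(31, 31, 31), origin=(-15, -15, -15))
    grid.data[15, 15, 15] = 1.0
    out = gaussian_smooth_volume(grid, fwhm=2.0)
    assert out.data.sum() == pytest.approx(1.0, rel=0.01)
    # 1D profile through the centre equals the separable discrete kernel
    from scipy.ndimage import gaussian_filter1d

    sigma = fwhm_to_sigma(2.0)
    imp = np.zeros(31)
    imp[15] = 1.0
    k = gaussian_filter1d(imp, sigma)
    assert np.allclose(out.data[:, 15, 15], k * k[15] * k[15], atol=1e-12)
    assert gaussian_smooth_volume(_toy_grid(), 2.0).data.sum() == 0.0


def test_volume_grid_affine_round_trip():
    grid = _toy_grid(vox=0.5, origin=(1.0, 2.0, 3.0))
    ijk = np.array([[0, 0, 0], [1, 2, 3]])
    w = grid.voxel_to_world(ijk)
    assert np.allclose(w[0], [1, 2, 3])
    assert np.allclose(grid.world_to_voxel(w), ijk)
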