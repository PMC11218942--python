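import numpy as np
import pytest
import scipy.sparse as sp

from image2flow.mesh_core import (
    FieldSet,
    ImageVolume,
    MeshValidationError,
    VolumeMesh,
    extract_edges,
    extract_surface,
    face_normals,
    laplacian_from_edges,
    sample_image_features,
    scaled_laplacian,
    tet_volumes,
    voxelize,
)
from image2flow.synthetic import build_tube_mesh


def edges_as_set(mesh):
    return {tuple(e) for e in extract_edges(mesh)}


class TestExtractEdges:
    def test_single_tet_has_six_edges(self, single_tet):
        assert edges_as_set(single_tet) == {
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
        }

    def test_two_tets_sharing_face(self, two_tets):
        # 12 raw edges, 3 shared -> 9 unique (hand deduplication)
        assert len(edges_as_set(two_tets)) == 9

    def test_empty_tet_list(self):
        mesh = VolumeMesh(np.zeros((3, 3)), np.empty((0, 4)))
        assert extract_edges(mesh).shape == (0, 2)

    def test_degenerate_tet_raises(self):
        mesh = VolumeMesh(np.zeros((4, 3)), np.array([[0, 1, 2, 2]]))
        with pytest.raises(MeshValidationError, match="degenerate"):
            extract_edges(mesh)

    def test_sorted_deterministic(self, two_tets):
        e = extract_edges(two_tets)
        assert (e[:, 0] <= e[:, 1]).all()
        assert np.array_equal(e, extract_edges(two_tets))


class TestExtractSurface:
    def test_single_tet_four_faces(self, single_tet):
        surf = extract_surface(single_tet)
        assert surf.triangles.shape[0] == 4
        assert set(surf.node_indices) == {0, 1, 2, 3}

    def test_shared_face_absent(self, two_tets):
        surf = extract_surface(two_tets)
        assert surf.triangles.shape[0] == 6
        keys = {tuple(t) for t in np.sort(surf.triangles, axis=1)}
        assert (0, 1, 2) not in keys

    def test_two_tet_surface_edge_count(self, two_tets):
        assert extract_surface(two_tets).edges.shape[0] == 9

    def test_outward_normals(self, single_tet):
        surf = extract_surface(single_tet)
        centroid = single_tet.nodes.mean(axis=0)
        normals = face_normals(single_tet.nodes, surf.triangles)
        centers = single_tet.nodes[surf.triangles].mean(axis=1)
        assert (np.einsum("ij,ij->i", normals, centers - centroid) > 0).all()

    def test_nonmanifold_face_raises(self):
        nodes = np.array(
            [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, -1], [1, 1, 1]]
        )
        tets = np.array([[0, 1, 2, 3], [0, 1, 2, 4], [0, 1, 2, 5]])
        with pytest.raises(MeshValidationError, match="non-manifold"):
            extract_surface(VolumeMesh(nodes, tets))

    def test_watertight_convex(self, wye):
        mesh, _, _ = wye
        surf = extract_surface(mesh)
        counts = {}
        for tri in surf.triangles:
            for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])):
                counts[tuple(sorted(e))] = counts.get(tuple(sorted(e)), 0) + 1
        assert set(counts.values()) == {2}


class TestFaceNormals:
    def test_xy_triangle_up(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        np.testing.assert_allclose(
            face_normals(nodes, [[0, 1, 2]]), [[0, 0, 1]], atol=1e-12
        )

    def test_flipped_orientation(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        np.testing.assert_allclose(
            face_normals(nodes, [[0, 2, 1]]), [[0, 0, -1]], atol=1e-12
        )

    def test_xz_triangle(self):
        # cross((1,0,0), (0,0,1)) = (0,-1,0) by hand
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 0, 1]])
        np.testing.assert_allclose(
            face_normals(nodes, [[0, 1, 2]]), [[0, -1, 0]], atol=1e-12
        )

    def test_unit_length(self, wye):
        mesh, _, _ = wye
        surf = extract_surface(mesh)
        n = face_normals(mesh.nodes, surf.triangles)
        np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)

    def test_zero_area_raises(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(MeshValidationError, match="zero-area"):
            face_normals(nodes, [[0, 1, 2]])


def dense_laplacian_oracle(edges, n):
    """Brute-force dense L~ = L - I with lambda_max fixed at 2."""
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    deg = A.sum(axis=1)
    dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1)), 0.0)
    L = np.eye(n) - dinv[:, None] * A * dinv[None, :]
    Lt = L - np.eye(n)
    for i in range(n):
        if deg[i] == 0:
            Lt[i, i] = -1.0
    return Lt


class TestScaledLaplacian:
    def test_two_nodes_one_edge(self):
        op = laplacian_from_edges(np.array([[0, 1]]), 2).toarray()
        np.testing.assert_array_equal(op, [[0, -1], [-1, 0]])

    def test_k3_matches_dense_oracle(self):
        edges = np.array([[0, 1], [0, 2], [1, 2]])
        op = laplacian_from_edges(edges, 3).toarray()
        np.testing.assert_allclose(op, dense_laplacian_oracle(edges, 3), atol=1e-12)

    def test_random_graphs_match_dense(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = rng.integers(4, 21)
            all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            m = rng.integers(1, len(all_pairs) + 1)
            sel = rng.choice(len(all_pairs), size=m, replace=False)
            edges = np.array([all_pairs[i] for i in sel])
            got = laplacian_from_edges(edges, int(n)).toarray()
            want = dense_laplacian_oracle(edges, int(n))
            assert np.abs(got - want).max() <= 1e-12

    def test_symmetric_and_finite(self, wye):
        op = scaled_laplacian(wye[0])
        diff = (op - op.T).tocoo()
        assert np.abs(diff.data).max() if diff.nnz else 0 <= 1e-12
        assert np.isfinite(op.data).all()

    def test_eigenvalues_in_range(self):
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
        op = laplacian_from_edges(edges, 4).toarray()
        ev = np.linalg.eigvalsh(op)
        assert ev.min() >= -1 - 1e-12 and ev.max() <= 1 + 1e-12

    def test_isolated_node_warns_self_only(self):
        with pytest.warns(UserWarning, match="isolated"):
            op = laplacian_from_edges(np.array([[0, 1]]), 3).toarray()
        assert op[2, 2] == -1.0 and op[2, :2].sum() == 0


class TestVoxelize:
    def test_large_tet_contains_voxel(self):
        mesh = VolumeMesh(
            np.array([[-5.0, -5, -5], [10, -5, -5], [-5, 10, -5], [-5, -5, 10]]),
            np.array([[0, 1, 2, 3]]),
        )
        grid = ImageVolume(np.zeros((4, 4, 4)))
        with pytest.warns(UserWarning):
            mask = voxelize(mesh, grid)
        assert mask[0, 0, 0] == 1

    def test_mesh_outside_grid(self):
        mesh = VolumeMesh(
            np.array([[100.0, 100, 100], [101, 100, 100], [100, 101, 100], [100, 100, 101]]),
            np.array([[0, 1, 2, 3]]),
        )
        grid = ImageVolume(np.zeros((8, 8, 8)))
        with pytest.warns(UserWarning):
            mask = voxelize(mesh, grid)
        assert mask.sum() == 0

    def test_zero_volume_mesh(self):
        mesh = VolumeMesh(np.zeros((4, 3)), np.empty((0, 4)))
        with pytest.warns(UserWarning, match="zero-volume"):
            mask = voxelize(mesh, ImageVolume(np.zeros((4, 4, 4))))
        assert mask.sum() == 0

    def test_tube_volume_within_five_percent(self):
        radius, length = 4.5, 20.0
        mesh = build_tube_mesh(radius, length, rings=4, sectors=16, stations=12,
                               origin=np.array([16.0, 16.0, 5.0]))
        mask = voxelize(mesh, ImageVolume(np.zeros((32, 32, 32))))
        analytic = np.pi * radius**2 * length
        assert abs(int(mask.sum()) - analytic) / analytic < 0.05

    def test_tube_dice_against_analytic_rasterization(self):
        radius, length = 4.0, 18.0
        center = np.array([16.0, 16.0])
        mesh = build_tube_mesh(radius, length, rings=4, sectors=16, stations=12,
                               origin=np.array([16.0, 16.0, 6.0]))
        mask = voxelize(mesh, ImageVolume(np.zeros((32, 32, 32))))
        ii, jj, kk = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
        analytic = (
            ((ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2)
            & (kk >= 6) & (kk <= 6 + length)
        )
        inter = (mask.astype(bool) & analytic).sum()
        dice = 2 * inter / (mask.sum() + analytic.sum())
        assert dice >= 0.95


class TestSampleImageFeatures:
    def test_voxel_center_exact(self):
        rng = np.random.default_rng(0)
        grid = rng.random((2, 5, 5, 5))
        out = sample_image_features(grid, [[2.0, 3.0, 1.0]])
        np.testing.assert_allclose(out[0], grid[:, 2, 3, 1], atol=1e-12)

    def test_midpoint_is_mean(self):
        rng = np.random.default_rng(1)
        grid = rng.random((3, 4, 4, 4))
        out = sample_image_features(grid, [[1.5, 2.0, 2.0]])
        np.testing.assert_allclose(
            out[0], (grid[:, 1, 2, 2] + grid[:, 2, 2, 2]) / 2, atol=1e-12
        )

    def test_exact_on_trilinear_field(self):
        ax = np.arange(6, dtype=float)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        grid = (2 * x + 3 * y - z)[None]
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 5, size=(50, 3))
        out = sample_image_features(grid, pts)
        want = 2 * pts[:, 0] + 3 * pts[:, 1] - pts[:, 2]
        np.testing.assert_allclose(out[:, 0], want, rtol=1e-9)

    def test_clamps_out_of_bounds(self):
        grid = np.arange(27, dtype=float).reshape(1, 3, 3, 3)
        out = sample_image_features(grid, [[-5.0, 1.0, 1.0]])
        np.testing.assert_allclose(out[0, 0], grid[0, 0, 1, 1])

    def test_spacing_and_origin(self):
        grid = np.arange(8, dtype=float).reshape(1, 2, 2, 2)
        out = sample_image_features(
            grid, [[3.0, 1.0, 1.0]], spacing=2.0, origin=np.array([1.0, 1.0, 1.0])
        )
        np.testing.assert_allclose(out[0, 0], grid[0, 1, 0, 0])

    def test_nonfinite_point_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            sample_image_features(np.zeros((1, 3, 3, 3)), [[np.nan, 0, 0]])


class TestValidation:
    def test_valid_wye(self, wye):
        wye[0].validate()

    def test_negative_volume_detected(self, single_tet):
        bad = VolumeMesh(single_tet.nodes, single_tet.tets[:, [0, 1, 3, 2]])
        with pytest.raises(MeshValidationError, match="volume"):
            bad.validate()

    def test_index_out_of_range(self):
        with pytest.raises(MeshValidationError, match="range"):
            VolumeMesh(np.zeros((3, 3)), np.array([[0, 1, 2, 3]])).validate()

    def test_cap_not_on_boundary(self, two_tets):
        two_tets.cap_faces = {"inlet": np.array([[0, 1, 2]])}  # interior face
        with pytest.raises(MeshValidationError, match="boundary"):
            two_tets.validate()

    def test_fieldset_length_mismatch(self, single_tet):
        fs = FieldSet(np.zeros(3), np.zeros((3, 3)))
        with pytest.raises(MeshValidationError):
            fs.validate(single_tet)

    def test_tet_volumes_positive(self, wye):
        assert (tet_volumes(wye[0]) > 0).all()
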