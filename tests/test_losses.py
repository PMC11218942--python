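"""Loss terms against brute-force oracles, printed examples, and invariants."""

import numpy as np
import pytest

from image2flow.autodiff import Tensor, parameter
from image2flow.losses import (
    LossWeights,
    TopologyCache,
    aspect_ratio_loss,
    branch_mesh_loss,
    cap_coplanar_loss,
    cfd_loss,
    chamfer_loss,
    edge_deviation_loss,
    edge_lengths,
    total_loss,
)
from image2flow.mesh_core import VolumeMesh
from conftest import regular_tet_nodes


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def chamfer_bruteforce(P, G, reduction="mean"):
    fwd = [min(np.sum((p - g) ** 2) for g in G) for p in P]
    bwd = [min(np.sum((p - g) ** 2) for p in P) for g in G]
    if reduction == "mean":
        return np.mean(fwd) + np.mean(bwd)
    return np.sum(fwd) + np.sum(bwd)


def aspect_bruteforce(nodes, tets):
    ratios = []
    for tet in tets:
        lens = [
            np.linalg.norm(nodes[a] - nodes[b])
            for i, a in enumerate(tet)
            for b in tet[i + 1 :]
        ]
        ratios.append(max(lens) / min(lens))
    return np.mean(ratios)


def cfd_bruteforce(pp, pv, tp, tv):
    total = np.mean([abs(a - b) for a, b in zip(pp, tp)])
    for k in range(3):
        total += np.mean([abs(a[k] - b[k]) for a, b in zip(pv, tv)])
    return total


class TestChamfer:
    def test_identity_zero(self):
        pts = np.random.default_rng(0).random((10, 3))
        assert float(chamfer_loss(pts, pts).value) == 0.0

    def test_hand_value(self):
        # 1^2 forward + 1^2 backward = 2
        assert float(chamfer_loss([[0.0, 0, 0]], [[1.0, 0, 0]]).value) == 2.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            P = rng.random((rng.integers(3, 50), 3))
            G = rng.random((rng.integers(3, 50), 3))
            for red in ("mean", "sum"):
                got = float(chamfer_loss(P, G, red).value)
                want = chamfer_bruteforce(P, G, red)
                assert abs(got - want) <= 1e-9 * max(1, abs(want))

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        P, G = rng.random((8, 3)), rng.random((5, 3))
        assert float(chamfer_loss(P, G).value) == pytest.approx(
            float(chamfer_loss(G, P).value), rel=1e-12
        )

    def test_scales_quadratically(self):
        rng = np.random.default_rng(3)
        P, G = rng.random((6, 3)), rng.random((7, 3))
        base = float(chamfer_loss(P, G).value)
        assert float(chamfer_loss(3 * P, 3 * G).value) == pytest.approx(
            9 * base, rel=1e-9
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            chamfer_loss(np.empty((0, 3)), np.ones((2, 3)))

    def test_kdtree_path_matches_dense(self):
        rng = np.random.default_rng(4)
        P, G = rng.random((600, 3)), rng.random((600, 3))  # above the dense cutoff
        got = float(chamfer_loss(P, G).value)
        dense = ((P[:, None] - G[None]) ** 2).sum(axis=2)
        want = dense.min(axis=1).mean() + dense.min(axis=0).mean()
        assert got == pytest.approx(want, rel=1e-12)


class TestEdgeDeviation:
    def test_uniform_zero(self):
        assert float(edge_deviation_loss(np.full(10, 2.5)).value) == 0.0

    def test_hand_value_population_std(self):
        # lengths {1, 3}: population sigma 1, mean 2 -> 0.5
        assert float(edge_deviation_loss([1.0, 3.0]).value) == pytest.approx(0.5)

    def test_scale_invariant(self):
        assert float(edge_deviation_loss([10.0, 30.0]).value) == pytest.approx(0.5)

    def test_zero_length_raises(self):
        with pytest.raises(ValueError, match="collapsed"):
            edge_deviation_loss([1.0, 0.0])

    def test_too_few_edges_raises(self):
        with pytest.raises(ValueError):
            edge_deviation_loss([1.0])


class TestAspectRatio:
    def test_regular_tet_is_one(self, regular_tet):
        assert float(aspect_ratio_loss(regular_tet).value) == pytest.approx(1.0)

    def test_hand_value_sqrt5(self):
        mesh = VolumeMesh(
            np.array([[0.0, 0, 0], [2, 0, 0], [0, 1, 0], [0, 0, 1]]),
            np.array([[0, 1, 2, 3]]),
        )
        assert float(aspect_ratio_loss(mesh).value) == pytest.approx(np.sqrt(5))

    def test_matches_bruteforce(self, wye):
        mesh, _, _ = wye
        got = float(aspect_ratio_loss(mesh).value)
        want = aspect_bruteforce(mesh.nodes, mesh.tets)
        assert got == pytest.approx(want, rel=1e-9)

    def test_at_least_one(self, small_case):
        assert float(aspect_ratio_loss(small_case.mesh).value) >= 1.0


class TestCapCoplanar:
    def _mesh_with_caps(self, normals_per_cap):
        """Synthetic nodes/faces giving prescribed unit face normals."""
        nodes, faces = [], {}
        for cap, normals in normals_per_cap.items():
            tris = []
            for n in normals:
                n = np.asarray(n, dtype=float)
                u = np.array([1.0, 0, 0])
                if abs(u @ n) > 0.9:
                    u = np.array([0.0, 1, 0])
                u = u - (u @ n) * n
                u /= np.linalg.norm(u)
                v = np.cross(n, u)
                base = len(nodes)
                nodes += [np.zeros(3) + 10 * base, 10 * base + u, 10 * base + v]
                tris.append([base, base + 1, base + 2])
            faces[cap] = np.array(tris)
        return np.array(nodes), faces

    def test_coplanar_zero(self):
        nodes, faces = self._mesh_with_caps(
            {
                "inlet": [[0, 0, 1], [0, 0, 1]],
                "outlet_left": [[1, 0, 0]],
                "outlet_right": [[0, 1, 0]],
            }
        )
        assert float(cap_coplanar_loss(nodes=nodes, cap_faces=faces).value) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_two_orthogonal_faces(self):
        # normals (0,0,1) and (1,0,0): mean (0.5,0,0.5); each deviation has
        # squared norm 0.5 -> cap contributes 1.0
        nodes, faces = self._mesh_with_caps(
            {
                "inlet": [[0, 0, 1], [1, 0, 0]],
                "outlet_left": [[0, 1, 0]],
                "outlet_right": [[0, 1, 0]],
            }
        )
        assert float(cap_coplanar_loss(nodes=nodes, cap_faces=faces).value) == pytest.approx(1.0)

    def test_rotation_invariance(self, small_case):
        mesh = small_case.mesh
        base = float(cap_coplanar_loss(mesh).value)
        th = np.pi / 2
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        rotated = mesh.with_nodes(mesh.nodes @ R.T + np.array([3.0, -2.0, 1.0]))
        assert float(cap_coplanar_loss(rotated).value) == pytest.approx(base, abs=1e-9)

    def test_missing_cap_raises(self):
        nodes, faces = self._mesh_with_caps({"inlet": [[0, 0, 1]]})
        with pytest.raises(ValueError, match="outlet_left"):
            cap_coplanar_loss(nodes=nodes, cap_faces=faces)


class TestCfdLoss:
    def test_identity_zero(self):
        p = np.ones(5)
        v = np.ones((5, 3))
        assert float(cfd_loss(p, v, p, v).value) == 0.0

    def test_offset_one_everywhere_is_four(self):
        p = np.zeros(6)
        v = np.zeros((6, 3))
        assert float(cfd_loss(p + 1, v + 1, p, v).value) == pytest.approx(4.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        pp, tp = rng.random(10), rng.random(10)
        pv, tv = rng.random((10, 3)), rng.random((10, 3))
        got = float(cfd_loss(pp, pv, tp, tv).value)
        assert got == pytest.approx(cfd_bruteforce(pp, pv, tp, tv), rel=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cfd_loss(np.zeros(3), np.zeros((3, 3)), np.zeros(4), np.zeros((4, 3)))


def _equilateral_fixture():
    """One regular tet; caps are three of its faces (trivially coplanar)."""
    nodes = regular_tet_nodes()
    mesh = VolumeMesh(
        nodes,
        np.array([[0, 1, 2, 3]]),
        {
            "inlet": np.array([[0, 1, 2]]),
            "outlet_left": np.array([[0, 1, 3]]),
            "outlet_right": np.array([[0, 2, 3]]),
        },
    )
    p = np.zeros(4)
    v = np.zeros((4, 3))
    return mesh, p, v


class TestBranchAndTotal:
    def test_identity_equilateral_only_aspect(self, weights):
        mesh, p, v = _equilateral_fixture()
        topo = TopologyCache.from_mesh(mesh)
        loss, terms = branch_mesh_loss(
            mesh.nodes, p, v, mesh.nodes, p, v, topo, weights
        )
        assert terms["aspect"] == pytest.approx(1.0)
        for k in ("point", "point_surface", "edge", "edge_surface", "cap", "cfd"):
            assert terms[k] == pytest.approx(0.0, abs=1e-12)
        assert float(loss.value) == pytest.approx(weights.lambda3 * 1.0)

    def test_zero_weights_zero(self):
        mesh, p, v = _equilateral_fixture()
        topo = TopologyCache.from_mesh(mesh)
        zero = LossWeights(0, 0, 0, 0, 0)
        loss, _ = branch_mesh_loss(mesh.nodes, p, v, mesh.nodes, p, v, topo, zero)
        assert float(loss.value) == 0.0

    def test_branch_composes_subterms(self, small_case, weights):
        mesh = small_case.mesh
        topo = TopologyCache.from_mesh(mesh)
        rng = np.random.default_rng(11)
        pred_nodes = mesh.nodes + rng.normal(0, 0.05, mesh.nodes.shape)
        pp, pv = rng.random(mesh.node_count), rng.random((mesh.node_count, 3))
        tp, tv = rng.random(mesh.node_count), rng.random((mesh.node_count, 3))
        loss, terms = branch_mesh_loss(
            pred_nodes, pp, pv, mesh.nodes, tp, tv, topo, weights
        )
        surf = topo.surface_nodes
        # compose from the individually verified implementations
        expect = (
            weights.lambda1
            * (
                float(chamfer_loss(pred_nodes, mesh.nodes).value)
                + float(chamfer_loss(pred_nodes[surf], mesh.nodes[surf]).value)
            )
            + weights.lambda2
            * (
                float(edge_deviation_loss(edge_lengths(pred_nodes, topo.edges)).value)
                + float(
                    edge_deviation_loss(
                        edge_lengths(pred_nodes, topo.surface_edges)
                    ).value
                )
            )
            + weights.lambda3 * float(aspect_ratio_loss(nodes=Tensor(pred_nodes), tets=topo.tets).value)
            + weights.lambda4 * float(cap_coplanar_loss(nodes=Tensor(pred_nodes), cap_faces=topo.cap_faces).value)
            + weights.lambda5 * float(cfd_loss(pp, pv, tp, tv).value)
        )
        assert float(loss.value) == pytest.approx(expect, rel=1e-12)

    def test_total_is_sum_of_branches(self, weights):
        mesh, p, v = _equilateral_fixture()
        topo = TopologyCache.from_mesh(mesh)
        rng = np.random.default_rng(13)
        preds = [
            (mesh.nodes + rng.normal(0, 0.02, mesh.nodes.shape), rng.random(4), rng.random((4, 3)))
            for _ in range(3)
        ]
        tot, report = total_loss(preds, mesh.nodes, p, v, topo, weights)
        singles = [
            float(
                branch_mesh_loss(n, pp, pv, mesh.nodes, p, v, topo, weights)[0].value
            )
            for n, pp, pv in preds
        ]
        assert float(tot.value) == pytest.approx(sum(singles), rel=1e-12)
        assert report.total == pytest.approx(sum(singles), rel=1e-12)

    def test_three_identical_branches_triple(self, weights):
        mesh, p, v = _equilateral_fixture()
        topo = TopologyCache.from_mesh(mesh)
        preds = [(mesh.nodes, p, v)] * 3
        tot, _ = total_loss(preds, mesh.nodes, p, v, topo, weights)
        assert float(tot.value) == pytest.approx(3 * weights.lambda3, rel=1e-12)

    def test_wrong_branch_count_raises(self, weights):
        mesh, p, v = _equilateral_fixture()
        topo = TopologyCache.from_mesh(mesh)
        with pytest.raises(ValueError, match="3 branch"):
            total_loss([(mesh.nodes, p, v)] * 2, mesh.nodes, p, v, topo, weights)


class TestGradients:
    """Finite-difference checks on every term (rel err <= 1e-3)."""

    def _fd(self, build, nodes, rtol=1e-3, n=10, eps=1e-6):
        loss = build()
        loss.backward()
        g = nodes.grad.reshape(-1)
        rng = np.random.default_rng(0)
        flat = nodes.value.reshape(-1)
        for i in rng.choice(flat.size, size=min(n, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + eps
            f1 = float(build().value)
            flat[i] = old - eps
            f2 = float(build().value)
            flat[i] = old
            num = (f1 - f2) / (2 * eps)
            assert abs(num - g[i]) <= rtol * max(1.0, abs(g[i]))

    def test_all_terms(self, small_case, weights):
        mesh = small_case.mesh
        topo = TopologyCache.from_mesh(mesh)
        rng = np.random.default_rng(21)
        nodes = parameter(mesh.nodes + rng.normal(0, 0.05, mesh.nodes.shape))
        tp, tv = rng.random(mesh.node_count), rng.random((mesh.node_count, 3))
        pp = parameter(rng.random(mesh.node_count))
        pv = parameter(rng.random((mesh.node_count, 3)))

        checks = {
            "chamfer": lambda: chamfer_loss(nodes, mesh.nodes),
            "edge": lambda: edge_deviation_loss(edge_lengths(nodes, topo.edges)),
            "aspect": lambda: aspect_ratio_loss(nodes=nodes, tets=topo.tets),
            "cap": lambda: cap_coplanar_loss(nodes=nodes, cap_faces=topo.cap_faces),
        }
        for name, build in checks.items():
            nodes.zero_grad()
            self._fd(build, nodes)
        pp.zero_grad()
        self._fd(lambda: cfd_loss(pp, pv, tp, tv), pp)
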