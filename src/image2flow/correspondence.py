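"""Template construction, deformation-based correspondence, and field
interpolation between meshes.

Two correspondence routes exist: the direct per-case optimization implemented
here (gradient descent over node positions, no learning) and the trained
simplified network (training module with the flow-loss weight set to zero).
Both preserve the template topology exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Adam, Tensor, parameter
from .losses import (
    LossWeights,
    TopologyCache,
    aspect_ratio_loss,
    cap_coplanar_loss,
    chamfer_loss,
    edge_deviation_loss,
    edge_lengths,
)
from .mesh_core import FieldSet, VolumeMesh, tet_volumes


@dataclass
class DeformationFit:
    """Result of fitting a template's nodes onto a target point set."""

    nodes: np.ndarray
    residual_chamfer: float
    iterations: int
    converged: bool

    def mesh(self, template: VolumeMesh) -> VolumeMesh:
        return template.with_nodes(self.nodes)


def average_template(meshes) -> VolumeMesh:
    """Node-wise mean of point-correspondent meshes (tets/caps copied)."""
    meshes = list(meshes)
    if not meshes:
        raise ValueError("average_template requires at least one mesh")
    ref = meshes[0]
    for i, m in enumerate(meshes[1:], start=1):
        if m.nodes.shape != ref.nodes.shape or not np.array_equal(m.tets, ref.tets):
            raise ValueError(f"mesh {i} topology differs from mesh 0")
        for cap, faces in ref.cap_faces.items():
            if cap not in m.cap_faces or not np.array_equal(m.cap_faces[cap], faces):
                raise ValueError(f"mesh {i} cap labels differ from mesh 0")
    mean_nodes = np.mean([m.nodes for m in meshes], axis=0)
    out = VolumeMesh(mean_nodes, ref.tets.copy(), {k: v.copy() for k, v in ref.cap_faces.items()})
    if out.tets.size and (tet_volumes(out) <= 0).any():
        raise ValueError("averaging inverted cells; meshes are too dissimilar")
    return out


def fit_correspondence(
    template: VolumeMesh,
    target_points: np.ndarray,
    weights: LossWeights | None = None,
    lr: float = 0.05,
    max_iters: int = 2000,
    tol: float = 1e-6,
    window: int = 20,
    target_volume_points: np.ndarray | None = None,
) -> DeformationFit:
    """Deform the template's nodes onto a target surface point cloud.

    Minimizes the geometric loss terms (point + edge + aspect + cap; no flow
    terms) by Adam over the node coordinates.  The all-points Chamfer term is
    matched against ``target_volume_points`` when given (a target volume point
    cloud); against a surface-only target, pulling interior nodes onto the
    surface would fight the fit, so both point terms then use the surface
    nodes.  Stops when the relative loss change over a 20-iteration window
    falls below ``tol`` or at ``max_iters``; raises if the loss diverges to
    10x its initial value.
    """
    target_points = np.asarray(target_points, dtype=np.float64)
    if target_points.size == 0:
        raise ValueError("target point set is empty")
    weights = weights or LossWeights(lambda5=0.0)
    nodes = parameter(template.nodes.copy())
    opt = Adam([nodes], lr=lr)
    has_cells = template.tets.size > 0
    if has_cells:
        topo = TopologyCache.from_mesh(template)
        surf_idx = topo.surface_nodes
    else:
        surf_idx = np.arange(template.node_count)

    def objective():
        if target_volume_points is not None:
            point = chamfer_loss(nodes, target_volume_points)
        else:
            point = chamfer_loss(nodes[surf_idx], target_points)
        point_s = chamfer_loss(nodes[surf_idx], target_points)
        loss = weights.lambda1 * (point + point_s)
        if has_cells:
            if weights.lambda2:
                loss = loss + weights.lambda2 * (
                    edge_deviation_loss(edge_lengths(nodes, topo.edges))
                    + edge_deviation_loss(edge_lengths(nodes, topo.surface_edges))
                )
            if weights.lambda3:
                loss = loss + weights.lambda3 * aspect_ratio_loss(
                    nodes=nodes, tets=topo.tets
                )
            if weights.lambda4 and template.cap_faces:
                loss = loss + weights.lambda4 * cap_coplanar_loss(
                    nodes=nodes, cap_faces=topo.cap_faces
                )
        return loss

    history = []
    initial = None
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        loss = objective()
        val = float(loss.value)
        if initial is None:
            initial = val
        if val > 10.0 * max(initial, 1e-12):
            raise RuntimeError(
                f"fit diverged (loss {val:.3g} vs initial {initial:.3g}); "
                "reduce the learning rate"
            )
        history.append(val)
        if len(history) > window:
            prev = history[-window - 1]
            if abs(prev - val) <= tol * max(abs(prev), 1e-12):
                converged = True
                break
        opt.zero_grad()
        loss.backward()
        opt.step()
    residual = float(chamfer_loss(Tensor(nodes.value[surf_idx]), target_points).value)
    return DeformationFit(
        nodes=nodes.value.copy(),
        residual_chamfer=residual,
        iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# barycentric field interpolation
# ---------------------------------------------------------------------------


class _TetLocator:
    """Uniform spatial hash over tets; cell size = mean edge length."""

    def __init__(self, mesh: VolumeMesh):
        from .mesh_core import extract_edges

        self.mesh = mesh
        edges = extract_edges(mesh)
        lens = np.linalg.norm(
            mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]], axis=1
        )
        self.cell = float(lens.mean()) if lens.size else 1.0
        self.origin = mesh.nodes.min(axis=0)
        self.table: dict[tuple, list[int]] = {}
        verts = mesh.nodes[mesh.tets]
        los = np.floor((verts.min(axis=1) - self.origin) / self.cell).astype(int)
        his = np.floor((verts.max(axis=1) - self.origin) / self.cell).astype(int)
        for t, (lo, hi) in enumerate(zip(los, his)):
            for i in range(lo[0], hi[0] + 1):
                for j in range(lo[1], hi[1] + 1):
                    for k in range(lo[2], hi[2] + 1):
                        self.table.setdefault((i, j, k), []).append(t)

    def locate(self, point: np.ndarray, tol: float = 1e-9):
        """Containing tet index + barycentric coords, or (None, None)."""
        key = tuple(np.floor((point - self.origin) / self.cell).astype(int))
        for t in sorted(self.table.get(key, [])):  # lowest index wins ties
            tet = self.mesh.tets[t]
            v = self.mesh.nodes[tet]
            T = np.column_stack([v[1] - v[0], v[2] - v[0], v[3] - v[0]])
            try:
                lam = np.linalg.solve(T, point - v[0])
            except np.linalg.LinAlgError:
                continue
            if (lam >= -tol).all() and lam.sum() <= 1 + tol:
                bary = np.concatenate([[1 - lam.sum()], lam])
                return t, bary
        return None, None


def interpolate_fields(
    source_mesh: VolumeMesh, source_fields: FieldSet, query_points: np.ndarray
):
    """Barycentric interpolation of nodal fields at arbitrary points.

    Points outside the source mesh fall back to the nearest source node's
    values.  Returns ``(FieldSet at the queries, number of outside points)``.
    """
    if source_mesh.node_count == 0:
        raise ValueError("empty source mesh")
    source_fields.validate(source_mesh)
    query_points = np.asarray(query_points, dtype=np.float64).reshape(-1, 3)
    locator = _TetLocator(source_mesh)
    tree = cKDTree(source_mesh.nodes)
    pressure = np.zeros(query_points.shape[0])
    velocity = np.zeros((query_points.shape[0], 3))
    outside = 0
    for i, q in enumerate(query_points):
        t, bary = locator.locate(q)
        if t is None:
            outside += 1
            j = tree.query(q)[1]
            pressure[i] = source_fields.pressure[j]
            velocity[i] = source_fields.velocity[j]
        else:
            tet = source_mesh.tets[t]
            pressure[i] = bary @ source_fields.pressure[tet]
            velocity[i] = bary @ source_fields.velocity[tet]
    return FieldSet(pressure, velocity), outside
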