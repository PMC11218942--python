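"""Differentiable mesh and flow-field loss terms and their weighted total.

Five families: symmetric Chamfer point losses (volume + surface), edge-length
deviation (volume + surface), per-tet aspect ratio, cap coplanarity, and the
four-channel MAE flow loss on standardized fields.  Every function accepts
plain arrays or autodiff Tensors and returns a Tensor; take ``.value`` for a
number.  The Chamfer reduction defaults to the mean over each set so the term
is independent of node count; ``reduction="sum"`` restores plain summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Tensor, astensor, concatenate, stack
from .mesh_core import VolumeMesh, extract_edges, extract_surface


@dataclass
class LossWeights:
    """Weights lambda1..lambda5 of the combined mesh loss."""

    lambda1: float = 1.0  # point (Chamfer) losses
    lambda2: float = 0.1  # edge-length deviation losses
    lambda3: float = 0.5  # aspect-ratio loss
    lambda4: float = 0.05  # cap-coplanarity loss
    lambda5: float = 30.0  # flow-field MAE loss

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self):
        return {f"lambda{i}": getattr(self, f"lambda{i}") for i in range(1, 6)}


@dataclass
class TopologyCache:
    """Precomputed connectivity shared by every deformation of one template."""

    tets: np.ndarray
    edges: np.ndarray
    surface_nodes: np.ndarray
    surface_edges: np.ndarray
    cap_faces: dict

    @classmethod
    def from_mesh(cls, mesh: VolumeMesh) -> "TopologyCache":
        surf = extract_surface(mesh)
        return cls(
            tets=mesh.tets,
            edges=extract_edges(mesh),
            surface_nodes=surf.node_indices,
            surface_edges=surf.edges,
            cap_faces=mesh.cap_faces,
        )


@dataclass
class LossReport:
    """Per-term loss breakdown per branch plus the weighted total."""

    branches: list = field(default_factory=list)  # list of dicts of floats
    total: float = 0.0

    TERMS = ("point", "point_surface", "edge", "edge_surface", "aspect", "cap", "cfd")

    def as_row(self) -> dict:
        row = {}
        for i, b in enumerate(self.branches, start=1):
            for k, v in b.items():
                row[f"branch{i}_{k}"] = v
        row["total"] = self.total
        return row


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------


def chamfer_loss(P, G, reduction: str = "mean") -> Tensor:
    """Symmetric squared-distance Chamfer loss between two 3-D point sets."""
    P, G = astensor(P), astensor(G)
    if P.value.shape[0] == 0 or G.value.shape[0] == 0:
        raise ValueError("chamfer_loss requires non-empty point sets")
    if P.value.shape[0] * G.value.shape[0] <= 250_000:
        d2 = ((P.value[:, None, :] - G.value[None, :, :]) ** 2).sum(axis=2)
        idx_pg = d2.argmin(axis=1)
        idx_gp = d2.argmin(axis=0)
    else:
        idx_pg = cKDTree(G.value).query(P.value)[1]
        idx_gp = cKDTree(P.value).query(G.value)[1]
    fwd = ((P - G[idx_pg]) ** 2).sum(axis=1)
    bwd = ((P[idx_gp] - G) ** 2).sum(axis=1)
    if reduction == "mean":
        return fwd.mean() + bwd.mean()
    if reduction == "sum":
        return fwd.sum() + bwd.sum()
    raise ValueError(f"unknown reduction {reduction!r}")


def edge_lengths(nodes, edges: np.ndarray) -> Tensor:
    nodes = astensor(nodes)
    diff = nodes[edges[:, 0]] - nodes[edges[:, 1]]
    return ((diff**2).sum(axis=1)) ** 0.5


def edge_deviation_loss(lengths) -> Tensor:
    """Population standard deviation of edge lengths over their mean."""
    lengths = astensor(lengths)
    if lengths.value.shape[0] < 2:
        raise ValueError("edge_deviation_loss requires at least 2 edges")
    if (lengths.value <= 0).any():
        raise ValueError("collapsed (zero-length) edge")
    mu = lengths.mean()
    var = ((lengths - mu) ** 2).mean()
    return var**0.5 / mu


_TET_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def aspect_ratio_loss(mesh: VolumeMesh | None = None, *, nodes=None, tets=None) -> Tensor:
    """Mean over tets of (longest edge / shortest edge); 1 for equilateral."""
    if mesh is not None:
        nodes, tets = mesh.nodes, mesh.tets
    nodes = astensor(nodes)
    pairs = tets[:, _TET_EDGES]  # (M, 6, 2)
    diff = nodes[pairs[..., 0]] - nodes[pairs[..., 1]]  # (M, 6, 3)
    lens = ((diff**2).sum(axis=2)) ** 0.5
    if (lens.value <= 0).any():
        raise ValueError("zero-length edge in a tet")
    return (lens.max(axis=1) / lens.min(axis=1)).mean()


def _unit_face_normals(nodes: Tensor, faces: np.ndarray) -> Tensor:
    a, b, c = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    u, v = b - a, c - a
    nx = u[:, 1] * v[:, 2] - u[:, 2] * v[:, 1]
    ny = u[:, 2] * v[:, 0] - u[:, 0] * v[:, 2]
    nz = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    n = stack([nx, ny, nz], axis=1)
    norm = ((n**2).sum(axis=1, keepdims=True)) ** 0.5
    if (norm.value == 0).any():
        raise ValueError("zero-area cap face")
    return n / norm


def cap_coplanar_loss(mesh: VolumeMesh | None = None, *, nodes=None, cap_faces=None) -> Tensor:
    """Sum over caps of squared deviation of unit face normals from their mean."""
    if mesh is not None:
        nodes, cap_faces = mesh.nodes, mesh.cap_faces
    if not cap_faces:
        raise ValueError("cap_coplanar_loss: no cap faces labelled")
    for cap in ("inlet", "outlet_left", "outlet_right"):
        if cap not in cap_faces or len(cap_faces[cap]) == 0:
            raise ValueError(f"missing cap label {cap!r}")
    nodes = astensor(nodes)
    total = None
    for cap in ("inlet", "outlet_left", "outlet_right"):
        n = _unit_face_normals(nodes, np.asarray(cap_faces[cap]))
        dev = n - n.mean(axis=0, keepdims=True)
        term = (dev**2).sum()
        total = term if total is None else total + term
    return total


def cfd_loss(pred_pressure, pred_velocity, true_pressure, true_velocity) -> Tensor:
    """Sum of per-channel MAEs over the 4 standardized field channels."""
    pp, pv = astensor(pred_pressure), astensor(pred_velocity)
    tp, tv = astensor(true_pressure), astensor(true_velocity)
    if pp.value.shape[0] != tp.value.shape[0] or pv.value.shape != tv.value.shape:
        raise ValueError("field length mismatch in cfd_loss")
    loss = (pp - tp).abs().mean()
    for k in range(3):
        loss = loss + (pv[:, k] - tv[:, k]).abs().mean()
    return loss


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------


def branch_mesh_loss(
    pred_nodes,
    pred_pressure,
    pred_velocity,
    truth_nodes: np.ndarray,
    truth_pressure: np.ndarray,
    truth_velocity: np.ndarray,
    topo: TopologyCache,
    weights: LossWeights,
    truth_surface_nodes: np.ndarray | None = None,
    chamfer_reduction: str = "mean",
):
    """Weighted seven-term mesh loss for one transformation branch.

    Prediction and truth are in point-point correspondence; fields are in
    standardized space.  Returns ``(loss Tensor, dict of float sub-terms)``.
    """
    pred_nodes = astensor(pred_nodes)
    if truth_surface_nodes is None:
        truth_surface_nodes = np.asarray(truth_nodes)[topo.surface_nodes]
    terms: dict[str, Tensor] = {}
    terms["point"] = chamfer_loss(pred_nodes, truth_nodes, chamfer_reduction)
    terms["point_surface"] = chamfer_loss(
        pred_nodes[topo.surface_nodes], truth_surface_nodes, chamfer_reduction
    )
    terms["edge"] = edge_deviation_loss(edge_lengths(pred_nodes, topo.edges))
    terms["edge_surface"] = edge_deviation_loss(
        edge_lengths(pred_nodes, topo.surface_edges)
    )
    terms["aspect"] = aspect_ratio_loss(nodes=pred_nodes, tets=topo.tets)
    terms["cap"] = cap_coplanar_loss(nodes=pred_nodes, cap_faces=topo.cap_faces)
    terms["cfd"] = cfd_loss(
        pred_pressure, pred_velocity, truth_pressure, truth_velocity
    )
    loss = (
        weights.lambda1 * (terms["point"] + terms["point_surface"])
        + weights.lambda2 * (terms["edge"] + terms["edge_surface"])
        + weights.lambda3 * terms["aspect"]
        + weights.lambda4 * terms["cap"]
        + weights.lambda5 * terms["cfd"]
    )
    values = {k: float(v.value) for k, v in terms.items()}
    values["mesh"] = float(loss.value)
    return loss, values


def total_loss(
    branch_predictions,
    truth_nodes: np.ndarray,
    truth_pressure: np.ndarray,
    truth_velocity: np.ndarray,
    topo: TopologyCache,
    weights: LossWeights,
    chamfer_reduction: str = "mean",
):
    """Sum of the mesh losses of the three transformation branches.

    ``branch_predictions`` is a sequence of exactly three
    ``(nodes, pressure, velocity)`` triples (Tensors or arrays).
    Returns ``(total Tensor, LossReport)``.
    """
    if len(branch_predictions) != 3:
        raise ValueError("total_loss expects exactly 3 branch predictions")
    truth_surface = np.asarray(truth_nodes)[topo.surface_nodes]
    report = LossReport()
    total = None
    for nodes, p, v in branch_predictions:
        loss, values = branch_mesh_loss(
            nodes,
            p,
            v,
            truth_nodes,
            truth_pressure,
            truth_velocity,
            topo,
            weights,
            truth_surface_nodes=truth_surface,
            chamfer_reduction=chamfer_reduction,
        )
        report.branches.append(values)
        total = loss if total is None else total + loss
    report.total = float(total.value)
    return total, report
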