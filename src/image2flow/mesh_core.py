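"""Tetrahedral volume-mesh data structures and geometry operators.

Coordinates live in millimetres in the image frame: voxel ``(i, j, k)`` has
its center at ``origin + spacing * (i, j, k)`` (0-based).  Edges and faces are
canonicalized by sorting node indices and all set-valued outputs are returned
sorted, so every operator is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

CAP_IDS = {"inlet": 1, "outlet_left": 2, "outlet_right": 3}
CAP_NAMES = {v: k for k, v in CAP_IDS.items()}

# canonical vertex order of the 4 triangular faces of a tet (i0,i1,i2,i3)
_TET_FACES = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
_TET_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class VolumeMesh:
    """Tetrahedral mesh with labelled inlet/outlet caps.

    nodes: (N, 3) float coordinates in mm; tets: (M, 4) int node indices;
    cap_faces: cap name -> (F, 3) boundary triangles (node-index triples).
    """

    nodes: np.ndarray
    tets: np.ndarray
    cap_faces: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.float64).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.cap_faces = {
            k: np.asarray(v, dtype=np.int64).reshape(-1, 3)
            for k, v in self.cap_faces.items()
        }

    @property
    def node_count(self) -> int:
        return self.nodes.shape[0]

    def copy(self) -> "VolumeMesh":
        return VolumeMesh(
            self.nodes.copy(),
            self.tets.copy(),
            {k: v.copy() for k, v in self.cap_faces.items()},
        )

    def with_nodes(self, nodes: np.ndarray) -> "VolumeMesh":
        """Same topology, new coordinates."""
        return VolumeMesh(np.asarray(nodes), self.tets, self.cap_faces)

    def validate(self, check_caps: bool = True, strict_volumes: bool = True) -> None:
        n = self.node_count
        if not np.isfinite(self.nodes).all():
            raise MeshValidationError("non-finite node coordinates")
        if self.tets.size:
            if self.tets.min() < 0 or self.tets.max() >= n:
                raise MeshValidationError("tet index out of range")
            srt = np.sort(self.tets, axis=1)
            if (np.diff(srt, axis=1) == 0).any():
                bad = int(np.where((np.diff(srt, axis=1) == 0).any(axis=1))[0][0])
                raise MeshValidationError(f"degenerate tet {bad}: repeated index")
            vols = tet_volumes(self)
            if (vols <= 0).any():
                bad = int(np.argmin(vols))
                msg = f"tet {bad} has non-positive volume {vols[bad]:.3g}"
                if strict_volumes:
                    raise MeshValidationError(msg)
                warnings.warn(msg, stacklevel=2)
        if check_caps and self.cap_faces:
            boundary = {
                tuple(tri) for tri in np.sort(extract_surface(self).triangles, axis=1)
            }
            for cap, faces in self.cap_faces.items():
                if faces.shape[0] < 1:
                    raise MeshValidationError(f"cap {cap!r} has no faces")
                for tri in np.sort(faces, axis=1):
                    if tuple(tri) not in boundary:
                        raise MeshValidationError(
                            f"cap {cap!r} face {tuple(tri)} is not a boundary triangle"
                        )


@dataclass
class FieldSet:
    """Per-node pressure (Pa, gauge) and velocity (m/s) fields."""

    pressure: np.ndarray
    velocity: np.ndarray

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=np.float64).reshape(-1)
        self.velocity = np.asarray(self.velocity, dtype=np.float64).reshape(-1, 3)

    def validate(self, mesh: VolumeMesh | None = None) -> None:
        if self.velocity.shape[0] != self.pressure.shape[0]:
            raise MeshValidationError("pressure/velocity length mismatch")
        if mesh is not None and self.pressure.shape[0] != mesh.node_count:
            raise MeshValidationError("field length does not match mesh node count")
        if not (np.isfinite(self.pressure).all() and np.isfinite(self.velocity).all()):
            raise MeshValidationError("non-finite field values")

    def copy(self) -> "FieldSet":
        return FieldSet(self.pressure.copy(), self.velocity.copy())


@dataclass
class ImageVolume:
    """Cubic grayscale voxel grid."""

    voxels: np.ndarray
    spacing: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.voxels.ndim != 3 or len(set(self.voxels.shape)) != 1:
            raise MeshValidationError("image volume must be cubic (D, D, D)")
        if self.spacing <= 0:
            raise MeshValidationError("spacing must be positive")

    @property
    def size(self) -> int:
        return self.voxels.shape[0]

    def to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """mm coordinates -> continuous voxel indices."""
        return (np.asarray(points_mm, dtype=np.float64) - self.origin) / self.spacing


@dataclass
class SurfaceView:
    """Boundary surface of a volume mesh (indices refer to the parent mesh)."""

    node_indices: np.ndarray  # sorted unique surface node ids
    triangles: np.ndarray  # (F, 3) outward-oriented boundary triangles
    edges: np.ndarray  # (E, 2) sorted unique surface edges


# ---------------------------------------------------------------------------
# geometry operators
# ---------------------------------------------------------------------------


def tet_volumes(mesh: VolumeMesh) -> np.ndarray:
    """Signed volume of every tet (positive for consistent orientation)."""
    p = mesh.nodes[mesh.tets]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def extract_edges(mesh: VolumeMesh) -> np.ndarray:
    """All unique undirected edges, one (min, max) row each, lexsorted."""
    if mesh.tets.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    srt = np.sort(mesh.tets, axis=1)
    if (np.diff(srt, axis=1) == 0).any():
        bad = int(np.where((np.diff(srt, axis=1) == 0).any(axis=1))[0][0])
        raise MeshValidationError(f"degenerate tet {bad}: repeated index")
    pairs = mesh.tets[:, _TET_EDGES].reshape(-1, 2)
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def extract_surface(mesh: VolumeMesh) -> SurfaceView:
    """Boundary triangles (owned by exactly one tet), outward-oriented."""
    ntet = mesh.tets.shape[0]
    faces = mesh.tets[:, _TET_FACES].reshape(-1, 3)  # 4 faces per tet, tet order
    keys = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    if (counts > 2).any():
        bad = np.where(counts[inverse] > 2)[0][0]
        raise MeshValidationError(
            f"non-manifold face {tuple(keys[bad])} shared by more than two tets"
        )
    boundary_rows = np.where(counts[inverse] == 1)[0]
    tris = []
    for row in boundary_rows:
        tet = mesh.tets[row // 4]
        tri = faces[row]
        rest = [v for v in tet if v not in tri][0]
        a, b, c = mesh.nodes[tri]
        normal = np.cross(b - a, c - a)
        # outward: normal points away from the tet's opposite vertex
        if normal @ (mesh.nodes[rest] - a) > 0:
            tri = tri[[0, 2, 1]]
        tris.append(tri)
    tris = (
        np.asarray(tris, dtype=np.int64)
        if tris
        else np.empty((0, 3), dtype=np.int64)
    )
    # deterministic ordering by canonical key
    if tris.shape[0]:
        order = np.lexsort(np.sort(tris, axis=1).T[::-1])
        tris = tris[order]
        edges = np.unique(
            np.sort(tris[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1), axis=0
        )
        node_idx = np.unique(tris)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        node_idx = np.empty(0, dtype=np.int64)
    return SurfaceView(node_idx, tris, edges)


def face_normals(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit normals of triangles, right-hand rule on the vertex order."""
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    a, b, c = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    n = np.cross(b - a, c - a)
    norms = np.linalg.norm(n, axis=1)
    if (norms < 1e-300).any():
        raise MeshValidationError("zero-area triangle in face_normals")
    return n / norms[:, None]


def scaled_laplacian(mesh: VolumeMesh) -> sp.csr_matrix:
    """Rescaled symmetric-normalized Laplacian L_tilde = 2L/lambda_max - I.

    lambda_max is fixed at 2 (the upper bound for normalized Laplacians), so
    L_tilde = -D^{-1/2} A D^{-1/2}; isolated nodes are treated as self-only
    (diagonal entry -1) with a warning.
    """
    return laplacian_from_edges(extract_edges(mesh), mesh.node_count)


def laplacian_from_edges(edges: np.ndarray, n: int) -> sp.csr_matrix:
    """Rescaled normalized Laplacian of an explicit undirected edge list."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sp.coo_matrix(
        (np.ones(rows.shape[0]), (rows, cols)), shape=(n, n)
    ).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated node(s): treated as self-only",
            stacklevel=2,
        )
    dinv = np.zeros(n)
    dinv[~isolated] = 1.0 / np.sqrt(deg[~isolated])
    D = sp.diags(dinv)
    S = D @ adj @ D
    if isolated.any():
        S = S + sp.diags(isolated.astype(np.float64))
    return (-S).tocsr()


def _point_in_tets_mask(
    points: np.ndarray, verts: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Barycentric inside test of points against ONE tet's 4x3 vertices."""
    T = np.column_stack([verts[1] - verts[0], verts[2] - verts[0], verts[3] - verts[0]])
    try:
        Tinv = np.linalg.inv(T)
    except np.linalg.LinAlgError:
        return np.zeros(points.shape[0], dtype=bool)
    bary = (points - verts[0]) @ Tinv.T
    return (bary >= -tol).all(axis=1) & (bary.sum(axis=1) <= 1 + tol)


def voxelize(mesh: VolumeMesh, grid: ImageVolume) -> np.ndarray:
    """Binary mask: voxel center is 1 iff inside any tet (boundary inclusive)."""
    d = grid.size
    mask = np.zeros((d, d, d), dtype=np.uint8)
    if mesh.tets.size == 0 or np.abs(tet_volumes(mesh)).sum() == 0:
        warnings.warn("voxelize: zero-volume mesh, returning empty mask", stacklevel=2)
        return mask
    lo_all = mesh.nodes.min(axis=0)
    hi_all = mesh.nodes.max(axis=0)
    gmin, gmax = grid.origin, grid.origin + grid.spacing * (d - 1)
    if (lo_all < gmin).any() or (hi_all > gmax).any():
        warnings.warn("voxelize: mesh extends outside grid, clipping", stacklevel=2)
    for tet in mesh.tets:
        verts = mesh.nodes[tet]
        lo = np.floor(grid.to_index(verts.min(axis=0))).astype(int)
        hi = np.ceil(grid.to_index(verts.max(axis=0))).astype(int)
        lo = np.clip(lo, 0, d - 1)
        hi = np.clip(hi, 0, d - 1)
        if (lo > hi).any():
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0] + 1),
            np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1),
            indexing="ij",
        )
        idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        centers = grid.origin + grid.spacing * idx
        inside = _point_in_tets_mask(centers, verts)
        sel = idx[inside]
        mask[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    return mask


def sample_image_features(
    feature_grid: np.ndarray,
    points_mm: np.ndarray,
    spacing: float = 1.0,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Trilinear sampling of a (C, D, H, W) feature grid at mm points.

    Out-of-bounds points are clamped to the boundary.  Exact on trilinear
    fields; linear in the feature values.
    """
    from .autodiff import Tensor, trilinear_sample

    points_mm = np.asarray(points_mm, dtype=np.float64)
    if not np.isfinite(points_mm).all():
        raise ValueError("non-finite point coordinates")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=np.float64)
    idx = (points_mm - origin) / spacing
    grid = np.asarray(feature_grid, dtype=np.float64)
    if grid.ndim == 3:
        grid = grid[None]
    return trilinear_sample(grid, Tensor(idx)).value
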