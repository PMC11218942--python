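"""Seeded synthetic bifurcating-vessel data: correspondent tetrahedral meshes,
analytic steady laminar flow fields, and pseudo-MRI volumes.

The mesh is a structured lattice — (segment, station, ring, sector) — so every
anatomy drawn from the same resolution shares an identical ``tets`` array and
node correspondence by construction.  Prisms between consecutive station disks
are split into tets with the min-vertex-diagonal rule, which guarantees
conforming faces between neighbours.  Each branch root station duplicates the
trunk's final disk geometry with its own node ids so that every face stays
manifold (owned by at most two tets).

The flow stand-in is Hagen-Poiseuille per segment: the inlet flow splits
between the branches in proportion to their conductances r^4/L, pressure drops
linearly along each centerline with outlet gauge pressure exactly 0, and the
nodal velocity is parallel to the local centerline tangent with a parabolic
no-slip profile.  Everything is linear in the inlet velocity.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .mesh_core import FieldSet, ImageVolume, VolumeMesh, tet_volumes, voxelize
from . import mesh_io

BLOOD_VISCOSITY = 0.04  # Pa*s
BLOOD_DENSITY = 1060.0  # kg/m^3


# ---------------------------------------------------------------------------
# parameters and resolution
# ---------------------------------------------------------------------------


@dataclass
class Resolution:
    """Lattice resolution: rings x sectors per disk, stations per segment."""

    rings: int = 3
    sectors: int = 8
    stations_trunk: int = 8
    stations_branch: int = 8

    def __post_init__(self):
        if self.rings < 2 or self.sectors < 6:
            raise ValueError("need >= 2 rings and >= 6 sectors")
        if self.stations_trunk < 4 or self.stations_branch < 4:
            raise ValueError("need >= 4 stations per segment")

    @property
    def nodes_per_disk(self) -> int:
        return 1 + self.rings * self.sectors

    @property
    def disk_count(self) -> int:
        return self.stations_trunk + 2 * self.stations_branch

    @property
    def node_count(self) -> int:
        return self.disk_count * self.nodes_per_disk

    @property
    def tris_per_disk(self) -> int:
        return self.sectors * (2 * self.rings - 1)

    @property
    def tet_count(self) -> int:
        slabs = (self.stations_trunk - 1) + 2 * (self.stations_branch - 1)
        return 3 * self.tris_per_disk * slabs


@dataclass
class AnatomyParams:
    """Y-vessel anatomy: a trunk that bifurcates into two branches (mm, deg)."""

    trunk_radius: float = 4.0
    trunk_length: float = 12.0
    branch_radii: np.ndarray = field(default_factory=lambda: np.array([3.0, 3.0]))
    branch_lengths: np.ndarray = field(default_factory=lambda: np.array([10.0, 10.0]))
    half_angles: np.ndarray = field(default_factory=lambda: np.array([35.0, 35.0]))
    curvature_amp: float = 0.3
    bumpiness: float = 0.04
    plane_twist: float = 0.0  # rotation of the bifurcation plane about z (deg)
    bump_phases: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.branch_radii = np.asarray(self.branch_radii, dtype=np.float64)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=np.float64)
        self.half_angles = np.asarray(self.half_angles, dtype=np.float64)
        self.bump_phases = np.asarray(self.bump_phases, dtype=np.float64)
        if self.trunk_radius <= 0 or (self.branch_radii <= 0).any():
            raise ValueError("radii must be positive")
        if self.trunk_length <= 0 or (self.branch_lengths <= 0).any():
            raise ValueError("lengths must be positive")
        if self.bumpiness >= 0.5:
            raise ValueError("bumpiness must be < 0.5")

    def to_dict(self) -> dict:
        return {
            "trunk_radius": self.trunk_radius,
            "trunk_length": self.trunk_length,
            "branch_radii": self.branch_radii.tolist(),
            "branch_lengths": self.branch_lengths.tolist(),
            "half_angles": self.half_angles.tolist(),
            "curvature_amp": self.curvature_amp,
            "bumpiness": self.bumpiness,
            "plane_twist": self.plane_twist,
            "bump_phases": self.bump_phases.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnatomyParams":
        return cls(
            trunk_radius=d["trunk_radius"],
            trunk_length=d["trunk_length"],
            branch_radii=np.array(d["branch_radii"]),
            branch_lengths=np.array(d["branch_lengths"]),
            half_angles=np.array(d["half_angles"]),
            curvature_amp=d["curvature_amp"],
            bumpiness=d["bumpiness"],
            plane_twist=d.get("plane_twist", 0.0),
            bump_phases=np.array(d.get("bump_phases", [0.0, 0.0])),
        )


#: per-parameter uniform sampling ranges for the small-scale population
SMALL_RANGES = {
    "trunk_radius": (3.4, 4.6),
    "trunk_length": (10.0, 13.0),
    "branch_radius": (2.4, 3.4),
    "branch_length": (8.0, 11.0),
    "half_angle": (28.0, 42.0),
    "curvature_amp": (0.0, 0.7),
    "bumpiness": (0.0, 0.08),
    "plane_twist": (-30.0, 30.0),
}

FULL_RANGES = {
    "trunk_radius": (12.0, 16.0),
    "trunk_length": (36.0, 46.0),
    "branch_radius": (8.0, 12.0),
    "branch_length": (30.0, 40.0),
    "half_angle": (28.0, 42.0),
    "curvature_amp": (0.0, 2.5),
    "bumpiness": (0.0, 0.08),
    "plane_twist": (-30.0, 30.0),
}


def sample_params(rng: np.random.Generator, ranges: dict = SMALL_RANGES) -> AnatomyParams:
    u = lambda key: rng.uniform(*ranges[key])
    return AnatomyParams(
        trunk_radius=u("trunk_radius"),
        trunk_length=u("trunk_length"),
        branch_radii=np.array([u("branch_radius"), u("branch_radius")]),
        branch_lengths=np.array([u("branch_length"), u("branch_length")]),
        half_angles=np.array([u("half_angle"), u("half_angle")]),
        curvature_amp=u("curvature_amp"),
        bumpiness=u("bumpiness"),
        plane_twist=u("plane_twist"),
        bump_phases=rng.uniform(0, 2 * np.pi, size=2),
    )


def average_params(ranges: dict = SMALL_RANGES) -> AnatomyParams:
    """Population-mean anatomy used to build the network's template mesh."""
    mid = lambda key: 0.5 * (ranges[key][0] + ranges[key][1])
    return AnatomyParams(
        trunk_radius=mid("trunk_radius"),
        trunk_length=mid("trunk_length"),
        branch_radii=np.array([mid("branch_radius")] * 2),
        branch_lengths=np.array([mid("branch_length")] * 2),
        half_angles=np.array([mid("half_angle")] * 2),
        curvature_amp=0.0,
        bumpiness=0.0,
    )


# ---------------------------------------------------------------------------
# structured lattice mesh
# ---------------------------------------------------------------------------


@dataclass
class Lattice:
    """Per-node lattice bookkeeping for a built mesh.

    segment: 0 trunk, 1 left branch, 2 right branch (junction disk -> trunk);
    radial_frac: ring / rings in [0, 1] (1 at the wall);
    arc_mm: arclength from the segment start along the centerline;
    tangent: unit local centerline direction (flow direction);
    disks[segment]: list of node-id arrays, one per station.
    """

    segment: np.ndarray
    radial_frac: np.ndarray
    arc_mm: np.ndarray
    tangent: np.ndarray
    disks: list
    segment_lengths: np.ndarray  # (3,) mm


def _disk_triangles(rings: int, sectors: int) -> np.ndarray:
    """Triangulation of the canonical disk, in local disk-node indices."""
    tris = []
    idx = lambda r, s: 1 + (r - 1) * sectors + (s % sectors)
    for s in range(sectors):
        tris.append([0, idx(1, s), idx(1, s + 1)])
    for r in range(1, rings):
        for s in range(sectors):
            a, b = idx(r, s), idx(r, s + 1)
            c, d = idx(r + 1, s), idx(r + 1, s + 1)
            tris.append([a, c, d])
            tris.append([a, d, b])
    return np.asarray(tris, dtype=np.int64)


def _split_wedge(bot, top):
    """Min-vertex-rule split of a prism (bot triangle under top) into 3 tets."""
    v = [bot[0], bot[1], bot[2], top[0], top[1], top[2]]
    kmin = int(np.argmin(v))
    if kmin >= 3:  # smallest vertex in the top: flip the prism
        v = [v[3], v[4], v[5], v[0], v[1], v[2]]
        kmin -= 3
    # rotate so the smallest vertex is at position 0
    rot = [(kmin + i) % 3 for i in range(3)]
    v = [v[rot[0]], v[rot[1]], v[rot[2]], v[rot[0] + 3], v[rot[1] + 3], v[rot[2] + 3]]
    if min(v[1], v[5]) < min(v[2], v[4]):
        return [
            (v[0], v[1], v[2], v[5]),
            (v[0], v[1], v[5], v[4]),
            (v[0], v[4], v[5], v[3]),
        ]
    return [
        (v[0], v[1], v[2], v[4]),
        (v[0], v[4], v[2], v[5]),
        (v[0], v[4], v[5], v[3]),
    ]


def _turn_stations(alpha_deg: float, step: float, radius: float, n_stations: int) -> int:
    """Stations over which a branch builds up its tilt.

    Limits the per-station disk rotation so the disk rim never sweeps past the
    axial step (r * tan(d_alpha) <= step / 2), which would invert cells.
    """
    max_per_station = np.rad2deg(np.arctan(step / (2.0 * radius)))
    need = int(np.ceil(abs(alpha_deg) / max(max_per_station, 1e-6)))
    if need > n_stations - 1:
        raise ValueError(
            f"bifurcation half-angle {alpha_deg:.1f} deg incompatible with "
            f"trunk radius {radius:.2f} mm at {n_stations} branch stations"
        )
    return int(np.clip(need, min(4, n_stations - 1), n_stations - 1))


def _transport_frame(u_prev: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    u = u_prev - (u_prev @ t_new) * t_new
    n = np.linalg.norm(u)
    if n < 1e-12:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ref @ t_new) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ t_new) * t_new
        n = np.linalg.norm(u)
    return u / n


def build_structured_tube_mesh(
    params: AnatomyParams,
    resolution: Resolution = Resolution(),
    center_xy: np.ndarray | None = None,
    base_z: float = 4.0,
):
    """Build the Y-vessel lattice mesh -> (VolumeMesh, Lattice).

    Identical connectivity for any params at a fixed resolution; the two
    branches are welded onto the trunk's final station disk.  Raises when the
    drawn geometry inverts lattice cells (half-angles too small/large for the
    radii at this resolution).
    """
    res = resolution
    R, S = res.rings, res.sectors
    npd = res.nodes_per_disk
    center_xy = (
        np.array([16.0, 16.0]) if center_xy is None else np.asarray(center_xy)
    )

    # ---- centerlines: points and tangents per station -----------------------
    phi = np.deg2rad(params.plane_twist)
    e_plane = np.array([np.cos(phi), np.sin(phi), 0.0])  # bifurcation plane

    def trunk_centers():
        n = res.stations_trunk
        pts = np.zeros((n, 3))
        zs = np.linspace(0.0, params.trunk_length, n)
        pts[:, 2] = base_z + zs
        pts[:, :2] = center_xy
        bow = params.curvature_amp * np.sin(np.pi * zs / params.trunk_length)
        pts[:, 0] += bow * e_plane[0]
        pts[:, 1] += bow * e_plane[1]
        return pts

    def branch_centers(i, start, t_end):
        """Branch centerline turning away from the trunk's END tangent, so
        the relative per-station tilt stays within the inversion-safe limit
        even when trunk curvature tilts the junction disk."""
        n = res.stations_branch
        step = params.branch_lengths[i] / (n - 1)
        alpha = np.deg2rad(params.half_angles[i]) * (1 if i == 0 else -1)
        turn = _turn_stations(params.half_angles[i], step, params.trunk_radius, n)
        axis = np.cross(t_end, e_plane)
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            axis = np.array([0.0, 1.0, 0.0])
        else:
            axis = axis / nrm
        pts = [start]
        tangents = []
        for k in range(n - 1):
            a = alpha * min((k + 1) / turn, 1.0)
            # Rodrigues rotation of the trunk end tangent about the axis
            t = (
                t_end * np.cos(a)
                + np.cross(axis, t_end) * np.sin(a)
                + axis * (axis @ t_end) * (1 - np.cos(a))
            )
            tangents.append(t)
            pts.append(pts[-1] + step * t)
        return np.asarray(pts), np.asarray(tangents)

    tc = trunk_centers()
    t_end = tc[-1] - tc[-2]
    t_end = t_end / np.linalg.norm(t_end)
    bc0, _ = branch_centers(0, tc[-1], t_end)
    bc1, _ = branch_centers(1, tc[-1], t_end)
    seg_centers = [tc, bc0, bc1]

    def station_tangents(centers):
        t = np.gradient(centers, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    # ---- per-disk frames and radii ------------------------------------------
    def bump(seg, u, theta):
        if params.bumpiness == 0:
            return 0.0
        ph = params.bump_phases
        envelope = np.sin(np.pi * u)
        return (
            params.bumpiness
            * envelope
            * (np.cos(2 * theta + ph[0]) + 0.5 * np.cos(3 * theta + ph[1] + seg))
        )

    nodes = np.zeros((res.node_count, 3))
    ref_nodes = np.zeros((res.node_count, 3))  # canonical straight lattice
    seg_of = np.zeros(res.node_count, dtype=np.int64)
    rad_frac = np.zeros(res.node_count)
    arc = np.zeros(res.node_count)
    tang = np.zeros((res.node_count, 3))
    disks: list[list[np.ndarray]] = [[], [], []]

    theta = 2 * np.pi * np.arange(S) / S
    next_node = 0

    def fill_disk(ids, seg, center, t_hat, u_hat, radius, u_frac, arc_mm, level):
        nonlocal nodes
        v_hat = np.cross(t_hat, u_hat)
        nodes[ids[0]] = center
        ref_center = np.array([10.0 * seg, 0.0, float(level)])
        ref_nodes[ids[0]] = ref_center
        for r in range(1, R + 1):
            for s in range(S):
                rho = (r / R) * radius * (1.0 + bump(seg, u_frac, theta[s]))
                nodes[ids[1 + (r - 1) * S + s]] = center + rho * (
                    np.cos(theta[s]) * u_hat + np.sin(theta[s]) * v_hat
                )
                ref_nodes[ids[1 + (r - 1) * S + s]] = ref_center + (r / R) * np.array(
                    [np.cos(theta[s]), np.sin(theta[s]), 0.0]
                )
        seg_of[ids] = seg
        arc[ids] = arc_mm
        tang[ids] = t_hat
        for r in range(R + 1):
            lo = 0 if r == 0 else 1 + (r - 1) * S
            hi = 1 if r == 0 else 1 + r * S
            rad_frac[ids[lo:hi]] = r / R

    # trunk
    t_tan = station_tangents(tc)
    u_hat = _transport_frame(np.array([1.0, 0.0, 0.0]), t_tan[0])
    arcs_t = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(tc, axis=0), axis=1))])
    for k in range(res.stations_trunk):
        ids = np.arange(next_node, next_node + npd)
        next_node += npd
        u_hat = _transport_frame(u_hat, t_tan[k])
        fill_disk(
            ids, 0, tc[k], t_tan[k], u_hat,
            params.trunk_radius, k / (res.stations_trunk - 1), arcs_t[k], k,
        )
        disks[0].append(ids)
    junction_u = u_hat

    # branches: station 0 duplicates the junction disk geometry with its own
    # node ids, keeping every boundary face owned by at most two tets
    for i, centers in enumerate([bc0, bc1], start=1):
        b_tan = station_tangents(centers)
        arcs_b = np.concatenate(
            [[0], np.cumsum(np.linalg.norm(np.diff(centers, axis=0), axis=1))]
        )
        root_ids = np.arange(next_node, next_node + npd)
        next_node += npd
        nodes[root_ids] = nodes[disks[0][-1]]
        ref_center = np.array([10.0 * i, 0.0, 0.0])
        ref_nodes[root_ids[0]] = ref_center
        for r in range(1, R + 1):
            sel = root_ids[1 + (r - 1) * S : 1 + r * S]
            ref_nodes[sel] = ref_center + (r / R) * np.column_stack(
                [np.cos(theta), np.sin(theta), np.zeros(S)]
            )
        seg_of[root_ids] = i
        arc[root_ids] = 0.0
        tang[root_ids] = b_tan[0]
        rad_frac[root_ids] = rad_frac[disks[0][-1]]
        disks[i].append(root_ids)
        u_hat = junction_u
        r0, r1 = params.trunk_radius, params.branch_radii[i - 1]
        turn = _turn_stations(
            params.half_angles[i - 1],
            params.branch_lengths[i - 1] / (res.stations_branch - 1),
            r0,
            res.stations_branch,
        )
        for k in range(1, res.stations_branch):
            ids = np.arange(next_node, next_node + npd)
            next_node += npd
            u_hat = _transport_frame(u_hat, b_tan[k])
            radius = r0 + (r1 - r0) * min(k / turn, 1.0)
            fill_disk(
                ids, i, centers[k], b_tan[k], u_hat,
                radius, k / (res.stations_branch - 1), arcs_b[k], k,
            )
            disks[i].append(ids)

    # ---- tets ---------------------------------------------------------------
    disk_tris = _disk_triangles(R, S)
    tets = []
    for seg_disks in disks:
        for bot_ids, top_ids in zip(seg_disks[:-1], seg_disks[1:]):
            for tri in disk_tris:
                tets.extend(_split_wedge(bot_ids[tri], top_ids[tri]))
    tets = np.asarray(tets, dtype=np.int64)

    # orient each tet by its sign on the canonical straight lattice (vertex
    # permutation preserves face conformity); a negative volume on the real
    # geometry afterwards is a genuine inversion, not a convention issue
    ref_vols = tet_volumes(VolumeMesh(ref_nodes, tets))
    flip = ref_vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    mesh = VolumeMesh(nodes, tets)
    vols = tet_volumes(mesh)
    if (vols <= 1e-12).any():
        raise ValueError(
            "degenerate/inverted lattice cells for params "
            f"{params.to_dict()} — bifurcation angles incompatible with radii "
            "at this resolution"
        )

    # ---- caps ---------------------------------------------------------------
    def disk_faces(ids):
        return ids[disk_tris]

    mesh.cap_faces = {
        "inlet": disk_faces(disks[0][0]),
        "outlet_left": disk_faces(disks[1][-1]),
        "outlet_right": disk_faces(disks[2][-1]),
    }
    lattice = Lattice(
        segment=seg_of,
        radial_frac=rad_frac,
        arc_mm=arc,
        tangent=tang,
        disks=disks,
        segment_lengths=np.array(
            [arc[disks[0][-1][0]], arc[disks[1][-1][0]], arc[disks[2][-1][0]]]
        ),
    )
    return mesh, lattice


def build_tube_mesh(
    radius: float,
    length: float,
    rings: int = 3,
    sectors: int = 12,
    stations: int = 10,
    origin: np.ndarray | None = None,
) -> VolumeMesh:
    """Straight axis-aligned (+z) cylinder mesh; handy for analytic oracles."""
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=np.float64)
    npd = 1 + rings * sectors
    theta = 2 * np.pi * np.arange(sectors) / sectors
    nodes = np.zeros((stations * npd, 3))
    disks = []
    for k in range(stations):
        ids = np.arange(k * npd, (k + 1) * npd)
        z = origin[2] + length * k / (stations - 1)
        nodes[ids[0]] = [origin[0], origin[1], z]
        for r in range(1, rings + 1):
            rho = radius * r / rings
            sel = ids[1 + (r - 1) * sectors : 1 + r * sectors]
            nodes[sel, 0] = origin[0] + rho * np.cos(theta)
            nodes[sel, 1] = origin[1] + rho * np.sin(theta)
            nodes[sel, 2] = z
        disks.append(ids)
    disk_tris = _disk_triangles(rings, sectors)
    tets = []
    for bot, top in zip(disks[:-1], disks[1:]):
        for tri in disk_tris:
            tets.extend(_split_wedge(bot[tri], top[tri]))
    tets = np.asarray(tets, dtype=np.int64)
    mesh = VolumeMesh(nodes, tets)
    vols = tet_volumes(mesh)
    tets[vols < 0] = tets[vols < 0][:, [0, 1, 3, 2]]
    return VolumeMesh(nodes, tets)


# ---------------------------------------------------------------------------
# analytic flow
# ---------------------------------------------------------------------------


def segment_pressure_drop(
    radius_mm: float, length_mm: float, flow_m3s: float, viscosity: float = BLOOD_VISCOSITY
) -> float:
    """Hagen-Poiseuille pressure drop 8*mu*L*Q / (pi*r^4) in Pa (SI inside)."""
    r = radius_mm * 1e-3
    L = length_mm * 1e-3
    return 8.0 * viscosity * L * flow_m3s / (np.pi * r**4)


def analytic_flow(
    mesh: VolumeMesh,
    lattice: Lattice,
    params: AnatomyParams,
    inlet_velocity: float,
    viscosity: float = BLOOD_VISCOSITY,
    density: float = BLOOD_DENSITY,
) -> FieldSet:
    """Steady laminar Poiseuille fields at every node of the lattice mesh.

    Inlet flow Q = v_in * pi * r_trunk^2 splits between the branches in
    proportion to r^4/L; outlet gauge pressure is exactly 0 and pressure
    accumulates linearly upstream; velocity is tangent-aligned with profile
    v(rho) = 2 * v_mean * (1 - rho^2).  ``density`` is carried for interface
    completeness (the viscous toy physics does not use it).
    """
    if inlet_velocity <= 0:
        raise ValueError("inlet velocity must be positive")
    del density
    r_t = params.trunk_radius * 1e-3
    q_in = inlet_velocity * np.pi * r_t**2
    cond = (params.branch_radii * 1e-3) ** 4 / (params.branch_lengths * 1e-3)
    q_branch = q_in * cond / cond.sum()
    dp_branch = segment_pressure_drop(
        params.branch_radii[0], params.branch_lengths[0], q_branch[0], viscosity
    )
    dp_trunk = segment_pressure_drop(
        params.trunk_radius, params.trunk_length, q_in, viscosity
    )
    p_junction = dp_branch  # both branches drop the same by construction
    seg_radius = np.array(
        [params.trunk_radius, params.branch_radii[0], params.branch_radii[1]]
    ) * 1e-3
    seg_q = np.array([q_in, q_branch[0], q_branch[1]])
    seg_vmean = seg_q / (np.pi * seg_radius**2)
    seg_len = lattice.segment_lengths

    pressure = np.zeros(mesh.node_count)
    velocity = np.zeros((mesh.node_count, 3))
    for seg in range(3):
        sel = lattice.segment == seg
        frac = lattice.arc_mm[sel] / seg_len[seg]
        if seg == 0:
            pressure[sel] = p_junction + dp_trunk * (1.0 - frac)
        else:
            pressure[sel] = p_junction * (1.0 - frac)
        mag = 2.0 * seg_vmean[seg] * (1.0 - lattice.radial_frac[sel] ** 2)
        velocity[sel] = mag[:, None] * lattice.tangent[sel]
    # outlet gauge pressure is exactly 0 by definition
    pressure[lattice.disks[1][-1]] = 0.0
    pressure[lattice.disks[2][-1]] = 0.0
    return FieldSet(pressure, velocity)


def fit_anatomy_params(
    mesh: VolumeMesh, lattice: Lattice, base: AnatomyParams
) -> AnatomyParams:
    """Least-squares anatomy estimate from a (possibly deformed) lattice mesh.

    Radii come from mean wall-ring distance to the station centroid, lengths
    from the centroid path arclength; used as the desk-scale stand-in for
    running conventional flow computation on a predicted geometry.
    """
    radii = np.zeros(3)
    lengths = np.zeros(3)
    angles = np.zeros(2)
    trunk_dir = None
    for seg in range(3):
        centers = np.array([mesh.nodes[ids].mean(axis=0) for ids in lattice.disks[seg]])
        lengths[seg] = np.linalg.norm(np.diff(centers, axis=0), axis=1).sum()
        wall_d = []
        n_stations = len(lattice.disks[seg])
        if seg > 0:
            skip = _turn_stations(
                base.half_angles[seg - 1],
                base.branch_lengths[seg - 1] / (n_stations - 1),
                base.trunk_radius,
                n_stations,
            )
        for k, ids in enumerate(lattice.disks[seg]):
            if seg > 0 and k < min(skip, n_stations - 2):
                continue  # skip the radius-transition region near the junction
            wall = ids[lattice.radial_frac[ids] > 0.999]
            wall_d.append(
                np.linalg.norm(mesh.nodes[wall] - centers[k], axis=1).mean()
            )
        radii[seg] = np.mean(wall_d)
        direction = centers[-1] - centers[0]
        direction = direction / np.linalg.norm(direction)
        if seg == 0:
            trunk_dir = direction
        else:
            angles[seg - 1] = np.rad2deg(
                np.arccos(np.clip(direction @ trunk_dir, -1, 1))
            )
    return replace(
        base,
        trunk_radius=float(radii[0]),
        trunk_length=float(lengths[0]),
        branch_radii=radii[1:].copy(),
        branch_lengths=lengths[1:].copy(),
        half_angles=angles,
    )


def flow_from_geometry(
    mesh: VolumeMesh,
    lattice: Lattice,
    base_params: AnatomyParams,
    inlet_velocity: float,
    viscosity: float = BLOOD_VISCOSITY,
) -> tuple[FieldSet, AnatomyParams]:
    """Fit anatomy params to a mesh, then run the analytic flow on the fit."""
    fitted = fit_anatomy_params(mesh, lattice, base_params)
    fields = analytic_flow(mesh, lattice, fitted, inlet_velocity, viscosity)
    return fields, fitted


# ---------------------------------------------------------------------------
# pseudo-MRI
# ---------------------------------------------------------------------------


@dataclass
class NoiseParams:
    lumen_mean: float = 0.8
    background_mean: float = 0.3
    sigma: float = 0.05
    n_blobs: int = 6
    blob_amplitude: float = 0.2
    bias_amplitude: float = 0.15


def rasterize_pseudo_mri(
    mesh: VolumeMesh,
    grid: ImageVolume,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
) -> tuple[ImageVolume, np.ndarray]:
    """Render a bright-lumen / noisy-tissue volume and its binary mask."""
    d = grid.size
    lo = grid.origin
    hi = grid.origin + grid.spacing * (d - 1)
    if (mesh.nodes.min(axis=0) < lo).any() or (mesh.nodes.max(axis=0) > hi).any():
        raise ValueError("mesh does not fit inside the image grid")
    mask = voxelize(mesh, grid)
    rng = np.random.default_rng(seed)
    image = np.where(mask > 0, noise.lumen_mean, noise.background_mean).astype(
        np.float64
    )
    if noise.n_blobs > 0 and noise.blob_amplitude > 0:
        blobs = np.zeros((d, d, d))
        for _ in range(noise.n_blobs):
            c = rng.uniform(0, d, size=3)
            s = rng.uniform(d / 16, d / 6)
            amp = rng.uniform(0.3, 1.0) * noise.blob_amplitude
            ax = np.arange(d)
            g = np.exp(-((ax - c[0]) ** 2) / (2 * s**2))[:, None, None]
            g = g * np.exp(-((ax - c[1]) ** 2) / (2 * s**2))[None, :, None]
            g = g * np.exp(-((ax - c[2]) ** 2) / (2 * s**2))[None, None, :]
            blobs += amp * g
        image = image + blobs * (mask == 0)  # tissue texture outside the lumen
    if noise.bias_amplitude > 0:
        bias = rng.standard_normal((d, d, d))
        bias = gaussian_filter(bias, sigma=d / 4)
        bias = bias / (np.abs(bias).max() + 1e-12) * noise.bias_amplitude
        image = image * (1.0 + bias)
    if noise.sigma > 0:
        image = image + rng.normal(0.0, noise.sigma, size=(d, d, d))
    image = np.clip(image, 0.0, 1.0)
    return ImageVolume(image, spacing=grid.spacing, origin=grid.origin), mask


# ---------------------------------------------------------------------------
# cases and datasets
# ---------------------------------------------------------------------------


@dataclass
class ScaleSpec:
    """Everything that fixes a dataset scale (image grid + lattice + ranges)."""

    name: str = "small"
    image_size: int = 32
    spacing: float = 1.0
    resolution: Resolution = field(default_factory=Resolution)
    ranges: dict = field(default_factory=lambda: dict(SMALL_RANGES))
    base_z: float = 4.0

    @classmethod
    def small(cls) -> "ScaleSpec":
        return cls()

    @classmethod
    def full(cls) -> "ScaleSpec":
        # 78 disks x 141 nodes/disk = 10,998 template nodes
        return cls(
            name="full",
            image_size=128,
            resolution=Resolution(
                rings=5, sectors=28, stations_trunk=26, stations_branch=26
            ),
            ranges=dict(FULL_RANGES),
            base_z=16.0,
        )

    @classmethod
    def tiny(cls) -> "ScaleSpec":
        """Minimal fixture scale for fast unit tests (16^3, 156-node mesh)."""
        return cls(
            name="tiny",
            image_size=16,
            resolution=Resolution(rings=2, sectors=6, stations_trunk=4, stations_branch=4),
            ranges={
                "trunk_radius": (1.8, 2.3),
                "trunk_length": (4.2, 5.2),
                "branch_radius": (1.2, 1.7),
                "branch_length": (3.4, 4.2),
                "half_angle": (28.0, 40.0),
                "curvature_amp": (0.0, 0.3),
                "bumpiness": (0.0, 0.05),
                "plane_twist": (-25.0, 25.0),
            },
            base_z=2.0,
        )

    @classmethod
    def by_name(cls, name: str) -> "ScaleSpec":
        if name == "small":
            return cls.small()
        if name == "full":
            return cls.full()
        if name == "tiny":
            return cls.tiny()
        raise ValueError(f"unknown scale {name!r}")

    @property
    def center_xy(self) -> np.ndarray:
        c = self.spacing * (self.image_size - 1) / 2.0
        return np.array([c, c])

    def grid(self) -> ImageVolume:
        d = self.image_size
        return ImageVolume(np.zeros((d, d, d)), spacing=self.spacing)


@dataclass
class SyntheticCase:
    """One generated anatomy with its images and per-velocity flow fields."""

    case_id: str
    seed: int
    params: AnatomyParams
    mesh: VolumeMesh
    lattice: Lattice
    fields: dict  # inlet velocity (float) -> FieldSet
    image: ImageVolume
    mask: np.ndarray
    inlet_velocities: list


def _case_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def draw_inlet_velocity(rng: np.random.Generator, mean=0.2, std=0.05) -> float:
    """Normal draw, redrawn until positive (4-sigma event at the defaults)."""
    for _ in range(100):
        v = rng.normal(mean, std)
        if v > 0:
            return float(v)
    raise RuntimeError("could not draw a positive inlet velocity")


def generate_case(
    case_id: str,
    index: int,
    master_seed: int,
    scale: ScaleSpec,
    n_velocities: int = 4,
    extra_velocities: tuple = (),
    noise: NoiseParams = NoiseParams(),
) -> SyntheticCase:
    rng = _case_rng(master_seed, index)
    params = sample_params(rng, scale.ranges)
    mesh, lattice = build_structured_tube_mesh(
        params, scale.resolution, center_xy=scale.center_xy, base_z=scale.base_z
    )
    velocities = [draw_inlet_velocity(rng) for _ in range(n_velocities)]
    fields = {v: analytic_flow(mesh, lattice, params, v) for v in velocities}
    for v in extra_velocities:
        fields[float(v)] = analytic_flow(mesh, lattice, params, float(v))
    img_seed = int(rng.integers(0, 2**31 - 1))
    image, mask = rasterize_pseudo_mri(mesh, scale.grid(), noise, seed=img_seed)
    return SyntheticCase(
        case_id=case_id,
        seed=img_seed,
        params=params,
        mesh=mesh,
        lattice=lattice,
        fields=fields,
        image=image,
        mask=mask,
        inlet_velocities=velocities,
    )


def template_for_scale(scale: ScaleSpec):
    """Average-anatomy template mesh + its flow fields at 0.2 m/s."""
    params = average_params(scale.ranges)
    mesh, lattice = build_structured_tube_mesh(
        params, scale.resolution, center_xy=scale.center_xy, base_z=scale.base_z
    )
    fields = analytic_flow(mesh, lattice, params, 0.2)
    return mesh, lattice, fields, params


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    data = Path(path).read_bytes()
    if path.suffix == ".gz":
        data = gzip.decompress(data)  # gzip headers may carry timestamps
    h.update(data)
    return h.hexdigest()


SWEEP_VELOCITIES = (0.1, 0.2, 0.3)


def generate_dataset(
    out_dir,
    n_cases: int,
    split: tuple,
    master_seed: int,
    scale: ScaleSpec | str = "small",
    n_velocities: int = 4,
    noise: NoiseParams = NoiseParams(),
) -> dict:
    """Write a full dataset (cases, template, manifest) to ``out_dir``.

    Split ``(train, val, test)`` assigns the first cases to train and the last
    to test; test cases carry the fixed 0.1/0.2/0.3 m/s inlet sweep on top of
    their random velocities.  Deterministic under ``master_seed``.
    """
    if isinstance(scale, str):
        scale = ScaleSpec.by_name(scale)
    if n_cases < sum(split):
        raise ValueError("n_cases smaller than the split sum")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_train, n_val, n_test = split
    assignments = (
        ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    ) + ["extra"] * (n_cases - sum(split))

    manifest = {
        "master_seed": master_seed,
        "scale": scale.name,
        "n_cases": n_cases,
        "split": list(split),
        "n_velocities": n_velocities,
        "sweep_velocities": list(SWEEP_VELOCITIES),
        "cases": {},
    }
    seen = set()
    for i in range(n_cases):
        case_id = f"case_{i:04d}"
        if case_id in seen:
            raise ValueError(f"case id collision: {case_id}")
        seen.add(case_id)
        role = assignments[i]
        extra = SWEEP_VELOCITIES if role == "test" else ()
        case = generate_case(
            case_id, i, master_seed, scale, n_velocities, extra, noise
        )
        cdir = out / "cases" / case_id
        cdir.mkdir(parents=True, exist_ok=True)
        mesh_io.write_vtu(cdir / "mesh.vtu", case.mesh)
        mesh_io.write_nifti(cdir / "image.nii.gz", case.image)
        mesh_io.write_nifti(
            cdir / "mask.nii.gz",
            ImageVolume(case.mask, case.image.spacing, case.image.origin),
            dtype=np.uint8,
        )
        files = {
            "mesh.vtu": _sha256(cdir / "mesh.vtu"),
            "image.nii.gz": _sha256(cdir / "image.nii.gz"),
            "mask.nii.gz": _sha256(cdir / "mask.nii.gz"),
        }
        field_files = {}
        for v, fs in sorted(case.fields.items()):
            name = f"fields_v{v:.6f}.vtu"
            mesh_io.write_vtu(cdir / name, case.mesh, fs)
            files[name] = _sha256(cdir / name)
            field_files[f"{v:.6f}"] = name
        manifest["cases"][case_id] = {
            "index": i,
            "split": role,
            "inlet_velocities": [f"{v:.6f}" for v in case.inlet_velocities],
            "sweep": [f"{float(v):.6f}" for v in SWEEP_VELOCITIES]
            if role == "test"
            else [],
            "params": case.params.to_dict(),
            "fields": field_files,
            "hashes": files,
        }
    tmesh, _, tfields, tparams = template_for_scale(scale)
    mesh_io.write_vtu(out / "template.vtu", tmesh, tfields)
    manifest["template"] = {
        "file": "template.vtu",
        "params": tparams.to_dict(),
        "hash": _sha256(out / "template.vtu"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
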