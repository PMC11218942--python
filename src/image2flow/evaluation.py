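"""Segmentation and flow-field accuracy metrics.

Dice works on binary masks; ASSD/Hausdorff on boundary surfaces (vertex to
closest triangle); the normalized absolute error (NAE) is a per-node
percentage normalized by the per-subject per-channel truth range (max - min),
with subject means (MNAE_s) and across-subject node means (MNAE_n).
"""

from __future__ import annotations

import warnings

import numpy as np

from .mesh_core import FieldSet, VolumeMesh, extract_surface

NAE_CHANNELS = ("pressure", "vmag", "vx", "vy", "vz")


# ---------------------------------------------------------------------------
# segmentation metrics
# ---------------------------------------------------------------------------


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Overlap 2|A∩B| / (|A|+|B|); two empty masks count as identical."""
    mask_a, mask_b = np.asarray(mask_a) > 0, np.asarray(mask_b) > 0
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask shape mismatch")
    denom = int(mask_a.sum()) + int(mask_b.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks: defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / denom


def _point_to_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Min distance from each point to a triangle soup; tri is (T, 3, 3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e0, e1 = b - a, c - a
    n = np.cross(e0, e1)
    nn = np.linalg.norm(n, axis=1)
    nn = np.where(nn == 0, 1.0, nn)
    n_unit = n / nn[:, None]
    # barycentric coordinates of the plane projection
    d00 = np.einsum("ij,ij->i", e0, e0)
    d01 = np.einsum("ij,ij->i", e0, e1)
    d11 = np.einsum("ij,ij->i", e1, e1)
    det = np.where(d00 * d11 - d01 * d01 == 0, 1.0, d00 * d11 - d01 * d01)

    def seg_dist(p_rel, seg):  # p_rel (K,T,3) relative to seg start, seg (T,3)
        ss = np.einsum("ij,ij->i", seg, seg)
        t = np.clip(np.einsum("ktj,tj->kt", p_rel, seg) / np.where(ss == 0, 1, ss), 0, 1)
        diff = p_rel - t[:, :, None] * seg
        return np.linalg.norm(diff, axis=2)

    out = np.empty(points.shape[0])
    for lo in range(0, points.shape[0], 256):
        p = points[lo : lo + 256]
        ap = p[:, None, :] - a[None]  # (K, T, 3)
        dist_plane = np.abs(np.einsum("ktj,tj->kt", ap, n_unit))
        d20 = np.einsum("ktj,tj->kt", ap, e0)
        d21 = np.einsum("ktj,tj->kt", ap, e1)
        s = (d11 * d20 - d01 * d21) / det
        t = (d00 * d21 - d01 * d20) / det
        inside = (s >= 0) & (t >= 0) & (s + t <= 1)
        d_edges = np.minimum(
            seg_dist(ap, e0),
            np.minimum(seg_dist(ap, e1), seg_dist(p[:, None, :] - b[None], c - b)),
        )
        out[lo : lo + 256] = np.where(inside, dist_plane, d_edges).min(axis=1)
    return out


def _surface_pieces(obj):
    """Accepts a VolumeMesh (boundary extracted) or a (points, triangles) pair."""
    if isinstance(obj, VolumeMesh):
        surf = extract_surface(obj)
        if surf.triangles.shape[0] == 0:
            raise ValueError("empty surface")
        return obj.nodes[surf.node_indices], obj.nodes[surf.triangles]
    points, triangles = obj
    points = np.asarray(points, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.int64)
    if triangles.size == 0:
        raise ValueError("empty surface")
    return points[np.unique(triangles)], points[triangles]


def _directed_distances(mesh_a, mesh_b):
    pts_a, tris_a = _surface_pieces(mesh_a)
    pts_b, tris_b = _surface_pieces(mesh_b)
    return _point_to_triangles(pts_a, tris_b), _point_to_triangles(pts_b, tris_a)


def assd(mesh_a, mesh_b) -> float:
    """Average symmetric surface distance (mm) between boundary surfaces."""
    d_ab, d_ba = _directed_distances(mesh_a, mesh_b)
    return float(np.concatenate([d_ab, d_ba]).mean())


def hausdorff(mesh_a, mesh_b, percentile: float = 100.0) -> float:
    """Symmetric Hausdorff distance (mm); ``percentile=95`` for HD95."""
    d_ab, d_ba = _directed_distances(mesh_a, mesh_b)
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


# ---------------------------------------------------------------------------
# flow-field error metrics
# ---------------------------------------------------------------------------


def _channels(fields: FieldSet) -> dict:
    v = fields.velocity
    return {
        "pressure": fields.pressure,
        "vmag": np.linalg.norm(v, axis=1),
        "vx": v[:, 0],
        "vy": v[:, 1],
        "vz": v[:, 2],
    }


def nae(pred: FieldSet, truth: FieldSet) -> dict:
    """Per-node normalized absolute error (%) per channel.

    Denominator: the truth channel's per-subject range (max - min).
    """
    if pred.pressure.shape[0] != truth.pressure.shape[0]:
        raise ValueError("prediction/truth node count mismatch")
    pc, tc = _channels(pred), _channels(truth)
    out = {}
    for ch in NAE_CHANNELS:
        rng = tc[ch].max() - tc[ch].min()
        if rng == 0:
            raise ValueError(f"constant truth channel {ch!r}: NAE undefined")
        out[ch] = 100.0 * np.abs(pc[ch] - tc[ch]) / rng
    return out


def mnae_subject(nae_arrays: dict) -> dict:
    """Mean NAE over nodes per channel for one subject."""
    out = {}
    for ch, arr in nae_arrays.items():
        if len(arr) == 0:
            raise ValueError("empty NAE array")
        out[ch] = float(np.mean(arr))
    return out


def mnae_node(nae_per_case: list) -> dict:
    """Node-wise mean NAE across subjects (the template error map)."""
    if not nae_per_case:
        raise ValueError("no cases given")
    out = {}
    for ch in nae_per_case[0]:
        out[ch] = np.mean([case[ch] for case in nae_per_case], axis=0)
    return out


def bland_altman(pred: np.ndarray, truth: np.ndarray):
    """Bias and 95% limits of agreement -> (bias, (low, high))."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=np.float64).ravel()
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    if pred.size < 3:
        raise ValueError("need at least 3 paired values")
    diff = pred - truth
    bias = float(diff.mean())
    spread = 1.96 * float(diff.std())
    return bias, (bias - spread, bias + spread)


def error_decomposition(
    pred_fields: FieldSet, oracle_fields: FieldSet, truth_fields: FieldSet
) -> dict:
    """Direct-prediction error minus flow-oracle-on-predicted-geometry error.

    Negative delta: the direct prediction beats re-running the flow solver on
    the predicted geometry.  Returns per-channel ``direct``/``oracle``/
    ``delta`` MNAE_s values.
    """
    direct = mnae_subject(nae(pred_fields, truth_fields))
    oracle = mnae_subject(nae(oracle_fields, truth_fields))
    return {
        "direct": direct,
        "oracle": oracle,
        "delta": {ch: direct[ch] - oracle[ch] for ch in direct},
    }


def summarize(values) -> dict:
    """Median and IQR of a sequence, as the reports print them."""
    arr = np.asarray(list(values), dtype=np.float64)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"median": float(med), "iqr": [float(q1), float(q3)]}
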