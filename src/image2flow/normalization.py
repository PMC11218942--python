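"""Field transforms between physical units and training space.

Pressure is passed through a signed cube root (gauge pressures may be
negative) before standardization; velocity components are standardized
directly.  Statistics are global over the training split (population std)
and serialized into checkpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .mesh_core import FieldSet

CHANNELS = ("pressure", "vx", "vy", "vz")


def signed_cube_root(x):
    """sign(x) * |x|^(1/3); odd, monotone, defined for all reals."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.abs(x) ** (1.0 / 3.0)


def signed_cube(x):
    """Inverse of :func:`signed_cube_root`."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.abs(x) ** 3


@dataclass
class FieldStats:
    """Per-channel mean/std in (cube-rooted pressure, raw velocity) space."""

    mean: np.ndarray  # (4,) order: cbrt-pressure, vx, vy, vz
    std: np.ndarray  # (4,)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(4)
        self.std = np.asarray(self.std, dtype=np.float64).reshape(4)
        if (self.std <= 0).any():
            bad = CHANNELS[int(np.argmin(self.std))]
            raise ValueError(f"non-positive std for channel {bad!r}")

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "std": self.std.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "FieldStats":
        d = json.loads(text)
        return cls(np.array(d["mean"]), np.array(d["std"]))


def fit_stats(field_sets) -> FieldStats:
    """Fit global per-channel statistics over all nodes of all cases."""
    field_sets = list(field_sets)
    if not field_sets:
        raise ValueError("fit_stats requires at least one FieldSet")
    cols = np.concatenate(
        [
            np.column_stack([signed_cube_root(f.pressure), f.velocity])
            for f in field_sets
        ],
        axis=0,
    )
    if cols.shape[0] < 2:
        raise ValueError("fit_stats requires at least 2 nodes in total")
    mean = cols.mean(axis=0)
    std = cols.std(axis=0)  # population std
    if (std == 0).any():
        bad = CHANNELS[int(np.argmin(std))]
        raise ValueError(f"constant channel {bad!r}: std is zero")
    return FieldStats(mean, std)


def standardize(fields: FieldSet, stats: FieldStats) -> FieldSet:
    """Physical units -> training space (cube-rooted, zero-mean, unit-std)."""
    if stats is None:
        raise ValueError("standardize requires fitted FieldStats")
    p = (signed_cube_root(fields.pressure) - stats.mean[0]) / stats.std[0]
    v = (fields.velocity - stats.mean[1:]) / stats.std[1:]
    return FieldSet(p, v)


def destandardize(fields: FieldSet, stats: FieldStats) -> FieldSet:
    """Training space -> physical units (pressure cubed back to Pa)."""
    if stats is None:
        raise ValueError("destandardize requires fitted FieldStats")
    p = signed_cube(fields.pressure * stats.std[0] + stats.mean[0])
    v = fields.velocity * stats.std[1:] + stats.mean[1:]
    return FieldSet(p, v)
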