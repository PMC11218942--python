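"""Hybrid image-encoder / graph-transformer network.

A five-level residual 3-D convolutional encoder extracts multi-scale image
features; three sequential graph-convolutional branches then deform a template
volume-mesh and refine per-node pressure/velocity, conditioned on the scalar
inlet velocity which is broadcast-concatenated to every node in every branch.
Branch outputs are additive deltas on the seven node channels (x, y, z,
pressure, vx, vy, vz), with zero-initialized bottlenecks so an untrained
model reproduces the template exactly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import (
    Adam,
    Tensor,
    astensor,
    concatenate,
    conv3d,
    leaky_relu,
    maxpool2,
    parameter,
    spmm,
    trilinear_sample,
)
from .losses import TopologyCache
from .mesh_core import FieldSet, ImageVolume, VolumeMesh, scaled_laplacian
from .normalization import FieldStats


@dataclass
class EncoderConfig:
    filters: tuple = (16, 48, 96, 192, 384)
    blocks_per_level: int = 2
    kernel: int = 3
    dropout: float = 0.1
    negative_slope: float = 0.2

    def __post_init__(self):
        self.filters = tuple(self.filters)
        if len(self.filters) < 2:
            raise ValueError("need at least 2 encoder levels")
        if any(b >= a for a, b in zip(self.filters[1:], self.filters)):
            raise ValueError("encoder filters must be strictly increasing")

    @property
    def levels(self) -> int:
        return len(self.filters)


@dataclass
class BranchConfig:
    levels: tuple = (5, 4)  # 1-based encoder levels to project features from
    hidden: int | None = None  # None -> channel count of levels[0]
    residual_blocks: int = 3


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    branches: tuple = (
        BranchConfig((5, 4)),
        BranchConfig((4, 3)),
        BranchConfig((3, 2)),
    )
    initial_width: int = 16
    negative_slope: float = 0.2
    seed: int = 0
    dtype: str = "float64"  # "float32" roughly halves CPU training time

    def __post_init__(self):
        if len(self.branches) != 3:
            raise ValueError("exactly 3 transformation branches are required")
        for b in self.branches:
            for lv in b.levels:
                if not 1 <= lv <= self.encoder.levels:
                    raise ValueError(f"branch references missing encoder level {lv}")

    @classmethod
    def small(cls, seed: int = 0, dtype: str = "float32") -> "ModelConfig":
        """CPU-friendly configuration for 32^3 images / ~600-node templates."""
        return cls(
            encoder=EncoderConfig(filters=(8, 16, 32, 64, 128)),
            branches=(
                BranchConfig((5, 4), hidden=32),
                BranchConfig((4, 3), hidden=32),
                BranchConfig((3, 2), hidden=32),
            ),
            initial_width=16,
            seed=seed,
            dtype=dtype,
        )

    @classmethod
    def tiny(cls, seed: int = 0, dtype: str = "float64") -> "ModelConfig":
        """Minimal configuration for 16^3 fixtures and gradient checks."""
        return cls(
            encoder=EncoderConfig(filters=(4, 6, 8, 10, 12), dropout=0.0),
            branches=(
                BranchConfig((5, 4), hidden=8),
                BranchConfig((4, 3), hidden=8),
                BranchConfig((3, 2), hidden=8),
            ),
            initial_width=8,
            seed=seed,
            dtype=dtype,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["branches"] = [asdict(b) for b in self.branches]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            encoder=EncoderConfig(**d["encoder"]),
            branches=tuple(BranchConfig(tuple(b["levels"]), b["hidden"], b["residual_blocks"]) for b in d["branches"]),
            initial_width=d["initial_width"],
            negative_slope=d["negative_slope"],
            seed=d["seed"],
            dtype=d.get("dtype", "float64"),
        )


def graph_conv(features, operator, w0, w1, b) -> Tensor:
    """First-order Chebyshev graph convolution: X W0 + (L~ X) W1 + b."""
    x = astensor(features)
    return x @ w0 + spmm(operator, x) @ w1 + astensor(b)


def instance_norm(x: Tensor, gamma, beta, axes, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=axes, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    return xc / ((var + eps) ** 0.5) * gamma + beta


class Image2FlowNet:
    """The full model: parameters + template + normalization statistics."""

    def __init__(
        self,
        config: ModelConfig,
        template: VolumeMesh,
        template_fields_std: FieldSet,
        stats: FieldStats,
        delta_scale: float = 1.0,
    ):
        self.config = config
        self.template = template
        self.template_fields = template_fields_std
        self.stats = stats
        self.delta_scale = delta_scale
        self.dtype = np.dtype(config.dtype)
        self.operator = scaled_laplacian(template).astype(self.dtype)
        self.topology = TopologyCache.from_mesh(template)
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # -- parameter helpers ----------------------------------------------------
    def _weight(self, name, shape, zero=False):
        if zero:
            w = np.zeros(shape)
        else:
            fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
            w = self._rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))
        p = parameter(w, dtype=self.dtype)
        self.params[name] = p
        return p

    def _gc_params(self, name, f_in, f_out, zero=False):
        return (
            self._weight(f"{name}.w0", (f_in, f_out), zero),
            self._weight(f"{name}.w1", (f_in, f_out), zero),
            self._weight(f"{name}.b", (f_out,), zero=True),
        )

    def _in_params(self, name, channels, conv=False):
        shape = (channels, 1, 1, 1) if conv else (channels,)
        g = parameter(np.ones(shape), dtype=self.dtype)
        b = parameter(np.zeros(shape), dtype=self.dtype)
        self.params[f"{name}.gamma"] = g
        self.params[f"{name}.beta"] = b
        return g, b

    def _build(self):
        cfg = self.config
        enc = cfg.encoder
        k = enc.kernel
        c_prev = 1
        for lv, c in enumerate(enc.filters):
            for blk in range(enc.blocks_per_level):
                c_in = c_prev if blk == 0 else c
                base = f"enc.l{lv}.b{blk}"
                for j in range(3):
                    cj = c_in if j == 0 else c
                    self._weight(f"{base}.conv{j}.w", (c, cj, k, k, k))
                    self._weight(f"{base}.conv{j}.b", (c,), zero=True)
                    self._in_params(f"{base}.in{j}", c, conv=True)
                if c_in != c:
                    self._weight(f"{base}.proj.w", (c, c_in, 1, 1, 1))
                    self._weight(f"{base}.proj.b", (c,), zero=True)
            c_prev = c

        self._gc_params("graph.init", 4, cfg.initial_width)
        w_prev = cfg.initial_width
        for i, br in enumerate(cfg.branches):
            hidden = br.hidden or enc.filters[br.levels[0] - 1]
            base = f"branch{i}"
            self._gc_params(f"{base}.adapt", w_prev, hidden)
            img_ch = sum(enc.filters[lv - 1] for lv in br.levels)
            c_in = hidden + img_ch + 1  # + broadcast inlet velocity
            for blk in range(br.residual_blocks):
                cj = c_in if blk == 0 else hidden
                for j in range(3):
                    f_in = cj if j == 0 else hidden
                    self._gc_params(f"{base}.res{blk}.gc{j}", f_in, hidden)
                    self._in_params(f"{base}.res{blk}.in{j}", hidden)
                if cj != hidden:
                    self._gc_params(f"{base}.res{blk}.proj", cj, hidden)
            self._gc_params(f"{base}.out", hidden, 7, zero=True)
            w_prev = hidden

    def parameters(self):
        return list(self.params.values())

    # -- encoder --------------------------------------------------------------
    def encode_image(self, image: ImageVolume, train=False, rng=None):
        """Run the residual conv encoder -> one feature Tensor per level."""
        cfg = self.config.encoder
        d = image.size
        if d % 2 ** (cfg.levels - 1):
            raise ValueError(
                f"image size {d} not divisible by 2^{cfg.levels - 1}; pad or crop"
            )
        x = Tensor(np.asarray(image.voxels, dtype=self.dtype)[None])
        feats = []
        for lv, c in enumerate(cfg.filters):
            for blk in range(cfg.blocks_per_level):
                base = f"enc.l{lv}.b{blk}"
                h = x
                for j in range(3):
                    h = conv3d(
                        h,
                        self.params[f"{base}.conv{j}.w"],
                        self.params[f"{base}.conv{j}.b"],
                    )
                    h = instance_norm(
                        h,
                        self.params[f"{base}.in{j}.gamma"],
                        self.params[f"{base}.in{j}.beta"],
                        axes=(1, 2, 3),
                    )
                    h = leaky_relu(h, cfg.negative_slope)
                if train and cfg.dropout > 0:
                    keep = (rng.random(h.shape[0]) >= cfg.dropout).astype(self.dtype)
                    h = h * Tensor(keep[:, None, None, None] / (1 - cfg.dropout))
                if f"{base}.proj.w" in self.params:
                    skip = conv3d(
                        x, self.params[f"{base}.proj.w"], self.params[f"{base}.proj.b"]
                    )
                else:
                    skip = x
                x = h + skip
            feats.append(x)
            if lv < cfg.levels - 1:
                x = maxpool2(x)
        return feats

    # -- graph arm ------------------------------------------------------------
    def _coord_feat(self, nodes: Tensor, image: ImageVolume) -> Tensor:
        half = image.spacing * (image.size - 1) / 2.0
        center = (image.origin + half).astype(self.dtype)
        return (nodes - Tensor(center)) * self.dtype.type(1.0 / half)

    def _sample_level(self, feats, level_1based, nodes: Tensor, image: ImageVolume):
        grid = feats[level_1based - 1]
        scale = 2 ** (level_1based - 1)
        idx = (nodes - Tensor(image.origin.astype(self.dtype))) * self.dtype.type(
            1.0 / (image.spacing * scale)
        )
        return trilinear_sample(grid, idx)

    def _run_gc(self, name, x):
        return graph_conv(
            x,
            self.operator,
            self.params[f"{name}.w0"],
            self.params[f"{name}.w1"],
            self.params[f"{name}.b"],
        )

    def transform_branch(
        self, i, nodes, pressure, velocity, graph_feats, feats, image, inlet_velocity
    ):
        """One refinement branch; returns updated (nodes, p, v, graph features)."""
        cfg = self.config
        br = cfg.branches[i]
        base = f"branch{i}"
        n = nodes.shape[0]
        h = self._run_gc(f"{base}.adapt", graph_feats)
        img_feats = [self._sample_level(feats, lv, nodes, image) for lv in br.levels]
        vin = Tensor(np.full((n, 1), inlet_velocity, dtype=self.dtype))
        h = concatenate([h] + img_feats + [vin], axis=1)
        for blk in range(br.residual_blocks):
            rbase = f"{base}.res{blk}"
            z = h
            for j in range(3):
                z = self._run_gc(f"{rbase}.gc{j}", z)
                z = instance_norm(
                    z,
                    self.params[f"{rbase}.in{j}.gamma"],
                    self.params[f"{rbase}.in{j}.beta"],
                    axes=0,
                )
                z = leaky_relu(z, cfg.negative_slope)
            skip = self._run_gc(f"{rbase}.proj", h) if f"{rbase}.proj.w0" in self.params else h
            h = z + skip
        delta = self._run_gc(f"{base}.out", h)
        if not np.isfinite(delta.value).all():
            raise FloatingPointError(f"NaN in transformation delta of branch {i + 1}")
        nodes = nodes + delta[:, 0:3] * self.delta_scale
        pressure = pressure + delta[:, 3]
        velocity = velocity + delta[:, 4:7]
        return nodes, pressure, velocity, h

    def forward(
        self, image: ImageVolume, inlet_velocity: float, train=False, rng=None
    ):
        """Full pass -> list of 3 (nodes, pressure, velocity) Tensor triples.

        Fields are in standardized space; use :meth:`predict` for physical
        units.  Deterministic when ``train`` is False (dropout disabled).
        """
        feats = self.encode_image(image, train=train, rng=rng)
        nodes = Tensor(self.template.nodes.astype(self.dtype))
        pressure = Tensor(self.template_fields.pressure.astype(self.dtype))
        velocity = Tensor(self.template_fields.velocity.astype(self.dtype))
        coord = self._coord_feat(nodes, image)
        vin = Tensor(np.full((nodes.shape[0], 1), inlet_velocity, dtype=self.dtype))
        graph_feats = leaky_relu(
            self._run_gc("graph.init", concatenate([coord, vin], axis=1)),
            self.config.negative_slope,
        )
        outputs = []
        for i in range(3):
            nodes, pressure, velocity, graph_feats = self.transform_branch(
                i, nodes, pressure, velocity, graph_feats, feats, image, inlet_velocity
            )
            outputs.append((nodes, pressure, velocity))
        return outputs

    def predict(self, image: ImageVolume, inlet_velocity: float):
        """Inference: final-branch mesh + fields de-standardized to Pa / m/s."""
        from .normalization import destandardize

        nodes, p, v = self.forward(image, inlet_velocity)[-1]
        mesh = self.template.with_nodes(nodes.value)
        fields = destandardize(FieldSet(p.value, v.value), self.stats)
        return mesh, fields

    # -- checkpointing --------------------------------------------------------
    def save(self, path):
        arrays = {f"param::{k}": v.value for k, v in self.params.items()}
        arrays["template::nodes"] = self.template.nodes
        arrays["template::tets"] = self.template.tets
        for cap, faces in self.template.cap_faces.items():
            arrays[f"template::cap::{cap}"] = faces
        arrays["tfields::pressure"] = self.template_fields.pressure
        arrays["tfields::velocity"] = self.template_fields.velocity
        meta = {
            "config": self.config.to_dict(),
            "stats": json.loads(self.stats.to_json()),
            "delta_scale": self.delta_scale,
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "Image2FlowNet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            caps = {
                k.split("::")[-1]: z[k] for k in z.files if k.startswith("template::cap::")
            }
            template = VolumeMesh(z["template::nodes"], z["template::tets"], caps)
            tfields = FieldSet(z["tfields::pressure"], z["tfields::velocity"])
            stats = FieldStats(
                np.array(meta["stats"]["mean"]), np.array(meta["stats"]["std"])
            )
            model = cls(
                ModelConfig.from_dict(meta["config"]),
                template,
                tfields,
                stats,
                delta_scale=meta["delta_scale"],
            )
            for k in z.files:
                if k.startswith("param::"):
                    model.params[k[len("param::") :]].value = z[k].astype(model.dtype)
        return model


def make_optimizer(model: Image2FlowNet, lr: float = 1e-4) -> Adam:
    return Adam(model.parameters(), lr=lr)
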