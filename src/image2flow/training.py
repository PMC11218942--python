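"""Training, validation and inference orchestration.

Per epoch, every training case contributes one step using ONE of its four
random-inlet-velocity flow solutions (drawn from a dedicated augmentation RNG
stream, so the augmentation schedule is independent of weight init);
validation evaluates all four per case.  The best-validation parameter set is
retained and early stopping watches the validation total loss.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import clip_grad_norm
from .losses import LossWeights, total_loss
from .mesh_core import FieldSet, ImageVolume, VolumeMesh
from .mesh_io import read_nifti, read_vtu
from .network import Image2FlowNet, ModelConfig, make_optimizer
from .normalization import fit_stats, standardize


@dataclass
class TrainConfig:
    dataset: str = "dataset"
    epochs: int = 20
    lr: float = 1e-4
    lr_final: float | None = None  # linear decay target over the epochs
    grad_clip: float | None = 20.0  # global gradient-norm ceiling
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    model: ModelConfig | None = None  # None -> ModelConfig.small(seed)
    patience: int = 10  # early-stopping patience in epochs
    min_epochs: int = 1
    checkpoint: str | None = None  # path for the best checkpoint
    log_csv: str | None = None
    batch_size: int = 1  # one anatomy per optimizer step

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class CaseRecord:
    case_id: str
    split: str
    image: ImageVolume
    mesh: VolumeMesh
    fields: dict  # velocity float -> FieldSet
    inlet_velocities: list
    sweep: list


class DiskDataset:
    """Loads a generated dataset directory (manifest + cases + template)."""

    def __init__(self, root):
        self.root = Path(root)
        manifest_path = self.root / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"no manifest.json under {self.root}")
        self.manifest = json.loads(manifest_path.read_text())
        self._cache: dict[str, CaseRecord] = {}

    def ids(self, split: str) -> list:
        return sorted(
            cid
            for cid, meta in self.manifest["cases"].items()
            if meta["split"] == split
        )

    def template(self):
        return read_vtu(self.root / self.manifest["template"]["file"])

    def load(self, case_id: str) -> CaseRecord:
        if case_id in self._cache:
            return self._cache[case_id]
        meta = self.manifest["cases"][case_id]
        cdir = self.root / "cases" / case_id
        image = read_nifti(cdir / "image.nii.gz")
        mesh, _ = read_vtu(cdir / "mesh.vtu")
        fields = {}
        for vstr, fname in meta["fields"].items():
            _, fs = read_vtu(cdir / fname)
            if fs is None:
                raise ValueError(f"case {case_id}: field file {fname} has no fields")
            fields[float(vstr)] = fs
        for vstr in meta["inlet_velocities"]:
            if float(vstr) not in fields:
                raise ValueError(f"case {case_id} missing FieldSet for v={vstr}")
        rec = CaseRecord(
            case_id=case_id,
            split=meta["split"],
            image=image,
            mesh=mesh,
            fields=fields,
            inlet_velocities=[float(v) for v in meta["inlet_velocities"]],
            sweep=[float(v) for v in meta["sweep"]],
        )
        self._cache[case_id] = rec
        return rec


def _case_loss(model, rec, velocity, weights, train_rng=None):
    std = standardize(rec.fields[velocity], model.stats)
    dt = model.dtype
    outs = model.forward(rec.image, velocity, train=train_rng is not None, rng=train_rng)
    return total_loss(
        outs,
        rec.mesh.nodes.astype(dt),
        std.pressure.astype(dt),
        std.velocity.astype(dt),
        model.topology,
        weights,
    )


def train(cfg: TrainConfig):
    """Run the full training loop -> (best model, log DataFrame)."""
    ds = DiskDataset(cfg.dataset)
    train_ids = ds.ids("train")
    val_ids = ds.ids("val")
    if not train_ids:
        raise ValueError("dataset has no training cases")

    template, template_fields = ds.template()
    train_fieldsets = []
    for cid in train_ids:
        rec = ds.load(cid)
        train_fieldsets.extend(
            rec.fields[v] for v in rec.inlet_velocities
        )
    stats = fit_stats(train_fieldsets)
    model_cfg = cfg.model or ModelConfig.small(seed=cfg.seed)
    model = Image2FlowNet(
        model_cfg, template, standardize(template_fields, stats), stats
    )
    opt = make_optimizer(model, lr=cfg.lr)
    aug_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    drop_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))

    rows = []
    best_val = np.inf
    best_params = {k: p.value.copy() for k, p in model.params.items()}
    best_epoch = 0
    for epoch in range(1, cfg.epochs + 1):
        t0 = time.time()
        if cfg.lr_final is not None and cfg.epochs > 1:
            frac = (epoch - 1) / (cfg.epochs - 1)
            opt.lr = cfg.lr + (cfg.lr_final - cfg.lr) * frac
        train_total = 0.0
        last_good = {k: p.value.copy() for k, p in model.params.items()}
        for cid in train_ids:
            rec = ds.load(cid)
            v = rec.inlet_velocities[aug_rng.integers(len(rec.inlet_velocities))]
            loss, report = _case_loss(model, rec, v, cfg.weights, train_rng=drop_rng)
            if not np.isfinite(loss.value):
                for k, p in model.params.items():  # roll back and abort
                    p.value = last_good[k]
                raise FloatingPointError(
                    f"NaN loss at epoch {epoch}, case {cid}; aborting with "
                    "last-good parameters restored"
                )
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip:
                clip_grad_norm(model.parameters(), cfg.grad_clip)
            opt.step()
            train_total += float(loss.value)
            row = {"epoch": epoch, "phase": "train", "case": cid, "velocity": v}
            row.update(report.as_row())
            rows.append(row)
        val_total = 0.0
        n_val = 0
        for cid in val_ids:
            rec = ds.load(cid)
            for v in rec.inlet_velocities:
                loss, report = _case_loss(model, rec, v, cfg.weights)
                val_total += float(loss.value)
                n_val += 1
                row = {"epoch": epoch, "phase": "val", "case": cid, "velocity": v}
                row.update(report.as_row())
                rows.append(row)
        val_mean = val_total / max(n_val, 1)
        # wall time deliberately not logged: the CSV is byte-reproducible
        del t0
        rows.append(
            {
                "epoch": epoch,
                "phase": "summary",
                "case": "",
                "velocity": np.nan,
                "total": train_total / len(train_ids),
                "val_total": val_mean,
            }
        )
        if n_val == 0 or val_mean < best_val:
            best_val = val_mean
            best_epoch = epoch
            best_params = {k: p.value.copy() for k, p in model.params.items()}
        elif epoch >= cfg.min_epochs and epoch - best_epoch >= cfg.patience:
            break

    for k, p in model.params.items():
        p.value = best_params[k]
    log = pd.DataFrame(rows)
    if cfg.log_csv:
        Path(cfg.log_csv).parent.mkdir(parents=True, exist_ok=True)
        log.to_csv(cfg.log_csv, index=False)
    if cfg.checkpoint:
        Path(cfg.checkpoint).parent.mkdir(parents=True, exist_ok=True)
        model.save(cfg.checkpoint)
    return model, log


def predict(model: Image2FlowNet, image: ImageVolume, inlet_velocity: float):
    """Inference -> (VolumeMesh, FieldSet in physical units, wall seconds)."""
    t0 = time.time()
    mesh, fields = model.predict(image, inlet_velocity)
    wall = time.time() - t0
    # inverted cells are reported, not fatal: the network does not hard-
    # constrain cell positivity, the quality losses only encourage it
    mesh.validate(strict_volumes=False)
    fields.validate(mesh)
    return mesh, fields, wall
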