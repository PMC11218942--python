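# image2flow

A template-deforming hybrid image/graph convolutional network that turns a 3-D
grayscale vessel image plus a scalar inlet velocity into a patient-specific
tetrahedral volume-mesh with per-node pressure (Pa) and velocity (m/s) —
together with its loss functions, a point-correspondent synthetic data
generator with an analytic laminar-flow oracle, training/inference
orchestration, and evaluation statistics.

Everything runs on CPU with numpy/scipy: the network and losses are built on a
small reverse-mode autodiff engine included in the package
(`image2flow.autodiff`), so no deep-learning framework is required.

## Layout

| module | contents |
| --- | --- |
| `image2flow.mesh_core` | `VolumeMesh`/`FieldSet`/`ImageVolume`/`SurfaceView`, edges, boundary surface, normals, rescaled graph Laplacian, voxelization, trilinear feature sampling |
| `image2flow.mesh_io` | VTK unstructured-grid I/O (`.vtu` XML + legacy `.vtk`, ASCII), NIfTI images |
| `image2flow.losses` | Chamfer point losses, edge-length deviation, tet aspect ratio, cap coplanarity, 4-channel field MAE; per-branch and total weighted combinations |
| `image2flow.network` | 5-level residual 3-D conv encoder + 3 graph-convolutional transformation branches (first-order Chebyshev), checkpointing |
| `image2flow.normalization` | signed-cube-root pressure transform and global per-channel standardization |
| `image2flow.synthetic` | seeded Y-vessel lattice mesher (identical topology across cases), Hagen–Poiseuille flow fields, pseudo-MRI rendering, dataset generation |
| `image2flow.correspondence` | template averaging, deformation-fitting onto target point clouds, barycentric field interpolation |
| `image2flow.training` | train/validate loop with per-epoch inlet-velocity augmentation, early stopping, reproducible CSV logs, inference |
| `image2flow.evaluation` | Dice, ASSD, Hausdorff, range-normalized absolute error (NAE/MNAE), Bland–Altman, error decomposition |

## CLI

```bash
# generate a 56-case synthetic dataset (40/8/8 split) at the 32^3 scale
image2flow synth --n 56 --seed 7 --scale small --out dataset --split 40,8,8

# train from a YAML config (dataset, epochs, lr, loss.lambda1..5, model, seed)
image2flow train --config train.yaml

# predict a mesh + flow fields for one image at a chosen inlet velocity
image2flow predict --ckpt model.ckpt --image case.nii.gz --vin 0.2 --out pred.vtu

# per-case Dice/ASSD/HD and MNAE metrics against the dataset ground truth
image2flow evaluate --pred-dir preds/ --truth-dir dataset/ --out report/

# average correspondent training meshes into a template
image2flow template --from dataset --out template.vtu

# interpolate fields from one mesh onto another's nodes
image2flow resample --source a.vtu --onto b.vtu --out c.vtu

# export the normalization statistics stored in a checkpoint
image2flow stats export --ckpt model.ckpt
```

A minimal `train.yaml`:

```yaml
dataset: dataset
epochs: 8
lr: 0.001
lr_final: 0.00025
seed: 11
model: small
loss: {lambda1: 1, lambda2: 0.1, lambda3: 0.5, lambda4: 0.05, lambda5: 30}
checkpoint: model.ckpt
log_csv: log.csv
```

## Scales

- `small` — 32³ images, 600-node template; the CPU test scale.
- `full` — 128³ images, 10,998-node template; the full-size configuration.
- `tiny` — 16³ images, 156-node template; unit-test fixtures.
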