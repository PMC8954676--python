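"""3D convolutional affinity scoring with Boltzmann pose-ensemble averaging.

The model maps a multi-channel occupancy grid of a protein–ligand pose to
a predicted binding affinity on the pK scale (pKd/pKi/pIC50 treated as a
single scale; higher = stronger binding). The default architecture is
five convolutions of 32x3^3, 64x3^3, 64x3^3, 64x3^3, 64x2^3 filters
followed by a 256-unit ReLU dense layer and a scalar linear output, with
stride-1 convolutions and two 2^3 max-pools (after the second and fourth
convolutions) to keep the flattened size tractable.

Scores of the poses of one compound are combined by softmax-weighted
(Boltzmann) averaging::

    S = sum_i s_i * exp(beta * s_i) / sum_j exp(beta * s_j)

which reduces to the arithmetic mean at beta = 0 and to the maximum as
beta -> infinity. Training minimizes mean-squared error against pK labels
with Adam on mini-batches (default 64).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nnet
from .chemio import MolGraph, Structure
from .posegrid import GridSpec, NoPlaceablePoseError, VoxelGrid, rasterize, sample_poses
from .sitefinder import BindingSite

__all__ = [
    "LayerSpec",
    "ScoreModel",
    "TrainConfig",
    "EnsembleParams",
    "ScreenResult",
    "BuildError",
    "TrainingDivergedError",
    "default_architecture",
    "build_model",
    "predict_pose",
    "ensemble_score",
    "train",
    "screen",
    "save_model",
    "load_model",
    "write_screen_csv",
]


class BuildError(ValueError):
    """Layer shapes do not chain together."""


class TrainingDivergedError(RuntimeError):
    """Loss became NaN/inf during training."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the scoring network.

    ``filters`` doubles as the unit count for dense layers. Convolution
    kernels are restricted to edge 2 or 3 and pooling is fixed 2x2x2,
    matching the architecture family the scorer is built from.
    """

    kind: str  # conv3d | maxpool | flatten | dense
    filters: int = 0
    kernel: int = 0
    stride: int = 1
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kind not in ("conv3d", "maxpool", "flatten", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv3d":
            if self.kernel not in (2, 3):
                raise ValueError("conv kernel must be 2 or 3")
            if self.filters <= 0:
                raise ValueError("conv filters must be > 0")
        if self.kind == "dense" and self.filters <= 0:
            raise ValueError("dense units must be > 0")
        if self.activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")


def default_architecture() -> list[LayerSpec]:
    """The standard scoring stack: 32x3^3, 64x3^3, P, 64x3^3, 64x3^3, P,
    64x2^3, flatten, 256-ReLU dense, scalar linear output."""
    return [
        LayerSpec("conv3d", filters=32, kernel=3),
        LayerSpec("conv3d", filters=64, kernel=3),
        LayerSpec("maxpool"),
        LayerSpec("conv3d", filters=64, kernel=3),
        LayerSpec("conv3d", filters=64, kernel=3),
        LayerSpec("maxpool"),
        LayerSpec("conv3d", filters=64, kernel=2),
        LayerSpec("flatten"),
        LayerSpec("dense", filters=256, activation="relu"),
        LayerSpec("dense", filters=1, activation="linear"),
    ]


def small_architecture() -> list[LayerSpec]:
    """A reduced-width stack for small grids (e.g. 16^3) and quick runs."""
    return [
        LayerSpec("conv3d", filters=8, kernel=3),
        LayerSpec("maxpool"),
        LayerSpec("conv3d", filters=16, kernel=3),
        LayerSpec("maxpool"),
        LayerSpec("flatten"),
        LayerSpec("dense", filters=32, activation="relu"),
        LayerSpec("dense", filters=1, activation="linear"),
    ]


@dataclass
class ScoreModel:
    """A built network: layer specs plus live layer objects."""

    specs: list[LayerSpec]
    layers: list
    input_spec: GridSpec
    flat_features: int  # size entering the first dense layer

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, need_grad: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, need_grad=need_grad)
        return x[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        d = dpred[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            if layer.params:
                out.extend([layer.dW, layer.db])
        return out


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-3
    epochs: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class EnsembleParams:
    """Boltzmann inverse temperature in pK units; 0 = plain mean."""

    beta: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError("beta must be finite and >= 0")


def build_model(layers: Sequence[LayerSpec] | None = None,
                spec: GridSpec = GridSpec(), rng_seed: int = 0) -> ScoreModel:
    """Instantiate a network, validating the shape chain layer by layer.

    Parameter initialization is a deterministic function of ``rng_seed``.
    """
    specs = list(layers) if layers is not None else default_architecture()
    rng = np.random.default_rng(rng_seed)
    shape: tuple[int, ...] = (spec.n_channels, spec.n, spec.n, spec.n)
    built: list = []
    flat_features = 0
    for k, ls in enumerate(specs):
        try:
            if ls.kind == "conv3d":
                layer = nnet.Conv3D(shape[0], ls.filters, ls.kernel,
                                    stride=ls.stride, activation=ls.activation,
                                    rng=rng)
            elif ls.kind == "maxpool":
                layer = nnet.MaxPool3D()
            elif ls.kind == "flatten":
                layer = nnet.Flatten()
            else:
                if len(shape) != 1:
                    raise ValueError("dense layer needs a flatten before it")
                layer = nnet.Dense(shape[0], ls.filters,
                                   activation=ls.activation, rng=rng)
            shape = layer.out_shape(shape)
        except ValueError as exc:
            raise BuildError(f"layer {k} ({ls.kind}): {exc}") from exc
        if ls.kind == "flatten":
            flat_features = shape[0]
        built.append(layer)
    if shape != (1,):
        raise BuildError(f"network output shape is {shape}, expected a scalar")
    return ScoreModel(specs=specs, layers=built, input_spec=spec,
                      flat_features=flat_features)


def predict_pose(m: ScoreModel, g: VoxelGrid) -> float:
    """Score a single pose grid (pK units)."""
    expected = (m.input_spec.n_channels,) + (m.input_spec.n,) * 3
    if g.values.shape != expected:
        raise ValueError(f"grid shape {g.values.shape} != model input {expected}")
    x = g.values[None].astype(np.float32)
    return float(m.forward(x)[0])


def predict_batch(m: ScoreModel, grids: Sequence[VoxelGrid]) -> np.ndarray:
    x = np.stack([g.values for g in grids]).astype(np.float32)
    return m.forward(x)


def ensemble_score(scores: Sequence[float],
                   p: EnsembleParams = EnsembleParams()) -> float:
    """Boltzmann-weighted average of pose scores, overflow-safe."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("ensemble_score needs at least one pose score")
    z = p.beta * s
    z -= z.max()  # max-shift: weights unchanged, no overflow
    w = np.exp(z)
    return float(np.sum(s * w) / np.sum(w))


def train(m: ScoreModel, data: Sequence[tuple[VoxelGrid, float]],
          cfg: TrainConfig = TrainConfig()) -> tuple[ScoreModel, list[float]]:
    """Train in place by mini-batch Adam on MSE; returns (model, history).

    History holds the mean per-batch training MSE of each epoch. Shuffling
    and (via ``build_model``) initialization are reproducible from seeds.
    """
    if not data:
        raise ValueError("training data is empty")
    y = np.array([lbl for _, lbl in data], dtype=np.float32)
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    X = np.stack([g.values for g, _ in data]).astype(np.float32)
    n = len(data)
    rng = np.random.default_rng(cfg.rng_seed)
    opt = nnet.Adam(m.parameters, lr=cfg.learning_rate)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            pred = m.forward(xb, need_grad=True)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss is not finite at epoch {epoch}; try a lower "
                    f"learning rate than {cfg.learning_rate}")
            losses.append(loss)
            if cfg.learning_rate > 0:
                m.backward(2.0 * err / len(idx))
                opt.step(m.gradients())
        history.append(float(np.mean(losses)))
    return m, history


def mse(m: ScoreModel, data: Sequence[tuple[VoxelGrid, float]]) -> float:
    """Mean squared error of the current parameters on a dataset."""
    y = np.array([lbl for _, lbl in data], dtype=np.float32)
    X = np.stack([g.values for g, _ in data]).astype(np.float32)
    pred = m.forward(X)
    return float(np.mean((pred - y) ** 2))


@dataclass
class ScreenResult:
    rank: int
    compound_id: str
    score: float  # NaN when no pose could be placed
    n_poses_accepted: int
    flags: str = ""


def screen(m: ScoreModel, lib: Sequence[MolGraph], s: Structure,
           site: BindingSite, *, n_poses: int = 16, t_max: float = 4.0,
           clash_factor: float = 0.75,
           ensemble: EnsembleParams = EnsembleParams(),
           grid_spec: GridSpec | None = None,
           rng_seed: int = 0) -> list[ScreenResult]:
    """Score and rank a compound library against one site.

    Per compound: sample poses, rasterize each, score each, combine by
    Boltzmann averaging. Ranking is descending by score with ties broken
    lexicographically by compound id; compounds with no placeable pose are
    ranked last and flagged rather than dropped. Fully deterministic given
    the model parameters and ``rng_seed``.
    """
    import zlib

    def compound_seed(mol: MolGraph) -> int:
        # content-derived: identical compounds get identical pose streams,
        # and the result does not depend on library order
        if mol.smiles:
            content = mol.smiles.encode()
        else:
            content = (",".join(mol.atoms).encode()
                       + np.round(mol.coords, 6).tobytes())
        return (zlib.crc32(content) ^ (rng_seed * 2654435761)) % (2 ** 31 - 1)

    grid_spec = grid_spec or m.input_spec
    scored: list[ScreenResult] = []
    for mol in lib:
        sub_seed = compound_seed(mol)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                poses = sample_poses(s, mol, site, n_poses=n_poses, t_max=t_max,
                                     clash_factor=clash_factor, rng_seed=sub_seed)
        except NoPlaceablePoseError:
            scored.append(ScreenResult(0, mol.id, float("nan"), 0,
                                       flags="no_placeable_pose"))
            continue
        grids = [rasterize(s, pose, site, grid_spec) for pose in poses]
        pose_scores = predict_batch(m, grids)
        final = ensemble_score(pose_scores, ensemble)
        flags = "" if len(poses) == n_poses else "partial_poses"
        scored.append(ScreenResult(0, mol.id, final, len(poses), flags))

    placed = [r for r in scored if np.isfinite(r.score)]
    failed = [r for r in scored if not np.isfinite(r.score)]
    placed.sort(key=lambda r: (-r.score, r.compound_id))
    failed.sort(key=lambda r: r.compound_id)
    ranked = placed + failed
    for k, r in enumerate(ranked, start=1):
        r.rank = k
    return ranked


def write_screen_csv(results: Sequence[ScreenResult], path: str | Path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "compound_id", "score", "n_poses_accepted", "flags"])
        for r in results:
            w.writerow([r.rank, r.compound_id, repr(r.score),
                        r.n_poses_accepted, r.flags])


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(m: ScoreModel, path: str | Path) -> None:
    """Save layer specs + parameters to a single self-describing .npz."""
    header = {
        "specs": [vars(ls) for ls in m.specs],
        "grid": {"n": m.input_spec.n, "spacing": m.input_spec.spacing},
    }
    arrays = {f"param_{i}": p for i, p in enumerate(m.parameters)}
    np.savez(path, header=json.dumps(header), **arrays)


def load_model(path: str | Path) -> ScoreModel:
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["header"]))
        specs = [LayerSpec(**d) for d in header["specs"]]
        gspec = GridSpec(n=header["grid"]["n"], spacing=header["grid"]["spacing"])
        m = build_model(specs, gspec, rng_seed=0)
        params = m.parameters
        for i, p in enumerate(params):
            p[...] = npz[f"param_{i}"]
    return m
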