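"""Reference U-Net predictors, training callbacks, and binarization.

The predictor contract is deliberately thin: anything that can turn a
Volume into a foreground-probability Volume can feed the voting and
evaluation modules, so externally trained models slot in by simply
providing aligned masks.  The bundled implementation is a compact NumPy
U-Net (see :mod:`voteseg._unet`) configured by :class:`ModelSpec`.

Three input modes map onto the view decompositions: ``2d`` runs per slice
of one orthogonal view, ``2.5d`` runs per three-channel axial slab, and
``3d`` runs per non-overlapping patch.  Stock specifications follow the
reference configuration: 3^d convolutions (stride 1, zero-padding), 2^d
max pooling, 4 levels, 32 first-layer features, ReLU, a dual-class
softmax head, Adam at 1e-4 on binary cross-entropy, batch 12 (2D/2.5D) or
6 (3D), 150 or 200 epochs, learning rate multiplied by 0.95 after 10
epochs without validation improvement, and early stopping after 50.
Full-size inputs are 512x512x1 (2D), 512x512x3 (2.5D) and a 64x64x128
cuboid (3D); reduced variants train in seconds on a CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._unet import Adam, NumpyUNet
from .errors import DataError, ParameterError, SpecError
from .io_preprocess import BinaryMask, Volume
from .views import (
    ViewStack,
    extract_slices,
    make_slabs,
    stack_to_volume,
    tile_patches,
    assemble_patches,
)

Mode = Literal["2d", "2.5d", "3d"]

_MODE_DEFAULTS = {
    "2d": dict(input_shape=(512, 512, 1), batch=12, epochs=150),
    "2.5d": dict(input_shape=(512, 512, 3), batch=12, epochs=150),
    "3d": dict(input_shape=(64, 64, 128), batch=6, epochs=200),
}


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters of one U-Net."""

    mode: Mode
    view: str = "axial"  # which orthogonal view a 2d model consumes
    depth: int = 4
    first_features: int = 32
    input_shape: tuple[int, ...] | None = None
    lr0: float = 1e-4
    batch: int | None = None
    epochs: int | None = None
    lr_decay_factor: float = 0.95
    lr_patience: int = 10
    early_stop_patience: int = 50
    # HU normalisation applied before the first convolution
    input_center: float = 0.0
    input_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.mode not in _MODE_DEFAULTS:
            raise SpecError(f"unknown mode {self.mode!r}")
        d = _MODE_DEFAULTS[self.mode]
        if self.input_shape is None:
            self.input_shape = d["input_shape"]
        if self.batch is None:
            self.batch = d["batch"]
        if self.epochs is None:
            self.epochs = d["epochs"]
        if self.depth < 1 or self.first_features < 1 or self.batch < 1:
            raise SpecError("depth, first_features, batch must all be >= 1")
        if self.lr0 <= 0:
            raise SpecError("lr0 must be positive")

    @property
    def spatial_ndim(self) -> int:
        return 3 if self.mode == "3d" else 2

    @property
    def in_channels(self) -> int:
        return 3 if self.mode == "2.5d" else 1

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        if self.mode == "3d":
            return tuple(self.input_shape)
        return tuple(self.input_shape[:2])


def _check_divisible(spatial: Sequence[int], depth: int) -> None:
    f = 2 ** (depth - 1)
    if any(s % f != 0 for s in spatial):
        raise SpecError(
            f"spatial extent {tuple(spatial)} not divisible by 2^(depth-1)={f}"
        )


@dataclass
class Predictor:
    """A trainable U-Net with a name usable in voting schemes."""

    spec: ModelSpec
    net: NumpyUNet
    name: str = "unet"

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability for one channel-first frame/patch."""
        z = (np.asarray(x, dtype=float) - self.spec.input_center) / self.spec.input_scale
        return self.net.predict_proba(z)

    def n_params(self) -> int:
        return self.net.n_params()


def build_predictor(spec: ModelSpec, seed: int = 0, name: str = "unet") -> Predictor:
    """Instantiate an untrained, seed-initialised network for a spec."""
    _check_divisible(spec.spatial_shape, spec.depth)
    net = NumpyUNet(
        spatial_ndim=spec.spatial_ndim,
        in_channels=spec.in_channels,
        depth=spec.depth,
        first_features=spec.first_features,
        seed=seed,
    )
    return Predictor(spec=spec, net=net, name=name)


# ---------------------------------------------------------------------------
# Training loop with plateau LR decay and early stopping
# ---------------------------------------------------------------------------


class PlateauSchedule:
    """Reduce-on-plateau LR decay plus early stopping.

    The baseline is the validation loss *before* the first epoch; after
    any ``lr_patience`` consecutive epochs without improvement the LR is
    multiplied by ``factor`` (and the window restarts), and after
    ``stop_patience`` consecutive stalled epochs training stops.
    """

    def __init__(self, lr0: float, factor: float = 0.95,
                 lr_patience: int = 10, stop_patience: int = 50):
        self.lr = lr0
        self.factor = factor
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.best = np.inf
        self._wait_lr = 0
        self._wait_stop = 0

    def set_baseline(self, val_loss: float) -> None:
        self.best = val_loss

    def update(self, val_loss: float) -> tuple[float, bool]:
        """Record one epoch's validation loss; returns (new LR, stop?)."""
        if val_loss < self.best:
            self.best = val_loss
            self._wait_lr = 0
            self._wait_stop = 0
        else:
            self._wait_lr += 1
            self._wait_stop += 1
        if self._wait_lr >= self.lr_patience:
            self.lr *= self.factor
            self._wait_lr = 0
        return self.lr, self._wait_stop >= self.stop_patience


def _as_pairs(pairs, what: str):
    pairs = list(pairs)
    if not pairs:
        raise DataError(f"{what} set is empty")
    out = []
    for x, t in pairs:
        x = np.asarray(x, dtype=float)
        t = np.asarray(t)
        if x.ndim == t.ndim:  # no channel axis supplied
            x = x[None]
        if not np.isin(np.unique(t), (0, 1)).all():
            raise DataError("targets must be binary")
        out.append((x, t.astype(float)))
    return out


def train(
    pred: Predictor,
    train_pairs,
    val_pairs,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> tuple[Predictor, list[dict]]:
    """Optimise BCE with Adam under the plateau/early-stop callbacks.

    ``train_pairs`` / ``val_pairs`` are (input, binary target) frames or
    patches.  Returns the predictor (updated in place) and a history with
    one entry per completed epoch: train loss, validation loss, and the LR
    in effect during that epoch.
    """
    spec = spec or pred.spec
    tr = _as_pairs(train_pairs, "training")
    va = _as_pairs(val_pairs, "validation")
    rng = np.random.default_rng(seed)
    opt = Adam(pred.net.params(), lr=spec.lr0)
    sched = PlateauSchedule(
        spec.lr0, spec.lr_decay_factor, spec.lr_patience, spec.early_stop_patience
    )

    def norm(x):
        return (x - spec.input_center) / spec.input_scale

    def val_loss() -> float:
        return float(np.mean([pred.net.loss(norm(x), t) for x, t in va]))

    sched.set_baseline(val_loss())
    history: list[dict] = []
    for epoch in range(1, spec.epochs + 1):
        lr_used = sched.lr
        opt.lr = lr_used
        order = rng.permutation(len(tr))
        losses = []
        for start in range(0, len(tr), spec.batch):
            chunk = order[start:start + spec.batch]
            pred.net.zero_grad()
            batch_loss = 0.0
            for i in chunk:
                x, t = tr[i]
                batch_loss += pred.net.loss_and_grad(norm(x), t)
            for _, g in pred.net.params():
                g /= len(chunk)
            opt.step()
            losses.append(batch_loss / len(chunk))
        vl = val_loss()
        new_lr, stop = sched.update(vl)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": vl, "lr": lr_used}
        )
        if stop:
            break
    return pred, history


# ---------------------------------------------------------------------------
# Whole-volume inference
# ---------------------------------------------------------------------------


def predict_volume(pred, vol: Volume) -> Volume:
    """Run a predictor over a whole volume, reassembling probabilities.

    Dispatches on ``pred.spec.mode``: per-view slices (2d), axial slabs
    (2.5d), or non-overlapping patches (3d, zero-padded then cropped).
    Any object with a ``spec`` and a ``forward(channel-first array)``
    method satisfies the contract.
    """
    spec = pred.spec
    if spec.mode == "2d":
        stack = extract_slices(vol, spec.view)
        _check_divisible(stack.frames[0].shape, spec.depth)
        probs = [np.asarray(pred.forward(f[None]), dtype=float) for f in stack.frames]
        out = ViewStack(
            view=stack.view, frames=probs, index_map=stack.index_map,
            source_shape=stack.source_shape, spacing=stack.spacing, is_mask=False,
        )
        return stack_to_volume(out)  # type: ignore[return-value]
    if spec.mode == "2.5d":
        slabs = make_slabs(vol)
        _check_divisible(slabs.frames[0].shape[1:], spec.depth)
        probs = [np.asarray(pred.forward(f), dtype=float) for f in slabs.frames]
        out = ViewStack(
            view="axial", frames=probs, index_map=slabs.index_map,
            source_shape=slabs.source_shape, spacing=slabs.spacing, is_mask=False,
        )
        return stack_to_volume(out)  # type: ignore[return-value]
    if spec.mode == "3d":
        patch_shape = tuple(spec.input_shape)
        _check_divisible(patch_shape, spec.depth)
        grid = tile_patches(vol, patch_shape=patch_shape)  # type: ignore[arg-type]
        grid = dataclasses.replace(
            grid,
            patches=[np.asarray(pred.forward(p[None]), dtype=float)
                     for p in grid.patches],
            is_mask=False,
        )
        return assemble_patches(grid)  # type: ignore[return-value]
    raise SpecError(f"unknown mode {spec.mode!r}")


def binarize(prob: Volume, tau: float = 0.5) -> BinaryMask:
    """Threshold a probability volume: foreground where prob >= tau.

    For two softmax classes, tau = 0.5 reproduces the argmax decision;
    an exact tie goes to foreground.
    """
    if not 0.0 < tau < 1.0:
        raise ParameterError(f"tau must lie in (0, 1), got {tau}")
    data = np.asarray(prob.data, dtype=float)
    if data.min() < 0.0 or data.max() > 1.0:
        raise ParameterError("probability volume must lie in [0, 1]")
    return BinaryMask(data=data >= tau, spacing=prob.spacing)
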