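"""Training loop, Adam optimizer, and volume-level inference."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import PatchSet, _fit_2d, dihedral_orbit
from ..volume import Volume
from .losses import LossComponents, multitask_loss
from .network import MultitaskNet


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4  # Adam initial step size
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    #: False/"none", "flip" (left-right mirror, x2 data), or True/"dihedral"
    #: (full 8-element orbit, x8 data)
    augment: bool | str = True
    recon_weight: float = 1.0
    dice_weight: float = 1.0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, parameters, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.parameters = parameters  # list of (layer, name)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(l.params[n]) for l, n in parameters]
        self.v = [np.zeros_like(l.params[n]) for l, n in parameters]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self.parameters):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            layer.params[name] = (layer.params[name]
                                  - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                                  ).astype(np.float32)


def _as_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(net: MultitaskNet, patches: PatchSet, tc: TrainConfig
          ) -> tuple[MultitaskNet, list[LossComponents]]:
    """Train in place; returns the net and the per-epoch mean loss history.

    Fully deterministic for a fixed (net init, TrainConfig.seed) pair.
    Optional augmentation expands the patch set by the full 8-element
    dihedral orbit of every patch once, up front.
    """
    if len(patches) == 0:
        raise ValueError("cannot train on an empty patch set")
    rng = np.random.default_rng(tc.seed)
    xs, ys = list(patches.patches), list(patches.masks)
    mode = {True: "dihedral", False: "none"}.get(tc.augment, tc.augment)
    if mode == "dihedral":
        aug_x, aug_y = [], []
        for p, m in zip(xs, ys):
            for pa, ma in dihedral_orbit(p, m):
                aug_x.append(pa)
                aug_y.append(ma)
        xs, ys = aug_x, aug_y
    elif mode == "flip":
        xs = xs + [np.ascontiguousarray(np.flip(p, 0)) for p in xs]
        ys = ys + [np.ascontiguousarray(np.flip(m, 0)) for m in ys]
    elif mode != "none":
        raise ValueError(f"unknown augment mode {tc.augment!r}")
    X = np.stack(xs)[:, None].astype(np.float32)
    Y = np.stack(ys)[:, None].astype(np.float32)

    history: list[LossComponents] = []
    for _ in range(tc.epochs):
        if not hasattr(net, "_optimizer"):
            net._optimizer = Adam(net.parameters(), tc.learning_rate)
        totals = np.zeros(3)
        nb = 0
        for idx in _as_batches(len(X), tc.batch_size, rng):
            out = net.forward(X[idx], train=True)
            comps, grads = multitask_loss(X[idx], Y[idx], out,
                                          tc.recon_weight, tc.dice_weight)
            net.backward(grads["dO"], grads["dF"], grads["dB"])
            net._optimizer.step()
            totals += (comps.reconstruction, comps.dice, comps.total)
            nb += 1
        history.append(LossComponents(*(totals / nb)))
    return net, history


def predict_volume(net: MultitaskNet, v: Volume, threshold: float = 0.5,
                   batch_size: int = 8) -> Volume:
    """Segment a preprocessed (windowed, resampled) volume slice by slice.

    Axial frames are center-cropped/zero-padded to the nearest side the
    network accepts, probabilities are mapped back onto the volume grid, and
    the result is binarized at ``threshold``.
    """
    if not hasattr(net, "forward"):
        raise ValueError("net does not look like a model (missing forward)")
    div = 2 ** (net.cfg.levels - 1)
    nx, ny, nz = v.shape
    side = max(int(np.ceil(max(nx, ny) / div)) * div, div)
    frames = np.stack([_fit_2d(v.data[:, :, z].astype(np.float32), side)
                       for z in range(nz)])[:, None]
    probs = np.empty((nz, side, side), dtype=np.float32)
    for start in range(0, nz, batch_size):
        out = net.forward(frames[start:start + batch_size], train=False)
        probs[start:start + batch_size] = out.O[:, 0]
    # undo the center crop/pad per axis
    mask = np.zeros(v.shape, dtype=bool)
    dx0, sx0 = max((side - nx) // 2, 0), max((nx - side) // 2, 0)
    dy0, sy0 = max((side - ny) // 2, 0), max((ny - side) // 2, 0)
    cx, cy = min(nx, side), min(ny, side)
    binary = probs >= threshold
    mask[sx0:sx0 + cx, sy0:sy0 + cy, :] = binary[:, dx0:dx0 + cx, dy0:dy0 + cy].transpose(1, 2, 0)
    return Volume(mask, v.spacing_mm, v.origin_mm)
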