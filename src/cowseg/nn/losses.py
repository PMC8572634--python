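"""The multitask reconstruction-plus-Dice loss and its gradients.

For a batch of images I with ground-truth binary masks S and network outputs
(O, F, B), the total objective is

    J = mean_pixels[(I - (F*O + B*(1-O)))^2]
        + mean_batch[ 1 - 2*sum(O*S) / (sum(O^2) + sum(S^2) + eps) ]

The first term asks the model to explain the input as a probability-weighted
blend of a foreground image and a background image — the segmentation map O
is the blending weight, so reconstruction quality directly supervises it.
The second is the soft Dice loss with per-image spatial sums. With eps in
numerator and denominator an all-empty (S = O = 0) image contributes a Dice
term of 0, i.e. counts as perfect agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import MultitaskOutput

EPSILON = 1e-6


@dataclass
class LossComponents:
    reconstruction: float
    dice: float
    total: float


def _check_shapes(I, S, out: MultitaskOutput):
    shapes = {I.shape, S.shape, out.O.shape}
    if out.F is not None:
        shapes |= {out.F.shape, out.B.shape}
    if len(shapes) != 1:
        raise ValueError(f"image/mask/output shape mismatch: {shapes}")


def dice_loss(O: np.ndarray, S: np.ndarray,
              eps: float = EPSILON) -> tuple[float, np.ndarray]:
    """Soft Dice loss, per-image spatial sums averaged over the batch.

    Arrays are NCHW (or any layout whose axis 0 is the batch). Returns the
    scalar loss and its gradient with respect to O.
    """
    O = np.asarray(O, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if O.shape != S.shape:
        raise ValueError(f"shape mismatch {O.shape} vs {S.shape}")
    nb = O.shape[0]
    ax = tuple(range(1, O.ndim))
    num = 2.0 * (O * S).sum(axis=ax) + eps
    den = (O * O).sum(axis=ax) + (S * S).sum(axis=ax) + eps
    loss = float(np.mean(1.0 - num / den))
    # d/dO_i of (num/den) = (2*S_i*den - num*2*O_i) / den^2
    bshape = (nb,) + (1,) * (O.ndim - 1)
    dO = -(2.0 * S * den.reshape(bshape) - num.reshape(bshape) * 2.0 * O) \
        / (den ** 2).reshape(bshape) / nb
    return loss, dO.astype(np.float32)


def multitask_loss(I: np.ndarray, S: np.ndarray, out: MultitaskOutput,
                   recon_weight: float = 1.0, dice_weight: float = 1.0,
                   eps: float = EPSILON):
    """Total loss J = recon_weight * reconstruction + dice_weight * Dice term.

    Returns (LossComponents, grads) where grads is a dict with dO, dF, dB
    (dF/dB are None for a single-task output). The default unit weights make
    J exactly the sum of the two terms.
    """
    I = np.asarray(I, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    _check_shapes(I, S, out)
    O = np.asarray(out.O, dtype=np.float64)

    dice_val, dO_dice = dice_loss(O, S, eps)
    grads = {"dF": None, "dB": None}
    if out.F is not None:
        F = np.asarray(out.F, dtype=np.float64)
        B = np.asarray(out.B, dtype=np.float64)
        residual = I - (F * O + B * (1.0 - O))
        n = I.size
        recon = float(np.mean(residual ** 2))
        dresid = -2.0 * residual / n
        grads["dF"] = (dresid * O).astype(np.float32) * recon_weight
        grads["dB"] = (dresid * (1.0 - O)).astype(np.float32) * recon_weight
        dO_recon = (dresid * (F - B)).astype(np.float32)
    else:
        recon = 0.0
        dO_recon = np.zeros_like(dO_dice)

    grads["dO"] = recon_weight * dO_recon + dice_weight * dO_dice
    total = recon_weight * recon + dice_weight * dice_val
    return LossComponents(recon, dice_val, total), grads
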