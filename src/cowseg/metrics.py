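"""Segmentation evaluation: Dice overlap and per-segment detection accuracy.

The Dice coefficient DC = 2|O∩T| / (|O| + |T|) measures set overlap between
a predicted binary mask O and the reference T; 1 is perfect agreement, 0 is
no overlap. Per-segment detection accuracy replaces expert visual review of
whether each Circle-of-Willis segment was captured: a mechanical rule based
on ground-truth centerline coverage, documented as a surrogate, decides
"present" per case and is compared with the generative status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import Phantom
from .volume import Volume


@dataclass
class SegmentationScore:
    dice: float
    n_pred: int
    n_truth: int
    n_overlap: int


def dice_coefficient(pred: Volume | np.ndarray, truth: Volume | np.ndarray) -> SegmentationScore:
    """Exact set-overlap Dice between two binary masks on the same grid.

    Both-empty masks score 1 by convention (perfect agreement on "nothing").
    """
    p = pred.data if isinstance(pred, Volume) else np.asarray(pred)
    t = truth.data if isinstance(truth, Volume) else np.asarray(truth)
    if isinstance(pred, Volume) and isinstance(truth, Volume) and not pred.same_grid(truth):
        raise ValueError("prediction and truth are on different grids")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    n_p, n_t = int(p.sum()), int(t.sum())
    n_o = int(np.logical_and(p, t).sum())
    dice = 1.0 if (n_p + n_t) == 0 else 2.0 * n_o / (n_p + n_t)
    return SegmentationScore(dice, n_p, n_t, n_o)


def segment_present_in_prediction(pred: Volume, phantom: Phantom, segment: str,
                                  coverage_threshold: float = 0.5,
                                  dilation_voxels: int = 1,
                                  junction_trim_mm: float = 1.5) -> bool:
    """Centerline-coverage presence call.

    A segment is called present when at least ``coverage_threshold`` of its
    ground-truth centerline sample points fall inside the predicted mask
    dilated by ``dilation_voxels``. Samples within ``junction_trim_mm`` of
    either centerline end are excluded: the endpoints sit inside the lumina
    of the neighbouring arteries, so without trimming a correctly segmented
    neighbourhood would "cover" the stumps of an absent communicating segment
    (the same confusion that makes close bilateral ACAs read as an Aco on
    real angiograms). For generative status "absent" the matching outcome is
    a failed coverage test on the nominal (non-absent) geometry.
    """
    seg = phantom.segment(segment)
    mask = pred.data.astype(bool)
    if dilation_voxels > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilation_voxels)
    cl = seg.centerline
    arclen = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(cl, axis=0), axis=1))])
    interior = (arclen >= junction_trim_mm) & (arclen <= arclen[-1] - junction_trim_mm)
    if interior.sum() >= 3:
        cl = cl[interior]
    idx = np.round(pred.world_to_voxel(cl)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(pred.shape)), axis=1)
    hits = np.zeros(len(idx), dtype=bool)
    ii = idx[inside]
    hits[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return float(hits.mean()) >= coverage_threshold


def segment_detection_accuracy(predictions: list[Volume], phantoms: list[Phantom],
                               segment: str, coverage_threshold: float = 0.5,
                               dilation_voxels: int = 1) -> float:
    """Fraction of cases where the presence call matches the generated status.

    Ground truth "present" = status normal or hypoplastic; "absent" = absent.
    """
    if len(predictions) != len(phantoms):
        raise ValueError("predictions and phantoms must align")
    if not phantoms:
        raise ValueError("empty cohort")
    correct = 0
    for pred, ph in zip(predictions, phantoms):
        truly_present = ph.segment(segment).status != "absent"
        called_present = segment_present_in_prediction(
            pred, ph, segment, coverage_threshold, dilation_voxels)
        correct += (called_present == truly_present)
    return correct / len(phantoms)


def detection_report(predictions: list[Volume], phantoms: list[Phantom],
                     segments=("A1", "P1", "Pco", "Aco")) -> dict[str, float]:
    """Per-segment-family detection accuracy; bilateral families (A1, P1, Pco)
    pool both sides."""
    out = {}
    for fam in segments:
        names = [fam] if fam == "Aco" else [fam + "_L", fam + "_R"]
        accs = [segment_detection_accuracy(predictions, phantoms, n) for n in names]
        out[fam] = float(np.mean(accs))
    return out
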