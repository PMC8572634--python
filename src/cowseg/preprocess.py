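"""CTA dataset preparation: isotropic resampling, intensity windowing,
axial patch extraction, and rigid augmentation.

The preparation pipeline mirrors standard practice for head-neck CTA
segmentation: volumes are resampled to a common isotropic spacing
(default 0.5 mm), intensities are clamped to the [0, 2000] HU band that
contains soft tissue, contrast-enhanced vessels and bone, rescaled to
[0, 1], and axial slices are cropped/padded to a fixed side length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume


def resample_isotropic(v: Volume, target_spacing: float = 0.5,
                       is_mask: bool = False) -> Volume:
    """Resample to isotropic spacing ``target_spacing`` mm.

    Output shape is round(shape * spacing / target) per axis; intensities are
    trilinearly interpolated, masks with nearest-neighbour.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if any(n == 0 for n in v.shape):
        raise ValueError("cannot resample a degenerate (zero-extent) volume")
    zoom = np.array(v.spacing_mm) / target_spacing
    out_shape = np.round(np.array(v.shape) * zoom).astype(int)
    if np.any(out_shape == 0):
        raise ValueError("target spacing coarser than the volume extent")
    data = v.data.astype(np.float32) if not is_mask else v.data
    resampled = ndimage.zoom(data, out_shape / np.array(v.shape),
                             order=0 if is_mask else 1, grid_mode=True,
                             mode="nearest", prefilter=False)
    if is_mask:
        resampled = resampled.astype(v.data.dtype)
    return Volume(resampled, (target_spacing,) * 3, v.origin_mm)


def window_intensity(v: Volume, lo: float = 0.0, hi: float = 2000.0) -> Volume:
    """Clamp HU values to [lo, hi] and rescale linearly to [0, 1].

    The band [0, 2000] HU removes the influence of air/background below and
    dense bone/metal above, keeping the grid intact for reconstruction.
    """
    if lo >= hi:
        raise ValueError("window requires lo < hi")
    data = (np.clip(v.data, lo, hi) - lo) / (hi - lo)
    return Volume(data.astype(np.float32), v.spacing_mm, v.origin_mm)


@dataclass
class PatchSet:
    """Aligned axial 2D patches and mask patches, with provenance."""

    patches: list[np.ndarray]
    masks: list[np.ndarray]
    provenance: list[tuple[int | str, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.patches) != len(self.masks):
            raise ValueError("patches and masks must align one-to-one")
        sides = {p.shape for p in self.patches} | {m.shape for m in self.masks}
        if len(sides) > 1:
            raise ValueError(f"inconsistent patch shapes: {sides}")

    def __len__(self):
        return len(self.patches)

    @property
    def side(self) -> int:
        return self.patches[0].shape[0] if self.patches else 0


def _fit_2d(arr: np.ndarray, side: int, pad_value: float = 0.0) -> np.ndarray:
    """Center-crop or zero-pad a 2D array to side x side."""
    out = np.full((side, side), pad_value, dtype=arr.dtype)
    h, w = arr.shape
    # source and destination windows for each axis
    sh0 = max((h - side) // 2, 0)
    sw0 = max((w - side) // 2, 0)
    dh0 = max((side - h) // 2, 0)
    dw0 = max((side - w) // 2, 0)
    ch, cw = min(h, side), min(w, side)
    out[dh0:dh0 + ch, dw0:dw0 + cw] = arr[sh0:sh0 + ch, sw0:sw0 + cw]
    return out


def extract_patches(v: Volume, m: Volume, side: int = 288,
                    drop_empty: bool = False,
                    volume_id: int | str = 0) -> PatchSet:
    """One patch per axial slice (z axis), center-cropped/zero-padded to
    ``side`` x ``side``. ``drop_empty`` discards slices with an empty mask."""
    if not v.same_grid(m):
        raise ValueError("image and mask volumes must share the same grid")
    patches, masks, prov = [], [], []
    for z in range(v.shape[2]):
        msl = m.data[:, :, z]
        if drop_empty and not np.any(msl):
            continue
        patches.append(_fit_2d(v.data[:, :, z].astype(np.float32), side))
        masks.append(_fit_2d(msl.astype(np.float32), side))
        prov.append((volume_id, z))
    return PatchSet(patches, masks, prov)


def augment(patch: np.ndarray, mask: np.ndarray,
            seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Apply the same random dihedral-group transform (k*90 deg rotation plus
    optional flip) to a patch and its mask.

    Restricting to the 8-element dihedral group keeps binary masks exact:
    arbitrary-angle rotation would require interpolation.
    """
    if patch.shape != mask.shape:
        raise ValueError("patch and mask shapes differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(rng.integers(0, 4))
    flip = bool(rng.integers(0, 2))
    p, m = np.rot90(patch, k), np.rot90(mask, k)
    if flip:
        p, m = np.flip(p, axis=0), np.flip(m, axis=0)
    return np.ascontiguousarray(p), np.ascontiguousarray(m)


def dihedral_orbit(patch: np.ndarray, mask: np.ndarray):
    """All 8 dihedral transforms of an aligned (patch, mask) pair."""
    out = []
    for k in range(4):
        p, m = np.rot90(patch, k), np.rot90(mask, k)
        out.append((np.ascontiguousarray(p), np.ascontiguousarray(m)))
        out.append((np.ascontiguousarray(np.flip(p, 0)),
                    np.ascontiguousarray(np.flip(m, 0))))
    return out
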