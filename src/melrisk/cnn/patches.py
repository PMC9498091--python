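"""Lesion field-of-view cropping, patch sampling and slice normalisation.

The network consumes 32x32x32 patches drawn from a fixed physical block
(default 132 x 160 x 250 mm, LR x AP x HF) centred on the target lesion and
resampled to an isotropic working grid (default 2 mm).  Each 3D patch is
sliced into 32 co-indexed (axial, coronal, sagittal) 2D triples; one triple
of one modality pair is one training sample.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..imaging_io import ValidationError, Volume

PATCH = 32

#: modality pairs fed to the (PET branch, anatomical branch)
MODALITY_PAIRS = {
    "PET_MR+VIBE": ("PET_MR", "MR_VIBE"),
    "PET_MR+ADC": ("PET_MR", "ADC"),
    "PET_CT+CT": ("PET_CT", "CT"),
}

SUBSET_PAIRS = {
    "both": ("PET_MR+VIBE", "PET_MR+ADC", "PET_CT+CT"),
    "PET_CT+CT": ("PET_CT+CT",),
    "PET_MR+MR": ("PET_MR+VIBE", "PET_MR+ADC"),
}


def lesion_fov_crop(
    volumes: dict[str, Volume],
    center_mm: tuple[float, float, float],
    extent_mm: tuple[float, float, float] = (132.0, 160.0, 250.0),
    working_spacing_mm: float = 2.0,
) -> dict[str, np.ndarray]:
    """Crop a fixed physical block around a lesion from each modality.

    All volumes are sampled on a common isotropic working grid centred on
    ``center_mm`` (physical coordinates); regions outside a volume are
    zero-padded.  Returns one 3D array per modality.
    """
    shape = tuple(
        max(1, int(round(e / working_spacing_mm))) for e in extent_mm
    )
    out: dict[str, np.ndarray] = {}
    for name, vol in volumes.items():
        c_idx = [
            (center_mm[d] - vol.origin[d]) / vol.spacing[d] for d in range(3)
        ]
        if any(c < 0 or c > vol.shape[d] - 1 for d, c in enumerate(c_idx)):
            raise ValidationError(
                f"lesion centre {center_mm} outside the {name} volume"
            )
        axes = [
            c_idx[d]
            + (np.arange(shape[d]) - (shape[d] - 1) / 2.0)
            * (working_spacing_mm / vol.spacing[d])
            for d in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        out[name] = ndimage.map_coordinates(
            np.asarray(vol.values, dtype=np.float32),
            np.stack(grid),
            order=1,
            mode="constant",
            cval=0.0,
        ).astype(np.float32)
    return out


def sample_patch_positions(
    block_shape: tuple[int, int, int], n: int, seed: int
) -> np.ndarray:
    """(n, 3) corner indices of 32^3 patches uniformly inside the block."""
    if any(s < PATCH for s in block_shape):
        raise ValidationError(
            f"block {block_shape} smaller than a {PATCH}^3 patch"
        )
    rng = np.random.default_rng(seed)
    highs = [s - PATCH + 1 for s in block_shape]
    return np.stack(
        [rng.integers(0, h, size=n) for h in highs], axis=1
    ).astype(int)


def sample_patches(
    block: np.ndarray, n: int = 384, seed: int = 0
) -> list[np.ndarray]:
    """Extract ``n`` seeded random 32^3 patches fully inside the block."""
    pos = sample_patch_positions(block.shape, n, seed)
    return [
        block[i : i + PATCH, j : j + PATCH, k : k + PATCH] for i, j, k in pos
    ]


def tile_patch_positions(
    block_shape: tuple[int, int, int], stride: int = 16
) -> np.ndarray:
    """Deterministic tiling of the block with 32^3 patches at a given stride,
    used for validation and test lesions."""
    if any(s < PATCH for s in block_shape):
        raise ValidationError(
            f"block {block_shape} smaller than a {PATCH}^3 patch"
        )
    axes = []
    for s in block_shape:
        starts = list(range(0, s - PATCH + 1, stride))
        if starts[-1] != s - PATCH:
            starts.append(s - PATCH)
        axes.append(starts)
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1).astype(int)


def slice_patch(patch: np.ndarray) -> np.ndarray:
    """Slice a 32^3 patch into 32 co-indexed orientation triples.

    Returns an array of shape (32, 3, 32, 32): triple i holds the axial
    (fixed z = i), coronal (fixed y = i) and sagittal (fixed x = i) slices.
    96 individual 2D slices per patch in total.
    """
    if patch.shape != (PATCH, PATCH, PATCH):
        raise ValidationError(f"patch must be {PATCH}^3, got {patch.shape}")
    axial = np.moveaxis(patch, 2, 0)  # (32, x, y)
    coronal = np.moveaxis(patch, 1, 0)  # (32, x, z)
    sagittal = patch  # (32, y, z) indexed by x
    return np.stack([axial, coronal, sagittal], axis=1).astype(np.float32)


def total_2d_patches(n_patients: int, patches_per_patient: int = 384) -> int:
    """Total number of 2D training slices: patients x patches x 96."""
    return n_patients * patches_per_patient * 3 * PATCH


#: normalisation windows per modality (applied slice-wise)
_CT_WINDOW = (-200.0, 300.0)
_SUL_CLIP = 15.0
_ADC_SCALE = 3000.0


def normalize_modality(slices: np.ndarray, modality: str) -> np.ndarray:
    """Map raw voxel values to [0, 1] per modality.

    PET: SUL clipped to [0, 15] then divided by 15.  CT: HU windowed
    [-200, 300].  VIBE: per-array z-score squashed through a sigmoid.  ADC:
    divided by 3000 (units 1e-6 mm^2/s) and clipped to [0, 1].
    """
    x = np.asarray(slices, dtype=np.float32)
    if modality in ("PET_CT", "PET_MR"):
        return np.clip(x, 0.0, _SUL_CLIP) / _SUL_CLIP
    if modality == "CT":
        lo, hi = _CT_WINDOW
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    if modality == "MR_VIBE":
        sd = x.std()
        if sd < 1e-6:
            return np.full_like(x, 0.5)
        z = (x - x.mean()) / sd
        return (1.0 / (1.0 + np.exp(-z))).astype(np.float32)
    if modality == "ADC":
        return np.clip(x / _ADC_SCALE, 0.0, 1.0)
    raise ValidationError(f"unknown modality {modality!r}")
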