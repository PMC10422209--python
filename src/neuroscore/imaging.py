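"""Volume reading, coronal mid-slice extraction and intensity normalization.

Consumes already-preprocessed (AC-PC corrected, skull-stripped, template-
registered) volumes; no preprocessing is performed here. The expected
conformant shape is 113 x 137 x 113 with axis order (sagittal, coronal,
axial); a different shape is a warning, not an error, because the slice
extraction only needs a sufficient coronal extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantom import LabeledImage

#: Conformant volume shape after template registration.
EXPECTED_SHAPE = (113, 137, 113)

#: 1-based index of the extracted coronal plane — the printed middle of a
#: 137-plane coronal axis.
CORONAL_MIDSLICE_1BASED = 69

#: Default position of the coronal axis in the voxel array.
CORONAL_AXIS = 1


@dataclass
class BrainVolume:
    """A 3D voxel array with subject metadata and provenance affine."""

    voxels: np.ndarray
    subject_id: str | None = None
    stage: str | None = None
    affine: np.ndarray | None = None
    path: str | None = None


def load_volume(
    path: str | Path, subject_id: str | None = None, stage: str | None = None
) -> BrainVolume:
    """Load a NIfTI volume, checking finiteness and the expected shape.

    Non-finite voxels are rejected with an error naming the affected count;
    an unexpected shape only warns.
    """
    import nibabel as nib

    path = Path(path)
    try:
        nii = nib.load(path)
        voxels = np.asarray(nii.dataobj, dtype=np.float64)
    except Exception as exc:  # corrupt or unreadable file
        raise IOError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    bad = int(np.size(voxels) - np.isfinite(voxels).sum())
    if bad:
        raise ValueError(f"volume {path} contains {bad} non-finite voxel(s)")
    if voxels.ndim == 3 and voxels.shape != EXPECTED_SHAPE:
        warnings.warn(
            f"volume shape {voxels.shape} differs from expected {EXPECTED_SHAPE}",
            stacklevel=2,
        )
    return BrainVolume(
        voxels=voxels, subject_id=subject_id, stage=stage,
        affine=np.asarray(nii.affine), path=str(path),
    )


def extract_coronal_midslice(
    volume: BrainVolume,
    coronal_axis: int = CORONAL_AXIS,
    plane_1based: int = CORONAL_MIDSLICE_1BASED,
) -> LabeledImage:
    """Extract the mid-coronal plane (plane 69 of 137, 1-based).

    ``coronal_axis`` is configurable because NIfTI orientation varies; the
    default matches the template-registered (sagittal, coronal, axial)
    convention, so a conformant 113x137x113 volume yields a 113x113 slice.
    """
    voxels = volume.voxels
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {voxels.shape}")
    extent = voxels.shape[coronal_axis]
    if extent < plane_1based:
        raise ValueError(
            f"coronal extent {extent} is smaller than required plane {plane_1based}"
        )
    pixels = np.take(voxels, plane_1based - 1, axis=coronal_axis)
    return LabeledImage(
        pixels=np.asarray(pixels, dtype=np.float64),
        subject_id=volume.subject_id or "",
        stage=volume.stage or "",
        path=volume.path,
    )


def normalize_intensity(image: LabeledImage | np.ndarray) -> LabeledImage | np.ndarray:
    """Min-max rescale pixels to [0, 1]; a constant image maps to zeros.

    Normalization is per image (not per dataset) so scanner-scale effects
    cancel; it is idempotent on its own output. Accepts either a
    :class:`LabeledImage` (returns a new one) or a bare array.
    """
    arr = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if not np.all(np.isfinite(arr)):
        raise ValueError("pixels must be finite")
    lo, hi = float(arr.min()), float(arr.max())
    scaled = np.zeros_like(arr, dtype=np.float64) if hi == lo else (arr - lo) / (hi - lo)
    if isinstance(image, LabeledImage):
        import dataclasses

        return dataclasses.replace(image, pixels=scaled)
    return scaled
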