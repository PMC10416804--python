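"""Segmentation of spheroid z-stacks into masks, cells and a reference surface.

The steps mirror a typical surface-rendering workflow for 3D invasion assays:
threshold the stack, label connected components (26-connectivity), crop the
stack at the Z-depth of the spheroid's widest point (single-photon imaging
cannot see past it), separate the bulk spheroid from escaped cells, and build
a morphologically smoothed reference surface around the spheroid so that
distance-travelled measurements reflect distance from the bulk mass rather
than from any elongated invasive protrusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volumes import LabeledMask, VoxelVolume

__all__ = [
    "segment_foreground",
    "crop_at_widest",
    "split_spheroid_and_cells",
    "smoothed_reference_surface",
    "mean_intensity",
    "ReferenceSurface",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: Default minimum object volume in μm³ (≈ a 2.5 μm-radius sphere); smaller
#: components are treated as noise specks.
DEFAULT_MIN_VOLUME = 65.0


def segment_foreground(volume: VoxelVolume, method: str = "otsu",
                       threshold: float | None = None,
                       min_volume: float = DEFAULT_MIN_VOLUME) -> LabeledMask:
    """Threshold a stack and label its connected components.

    Parameters
    ----------
    method : {"otsu", "fixed"}
        ``otsu`` picks the threshold from the intensity histogram; ``fixed``
        uses the supplied ``threshold``.
    min_volume : float
        Components smaller than this physical volume (μm³) are removed.

    Components are labeled with 26-connectivity and relabeled contiguously
    from 1.  An all-background result yields an empty mask with a warning.
    """
    if method not in ("otsu", "fixed"):
        raise ValueError(f"method must be 'otsu' or 'fixed', got {method!r}")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        flat = volume.intensities.ravel()
        if np.all(flat == flat[0]):
            thr = np.inf  # constant image: nothing stands out
        else:
            thr = float(threshold_otsu(volume.intensities))

    binary = volume.intensities > thr
    labels, n = ndimage.label(binary, structure=_STRUCT_26)
    if n:
        counts = np.bincount(labels.ravel())
        min_voxels = min_volume / volume.voxel_volume
        keep = np.flatnonzero(counts >= min_voxels)
        keep = keep[keep > 0]
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, keep.size + 1)
        labels = remap[labels]
        n = keep.size
    if n == 0:
        warnings.warn("segmentation produced no foreground objects", stacklevel=2)
        labels = np.zeros(volume.shape, dtype=np.int32)
    return LabeledMask(labels.astype(np.int32), volume.spacing)


def _largest_label(mask: LabeledMask) -> int:
    """Label of the largest-volume component; ties go to the lowest label."""
    counts = np.bincount(mask.labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))  # argmax returns the first (lowest) on ties
    n_tied = int(np.sum(counts == counts[best]))
    if n_tied > 1:
        warnings.warn(
            f"{n_tied} components tie for largest volume; choosing label {best}",
            stacklevel=3,
        )
    return best


def crop_at_widest(mask: LabeledMask) -> tuple[LabeledMask, float]:
    """Crop the stack from the imaging face to the spheroid's widest plane.

    The spheroid is taken as the largest-volume component.  The widest plane
    is the z-slice with maximal spheroid cross-sectional area; ties break
    toward the imaging face (z = 0).  Returns the cropped mask (everything
    from the face down to the widest plane) and the imaged depth of the
    spheroid in μm: the physical distance from the spheroid's topmost slice
    to the widest plane, so that an acquisition margin above the spheroid
    does not inflate the depth.
    """
    if mask.n_labels == 0:
        raise ValueError("cannot crop an empty mask")
    spheroid = _largest_label(mask)
    per_slice = np.count_nonzero(mask.labels == spheroid, axis=(1, 2))
    widest = int(np.argmax(per_slice))
    top = int(np.flatnonzero(per_slice)[0])
    z_depth = (widest - top) * mask.spacing[0]
    cropped = LabeledMask(mask.labels[: widest + 1].copy(), mask.spacing)
    return cropped, float(z_depth)


def split_spheroid_and_cells(mask: LabeledMask) -> tuple[LabeledMask, LabeledMask]:
    """Separate the bulk spheroid (largest component) from candidate cells.

    Returns ``(spheroid_mask, cells_mask)``; the spheroid carries label 1 and
    cells are relabeled contiguously from 1 preserving their original order.
    """
    if mask.n_labels == 0:
        raise ValueError("cannot split an empty mask")
    spheroid = _largest_label(mask)
    spheroid_labels = np.where(mask.labels == spheroid, 1, 0).astype(np.int32)

    cell_ids = [lid for lid in mask.label_ids if lid != spheroid]
    remap = np.zeros(max(mask.label_ids) + 1, dtype=np.int32)
    for new, old in enumerate(cell_ids, start=1):
        remap[old] = new
    cells_labels = remap[mask.labels]
    return (
        LabeledMask(spheroid_labels, mask.spacing),
        LabeledMask(cells_labels.astype(np.int32), mask.spacing),
    )


@dataclass
class ReferenceSurface:
    """Smoothed solid around the spheroid used as the distance reference.

    ``mask`` is the (closed) solid; ``surface`` marks its boundary voxels,
    i.e. mask voxels with at least one non-mask 6-neighbour.
    """

    mask: np.ndarray  # bool, (z, y, x)
    spacing: tuple[float, float, float]
    surface: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("reference surface mask is empty")
        eroded = ndimage.binary_erosion(self.mask)
        self.surface = self.mask & ~eroded

    @property
    def surface_voxel_indices(self) -> np.ndarray:
        return np.argwhere(self.surface)


def _dilate_ball(mask: np.ndarray, radius_um: float, spacing) -> np.ndarray:
    """Spacing-aware dilation by a Euclidean ball (via the distance transform)."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing) <= radius_um


def _erode_ball(mask: np.ndarray, radius_um: float, spacing) -> np.ndarray:
    """Spacing-aware erosion by a Euclidean ball: keep voxels deeper than the radius."""
    return ndimage.distance_transform_edt(mask, sampling=spacing) > radius_um


def smoothed_reference_surface(spheroid_mask: LabeledMask,
                               smoothing_scale: float) -> ReferenceSurface:
    """Morphologically smooth the spheroid at the given scale (μm).

    Opening (erosion then dilation) sheds protrusions thinner than
    ``smoothing_scale`` — elongated invasive cells still attached to the
    periphery must not pull the reference outward, since distances are meant
    to measure travel from the bulk spheroid core — and the subsequent
    closing fills comparably thin invaginations, so the reference encloses
    the bulk mass.  Both steps use a Euclidean ball realized through
    spacing-aware distance transforms.  ``smoothing_scale = 0`` returns the
    raw spheroid surface.  If the opening would erase the spheroid entirely
    (scale of the order of the spheroid radius), the opening is skipped with
    a warning.
    """
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be non-negative")
    binary = spheroid_mask.labels > 0
    if not binary.any():
        raise ValueError("spheroid mask is empty")
    if smoothing_scale == 0:
        return ReferenceSurface(binary, spheroid_mask.spacing)

    spacing = spheroid_mask.spacing
    pad = [int(np.ceil(smoothing_scale / s)) + 1 for s in spacing]
    padded = np.pad(binary, [(p, p) for p in pad], mode="constant")

    opened = _dilate_ball(_erode_ball(padded, smoothing_scale, spacing),
                          smoothing_scale, spacing)
    if not opened.any():
        warnings.warn(
            f"smoothing_scale {smoothing_scale} μm erases the whole spheroid; "
            "skipping the opening step",
            stacklevel=2,
        )
        opened = padded
    closed = _erode_ball(_dilate_ball(opened, smoothing_scale, spacing),
                         smoothing_scale, spacing)
    slices = tuple(slice(p, p + n) for p, n in zip(pad, binary.shape))
    return ReferenceSurface(closed[slices], spacing)


def mean_intensity(label_id: int, mask: LabeledMask, channel: VoxelVolume) -> float:
    """Arithmetic mean of channel intensities over one labeled object's voxels."""
    if channel.shape != mask.shape:
        raise ValueError(
            f"channel shape {channel.shape} does not match mask shape {mask.shape}"
        )
    voxels = mask.binary(label_id)  # KeyError if label missing
    return float(channel.intensities[voxels].mean())
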