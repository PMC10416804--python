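"""Core voxel-grid containers shared by the imaging modules.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` with ``z`` increasing away from the imaging
face (the glass/objective side of the well).  ``spacing`` is the physical
voxel pitch in micrometres per axis, in the same ``(z, y, x)`` order.
Physical coordinates refer to voxel centers: voxel ``(i, j, k)`` sits at
``(i*dz, j*dy, k*dx)`` μm.  Confocal stacks are typically anisotropic
(coarser in z), so spacing is carried everywhere rather than assumed unity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "LabeledMask"]


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries (z, y, x), got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive on all axes, got {spacing}")
    return spacing


@dataclass
class VoxelVolume:
    """A single-channel 3D fluorescence stack with physical voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Raw intensity grid in arbitrary units.
    spacing : tuple of float
        Voxel pitch in μm per axis, ``(z, y, x)``.
    channel_name : str
        Fluorescence channel label, e.g. ``"Dendra2-green"``.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    channel_name: str = "Dendra2-green"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3D array (z, y, x)")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in μm³."""
        return float(np.prod(self.spacing))

    def physical_extent(self) -> tuple[float, float, float]:
        """Extent spanned by voxel centers per axis, in μm."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    # -- I/O -----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write as multi-page TIFF with a JSON spacing sidecar (``.json``)."""
        path = Path(path)
        tifffile.imwrite(path, self.intensities, photometric="minisblack")
        sidecar = {
            "spacing_um_zyx": list(self.spacing),
            "channel_name": self.channel_name,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path, spacing=None, channel_name=None) -> "VoxelVolume":
        """Read a multi-page TIFF; spacing from the JSON sidecar unless overridden."""
        path = Path(path)
        data = tifffile.imread(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        meta = {}
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
        if spacing is None:
            spacing = meta.get("spacing_um_zyx")
        if spacing is None:
            raise ValueError(
                f"no voxel spacing: {sidecar_path.name} missing and no override given"
            )
        if channel_name is None:
            channel_name = meta.get("channel_name", "unknown")
        return cls(np.asarray(data), tuple(spacing), channel_name)


@dataclass
class LabeledMask:
    """Integer-labeled segmentation aligned with a :class:`VoxelVolume`.

    ``labels == 0`` is background; objects carry contiguous positive labels.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_ids: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 3D array (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _validate_spacing(self.spacing)
        ids = np.unique(self.labels)
        self.label_ids = tuple(int(i) for i in ids[ids > 0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_labels(self) -> int:
        return len(self.label_ids)

    def binary(self, label_id: int) -> np.ndarray:
        if label_id not in self.label_ids:
            raise KeyError(f"label {label_id} not present (have {self.label_ids})")
        return self.labels == label_id

    def voxel_count(self, label_id: int) -> int:
        return int(np.count_nonzero(self.binary(label_id)))

    def object_volume(self, label_id: int) -> float:
        """Physical volume of one labeled object in μm³ (voxel counting)."""
        return self.voxel_count(label_id) * self.voxel_volume

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.labels.astype(np.int32), photometric="minisblack")
        sidecar = {"spacing_um_zyx": list(self.spacing)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
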