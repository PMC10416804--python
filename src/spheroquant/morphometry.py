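"""Morphometric measurements: cell volume/area/sphericity, spheroid geometry.

Implements the three core formulas of the quantification workflow:

* estimated spheroid volume from the mean radius,  V = (4/3)·π·r³ with
  r = (a + b + z)/3, where a and b are the semi-axes of an ellipse fitted to
  the spheroid periphery at its widest plane and z is the imaging depth;
* lateral surface area of the imaged hemispheroid as a spherical cap,
  SA = π·(e² + z²), with e = (a + b)/2 the mean ellipsoid axis;
* Wadell sphericity Ψ = π^(1/3)·(6·V_p)^(2/3) / A_p per cell.

Cell volume is voxel counting; cell surface area comes from a spacing-aware
marching-cubes mesh (voxel-face counting would overestimate area by ~1.5×
and bias Ψ low).  Distances to the smoothed reference surface are
surface-to-surface, computed with a spacing-aware Euclidean distance
transform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import EllipseModel, find_contours, marching_cubes, mesh_surface_area

from .segmentation import ReferenceSurface
from .volumes import LabeledMask, VoxelVolume

__all__ = [
    "SpheroidGeometry",
    "measure_object",
    "sphericity",
    "fit_periphery_ellipse",
    "estimate_spheroid_volume",
    "cap_surface_area",
    "distance_to_reference",
    "measure_all_cells",
]


@dataclass
class SpheroidGeometry:
    """Size summary of one spheroid at one timepoint.

    a, b : μm — semi-axes of the periphery ellipse at the widest plane
    z    : μm — imaging (crop) depth
    r    : μm — mean radius, (a + b + z)/3
    e    : μm — mean ellipsoid axis, (a + b)/2
    V    : μm³ — estimated spheroid volume, (4/3)·π·r³
    SA   : μm² — spherical-cap surface area of the imaged hemispheroid
    """

    a: float
    b: float
    z: float
    r: float
    e: float
    V: float
    SA: float

    @classmethod
    def from_measurements(cls, a: float, b: float, z: float) -> "SpheroidGeometry":
        if a < b:
            a, b = b, a
        r, V = estimate_spheroid_volume(a, b, z)
        e = (a + b) / 2.0
        return cls(a=a, b=b, z=z, r=r, e=e, V=V, SA=cap_surface_area(e, z))

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("a", "b", "z", "r", "e", "V", "SA")}


def measure_object(label_id: int, mask: LabeledMask,
                   smooth_sigma: float = 0.8) -> tuple[float, float]:
    """Volume (μm³) and mesh surface area (μm²) of one labeled object.

    Volume is voxel count × voxel volume.  Area is a marching-cubes mesh at
    the 0.5 isolevel with physical spacing, extracted after a small Gaussian
    blur (``smooth_sigma`` voxels) of the binary — meshing a raw binary
    leaves a staircase surface whose area overestimates smooth objects by
    ~9% and does not improve with resolution.  Objects thinner than ~8
    voxels on any axis skip the blur (which would shave a large fraction of
    their area) and accept the bounded staircase bias instead.  The binary
    is zero-padded so objects touching the volume border are closed there
    (reported with a warning since the closing plane is an imaging
    artifact).
    """
    binary = mask.binary(label_id)
    volume = float(np.count_nonzero(binary)) * mask.voxel_volume
    bbox = ndimage.find_objects(binary.astype(np.int8))[0]
    min_extent = min(s.stop - s.start for s in bbox)

    touches_border = any(
        np.take(binary, [0, -1], axis=ax).any() for ax in range(3)
    )
    if touches_border:
        warnings.warn(
            f"object {label_id} touches the volume border; its open surface is "
            "closed at the border plane",
            stacklevel=2,
        )
    padded = np.pad(binary, 4, mode="constant").astype(np.float64)
    if smooth_sigma > 0 and min_extent >= 8:
        smoothed = ndimage.gaussian_filter(padded, smooth_sigma)
        if smoothed.max() <= 0.5:  # object thinner than the blur kernel
            smoothed = padded
    else:
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=mask.spacing)
    area = float(mesh_surface_area(verts, faces))
    return volume, area


def sphericity(V_p: float, A_p: float) -> float:
    """Wadell sphericity Ψ = π^(1/3)·(6·V_p)^(2/3) / A_p, in (0, 1] for true shapes."""
    if V_p <= 0 or A_p <= 0:
        raise ValueError("V_p and A_p must be positive")
    return math.pi ** (1.0 / 3.0) * (6.0 * V_p) ** (2.0 / 3.0) / A_p


def fit_periphery_ellipse(slice_mask: np.ndarray,
                          spacing_yx: tuple[float, float]) -> tuple[float, float]:
    """Least-squares ellipse fit to the boundary contour of the widest slice.

    Parameters
    ----------
    slice_mask : 2D bool array (y, x) — spheroid cross-section.
    spacing_yx : pixel pitch in μm.

    Returns ``(a, b)``: semi-major and semi-minor axes in μm.
    """
    slice_mask = np.asarray(slice_mask, dtype=bool)
    if slice_mask.ndim != 2 or not slice_mask.any():
        raise ValueError("slice mask must be a non-empty 2D array")
    contours = find_contours(slice_mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary contour found")
    contour = max(contours, key=len)  # outer periphery
    if len(contour) < 5:
        raise ValueError(f"only {len(contour)} boundary points; need at least 5")
    points = contour * np.asarray(spacing_yx)  # (y, x) μm

    model = EllipseModel.from_estimate(points[:, ::-1])  # EllipseModel wants (x, y)
    if not model:
        raise ValueError("ellipse fit failed on the boundary contour")
    ea, eb = model.axis_lengths
    a, b = max(ea, eb), min(ea, eb)
    if b < min(spacing_yx):
        raise ValueError("degenerate fit: minor semi-axis below one pixel")
    return float(a), float(b)


def estimate_spheroid_volume(a: float, b: float, z: float) -> tuple[float, float]:
    """Mean radius r = (a + b + z)/3 and estimated volume V = (4/3)·π·r³."""
    if min(a, b, z) <= 0:
        raise ValueError("a, b and z must be positive")
    r = (a + b + z) / 3.0
    return float(r), float(4.0 / 3.0 * math.pi * r**3)


def cap_surface_area(e: float, z: float) -> float:
    """Spherical-cap lateral surface area SA = π·(e² + z²).

    ``e`` is the cap's base radius (mean ellipsoid axis) and ``z`` its height
    (imaging depth); z = e recovers the hemisphere area 2π·e².
    """
    if e < 0 or z < 0:
        raise ValueError("e and z must be non-negative")
    if e == 0 and z == 0:
        raise ValueError("e and z cannot both be zero")
    return float(math.pi * (e**2 + z**2))


def distance_to_reference(cell_label: int, cells_mask: LabeledMask,
                          reference: ReferenceSurface,
                          mode: str = "surface") -> float:
    """Minimum Euclidean distance (μm) from a cell to the reference surface.

    Spacing-aware: the distance transform of the reference's boundary voxels
    is sampled at the cell.  ``mode="surface"`` (default) takes the minimum
    over the cell's voxels — attained on the cell surface — matching the
    "distance a cell has travelled" semantics; ``mode="centroid"`` samples at
    the voxel nearest the cell's centroid instead.  Cells overlapping or
    touching the reference solid return 0 in surface mode.
    """
    if mode not in ("surface", "centroid"):
        raise ValueError(f"mode must be 'surface' or 'centroid', got {mode!r}")
    if cells_mask.shape != reference.mask.shape:
        raise ValueError("cells mask and reference have different shapes")
    cell = cells_mask.binary(cell_label)
    edt = ndimage.distance_transform_edt(~reference.surface, sampling=cells_mask.spacing)
    if mode == "centroid":
        centroid = np.asarray(np.nonzero(cell)).mean(axis=1)
        idx = tuple(np.round(centroid).astype(int))
        return float(edt[idx])
    if np.any(cell & reference.mask):
        return 0.0
    return float(edt[cell].min())


def measure_all_cells(cells_mask: LabeledMask, reference: ReferenceSurface,
                      channel: VoxelVolume | None = None) -> pd.DataFrame:
    """Per-cell metrics table: V_p, A_p, Ψ, d, attachment, mean intensity.

    One distance transform is shared across cells.  ``attached`` means the
    cell overlaps/touches the reference solid (d = 0).
    """
    if cells_mask.n_labels and cells_mask.shape != reference.mask.shape:
        raise ValueError("cells mask and reference have different shapes")
    if channel is not None and channel.shape != cells_mask.shape:
        raise ValueError("intensity channel shape does not match the cells mask")
    edt = None
    rows = []
    for lid in cells_mask.label_ids:
        V_p, A_p = measure_object(lid, cells_mask)
        cell = cells_mask.binary(lid)
        if np.any(cell & reference.mask):
            d = 0.0
        else:
            if edt is None:
                edt = ndimage.distance_transform_edt(
                    ~reference.surface, sampling=cells_mask.spacing
                )
            d = float(edt[cell].min())
        row = {
            "cell_id": lid,
            "V_p": V_p,
            "A_p": A_p,
            "sphericity": sphericity(V_p, A_p),
            "distance": d,
            "attached": d == 0.0,
        }
        if channel is not None:
            row["mean_intensity"] = float(channel.intensities[cell].mean())
        rows.append(row)
    columns = ["cell_id", "V_p", "A_p", "sphericity", "distance", "attached"]
    if channel is not None:
        columns.append("mean_intensity")
    return pd.DataFrame(rows, columns=columns)
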