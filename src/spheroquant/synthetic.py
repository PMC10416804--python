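"""Synthetic imaging volumes and count matrices with known ground truth.

This module stands in for the microscope and the sequencer.  It produces

* 3D fluorescence stacks containing a dense central spheroid plus peripheral
  cells of controlled analytic shape (spheres, ellipsoids, capsules), with
  additive Gaussian noise, together with a ground-truth table of each cell's
  closed-form volume, surface area, sphericity, nearest distance to the
  spheroid, attachment flag and phenotype; and
* negative-binomial count matrices with a housekeeping-gene panel, planted
  phenotype marker blocks and log2 fold-changes, and a planted fraction of
  low-depth "failed" cells.

Rasterization rule: a voxel is foreground iff its *center* lies inside the
analytic shape.  This makes the voxel-counting measurement oracle exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .volumes import VoxelVolume

__all__ = [
    "CellSpec",
    "ImagingScenario",
    "CountScenario",
    "generate_volume",
    "generate_counts",
    "generate_timeseries",
    "synthetic_housekeeping_table",
]

PHENOTYPES = ("epithelial", "escaping", "amoeboid")
_SHAPES = ("sphere", "ellipsoid", "capsule")


@dataclass
class CellSpec:
    """One synthetic cell: an analytic shape placed in the volume.

    ``semi_axes`` are half-extents in μm per axis, ``(z, y, x)``.  For a
    sphere all three must agree; for a capsule the two minor axes must agree
    (the capsule's axis is the major one, and its cylinder half-length is
    ``max(semi_axes) - radius``).
    """

    shape: str
    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float]  # μm, (z, y, x)
    attached: bool = False
    true_phenotype: str = "amoeboid"

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        if self.true_phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")
        if np.isscalar(self.semi_axes):
            self.semi_axes = (float(self.semi_axes),) * 3
        self.semi_axes = tuple(float(s) for s in self.semi_axes)
        self.center = tuple(float(c) for c in self.center)
        if len(self.semi_axes) != 3 or len(self.center) != 3:
            raise ValueError("semi_axes and center must be (z, y, x) triplets")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")
        if self.shape == "sphere" and len(set(self.semi_axes)) != 1:
            raise ValueError("sphere requires equal semi-axes")
        if self.shape == "capsule":
            minor = sorted(self.semi_axes)[:2]
            if abs(minor[0] - minor[1]) > 1e-9 * max(self.semi_axes):
                raise ValueError("capsule requires its two minor semi-axes equal")

    # capsule decomposition -------------------------------------------------
    @property
    def _capsule_axis(self) -> int:
        return int(np.argmax(self.semi_axes))

    @property
    def _capsule_radius(self) -> float:
        return float(sorted(self.semi_axes)[0])

    @property
    def _capsule_half_length(self) -> float:
        """Half-length of the cylindrical section (0 degenerates to a sphere)."""
        return float(max(self.semi_axes) - self._capsule_radius)

    # closed-form ground truth ----------------------------------------------
    def volume(self) -> float:
        a, b, c = self.semi_axes
        if self.shape == "sphere":
            return geometry.sphere_volume(a)
        if self.shape == "ellipsoid":
            return geometry.ellipsoid_volume(a, b, c)
        return geometry.capsule_volume(self._capsule_radius, 2 * self._capsule_half_length)

    def surface_area(self) -> float:
        a, b, c = self.semi_axes
        if self.shape == "sphere":
            return geometry.sphere_surface_area(a)
        if self.shape == "ellipsoid":
            return geometry.ellipsoid_surface_area(a, b, c)
        return geometry.capsule_surface_area(self._capsule_radius, 2 * self._capsule_half_length)

    def sphericity(self) -> float:
        return geometry.wadell_sphericity(self.volume(), self.surface_area())

    # geometry queries -------------------------------------------------------
    def contains(self, Z: np.ndarray, Y: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Boolean mask of physical points (μm) inside the shape."""
        dz, dy, dx = (Z - self.center[0], Y - self.center[1], X - self.center[2])
        if self.shape == "sphere":
            r = self.semi_axes[0]
            return dz * dz + dy * dy + dx * dx <= r * r
        if self.shape == "ellipsoid":
            a, b, c = self.semi_axes
            return (dz / a) ** 2 + (dy / b) ** 2 + (dx / c) ** 2 <= 1.0
        axis = self._capsule_axis
        r, h = self._capsule_radius, self._capsule_half_length
        d = [dz, dy, dx]
        t = np.clip(d[axis], -h, h)
        d[axis] = d[axis] - t
        return d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= r * r

    def surface_points(self) -> np.ndarray:
        """Sampled points on the cell surface in absolute μm coords (N, 3)."""
        if self.shape == "sphere":
            pts = geometry.sample_ellipsoid_surface(*((self.semi_axes[0],) * 3))
        elif self.shape == "ellipsoid":
            pts = geometry.sample_ellipsoid_surface(*self.semi_axes)
        else:
            pts = geometry.sample_capsule_surface(
                self._capsule_radius, self._capsule_half_length, self._capsule_axis
            )
        return pts + np.asarray(self.center)

    def max_extent(self) -> float:
        return float(max(self.semi_axes))


@dataclass
class ImagingScenario:
    """Parameters of one synthetic acquisition.

    Defaults mirror a confocal spheroid-invasion acquisition at desk scale:
    anisotropic spacing (coarser in z), a bright Dendra2-green foreground on a
    dim background, and mild additive Gaussian noise.
    """

    grid_shape: tuple[int, int, int]  # voxels, (z, y, x)
    spheroid_center: tuple[float, float, float]  # μm, (z, y, x)
    spheroid_radius: float  # μm
    voxel_spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    cells: list[CellSpec] = field(default_factory=list)
    background_intensity: float = 10.0
    foreground_intensity: float = 200.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        self.spheroid_center = tuple(float(c) for c in self.spheroid_center)
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive on all axes")
        if self.spheroid_radius <= 0:
            raise ValueError("spheroid_radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        extent = self.physical_extent()
        for ax in range(3):
            lo = self.spheroid_center[ax] - self.spheroid_radius
            hi = self.spheroid_center[ax] + self.spheroid_radius
            if lo < -1e-9 or hi > extent[ax] + 1e-9:
                raise ValueError(
                    f"spheroid (radius {self.spheroid_radius} μm) exceeds volume "
                    f"bounds on axis {ax} ([0, {extent[ax]:.1f}] μm)"
                )
        for i, cell in enumerate(self.cells):
            for ax in range(3):
                lo = cell.center[ax] - cell.max_extent()
                hi = cell.center[ax] + cell.max_extent()
                if lo < -1e-9 or hi > extent[ax] + 1e-9:
                    raise ValueError(
                        f"cell {i} ({cell.shape} at {cell.center}) lies outside "
                        f"the volume bounds on axis {ax}"
                    )

    def physical_extent(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s for n, s in zip(self.grid_shape, self.voxel_spacing))


def _voxel_center_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _true_distance_to_spheroid(cell: CellSpec, center, radius) -> float:
    """Nearest distance (μm) from the cell surface to the spheroid sphere surface."""
    c0 = np.asarray(center, dtype=float)
    if cell.shape == "sphere":
        gap = float(np.linalg.norm(np.asarray(cell.center) - c0)) - radius - cell.semi_axes[0]
        return max(0.0, gap)
    pts = cell.surface_points()
    gap = float(np.min(np.linalg.norm(pts - c0, axis=1))) - radius
    return max(0.0, gap)


def generate_volume(scenario: ImagingScenario) -> tuple[VoxelVolume, pd.DataFrame]:
    """Rasterize a scenario into a noisy intensity stack plus its ground truth.

    Returns
    -------
    volume : VoxelVolume
    truth : DataFrame
        One row for the spheroid and one per cell: closed-form volume, surface
        area, sphericity, true nearest distance from the cell surface to the
        spheroid sphere, attachment flag and phenotype.
    """
    rng = np.random.default_rng(scenario.seed)
    Z, Y, X = _voxel_center_grids(scenario.grid_shape, scenario.voxel_spacing)

    c0 = scenario.spheroid_center
    fg = (Z - c0[0]) ** 2 + (Y - c0[1]) ** 2 + (X - c0[2]) ** 2 <= scenario.spheroid_radius**2
    for cell in scenario.cells:
        fg |= cell.contains(Z, Y, X)

    intensities = np.full(scenario.grid_shape, scenario.background_intensity, dtype=np.float64)
    intensities[fg] = scenario.foreground_intensity
    if scenario.noise_sigma > 0:
        intensities += rng.normal(0.0, scenario.noise_sigma, size=scenario.grid_shape)
    np.clip(intensities, 0.0, None, out=intensities)

    rows = [
        {
            "object_id": "spheroid",
            "shape": "sphere",
            "volume_um3": geometry.sphere_volume(scenario.spheroid_radius),
            "area_um2": geometry.sphere_surface_area(scenario.spheroid_radius),
            "sphericity": 1.0,
            "distance_um": np.nan,
            "attached": True,
            "phenotype": "",
        }
    ]
    for i, cell in enumerate(scenario.cells):
        d = 0.0 if cell.attached else _true_distance_to_spheroid(
            cell, scenario.spheroid_center, scenario.spheroid_radius
        )
        rows.append(
            {
                "object_id": f"cell_{i}",
                "shape": cell.shape,
                "volume_um3": cell.volume(),
                "area_um2": cell.surface_area(),
                "sphericity": cell.sphericity(),
                "distance_um": d,
                "attached": cell.attached,
                "phenotype": cell.true_phenotype,
            }
        )
    truth = pd.DataFrame(rows)
    return VoxelVolume(intensities, scenario.voxel_spacing), truth


def generate_timeseries(scenario: ImagingScenario, days, growth_rate: float,
                        escape_schedule) -> list[tuple[float, VoxelVolume, pd.DataFrame]]:
    """Simulate a multi-day invasion assay from a base scenario.

    The spheroid radius scales by ``growth_rate`` per day (relative to the
    first day); escaped cells accumulate according to ``escape_schedule`` and
    are placed at increasing distances from the spheroid surface.  The real
    assay provides no quantitative growth or escape model, so both are free
    parameters of the simulation.

    Parameters
    ----------
    days : sequence of numbers, strictly increasing.
    escape_schedule : mapping day -> number of *new* escaped cells appearing
        that day, or a sequence aligned with ``days``.
    """
    days = list(days)
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    if not isinstance(escape_schedule, dict):
        if len(escape_schedule) != len(days):
            raise ValueError("escape_schedule sequence must align with days")
        escape_schedule = dict(zip(days, escape_schedule))

    rng = np.random.default_rng(scenario.seed)
    extent = scenario.physical_extent()
    day0 = days[0]
    out = []
    cells: list[CellSpec] = list(scenario.cells)
    n_existing = 0
    for i, day in enumerate(days):
        radius = scenario.spheroid_radius * growth_rate ** (day - day0)
        for _ in range(int(escape_schedule.get(day, 0))):
            cell_r = 6.0
            dist = 20.0 + 14.0 * n_existing  # standoff from spheroid surface, μm
            c0 = np.asarray(scenario.spheroid_center)
            for _attempt in range(200):
                direction = rng.normal(size=3)
                direction[0] *= 0.25  # bias placement toward the equatorial plane
                direction /= np.linalg.norm(direction)
                # clamp the standoff so the cell stays inside the volume
                t_max = np.inf
                for ax in range(3):
                    if direction[ax] > 0:
                        t_max = min(t_max, (extent[ax] - cell_r - c0[ax]) / direction[ax])
                    elif direction[ax] < 0:
                        t_max = min(t_max, (cell_r - c0[ax]) / direction[ax])
                t = min(radius + dist + cell_r, t_max)
                if t < radius + cell_r + 2.0:  # no room to detach this way
                    continue
                center = c0 + direction * t
                break
            else:
                raise ValueError("could not place an escaped cell inside the volume")
            cells.append(
                CellSpec("sphere", (cell_r,) * 3, tuple(center), attached=False,
                         true_phenotype="amoeboid")
            )
            n_existing += 1
        day_scenario = ImagingScenario(
            grid_shape=scenario.grid_shape,
            spheroid_center=scenario.spheroid_center,
            spheroid_radius=radius,
            voxel_spacing=scenario.voxel_spacing,
            cells=list(cells),
            background_intensity=scenario.background_intensity,
            foreground_intensity=scenario.foreground_intensity,
            noise_sigma=scenario.noise_sigma,
            seed=(scenario.seed + 7919 * (i + 1)) % (2**31),
        )
        volume, truth = generate_volume(day_scenario)
        truth.insert(0, "day", day)
        out.append((day, volume, truth))
    return out


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountScenario:
    """Parameters of a synthetic plate-based single-cell count matrix.

    Defaults mirror the scale of the study this emulates: three phenotypes at
    12/16/16 cells, a 22-gene housekeeping panel with high baseline
    expression, per-phenotype marker blocks to create cluster structure, and
    negative-binomial noise (variance μ + μ²·dispersion).  "Failed" cells are
    ordinary cells with every mean multiplied by ``depth_scaling``.
    """

    n_genes: int = 300
    n_housekeeping: int = 22
    cells_per_phenotype: dict = field(
        default_factory=lambda: {"epithelial": 12, "escaping": 16, "amoeboid": 16}
    )
    base_mean: float = 20.0
    housekeeping_mean: float = 200.0
    dispersion: float = 0.3
    markers_per_phenotype: int = 25
    marker_log2fc: float = 3.0
    planted_log2fc: dict = field(default_factory=dict)  # gene -> {phenotype: lfc}
    n_zero_genes: int = 0
    low_quality_fraction: float = 0.0
    depth_scaling: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.low_quality_fraction <= 1:
            raise ValueError("low_quality_fraction must be in [0, 1]")
        if self.depth_scaling < 0:
            raise ValueError("depth_scaling must be non-negative")
        needed = (self.n_housekeeping + self.n_zero_genes
                  + self.markers_per_phenotype * len(self.cells_per_phenotype))
        if self.n_genes < needed:
            raise ValueError(f"n_genes={self.n_genes} too small for panel/marker/zero blocks ({needed})")
        for p in self.cells_per_phenotype:
            if p not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {p!r}")

    @property
    def housekeeping_genes(self) -> list[str]:
        return [f"HK_{i + 1:02d}" for i in range(self.n_housekeeping)]

    def gene_ids(self) -> list[str]:
        genes = list(self.housekeeping_genes)
        for p in self.cells_per_phenotype:
            genes += [f"MK_{p[:3].upper()}_{i + 1:03d}" for i in range(self.markers_per_phenotype)]
        genes += [f"ZERO_{i + 1:03d}" for i in range(self.n_zero_genes)]
        genes += [f"GENE_{i + 1:04d}" for i in range(self.n_genes - len(genes))]
        return genes


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial sample with Var = μ + μ²·dispersion (zeros where μ = 0)."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def generate_counts(scenario: CountScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a genes × cells raw count matrix plus per-cell truth labels.

    Returns
    -------
    counts : DataFrame (genes × cells), non-negative integers.
    labels : DataFrame with columns cell_id, phenotype, failed.
    """
    rng = np.random.default_rng(scenario.seed)
    genes = scenario.gene_ids()
    n_genes = len(genes)

    base = rng.lognormal(mean=math.log(scenario.base_mean), sigma=1.0, size=n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in scenario.housekeeping_genes:
        base[gene_index[g]] = scenario.housekeeping_mean
    for i, g in enumerate(genes):
        if g.startswith("ZERO_"):
            base[i] = 0.0

    # per-phenotype mean vectors
    means = {}
    for p in scenario.cells_per_phenotype:
        mu = base.copy()
        prefix = f"MK_{p[:3].upper()}_"
        for i, g in enumerate(genes):
            if g.startswith(prefix):
                mu[i] *= 2.0**scenario.marker_log2fc
        means[p] = mu
    for gene, per_pheno in scenario.planted_log2fc.items():
        if gene not in gene_index:
            raise KeyError(f"planted_log2fc gene {gene!r} not among generated genes")
        for p, lfc in per_pheno.items():
            means[p][gene_index[gene]] = base[gene_index[gene]] * 2.0**lfc

    prefix_map = {"epithelial": "E", "escaping": "Es", "amoeboid": "A"}
    cell_ids, phenos = [], []
    for p, n in scenario.cells_per_phenotype.items():
        cell_ids += [f"{prefix_map[p]}-{i + 1:02d}" for i in range(n)]
        phenos += [p] * n

    n_cells = len(cell_ids)
    n_failed = int(round(scenario.low_quality_fraction * n_cells))
    failed_idx = set(rng.choice(n_cells, size=n_failed, replace=False).tolist()) if n_failed else set()

    mat = np.zeros((n_genes, n_cells), dtype=np.int64)
    for j, p in enumerate(phenos):
        mu = means[p] * (scenario.depth_scaling if j in failed_idx else 1.0)
        mat[:, j] = _nb_draw(rng, mu, scenario.dispersion)

    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(cell_ids, name="cell"))
    labels = pd.DataFrame(
        {"cell_id": cell_ids, "phenotype": phenos,
         "failed": [j in failed_idx for j in range(n_cells)]}
    )
    return counts, labels


def synthetic_housekeeping_table(seed: int = 0) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic stand-in for the study's 43-cell housekeeping count table.

    The real deposited table is not redistributed here; this reconstruction
    matches its *described* structure — 22 housekeeping genes × 43 cells, with
    exactly the eight reported cells (A-59, A-60, A-62, E-13, Es-30, Es-36,
    Es-37, Es-55) built to have more than 30% of panel genes below 10 raw
    counts, and every other cell comfortably above that rule.

    Returns the table (genes × cells) and the list of planted failing cells.
    """
    rng = np.random.default_rng(seed)
    epithelial = ["E-5", "E-9", "E-12", "E-13", "E-17", "E-21", "E-26", "E-31",
                  "E-38", "E-41", "E-43"]
    escaping = ["Es-2", "Es-8", "Es-11", "Es-15", "Es-19", "Es-22", "Es-27",
                "Es-30", "Es-33", "Es-36", "Es-37", "Es-40", "Es-46", "Es-50",
                "Es-55", "Es-58"]
    amoeboid = ["A-45", "A-47", "A-49", "A-52", "A-54", "A-56", "A-57", "A-59",
                "A-60", "A-61", "A-62", "A-64", "A-66", "A-68", "A-70", "A-72"]
    cells = epithelial + escaping + amoeboid
    failing = ["A-59", "A-60", "A-62", "E-13", "Es-30", "Es-36", "Es-37", "Es-55"]
    genes = [f"HK_{i + 1:02d}" for i in range(22)]

    mat = np.zeros((22, 43), dtype=np.int64)
    for j, cell in enumerate(cells):
        if cell in failing:
            n_low = int(rng.integers(8, 23))  # > 30% of 22 (i.e. ≥ 7) low genes
            low = rng.choice(22, size=n_low, replace=False)
            col = rng.integers(30, 400, size=22)
            col[low] = rng.integers(0, 10, size=n_low)
        else:
            col = rng.integers(30, 800, size=22)  # all panel genes well-detected
        mat[:, j] = col
    table = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                         columns=pd.Index(cells, name="cell"))
    return table, failing
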