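# Methods

This note records the models, conventions, parameter choices and known
limitations behind `spheroquant`, in the order data flows through the
package.

## Coordinate and measurement conventions

Arrays are `(z, y, x)` with z increasing away from the imaging face; `spacing`
is the voxel pitch in μm per axis in the same order, and all physical
coordinates refer to voxel centers. Confocal stacks are anisotropic (coarser
in z), so the default synthetic spacing is 3×2×2 μm and every measurement is
spacing-aware rather than assuming unit voxels.

## Synthetic data generator

The generator replaces the microscope and the sequencer with scenes whose
answers are known in closed form.

**Imaging.** A scene is a central spheroid (sphere, radius in μm) plus cells
of three analytic shapes: spheres, triaxial ellipsoids, and capsules
(sphero-cylinders, the stand-in for elongated invasive cells). A voxel is
foreground iff its center lies inside a shape — this makes voxel counting the
exact volume oracle for the rasterized object. Intensities are
background/foreground constants plus additive Gaussian noise clipped at zero;
no optics (PSF, photobleaching, photoconversion kinetics) are simulated, so
segmentation on these images is easier than on real data — passing tests
validate the measurement chain, not robustness to real microscope artifacts.
Ground truth per cell: closed-form volume and surface area (ellipsoids via
Legendre's incomplete elliptic integrals, with the Knud Thomsen p = 1.6075
approximation available separately; capsules in closed form), Wadell
sphericity, attachment, phenotype, and the true nearest distance from the
cell surface to the spheroid sphere (closed form for spherical cells, dense
surface sampling otherwise).

**Time series.** The real assay provides no quantitative growth or escape
model, so both are free simulation parameters: the spheroid radius scales by
`growth_rate` per day, and `escape_schedule` adds new detached 6 μm spheres
per day at increasing standoffs (20 μm + 14 μm per cell already present),
clamped so cells stay inside the volume. Cells are placed with directions
biased toward the equatorial plane; cells that end up below the spheroid's
widest plane are invisible to the analysis, exactly as in the real assay.

**Counts.** Cells are drawn per phenotype (defaults 12/16/16 epithelial /
escaping / amoeboid, the scale of the study this emulates) with
negative-binomial counts (Var = μ + μ²·disp, default dispersion 0.3).
Baseline gene means are log-normal around 20; a 22-gene housekeeping panel
sits at mean 200; each phenotype gets a marker block (default 25 genes at
log2FC 3) to create real cluster structure; arbitrary per-gene,
per-phenotype log2 fold-changes can be planted on top. "Failed" cells are
ordinary cells with every mean multiplied by `depth_scaling` (default 0.01)
— a pure depth effect, which is the failure mode the housekeeping filter
targets. The generator does not simulate reads, mapping, dropout structure
beyond the NB, or batch effects.

## Segmentation

Foreground is thresholded (Otsu or fixed), components are labeled with
26-connectivity (matching rendered-surface contiguity; 6-connectivity would
split diagonal necks), and components smaller than 65 μm³ (≈ a 2.5 μm-radius
sphere; configurable) are dropped as noise specks. The spheroid is the
largest-volume component; ties go to the lowest label with a warning.

**Crop at the widest plane.** Single-photon imaging cannot penetrate past the
spheroid's widest point, so analysis is restricted to the sub-volume from the
imaging face down to the z-slice of maximal spheroid cross-sectional area
(ties toward the face — the paper-side workflow does not define ties). The
imaged depth `z` used in the geometry formulas is measured from the
spheroid's topmost occupied slice to the widest plane, so an acquisition
margin of empty slices above the spheroid does not inflate the mean radius.

**Reference surface.** Distances travelled must be measured from the bulk
spheroid core, not from elongated invasive cells still attached to the
periphery. The reference is therefore a morphological *smoothing* of the
spheroid mask: opening with a Euclidean ball of radius `smoothing_scale`
(default 10 μm) sheds protrusions thinner than the scale, and a subsequent
closing fills comparably thin invaginations so the reference still encloses
the bulk mass. (A closing alone — extensive by definition — could never
remove an attached protrusion, which would defeat the reference's purpose.)
Both operators are realized through spacing-aware Euclidean distance
transforms, which is exact for ball structuring elements and fast on
anisotropic grids. If the scale is so large that the opening would erase the
spheroid, the opening is skipped with a warning. `smoothing_scale = 0`
returns the raw surface.

## Morphometry

**Cell volume** is voxel count × voxel volume. **Cell surface area** comes
from a marching-cubes mesh at the 0.5 isolevel with physical spacing —
voxel-face counting overestimates smooth surfaces by ~1.5× and would bias
sphericity low. Meshing a raw binary still leaves a staircase surface (~9%
over, resolution-independent), so the binary is blurred with a small
Gaussian (σ = 0.8 voxels) before meshing; for objects thinner than 8 voxels
on any axis the blur would shave a large fraction of the object, so such
objects skip it and accept the bounded staircase bias instead. With these
choices, measured sphericity of rasterized ellipsoids is within 3% of the
closed form whenever spacing ≤ axis/10. Objects touching the volume border
are closed at the border plane and measured with a warning.

**Sphericity** is the Wadell form Ψ = π^(1/3)·(6·V_p)^(2/3)/A_p: the area of
the volume-equivalent sphere over the actual area, 1 for a sphere and < 1
otherwise. It is scale-invariant and, up to mesh tolerance, bounded by 1
(isoperimetric inequality).

**Spheroid geometry.** An ellipse is least-squares fitted to the boundary
contour of the widest slice (sub-pixel contour at the 0.5 level, axes in μm);
fits with fewer than 5 boundary points or a sub-pixel minor axis are
rejected as degenerate. The estimated volume V = (4/3)π·((a+b+z)/3)³ and cap
area SA = π·(e²+z²) with e = (a+b)/2 follow the variable definitions of the
source workflow; both are simple isotropic-equivalent summaries, not true
integrals of the mask, and V is symmetric in (a, b, z) by construction.

**Distance to the reference** is surface-to-surface by default (a
centroid-to-surface mode is exposed as an option): the Euclidean distance
transform of the reference's boundary voxels, sampled at the cell's voxels,
with 0 for cells overlapping or touching the reference solid. On small
instances this equals the brute-force minimum over all voxel pairs exactly.

## Phenotype classification and time series

A measured cell is **amoeboid** if detached (d > 0), **escaping** if attached
and elongated (Ψ < 0.8 — escaped cells in this assay keep Ψ ≈ 0.8–0.9, so the
threshold sits just below that band; configurable), otherwise **epithelial**.
Detached cells are classified amoeboid regardless of shape, matching the
definition of the classes by position first and morphology second.

"Escaped" for counting means detached cells only; attached escaping cells are
reported in a separate column. The cumulative escaped count sums per-day new
detections without tracking individual cells across days (the population is
re-detected each day), and invasion density divides that cumulative count by
the day's cap area. Invasion speed is the day-to-day change in *mean*
escaped-cell distance — a population-level proxy, not a tracked velocity; it
can legitimately be negative when newly escaped cells appear close to the
spheroid.

## Counts pipeline

Genes with zero reads across all cells are removed first. The housekeeping
filter counts panel genes with raw count **strictly below** 10 and excludes a
cell when that count **strictly exceeds** 30% of the panel size — with the
22-gene default, 7 low genes exclude a cell and 6 do not. All panel genes
must be present in the matrix; a missing gene is an error rather than a
silent shrinkage of the denominator. The shipped default panel is a standard
22-gene human housekeeping set; any user panel can be substituted.

Normalization for clustering is median-of-ratios size factors (computed over
genes expressed in every cell; library-size factors with a warning if no such
gene exists) followed by log2(x/sf + 1). This is a documented stand-in for a
variance-stabilizing transform: it removes depth differences, which is what
clustering needs here, but does not flatten the mean–variance trend, and no
differential-expression statistics are computed from it. Externally produced
transformed matrices can be ingested instead.

Clustering is Ward-linkage agglomeration on Euclidean distances (scipy's
implementation of the Lance–Williams recurrence), with heights on the
convention that two singletons merge at their Euclidean distance — dendrogram
heights differ across conventions by constant factors, so this is pinned and
tested against an exhaustive within-cluster-sum-of-squares oracle on small
problems. The outlier rule flags any cell that joins the tree *as a
singleton* at a height exceeding 3× the median merge height (configurable;
∞ disables). This is a reasonable surrogate for "visibly isolated on the
dendrogram", not a reproduction of any specific manual call.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded from the
scenario/config seed; fixed seed and config give byte-identical output
files, and every output directory carries a JSON summary with the config
hash and package version.

## Problem sizes

The test suite and examples use desk-scale instances chosen to keep each
stage's error regime representative: volumes up to ~70×120×120 voxels
(3×2×2 μm), spheroids of 15–90 μm radius, ellipsoid cells with semi-axes
10–24 μm at 1 μm spacing for sphericity validation, count matrices of ~300
genes × 44–400 cells, and clustering oracles at n ≤ 8 where exhaustive
search is exact.

## Known limitations

- No optics model: segmentation robustness to PSF blur, attenuation with
  depth, or photobleaching is untested by construction.
- Attached cells that touch the spheroid merge into its connected component
  and are not individually recovered by segmentation; attached-cell metrics
  are only available from shapes measured in isolation (or from a richer
  instance-segmentation front end, out of scope).
- The spherical-cap and mean-radius formulas assume a roughly ellipsoidal
  spheroid; strongly lobed spheroids will bias V and SA.
- The NB count model has no gene–gene correlation or zero-inflation beyond
  the NB itself; QC performance on real failed libraries may differ from the
  planted-failure setting.
- Sub-voxel surface refinement and cross-day cell tracking are deliberately
  absent; per-day populations are analyzed independently.
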