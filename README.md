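# spheroquant

Quantification of 3D tumor-spheroid invasion assays, plus quality control and
clustering of plate-based single-cell RNA count matrices.

Melanoma spheroids embedded in collagen shed invasive cells over days: compact
**epithelial** cells at the spheroid surface, elongated **escaping** cells
still attached to the periphery, and detached, rounded **amoeboid** cells
migrating away. `spheroquant` turns confocal z-stacks of such assays into the
quantitative per-cell and per-day metrics used to compare conditions (e.g.
drug treatments), and processes the companion single-cell count matrices
(failed-library filtering, normalization, hierarchical clustering). A
synthetic-data generator with analytically known ground truth stands in for
the microscope and the sequencer, so every stage is verifiable at desk scale.

## The quantities it computes

**Spheroid geometry.** The stack is cropped at the z-plane of the spheroid's
widest cross-section (single-photon imaging cannot see past it), an ellipse is
least-squares fitted to the periphery at that plane (semi-axes *a* ≥ *b*, μm),
and with imaged depth *z*:

- mean radius r = (a + b + z)/3 and estimated spheroid volume
  **V = (4/3)·π·r³** (μm³),
- mean ellipsoid axis e = (a + b)/2 and imaged-hemispheroid surface area as a
  spherical cap, **SA = π·(e² + z²)** (μm²).

**Per-cell morphometry.** Each escaped-cell surface gets a volume *V*ₚ (voxel
counting), surface area *A*ₚ (spacing-aware marching-cubes mesh), Wadell
sphericity

&nbsp;&nbsp;&nbsp;&nbsp;**Ψ = π¹ᐟ³·(6·Vₚ)²ᐟ³ / Aₚ**  ∈ (0, 1],

and the nearest distance *d* (μm) to a morphologically smoothed reference
surface around the spheroid (smoothed so distances measure travel from the
bulk core, not from elongated protrusions). Cells are classified as
epithelial (attached, compact), escaping (attached, Ψ below a threshold,
default 0.8) or amoeboid (detached).

**Invasion time series.** Per imaging day: relative volume V/V(day 0),
cumulative escaped cells normalized to the cap area (cells/μm², the invasion
measure), mean escaped-cell sphericity and distance, and invasion speed
(day-to-day change in mean escaped-cell distance).

**Counts side.** Genes with zero reads everywhere are dropped; a cell is
excluded when more than 30% of a 22-gene housekeeping panel has fewer than
10 raw counts (strict thresholds on both sides); retained cells are
normalized (median-of-ratios size factors, then log2(x/sf + 1)) and clustered
with Ward linkage on Euclidean distances; singleton cells merging at
anomalous heights are flagged as outliers.

## Worked example

Simulate a 90 μm spheroid growing 3%/day over 4 days while shedding cells,
then run the full imaging pipeline:

```python
import spheroquant as sq

cfg = sq.RunConfig(
    simulate=dict(
        grid_shape=[70, 120, 120], spheroid_center=[102.0, 119.0, 119.0],
        spheroid_radius=90.0, voxel_spacing=[3.0, 2.0, 2.0], noise_sigma=5.0,
        days=[0, 2, 4], growth_rate=1.03, escape_schedule={0: 0, 2: 2, 4: 3},
    ),
    smoothing_scale=10.0, seed=1, output_dir="demo_out",
)
result = sq.run_imaging_pipeline(cfg)
print(result["timeseries"].round(4).to_string(index=False))
```

prints (abridged):

```
 day  relative_volume         SA  cumulative_escaped  invasion_density  mean_escaped_sphericity  mean_escaped_distance
   0           1.0000 49280.0516                   0            0.0000                      NaN                    NaN
   2           1.1653 54149.2685                   1            0.0000                   0.9639                32.5730
   4           1.3978 61237.2085                   4            0.0001                   0.9603                25.4748
```

Reading it: the spheroid's estimated volume grew 1.40× by day 4 (the planted
growth of 3%/day in radius predicts 1.03¹² ≈ 1.43 in volume); four escaped
cells are visible above the widest plane by day 4, i.e. ~10⁻⁴ cells/μm² of
imaged surface; the escaped cells are near-spherical (Ψ ≈ 0.96, consistent
with amoeboid morphology — the simulated escapers are 6 μm-radius spheres).
`demo_out/` also contains `cells.csv` (one row per cell per day with V_p,
A_p, Ψ, d, attachment, phenotype) and `spheroid_geometry.csv` (a, b, z, r, e,
V, SA per day).

The same workflows are exposed on the command line:

```bash
spheroquant simulate   --config scenario.yaml
spheroquant segment    --input vol.tif --spacing 3,2,2 --method otsu --min-volume 65
spheroquant timeseries --config scenario.yaml
spheroquant counts-qc  --counts counts.csv --panel panel.txt
spheroquant cluster    --counts counts.csv --n-clusters 3
```

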