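# q3d — quantitative 3D histochemistry

`q3d` turns raw 3D fluorescence volumes of cleared tissue (light-sheet
whole-brain or hemisphere stacks) into voxel-level group statistics in a
common anatomical atlas space. It is aimed at studies that quantify
labeled objects — amyloid plaques, Iba1⁺ microglia, or any compact
bright structure — across treatment cohorts: where in the brain does an
intervention change object counts, sizes, or occupied volume, and do the
changes of two different markers colocalize?

## The pipeline

1. **Restoration.** Light-sheet volumes carry a smooth multiplicative
   autofluorescence background and per-voxel camera noise. The
   background is modeled as a Gaussian blur of the raw data at scale
   σ_b (default 50 voxels, larger than any object, smaller than the
   background undulations) and divided out, `R = I / G_{σ_b}(I)`,
   giving a dimensionless ratio image with flat tissue near 1; a small
   blur (σ = 1 voxel) then suppresses digitization noise.
2. **Detection.** Voxels with `R ≥ θ` (default θ = 1.8) are foreground;
   26-connected components are objects; components below a minimum
   volume (4 voxels) or peak ratio (2.0) are discarded as artifacts.
3. **Atlas mapping.** Object centroids (and, for volume maps, every
   member voxel) are mapped through a per-sample affine into the 25 µm
   isotropic atlas grid (voxel-centre convention, floor binning) and
   accumulated into per-voxel count, size-sum, and volume maps.
4. **Heatmaps.** A spherical ROI of 15 atlas voxels diameter (375 µm)
   is placed at every voxel and the map is summed within it; mean object
   size is the ratio of smoothed size-sum to smoothed count.
5. **Statistics.** At every heatmap voxel a two-sided two-sample t-test
   (treated − control) is computed; the t-map is enhanced with
   threshold-free cluster enhancement,
   `TFCE(v) = Σ_h e(v,h)^E · h^H · dh` (E = 0.5, H = 2), and
   family-wise error is controlled by the max-|TFCE| permutation null
   over group relabelings (exhaustive when feasible). Corrected-p maps
   are binarized at α = 0.05 with the sign of the effect.
6. **Summaries.** Maps are aggregated per anatomical region (optionally
   masked to significant voxels), group means ± SD are tabulated, and
   two signed significance maps are compared by a 2×2 colocalization
   matrix of increase/decrease overlaps.

A synthetic-cohort generator (`q3d.synth`) renders image cohorts with
the same statistical structure — spherical objects in box-shaped
regions, multiplicative background, camera noise, and region-specific
treatment effects on count and size — so the whole chain is testable
against known ground truth without any acquisition data.

## Worked example

Generate a synthetic cohort (6 treated vs 6 control, a 50% object-count
reduction injected in region 1) and run the full pipeline:

```python
from q3d import RunConfig, run_pipeline

config = RunConfig(
    out_dir="demo",
    seed=3,
    synth=dict(volume_shape=(96, 96, 96), n_regions=4,
               objects_per_region=40.0, n_per_group=6),
    restoration={"background_scale": 20.0},
    detection={"intensity_threshold": 1.8, "min_volume": 4, "min_peak": 2.0},
)
result = run_pipeline(config)
sig = result.significance["count"]
print("significant voxels:", sig.n_significant,
      "(+%d / -%d)" % (sig.increase_mask.sum(), sig.decrease_mask.sum()))
print(result.colocalization)
```

which prints

```
significant voxels: 58 (+0 / -58)
          increase  decrease
increase         0         0
decrease         0        52
```

Treated samples detect fewer objects (≈118 vs ≈137 per sample, visible
in `demo/run.log`), the count analysis flags 58 voxels — all decreases,
as injected — and 52 of them are also significant decreases in the
object-volume analysis, filling the (decrease, decrease) cell of the
colocalization matrix. The output directory holds the atlas, per-sample
object tables, t/TFCE/corrected-p/sign maps (NIfTI), region tables and
the colocalization matrix (CSV), plus a config snapshot that reproduces
the run bit-for-bit.

The same stages are available as shell verbs:

```bash
q3d synth --out-dir cohort --seed 5
q3d restore cohort/control_00.tif restored.tif
q3d detect restored.tif objects.csv --threshold 1.8 --min-volume 4 --min-peak 2.0
q3d run --config run.yaml
```

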