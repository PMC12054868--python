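# Methods

This note records the models, conventions and numerical choices behind
`q3d`, and what the synthetic experiments do and do not establish.

## Image model and restoration

The observed volume is modeled as
`I(v) = B(v) · (β + Σ_k S_k(v)) + ε(v)`: a smooth, strictly positive
multiplicative background `B` (autofluorescence and illumination
inhomogeneity), a constant tissue baseline `β`, additive compact bright
objects `S_k`, and i.i.d. Gaussian camera noise `ε`. Restoration
inverts the multiplicative part by dividing the raw data by a Gaussian
blur of itself and then suppresses voxel-scale noise with a σ = 1 voxel
blur. Consequences of the model worth keeping in mind:

- The ratio image is dimensionless, flat tissue sits at 1, and any
  global gain cancels (`restore(c·I) = restore(I)`), so one intensity
  threshold can serve all samples.
- The background scale (default σ_b = 50 voxels) must sit between the
  object radius and the background correlation length. "Scale" means
  the Gaussian σ in voxels; an option interprets the configured values
  as variances instead, since the convention is ambiguous in parts of
  the literature. Both smoothing passes use reflective boundaries to
  avoid darkened rims that would bias detection near volume edges.
- The division guard is `ε = 10⁻⁶ · mean(I)`, scale-free by
  construction.
- Restoration is deliberately not idempotent; re-running it on a ratio
  image re-estimates a background from already-flat data.

## Detection

Foreground is `R ≥ θ` with θ = 1.8 (inclusive, so behaviour at the
threshold is well defined and bit-reproducible); objects are
26-connected components; filters on minimum volume (4 voxels) and
minimum peak ratio (2.0) remove digitization artifacts. θ = 1.8 is the
established operating point for ratio images of this kind; the two
filter values are package defaults — they are mandatory config entries
and are echoed into every run log. There is no watershed splitting:
objects whose suprathreshold supports touch are counted once. Peak and
threshold both refer to the denoised ratio field.

## Atlas mapping

One fixed convention prevents half-voxel drift between samples:
0-based indices, physical position of voxel `i` is
`(i + 0.5) · voxel_size`, per-sample affine transforms act on physical
µm coordinates, and atlas binning is `floor(position / 25 µm)`. Counts
and sizes are point events at the object centroid; volume maps instead
map every member voxel, so an object spanning several atlas voxels
contributes volume to each (total volume is conserved up to
out-of-atlas losses, which are counted and reported, never silently
dropped). Registration itself is out of scope: transforms are inputs,
identity for synthetic cohorts.

## ROI heatmaps

The local density heatmap is a literal sum over a discrete sphere of
15 atlas voxels diameter (375 µm at 25 µm resolution). Sphere
membership is decided in exact integer arithmetic
(`4·|Δ|² ≤ diameter²`), avoiding floating-point boundary flakiness; at
volume borders the sphere is truncated without renormalization. The
uniform-weight sum is the default for both count and volume maps; a
radially decreasing weighting exists as an option. An FFT path computes
the same sum to ~1e-12 relative accuracy for large maps; the direct
path is exact for integer-valued maps and is the reference. Mean object
size is smoothed-size-sum over smoothed-count, NaN (not zero) where the
smoothed count is zero, so undefined voxels drop out of downstream
statistics instead of biasing them.

## Voxel statistics

Two-sample t-tests (pooled variance by default, Welch optional) run per
voxel on the per-sample heatmaps, oriented treated − control. Voxels
with zero pooled variance are masked (NaN) and excluded everywhere
downstream. TFCE integrates cluster extent^E × height^H over a
threshold ladder `h_k = k·dh`, with E = 0.5, H = 2,
`dh = max|t|/100`, 26-connectivity — the standard published defaults;
positive and negative parts are enhanced separately on the shared
ladder and recombined with sign.

The implementation is a single descending threshold sweep over a
union-find forest (numba): voxels activate as the threshold falls below
their value, clusters merge incrementally, each live root accumulates
its cluster's `e^E h^H dh` increment, and per-voxel totals are
recovered from offsets recorded at merge time. This is algebraically
identical to relabeling clusters independently at every threshold; the
test suite holds it to an independent per-threshold oracle within
floating-point round-off (≤ 1e-9 relative; observed ≈ 1e-14).

Family-wise error control uses the max-statistic scheme: group labels
are permuted (all distinct relabelings when their count fits the
permutation budget, uniform random otherwise), the maximum |TFCE| of
each permuted map forms the null, and
`p(v) = (1 + #{max ≥ |TFCE_obs(v)|}) / (1 + n_perm)`. Two properties
follow and are worth knowing:

- The group-swapped relabeling always ties the observed maximum
  (t → −t leaves |TFCE| unchanged), so the smallest achievable
  two-sided corrected p is `2/(1 + n_perm)` for symmetric designs.
- With 3 samples per group, exhaustive relabeling gives 20 assignments
  and a corrected-p floor of 2/20 = 0.1: no voxel can pass α = 0.05.
  Cohorts need ≥ 4 per group for the two-sided max-statistic test to be
  able to reject at all; the package does not silently change the test
  for small cohorts.

Significance masks use strict `p < α` with the t-map's sign attached
(+1 increase in treated, −1 decrease). Region aggregation can restrict
to the mask or use whole regions — both modes are exposed, since
either may be wanted for regional summaries. Colocalization of two
signed maps is the 2×2 count of voxels significant in both, split by
direction; it is transpose-symmetric by construction.

## Synthetic cohorts: what they emulate, and what not

The generator emulates the statistical structure the analysis assumes:
Poisson object counts per region with multiplicative treatment effects
on count and on size (radius scaled by the cube root of the size
effect), truncated-normal radii with a one-voxel floor, centres uniform
within box-shaped regions of a recursively bisected label volume, the
multiplicative background (smoothed white noise rescaled exactly to
`[1−a, 1+a]`, hence strictly positive), and Gaussian camera noise.
Per-sample seeds derive from the cohort seed by `SeedSequence`
spawning, so cohorts are bit-reproducible.

Default cohort conditions: an 800 µm cube at 5 µm isotropic native
voxels (a 32³ atlas grid), six regions, 12 objects per region
(≈140 objects/mm³, in the range of reported plaque loads and sparse
enough that individual objects are resolvable — the density at which
instance-level detection metrics are meaningful given that touching
objects merge into one component), radius 15 ± 2 µm, object intensity 4
over baseline 1, background amplitude 0.3 with 400 µm correlation
length, noise sd 0.2 (5% of object intensity), 6 samples per group, and
a 50% count reduction in region 1 of the treated group.

Deliberately not emulated: ramified microglial morphology (objects are
hard spheres — the detection operators use only intensity, volume and
peak, so shape fidelity adds nothing to their tests), optical PSF and
light-sheet striping, tile-stitching seams, and registration error
(transforms default to identity; a small-affine mode exists to test the
transform path). Background amplitude is a free parameter, not
calibrated to any instrument. Passing synthetic tests therefore
establishes the correctness and calibration of the computational chain
under its own model assumptions — not robustness to real-tissue
morphology, clearing artifacts, or registration failure.

## Experiment problem sizes

The test-suite experiments run at desk scale, chosen as the smallest
sizes at which each question is meaningful: detection fidelity pools
six rendered samples of the default cohort; family-wise error
calibration uses 200 null cohorts (4 vs 4, exhaustive 70 relabelings,
32³ grids) against the bound `α + 3·SE`; effect recovery uses a 64³
atlas grid with 12 regions and 850 objects/region (6 vs 6, exhaustive
924 relabelings) so that the affected region is large relative to the
375 µm ROI — ROI smoothing necessarily smears a region-confined effect
about one ROI radius past the region border, so localization claims are
only testable when regions are several ROI diameters across. The
FWER and effect-recovery cohorts build count heatmaps directly from
ground-truth object populations; rendering and detection change neither
the exchangeability null nor the injected contrast, and their fidelity
is established separately. Statistics-stage experiments therefore share
one t-map/TFCE/permutation code path with real runs.

## Pipeline engineering choices

Volumes are processed whole, per sample: at the volume sizes this
package targets (tens of millions of voxels) full-volume Gaussian
filtering and labeling are comfortably in memory, and slab streaming
would require halo exchange across seams for no benefit. The run log
contains no timestamps, and maps are written as uncompressed NIfTI, so
two runs from the same config snapshot produce byte-identical output
trees — determinism is an explicit contract, tested end to end. Every
parameter of every stage is echoed verbatim into the log and the config
snapshot; any output is reproducible from the snapshot alone.
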