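"""End-to-end orchestration: cohort in, significance maps and tables out.

A :class:`RunConfig` carries every parameter of every stage plus the
file manifest (or a synthetic-cohort description), and is echoed
verbatim into the output directory as a YAML snapshot, so any output
file is reproducible from the snapshot alone.  The run log is written
without timestamps for the same reason: two runs with the same config
and seed produce bit-identical output trees.

Pipeline order per sample: restore -> detect -> atlas maps -> ROI
heatmaps; then across samples: voxel t-test -> TFCE -> permutation FWER
-> signed significance masks -> region tables and the significance-map
colocalization matrix (object-count map vs object-volume map).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .atlas import LabelAtlas, SampleTransform, count_map, size_maps, volume_map
from .density import SphereKernel, mean_size_heatmap, smooth_map
from .detect import DetectionParams, ObjectTable, detect
from .grids import ImageStack, VoxelMap
from .regions import colocalization_matrix, group_region_summary, region_aggregate
from .restore import RestorationParams, restore
from .stats import (
    GroupDesign,
    PermutationResult,
    SignificanceMap,
    TfceParams,
    permutation_correct,
    significance_mask,
)
from .synth import SyntheticSpec, cohort_plan, generate_atlas, generate_sample

ANALYSES = ("count", "volume")


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    Exactly one of ``synth`` (synthetic-cohort spec fields) or
    ``samples`` (+ ``atlas_volume``/``atlas_table``) must be given.
    ``detection`` is mandatory and must state ``intensity_threshold``,
    ``min_volume`` and ``min_peak`` explicitly — they are echoed to the
    log on every run.
    """

    out_dir: str
    detection: dict
    seed: int = 0
    synth: dict | None = None
    samples: list[dict] | None = None
    atlas_volume: str | None = None
    atlas_table: str | None = None
    voxel_size_um: list | None = None
    restoration: dict = field(default_factory=dict)
    kernel: dict = field(default_factory=dict)
    tfce: dict = field(default_factory=dict)
    smoothing_method: str = "fft"
    analyses: tuple[str, ...] = ANALYSES
    save_heatmaps: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.detection, dict):
            raise ValueError("config must contain a detection section")
        missing = {"intensity_threshold", "min_volume", "min_peak"} - set(self.detection)
        if missing:
            raise ValueError(
                f"detection config must state {sorted(missing)} explicitly "
                "(mandatory parameters)"
            )
        if (self.synth is None) == (self.samples is None):
            raise ValueError("config needs exactly one of 'synth' or 'samples'")
        if self.samples is not None and (
            self.atlas_volume is None or self.atlas_table is None
        ):
            raise ValueError("file-based runs need atlas_volume and atlas_table")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}")
        self.analyses = tuple(self.analyses)

    # -- parameter objects -------------------------------------------------

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection)

    def restoration_params(self) -> RestorationParams:
        return RestorationParams(**self.restoration)

    def sphere_kernel(self) -> SphereKernel:
        return SphereKernel(**self.kernel)

    def tfce_params(self) -> TfceParams:
        d = dict(self.tfce)
        d.setdefault("seed", self.seed)
        return TfceParams(**d)

    def synthetic_spec(self) -> SyntheticSpec:
        d = dict(self.synth or {})
        d.setdefault("seed", self.seed)
        return SyntheticSpec.from_dict(d)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["analyses"] = list(self.analyses)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**qio.read_yaml(path))


@dataclass
class RunResult:
    out_dir: Path
    atlas: LabelAtlas
    design: GroupDesign
    objects: dict[str, ObjectTable]
    heatmaps: dict[str, dict[str, VoxelMap]]
    stats: dict[str, PermutationResult]
    significance: dict[str, SignificanceMap]
    region_tables: dict[str, pd.DataFrame]
    colocalization: pd.DataFrame | None


class _RunLog:
    """Timestamp-free run log: deterministic output, still auditable."""

    def __init__(self, path: Path):
        self._lines: list[str] = []
        self._path = path

    def info(self, msg: str) -> None:
        self._lines.append(msg)

    def flush(self) -> None:
        self._path.write_text("\n".join(self._lines) + "\n")


def _load_sample(entry: dict, cfg: RunConfig) -> tuple[str, str, ImageStack, SampleTransform]:
    sid = str(entry["sample_id"])
    group = str(entry["group"])
    vs = tuple(cfg.voxel_size_um) if cfg.voxel_size_um else None
    stack = qio.read_volume(entry["path"], voxel_size_um=vs)
    tr = (
        SampleTransform.from_file(entry["transform"])
        if entry.get("transform")
        else SampleTransform.identity()
    )
    return sid, group, stack, tr


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all outputs under
    ``config.out_dir``.  Deterministic given the config (incl. seed)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    qio.write_yaml(config.to_dict(), out / "config_snapshot.yaml")

    det = config.detection_params()
    rest = config.restoration_params()
    kernel = config.sphere_kernel()
    tfce = config.tfce_params()
    log.info(
        f"params: detection(threshold={det.intensity_threshold}, "
        f"min_volume={det.min_volume}, min_peak={det.min_peak}, "
        f"connectivity={det.connectivity}) "
        f"restoration(background_scale={rest.background_scale}, "
        f"noise_scale={rest.noise_scale}) "
        f"kernel(diameter={kernel.diameter}, weighting={kernel.weighting}) "
        f"tfce(E={tfce.E}, H={tfce.H}, dh_frac={tfce.dh_frac}, "
        f"n_perm={tfce.n_perm}, alpha={tfce.alpha}, seed={tfce.seed})"
    )

    # ------------------------------------------------------------------
    # Cohort: synthetic or from files
    # ------------------------------------------------------------------
    stage = "cohort"
    try:
        if config.synth is not None:
            spec = config.synthetic_spec()
            atlas = generate_atlas(spec.atlas_shape(), spec.n_regions, seed=spec.seed)
            plan = [(sid, grp, seed, None) for sid, grp, seed in cohort_plan(spec)]
        else:
            spec = None
            atlas = qio.read_atlas(config.atlas_volume, config.atlas_table)
            plan = [
                (str(e["sample_id"]), str(e["group"]), None, e)
                for e in config.samples  # type: ignore[union-attr]
            ]
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    qio.write_atlas(atlas, out / "atlas.nii", out / "atlas_regions.csv")

    sample_ids: list[str] = []
    groups: list[str] = []
    objects: dict[str, ObjectTable] = {}
    heat: dict[str, dict[str, VoxelMap]] = {a: {} for a in config.analyses}
    mean_size: dict[str, VoxelMap] = {}
    truths = {}

    for sid, group, seed, entry in plan:
        try:
            stage = "load"
            if spec is not None:
                truth, stack = generate_sample(spec, atlas, sid, group, seed)
                truths[sid] = truth
                transform = SampleTransform.identity()
            else:
                _, _, stack, transform = _load_sample(entry, config)

            stage = "restore"
            restored = restore(stack, rest)
            stage = "detect"
            obj = detect(restored, det, sample_id=sid)
            objects[sid] = obj
            obj.to_csv(out / f"objects_{sid}.csv")
            log.info(f"sample {sid} [{group}]: {len(obj)} objects detected")

            stage = "map"
            cmap = count_map(obj, atlas, transform)
            if cmap.meta["n_outside"]:
                log.info(f"sample {sid}: {cmap.meta['n_outside']} objects outside atlas")
            if "count" in config.analyses:
                stage = "heatmap"
                heat["count"][sid] = smooth_map(cmap, kernel, method=config.smoothing_method)
            if "volume" in config.analyses:
                stage = "heatmap"
                vmap = volume_map(obj, atlas, transform)
                heat["volume"][sid] = smooth_map(vmap, kernel, method=config.smoothing_method)
            stage = "mean_size"
            smap, cmap2 = size_maps(obj, atlas, transform)
            mean_size[sid] = mean_size_heatmap(smap, cmap2, kernel,
                                               method=config.smoothing_method)
            if config.save_heatmaps:
                for a in config.analyses:
                    qio.write_map(heat[a][sid], out / f"heatmap_{a}_{sid}.nii")
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed for sample {sid!r}: {err}") from err
        sample_ids.append(sid)
        groups.append(group)

    design = GroupDesign(sample_ids=sample_ids, groups=groups)

    # ------------------------------------------------------------------
    # Voxel statistics per analysis
    # ------------------------------------------------------------------
    stats_res: dict[str, PermutationResult] = {}
    sig: dict[str, SignificanceMap] = {}
    region_tables: dict[str, pd.DataFrame] = {}
    for a in config.analyses:
        stage = f"stats[{a}]"
        try:
            maps = [heat[a][sid] for sid in sample_ids]
            res = permutation_correct(maps, design, tfce)
            s = significance_mask(res.p_corrected, res.t, tfce.alpha)
            stats_res[a] = res
            sig[a] = s
            log.info(
                f"stats[{a}]: {res.n_perm_used} relabelings "
                f"({'exhaustive' if res.exhaustive else 'sampled'}), "
                f"{s.n_significant} significant voxels "
                f"(+{int(s.increase_mask.sum())}/-{int(s.decrease_mask.sum())})"
            )
            qio.write_map(res.t, out / f"stats_{a}_t.nii")
            qio.write_map(res.tfce, out / f"stats_{a}_tfce.nii")
            qio.write_map(res.p_corrected, out / f"stats_{a}_p_corrected.nii")
            sign_map = VoxelMap(s.sign.astype(np.float64), quantity="t",
                                resolution_um=res.t.resolution_um)
            qio.write_map(sign_map, out / f"stats_{a}_sign.nii")

            stage = f"regions[{a}]"
            per_sample = {
                sid: region_aggregate(heat[a][sid], atlas, mask=s)
                for sid in sample_ids
            }
            summary = group_region_summary(per_sample, design)
            summary.to_csv(out / f"regions_{a}.csv", index=False)
            region_tables[a] = summary
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # ------------------------------------------------------------------
    # Colocalization between the two analyses' significance maps
    # ------------------------------------------------------------------
    coloc = None
    if len(config.analyses) == 2:
        stage = "coloc"
        try:
            a, b = config.analyses
            coloc = colocalization_matrix(sig[a], sig[b])
            coloc.to_csv(out / "colocalization.csv")
            log.info(f"coloc[{a} vs {b}]: total overlap {int(coloc.to_numpy().sum())}")
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    log.flush()
    return RunResult(
        out_dir=out,
        atlas=atlas,
        design=design,
        objects=objects,
        heatmaps=heat,
        stats=stats_res,
        significance=sig,
        region_tables=region_tables,
        colocalization=coloc,
    )
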