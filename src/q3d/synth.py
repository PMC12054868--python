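"""Synthetic cohort generator.

Emulates the statistical structure of a cleared-brain light-sheet study:
bright compact objects (amyloid plaques / microglia somata) scattered in
anatomically parcellated regions, a smooth multiplicative autofluorescence
background, and per-voxel camera noise.  Treated samples differ from
controls through region-specific multiplicative effects on object count
and object size, so every downstream stage (restoration, detection, atlas
mapping, heatmaps, voxel statistics) can be exercised against a known
ground truth.

The forward model per sample is

    I(v) = B(v) * (baseline + sum_k S_k(v)) + eps(v)

where ``B`` is a smooth strictly positive field rescaled to
``[1 - a, 1 + a]`` (amplitude ``a``, correlation length
``background_length_scale``), ``S_k`` are hard spheres of constant added
intensity, and ``eps`` is i.i.d. Gaussian camera noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .atlas import LabelAtlas, SampleTransform
from .grids import ATLAS_RESOLUTION_UM, ImageStack

CONTROL = "control"
TREATED = "treated"


@dataclass(frozen=True)
class Effect:
    """Multiplicative effect of treatment within one region.

    ``count`` scales the expected object count; ``size`` scales the mean
    object volume (the mean radius is scaled by ``size ** (1/3)``).
    """

    count: float = 1.0
    size: float = 1.0

    def __post_init__(self) -> None:
        if self.count < 0 or self.size < 0:
            raise ValueError("effect multipliers must be >= 0")


@dataclass
class SyntheticSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults describe the desk-scale reference cohort: an 800 µm cube at
    5 µm native voxels (a 32-cubed grid at the 25 µm atlas resolution),
    six box-shaped regions, object density comparable to plaque loads in
    amyloidosis models (~230 objects/mm³, sparse enough that objects are
    individually resolvable), and a 50% object-count reduction in
    region 1 of the treated group.
    """

    volume_shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    n_regions: int = 6
    objects_per_region: float = 12.0
    object_radius_mean_um: float = 15.0
    object_radius_sd_um: float = 2.0
    object_intensity: float = 4.0
    baseline: float = 1.0
    background_amplitude: float = 0.3
    background_length_scale_um: float = 400.0
    noise_sd: float = 0.2
    effect_map: dict[int, Effect] = dc_field(
        default_factory=lambda: {1: Effect(count=0.5)}
    )
    n_per_group: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objects_per_region < 0:
            raise ValueError("objects_per_region must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.background_length_scale_um <= self.object_radius_mean_um:
            raise ValueError(
                "background_length_scale_um must exceed object_radius_mean_um"
            )
        self.effect_map = {
            int(k): (v if isinstance(v, Effect) else Effect(**v))
            for k, v in self.effect_map.items()
        }

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(
            n * d for n, d in zip(self.volume_shape, self.voxel_size_um)
        )  # type: ignore[return-value]

    def atlas_shape(self, resolution_um: float = ATLAS_RESOLUTION_UM) -> tuple[int, int, int]:
        """Atlas grid shape covering the native extent."""
        return tuple(
            int(np.ceil(e / resolution_um)) for e in self.extent_um
        )  # type: ignore[return-value]

    def to_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "effect_map"
        }
        d["effect_map"] = {
            int(k): {"count": e.count, "size": e.size}
            for k, e in self.effect_map.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for k in ("volume_shape", "voxel_size_um"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Known object population of one rendered sample.

    ``objects`` has one row per object: fractional native voxel
    coordinates of the centre (voxel-centre convention), radius in µm,
    the atlas region it was drawn in, and sample/group labels.
    """

    objects: pd.DataFrame
    sample_id: str
    group: str

    COLUMNS = ("sample_id", "group", "region_id", "z", "y", "x", "radius_um")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.objects.columns)
        if missing:
            raise ValueError(f"ground-truth table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.objects)

    def per_region(self) -> pd.DataFrame:
        """True object count and mean radius per region."""
        g = self.objects.groupby("region_id")
        out = pd.DataFrame(
            {"n_objects": g.size(), "mean_radius_um": g["radius_um"].mean()}
        )
        out.index.name = "region_id"
        return out.reset_index()


# ---------------------------------------------------------------------------
# Atlas generation: recursive bisection into connected axis-aligned boxes.
# ---------------------------------------------------------------------------

def generate_atlas(
    shape: tuple[int, int, int],
    n_regions: int,
    seed: int,
    resolution_um: float = ATLAS_RESOLUTION_UM,
) -> LabelAtlas:
    """Partition a grid into ``n_regions`` connected box regions.

    The volume is split by recursive bisection: the largest remaining box
    is cut along its longest axis at a seeded random fraction in
    [0.4, 0.6], until ``n_regions`` boxes exist.  Labels run 1..n_regions;
    label 0 (outside brain) does not occur in generated atlases.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"shape must be three positive integers, got {shape}")
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2 (group contrasts need >= 2 regions)")
    if n_regions > int(np.prod(shape)):
        raise ValueError("n_regions exceeds the number of voxels")

    rng = np.random.default_rng(seed)
    boxes: list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = [
        ((0, shape[0]), (0, shape[1]), (0, shape[2]))
    ]
    while len(boxes) < n_regions:
        sizes = [np.prod([hi - lo for lo, hi in b]) for b in boxes]
        i = int(np.argmax(sizes))
        box = boxes.pop(i)
        lengths = [hi - lo for lo, hi in box]
        axis = int(np.argmax(lengths))
        lo, hi = box[axis]
        if hi - lo < 2:  # largest box is a single voxel: nothing can split
            raise ValueError("grid too small to carve the requested regions")
        frac = rng.uniform(0.4, 0.6)
        cut = int(np.clip(round(lo + frac * (hi - lo)), lo + 1, hi - 1))
        left = list(box)
        right = list(box)
        left[axis] = (lo, cut)
        right[axis] = (cut, hi)
        boxes.append(tuple(left))  # type: ignore[arg-type]
        boxes.append(tuple(right))  # type: ignore[arg-type]

    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    for rid, ((z0, z1), (y0, y1), (x0, x1)) in enumerate(boxes, start=1):
        labels[z0:z1, y0:y1, x0:x1] = rid
        rows.append(
            {"region_id": rid, "name": f"region_{rid:02d}",
             "n_voxels": (z1 - z0) * (y1 - y0) * (x1 - x0)}
        )
    table = pd.DataFrame(rows)
    return LabelAtlas(labels=labels, regions=table, resolution_um=resolution_um)


# ---------------------------------------------------------------------------
# Object sampling.
# ---------------------------------------------------------------------------

def sample_objects(
    atlas: LabelAtlas,
    spec: SyntheticSpec,
    group: str,
    seed: int,
    sample_id: str = "sample",
) -> GroundTruth:
    """Draw a ground-truth object population for one sample.

    Per region, the object count is Poisson with mean
    ``objects_per_region`` times the region's count effect (treated
    samples only); radii are truncated normal with a hard floor of one
    native voxel; centres are uniform over the region's volume.
    """
    if group not in (CONTROL, TREATED):
        raise ValueError(f"group must be {CONTROL!r} or {TREATED!r}, got {group!r}")
    bad = set(spec.effect_map) - set(atlas.regions["region_id"].tolist())
    if bad:
        raise ValueError(f"effect_map refers to unknown region ids {sorted(bad)}")

    rng = np.random.default_rng(seed)
    voxel_size = np.asarray(spec.voxel_size_um, dtype=float)
    extent = np.asarray(spec.extent_um, dtype=float)
    res = atlas.resolution_um
    radius_floor = float(max(spec.voxel_size_um))

    rows = []
    for rid in atlas.regions["region_id"]:
        eff = spec.effect_map.get(int(rid), Effect())
        mean = spec.objects_per_region * (eff.count if group == TREATED else 1.0)
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        region_voxels = np.argwhere(atlas.labels == rid)
        # restrict to atlas voxels that intersect the native extent (the
        # atlas grid may overhang it); regions wholly outside get no objects
        region_voxels = region_voxels[np.all(region_voxels * res < extent, axis=1)]
        if len(region_voxels) == 0:
            continue
        # uniform over the region's volume: uniform voxel, uniform within it;
        # rejection keeps centres inside the native extent when the atlas
        # grid slightly overhangs it.
        centers_um = np.empty((n, 3))
        filled = 0
        while filled < n:
            take = n - filled
            idx = rng.integers(0, len(region_voxels), size=take)
            pos = (region_voxels[idx] + rng.uniform(0, 1, size=(take, 3))) * res
            ok = np.all(pos < extent, axis=1)
            k = int(ok.sum())
            centers_um[filled : filled + k] = pos[ok]
            filled += k

        r_mean = spec.object_radius_mean_um * eff.size ** (1.0 / 3.0) \
            if group == TREATED else spec.object_radius_mean_um
        r_sd = spec.object_radius_sd_um
        if r_sd > 0:
            a = (radius_floor - r_mean) / r_sd
            radii = sps.truncnorm.rvs(
                a, np.inf, loc=r_mean, scale=r_sd, size=n, random_state=rng
            )
        else:
            radii = np.full(n, max(r_mean, radius_floor))

        centers_vox = centers_um / voxel_size - 0.5
        for c, r in zip(centers_vox, radii):
            rows.append(
                {"sample_id": sample_id, "group": group, "region_id": int(rid),
                 "z": c[0], "y": c[1], "x": c[2], "radius_um": float(r)}
            )

    objects = pd.DataFrame(rows, columns=list(GroundTruth.COLUMNS))
    return GroundTruth(objects=objects, sample_id=sample_id, group=group)


# ---------------------------------------------------------------------------
# Rendering.
# ---------------------------------------------------------------------------

def background_field(
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    amplitude: float,
    length_scale_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth strictly positive multiplicative field in [1-a, 1+a].

    Heavily smoothed white noise, linearly rescaled so its minimum and
    maximum hit the band edges exactly; amplitude 0 gives a flat field.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("background amplitude must be in [0, 1)")
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    noise = rng.standard_normal(shape)
    sigma = [length_scale_um / d for d in voxel_size_um]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:
        return np.ones(shape, dtype=np.float64)
    return 1.0 - amplitude + 2.0 * amplitude * (smooth - lo) / (hi - lo)


def _add_sphere(
    signal: np.ndarray,
    center_vox: np.ndarray,
    radius_um: float,
    voxel_size: np.ndarray,
    intensity: float,
) -> None:
    """Add a constant-intensity hard sphere (in-place)."""
    lo = np.maximum(np.floor(center_vox - radius_um / voxel_size).astype(int), 0)
    hi = np.minimum(
        np.ceil(center_vox + radius_um / voxel_size).astype(int) + 1,
        np.asarray(signal.shape),
    )
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
    )
    d2 = (
        ((zz - center_vox[0]) * voxel_size[0]) ** 2
        + ((yy - center_vox[1]) * voxel_size[1]) ** 2
        + ((xx - center_vox[2]) * voxel_size[2]) ** 2
    )
    inside = d2 <= radius_um**2
    sub = signal[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[inside] += intensity


def render_volume(truth: GroundTruth, spec: SyntheticSpec, seed: int) -> ImageStack:
    """Render one sample with the multiplicative-background forward model."""
    shape = tuple(spec.volume_shape)
    voxel_size = np.asarray(spec.voxel_size_um, dtype=float)
    rng = np.random.default_rng(seed)

    field = background_field(
        shape, spec.voxel_size_um, spec.background_amplitude,
        spec.background_length_scale_um, rng,
    )
    signal = np.full(shape, spec.baseline, dtype=np.float64)
    for row in truth.objects.itertuples(index=False):
        _add_sphere(
            signal,
            np.array([row.z, row.y, row.x]),
            row.radius_um,
            voxel_size,
            spec.object_intensity,
        )
    image = field * signal
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)
    return ImageStack(data=image.astype(np.float32), voxel_size_um=spec.voxel_size_um)


def true_object_mask(truth: GroundTruth, spec: SyntheticSpec) -> np.ndarray:
    """Boolean native-grid mask of all ground-truth spheres."""
    mask = np.zeros(tuple(spec.volume_shape), dtype=np.float64)
    voxel_size = np.asarray(spec.voxel_size_um, dtype=float)
    for row in truth.objects.itertuples(index=False):
        _add_sphere(mask, np.array([row.z, row.y, row.x]), row.radius_um, voxel_size, 1.0)
    return mask > 0


# ---------------------------------------------------------------------------
# Cohorts.
# ---------------------------------------------------------------------------

def cohort_plan(spec: SyntheticSpec) -> list[tuple[str, str, int]]:
    """Deterministic (sample_id, group, sample_seed) list for a cohort.

    Per-sample seeds are derived from ``spec.seed`` with
    ``numpy.random.SeedSequence`` spawning, so samples are independent
    and the whole cohort is reproducible bit-for-bit.
    """
    groups = [CONTROL] * spec.n_per_group + [TREATED] * spec.n_per_group
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(groups))
    plan = []
    for i, (group, child) in enumerate(zip(groups, children)):
        sid = f"{group}_{i % spec.n_per_group:02d}"
        seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        plan.append((sid, group, seed))
    return plan


def generate_sample(
    spec: SyntheticSpec,
    atlas: LabelAtlas,
    sample_id: str,
    group: str,
    seed: int,
    render: bool = True,
) -> tuple[GroundTruth, ImageStack | None]:
    """Ground truth (and optionally the rendered stack) for one sample."""
    truth = sample_objects(atlas, spec, group, seed=seed, sample_id=sample_id)
    stack = render_volume(truth, spec, seed=seed + 1) if render else None
    return truth, stack


def identity_transform() -> SampleTransform:
    return SampleTransform.identity()


def truth_to_object_table(truth: GroundTruth, spec: SyntheticSpec):
    """Ground-truth objects as an :class:`~q3d.detect.ObjectTable`.

    Lets the atlas-mapping and statistics stages run directly on known
    object populations, bypassing rendering and detection (each object's
    volume is its analytic sphere volume).  Member-voxel lists are not
    populated.
    """
    from .detect import ObjectTable

    df = truth.objects
    vol_vox = (4.0 / 3.0) * np.pi * df["radius_um"] ** 3 / (
        np.prod(np.asarray(spec.voxel_size_um))
    )
    table = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "object_id": np.arange(1, len(df) + 1),
            "z": df["z"],
            "y": df["y"],
            "x": df["x"],
            "volume_voxels": vol_vox,
            "peak_ratio": np.inf,
        }
    )
    return ObjectTable(
        table=table, voxel_size_um=spec.voxel_size_um,
        sample_id=truth.sample_id, members=None,
    )


def evaluate_detection(
    truth: GroundTruth,
    detected,
    spec: SyntheticSpec,
    max_dist_um: float = 25.0,
) -> dict:
    """Object-level recall and precision of a detection run.

    Greedy one-to-one matching of detected centroids to ground-truth
    centres by physical distance, closest pairs first, up to
    ``max_dist_um``.  Two true objects merged into one detection leave
    one of them unmatched, so merging lowers recall, not precision.
    """
    from scipy.spatial import cKDTree

    vs = np.asarray(spec.voxel_size_um)
    t_um = (truth.objects[["z", "y", "x"]].to_numpy(float) + 0.5) * vs
    d_um = (detected.centroids + 0.5) * np.asarray(detected.voxel_size_um)
    n_t, n_d = len(t_um), len(d_um)
    if n_t == 0 or n_d == 0:
        return {"recall": 0.0 if n_t else 1.0, "precision": 0.0 if n_d else 1.0,
                "n_true": n_t, "n_detected": n_d, "n_matched": 0}
    pairs = cKDTree(t_um).query_ball_tree(cKDTree(d_um), r=max_dist_um)
    cand = [
        (float(np.linalg.norm(t_um[i] - d_um[j])), i, j)
        for i, js in enumerate(pairs) for j in js
    ]
    cand.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    for _, i, j in cand:
        if i not in used_t and j not in used_d:
            used_t.add(i)
            used_d.add(j)
    n_match = len(used_t)
    return {
        "recall": n_match / n_t,
        "precision": n_match / n_d,
        "n_true": n_t,
        "n_detected": n_d,
        "n_matched": n_match,
    }
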