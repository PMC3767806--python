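"""Synthetic inputs for every stage of the pipeline.

Three families of generators:

* **voxel phantoms** of analytically known fractal dimension (Menger
  sponge, fractal percolation, solid block, plane, line, rod, torus) —
  ground truth for the box-counting estimator;
* **segmentation-like probability volumes**, including a branching
  white-matter-tree phantom, for exercising the full subject-level
  pipeline (binarize, thin, split, count);
* **cohort tables** whose statistical structure mirrors a five-group ALS
  fractal-dimension study: group-dependent ages and gender imbalance, a
  gender-specific random intercept, a linear age effect, log-normal
  disease duration, El Escorial categories, and an ALSFRS-R score
  rank-coupled to whole-brain skeleton FD.

All generators are deterministic given a seed. A root seed fans out to
named substreams so adding a generator never perturbs existing streams.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from . import constants as C
from .volume_io import FD_COLUMNS, ProbabilityVolume, VoxelGrid

logger = logging.getLogger(__name__)

PHANTOM_KINDS = (
    "menger", "percolation", "solid_block", "plane", "line", "rod",
    "torus", "wm_tree",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclasses.dataclass
class PhantomSpec:
    """Recipe for one voxel phantom.

    ``expected_fd`` is the analytic box dimension when one exists:
    log20/log3 for the Menger sponge, 3 + log2(p) for fractal
    percolation, and 3 / 2 / 1 for block, plane and line.
    """

    kind: str
    level_or_size: int = 3
    retention_p: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; "
                             f"one of {PHANTOM_KINDS}")
        if self.kind == "percolation":
            if self.retention_p is None or not (1 / 8 < self.retention_p <= 1):
                raise ValueError(
                    "percolation needs retention_p in (1/8, 1] "
                    "(below 1/8 the set dies out almost surely)"
                )
        if self.level_or_size < 1:
            raise ValueError("level_or_size must be >= 1")

    @property
    def expected_fd(self) -> float | None:
        if self.kind == "menger":
            return float(np.log(20) / np.log(3))
        if self.kind == "percolation":
            assert self.retention_p is not None
            return float(3 + np.log2(self.retention_p))
        return {"solid_block": 3.0, "plane": 2.0, "line": 1.0}.get(self.kind)


def _menger(level: int) -> np.ndarray:
    g = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        n = g.shape[0]
        out = np.zeros((3 * n,) * 3, dtype=bool)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    # Drop the centre of each face-line: keep cells with at
                    # most one middle coordinate.
                    if (i == 1) + (j == 1) + (k == 1) >= 2:
                        continue
                    out[i * n:(i + 1) * n, j * n:(j + 1) * n, k * n:(k + 1) * n] = g
        g = out
    return g


def _percolation(level: int, p: float, rng: np.random.Generator,
                 max_retries: int = 1000) -> np.ndarray:
    """Fractal percolation with subdivision 2, conditioned on survival."""
    for attempt in range(max_retries):
        g = np.ones((1, 1, 1), dtype=bool)
        alive = True
        for _ in range(level):
            rep = np.repeat(np.repeat(np.repeat(g, 2, 0), 2, 1), 2, 2)
            keep = rng.random(rep.shape) < p
            g = rep & keep
            if not g.any():
                alive = False
                break
        if alive:
            if attempt:
                logger.info("percolation survived after %d retries", attempt)
            return g
    raise RuntimeError(
        f"percolation phantom failed to survive in {max_retries} attempts"
    )


def _torus(grid: int) -> np.ndarray:
    zz, yy, xx = np.mgrid[:grid, :grid, :grid]
    c = (grid - 1) / 2.0
    major, minor = grid / 3.5, grid / 10.0
    d = (np.sqrt((xx - c) ** 2 + (yy - c) ** 2) - major) ** 2 + (zz - c) ** 2
    return d <= minor**2


def make_phantom(spec: PhantomSpec) -> VoxelGrid:
    """Build the binary phantom described by ``spec``."""
    kind, n = spec.kind, spec.level_or_size
    if kind == "menger":
        data = _menger(n)
    elif kind == "percolation":
        rng = substream(spec.seed, "percolation")
        data = _percolation(n, float(spec.retention_p), rng)  # type: ignore[arg-type]
    elif kind == "solid_block":
        data = np.ones((n, n, n), dtype=bool)
    elif kind == "plane":
        data = np.zeros((n, n, n), dtype=bool)
        data[:, :, n // 2] = True
    elif kind == "line":
        data = np.zeros((n, n, n), dtype=bool)
        data[:, n // 2, n // 2] = True
    elif kind == "rod":
        # Solid 5 x 5 x n rod embedded in an n-cube.
        data = np.zeros((max(n, 8),) * 3, dtype=bool)
        c = data.shape[1] // 2
        data[:n, c - 2:c + 3, c - 2:c + 3] = True
    elif kind == "torus":
        data = _torus(max(n, 16))
    elif kind == "wm_tree":
        return binarize_tree(make_wm_tree_phantom(seed=spec.seed, grid=max(n, 64)))
    else:  # pragma: no cover - guarded in PhantomSpec
        raise ValueError(kind)
    return VoxelGrid(data=data)


def as_probability(
    grid: VoxelGrid, seed: int = 0, noise: float = 0.1
) -> ProbabilityVolume:
    """Segmentation-like probability map around a binary phantom.

    Foreground sits near 1 and background near 0 with bounded noise and a
    little smoothing, clipped to [0, 1]; thresholding at 0.5 recovers at
    least 99% of the phantom voxels by construction.
    """
    rng = substream(seed, "probability-noise")
    base = np.where(grid.data, 0.9, 0.1).astype(float)
    rough = rng.uniform(-noise, noise, size=grid.shape)
    smooth = ndimage.gaussian_filter(rough, sigma=1.0) * 3.0
    prob = np.clip(base + np.clip(smooth, -noise, noise), 0.0, 1.0)
    return ProbabilityVolume(data=prob, affine=grid.affine.copy())


def _draw_tube(data: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Rasterize a solid tube between two points."""
    length = float(np.linalg.norm(p1 - p0))
    steps = max(2, int(length * 2))
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1).astype(int),
                    np.array(data.shape) - 1)
    zz, yy, xx = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    for t in np.linspace(0.0, 1.0, steps):
        c = p0 + t * (p1 - p0)
        d2 = np.sum((pts - c) ** 2, axis=-1)
        data[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= d2 <= radius**2


def make_wm_tree_phantom(
    seed: int = 0, n_branches: int = 6, grid: int = 64
) -> ProbabilityVolume:
    """Branching tubular phantom emulating a WM probability map.

    A trunk climbs the volume and ``n_branches - 1`` side branches sprout
    from it at random heights with a left/right asymmetry. The binarized
    phantom is connected and its skeleton exposes at least
    ``n_branches - 1`` branch points (voxels with >= 3 skeleton
    neighbours).
    """
    if grid < 64:
        raise ValueError(f"grid must be >= 64, got {grid}")
    rng = substream(seed, "wm-tree")
    data = np.zeros((grid,) * 3, dtype=bool)
    margin = 6.0
    centre = grid / 2.0

    # Trunk: piecewise-linear path from bottom to top with small jitter.
    n_seg = 6
    zs = np.linspace(margin, grid - margin, n_seg + 1)
    trunk = [np.array([z,
                       centre + rng.uniform(-3, 3),
                       centre + rng.uniform(-3, 3)]) for z in zs]
    radius = 2.6
    for a, b in zip(trunk, trunk[1:]):
        _draw_tube(data, a, b, radius)

    for i in range(max(0, n_branches - 1)):
        t = rng.uniform(0.15, 0.85)
        base = trunk[0] + t * (trunk[-1] - trunk[0])
        # Alternate hemispheres with asymmetric reach to break symmetry.
        side = 1.0 if i % 2 == 0 else -1.0
        reach = rng.uniform(0.3, 0.45) * grid * (1.15 if side > 0 else 0.85)
        direction = np.array([
            rng.uniform(0.1, 0.6),
            rng.uniform(-0.7, 0.7),
            side * rng.uniform(0.5, 1.0),
        ])
        direction /= np.linalg.norm(direction)
        # Two curved segments per limb, plus a twig near the elbow, so
        # the skeleton fills scales between the voxel and the trunk.
        elbow = np.clip(base + 0.55 * reach * direction, margin, grid - margin)
        bend = rng.uniform(-0.35, 0.35, 3)
        tip_dir = direction + bend
        tip_dir /= np.linalg.norm(tip_dir)
        tip = np.clip(elbow + 0.45 * reach * tip_dir, margin, grid - margin)
        _draw_tube(data, base, elbow, radius * 0.8)
        _draw_tube(data, elbow, tip, radius * 0.7)
        twig_dir = np.cross(direction, [1.0, 0.0, 0.0]) + rng.uniform(-0.3, 0.3, 3)
        twig_dir /= np.linalg.norm(twig_dir)
        twig = np.clip(elbow + 0.3 * reach * twig_dir, margin, grid - margin)
        _draw_tube(data, elbow, twig, radius * 0.6)

    return as_probability(VoxelGrid(data=data), seed=seed)


def binarize_tree(prob: ProbabilityVolume, threshold: float = 0.5) -> VoxelGrid:
    """Threshold helper used when a phantom is requested as a binary grid."""
    return VoxelGrid(data=prob.data >= threshold, affine=prob.affine.copy())


@dataclasses.dataclass
class CohortSpec:
    """Generating model of a synthetic five-group cohort.

    Defaults reproduce the reference study conditions in
    :mod:`wmfractal.constants`: group sizes, group-dependent age
    distributions, gender imbalance, per-group FD means/SDs for all nine
    outcomes, a shared linear age effect on FD, a gender-specific random
    intercept, log-normal disease duration and an ALSFRS-R score
    rank-coupled (Gaussian copula) to whole-brain skeleton FD.
    """

    group_sizes: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(C.GROUP_SIZES))
    fd_means: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: C.FD_MEAN)
    fd_sds: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: C.FD_SD)
    age_means: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(C.AGE_MEAN))
    age_sds: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(C.AGE_SD))
    male_fraction: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(C.MALE_FRACTION))
    age_slope: float = C.DEFAULT_AGE_SLOPE
    gender_sd: float = C.DEFAULT_GENDER_SD
    alsfrs_coupling: float = C.DEFAULT_ALSFRS_COUPLING
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("every group size must be >= 1")
        if self.gender_sd < 0:
            raise ValueError("gender_sd must be >= 0")
        for outcome, per_group in self.fd_sds.items():
            if any(sd < 0 for sd in per_group.values()):
                raise ValueError(f"negative SD for {outcome}")
        if not (-1 <= self.alsfrs_coupling <= 1):
            raise ValueError("alsfrs_coupling must lie in [-1, 1]")


def make_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate one cohort table under the generating model of ``spec``.

    Per subject: age ~ Normal(group mean, group SD); gender Bernoulli with
    the group's male fraction; each FD outcome = group mean +
    age_slope * (age - expected grand mean) + gender effect +
    Normal(0, group SD). ALSFRS-R shares a latent Gaussian with the
    whole-brain skeleton FD noise at correlation ``alsfrs_coupling`` and
    is clipped to [0, 48]; duration is log-normal matched to the group
    median and quartiles; the El Escorial category is drawn from the
    group's reference proportions. Controls carry no clinical measures.
    """
    spec = spec or CohortSpec()
    root = spec.seed if seed is None else seed

    rng_age = substream(root, "age")
    rng_gender = substream(root, "gender")
    rng_fd = substream(root, "fd-noise")
    rng_clin = substream(root, "clinical")
    rng_geff = substream(root, "gender-effect")

    groups = [g for g in C.GROUPS if g in spec.group_sizes] + [
        g for g in spec.group_sizes if g not in C.GROUPS
    ]
    sizes = {g: int(spec.group_sizes[g]) for g in groups}
    total = sum(sizes.values())
    # Expected grand mean age, the centring point of the age effect.
    grand_age = sum(spec.age_means[g] * sizes[g] for g in groups) / total

    gender_effect = {
        "M": rng_geff.normal(0.0, spec.gender_sd),
        "F": rng_geff.normal(0.0, spec.gender_sd),
    }

    rows: list[dict] = []
    sid = 0
    for g in groups:
        n = sizes[g]
        ages = rng_age.normal(spec.age_means[g], spec.age_sds[g], size=n)
        males = rng_gender.random(n) < spec.male_fraction.get(g, 0.5)
        # Latent noise per outcome, standard normal.
        z = {o: rng_fd.standard_normal(n) for o in FD_COLUMNS}
        # Gaussian copula targeting a *rank* correlation: convert the
        # requested Spearman rho to the latent Pearson correlation.
        rho = 2.0 * np.sin(np.pi * spec.alsfrs_coupling / 6.0)
        eps = rng_clin.standard_normal(n)
        z_alsfrs = rho * z["fd_skeleton_wb"] + np.sqrt(max(0.0, 1 - rho**2)) * eps

        is_patient = g in C.ALSFRS_MEAN
        if is_patient:
            alsfrs = np.clip(
                np.rint(C.ALSFRS_MEAN[g] + C.ALSFRS_SD[g] * z_alsfrs), 0, 48
            ).astype(int)
            sigma = np.log(C.DURATION_Q3[g] / C.DURATION_Q1[g]) / (2 * 0.6745)
            duration = np.exp(
                np.log(C.DURATION_MEDIAN[g])
                + sigma * rng_clin.standard_normal(n)
            )
            ees = rng_clin.choice([1, 2, 3, 4], size=n, p=C.EES_PROBS[g])
        for i in range(n):
            sid += 1
            gender = "M" if males[i] else "F"
            row = {
                "subject_id": f"S{sid:03d}",
                "group": g,
                "age": float(ages[i]),
                "gender": gender,
                "alsfrs_r": int(alsfrs[i]) if is_patient else np.nan,
                "duration_months": float(duration[i]) if is_patient else np.nan,
                "ees": int(ees[i]) if is_patient else np.nan,
            }
            for o in FD_COLUMNS:
                row[o] = (
                    spec.fd_means[o][g]
                    + spec.age_slope * (ages[i] - grand_age)
                    + gender_effect[gender]
                    + spec.fd_sds[o][g] * z[o][i]
                )
            rows.append(row)
    return pd.DataFrame(rows)
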