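"""Synthetic tau-PET phantom cohorts with a planted Centiloid-dependent signal.

The generator emulates the statistical structure the downstream analysis is
designed to detect in real data: a cohort of subjects with a continuous
amyloid Centiloid (CL) covariate, and 3D volumes in which

* a "fronto-parietal/cingulate-like" region (role ``effect_low``) gains
  intensity with CL predominantly *below* a changepoint,
* two "medial-temporal-like" regions (roles ``effect_high_left/right``)
  gain intensity predominantly *above* it,
* null regions and the rest of the brain carry no CL signal, and
* i.i.d. Gaussian voxel noise is added on top of a flat baseline.

The changepoint defaults to CL = 25, the conventional amyloid-positivity
threshold, so the low-CL/high-CL informativeness crossover is planted at the
same place the analysis should recover it.

CL dependence of the two effects:

* ``g_low(cl)``  — linear ramp from 0 at ``cl_low`` saturating at 1 at the
  changepoint (dominant slope below the changepoint, zero slope above);
* ``g_high(cl)`` — logistic in ``(cl - changepoint)/tau_high`` with
  ``tau_high = 10`` CL (negligible slope far below the changepoint,
  dominant above).

Both are analytically simple so the planted crossover is checkable in
closed form.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import Atlas, Volume, default_affine

COHORT_COLUMNS = ["id", "cl", "age", "sex", "split", "fold"]

#: train/validation/test proportions of the reference cohort (109/12/13 of 134)
DEFAULT_SPLIT_FRACTIONS = (109 / 134, 12 / 134, 13 / 134)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the desk-scale conditions used throughout the test-suite:
    a 32x40x32 grid at 2 mm, 150 subjects with CL uniform on [-10, 140],
    changepoint at CL = 25, effect amplitudes of 0.4 / 0.5 SUV on a baseline
    of 1.0 SUV, and voxel noise of 0.1 SUV.
    """

    grid_shape: tuple[int, int, int] = (32, 40, 32)
    voxel_size_mm: float = 2.0
    n_subjects: int = 150
    cl_low: float = -10.0
    cl_high: float = 140.0
    changepoint_cl: float = 25.0
    tau_high: float = 10.0
    cl_distribution: str = "aibl-like"
    abeta_pos_fraction: float = 0.49
    cl_neg_mean: float = 2.0
    cl_neg_sd: float = 10.0
    cl_pos_mean: float = 70.0
    cl_pos_sd: float = 35.0
    effect_low_region: float = 0.8
    effect_high_region: float = 0.5
    baseline: float = 1.0
    region_baseline_contrast: float = 0.15
    noise_sd: float = 0.3
    subject_offset_ratio: float = 0.1
    hot_region_offset: float = 3.0
    age_mean: float = 70.5
    age_sd: float = 7.5
    p_female: float = 0.5
    split_fractions: tuple[float, float, float] = DEFAULT_SPLIT_FRACTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")
        if not self.cl_low < self.cl_high:
            raise ValueError("cl_low must be < cl_high")
        if not (self.cl_low <= self.changepoint_cl <= self.cl_high):
            raise ValueError("changepoint_cl must lie in [cl_low, cl_high]")
        for name in ("effect_low_region", "effect_high_region", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.cl_distribution not in ("aibl-like", "uniform"):
            raise ValueError("cl_distribution must be 'aibl-like' or 'uniform'")
        if not (0 <= self.abeta_pos_fraction <= 1):
            raise ValueError("abeta_pos_fraction must be in [0, 1]")
        f = self.split_fractions
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-8:
            raise ValueError("split_fractions must be 3 nonnegative values summing to 1")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size_mm)


def g_low(cl, config: SyntheticConfig):
    """Saturating ramp: rises on [cl_low, changepoint], flat at 1 above."""
    cl = np.asarray(cl, dtype=float)
    return np.clip((cl - config.cl_low) / (config.changepoint_cl - config.cl_low), 0.0, 1.0)


def g_high(cl, config: SyntheticConfig):
    """Logistic ramp centred on the changepoint with scale ``tau_high`` CL."""
    cl = np.asarray(cl, dtype=float)
    return 1.0 / (1.0 + np.exp(-(cl - config.changepoint_cl) / config.tau_high))


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """One atlas region: a sphere or axis-aligned ellipsoid.

    ``center`` and ``radius`` are fractions of the grid dimensions when
    ``units == "frac"`` (radius relative to the smallest dimension), or voxel
    coordinates when ``units == "voxel"``.
    """

    name: str
    role: str
    center: tuple[float, float, float]
    radius: float | tuple[float, float, float]
    units: str = "frac"


def _default_region_specs() -> list[RegionSpec]:
    return [
        RegionSpec("cerebellar cortex (synthetic)", "reference", (0.50, 0.22, 0.25), 0.11),
        RegionSpec("fronto-parietal/cingulate (synthetic)", "effect_low",
                   (0.50, 0.68, 0.72), (0.28, 0.20, 0.14)),
        RegionSpec("left medial temporal (synthetic)", "effect_high_left",
                   (0.30, 0.45, 0.35), 0.13),
        RegionSpec("right medial temporal (synthetic)", "effect_high_right",
                   (0.70, 0.45, 0.35), 0.13),
        RegionSpec("occipital (synthetic)", "null", (0.50, 0.18, 0.62), 0.11),
        RegionSpec("left insula (synthetic)", "null", (0.28, 0.62, 0.50), 0.09),
        RegionSpec("off-target hot spot (synthetic)", "hot", (0.50, 0.82, 0.45), 0.08),
    ]


def _region_mask(spec: RegionSpec, shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    dims = np.array(shape, dtype=float)
    center = np.asarray(spec.center, dtype=float)
    radius = np.asarray(spec.radius, dtype=float)
    if spec.units == "frac":
        center = center * dims
        radius = radius * (min(shape) if radius.ndim == 0 else dims)
    elif spec.units != "voxel":
        raise ValueError("RegionSpec.units must be 'frac' or 'voxel'")
    semi = np.broadcast_to(np.atleast_1d(radius), (3,))
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    d2 = (((ii - center[0]) / semi[0]) ** 2
          + ((jj - center[1]) / semi[1]) ** 2
          + ((kk - center[2]) / semi[2]) ** 2)
    return d2 <= 1.0


def generate_atlas(config: SyntheticConfig,
                   regions: list[RegionSpec] | None = None) -> Atlas:
    """Deterministic synthetic parcellation on the configured grid.

    An ellipsoidal brain mask is filled with the given regions (default: the
    six-region layout with reference, effect and null roles); remaining
    in-mask voxels become a catch-all "other brain" parcel.  Regions are
    clipped to the mask and assigned in order, earlier regions taking
    precedence, so labels are disjoint by construction.

    Raises
    ------
    ValueError
        If the grid is too small or a region ends up empty (the error names
        the failing region).
    """
    shape = config.grid_shape
    if any(n < 16 for n in shape):
        raise ValueError(f"grid {shape} too small: every dimension must be >= 16")
    if regions is None:
        regions = _default_region_specs()

    dims = np.array(shape, dtype=float)
    center = dims / 2.0
    semi = np.array([0.45 * dims[0], 0.45 * dims[1], 0.42 * dims[2]])
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    brain = (((ii - center[0]) / semi[0]) ** 2
             + ((jj - center[1]) / semi[1]) ** 2
             + ((kk - center[2]) / semi[2]) ** 2) <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    name_map: dict[int, str] = {}
    roles: dict[str, list[int]] = {}
    for idx, spec in enumerate(regions, start=1):
        mask = _region_mask(spec, shape) & brain & (labels == 0)
        if not mask.any():
            raise ValueError(
                f"region {spec.name!r} (role {spec.role!r}) is empty on grid {shape}: "
                "no unclaimed in-mask voxels fall inside it")
        labels[mask] = idx
        name_map[idx] = spec.name
        roles.setdefault(spec.role, []).append(idx)

    rest = brain & (labels == 0)
    if rest.any():
        rest_label = len(regions) + 1
        labels[rest] = rest_label
        name_map[rest_label] = "other brain (synthetic)"
        roles.setdefault("other", []).append(rest_label)

    return Atlas(labels, config.affine, name_map,
                 {role: tuple(labs) for role, labs in roles.items()})


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _sample_cl(rng: np.random.Generator, n: int, config: SyntheticConfig) -> np.ndarray:
    """Draw Centiloid values from the configured cohort distribution.

    ``aibl-like`` (default) is a two-component mixture calibrated to the
    amyloid-positivity rate of the reference cohort: with probability
    ``abeta_pos_fraction`` a truncated normal on [changepoint, cl_high]
    (Abeta+), otherwise a truncated normal on [cl_low, changepoint) (Abeta-).
    ``uniform`` draws uniformly on [cl_low, cl_high].
    """
    if config.cl_distribution == "uniform":
        return rng.uniform(config.cl_low, config.cl_high, size=n)
    from scipy import stats

    pos = rng.random(n) < config.abeta_pos_fraction
    cl = np.empty(n)

    def trunc(mean, sd, lo, hi, size):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                   random_state=rng)

    cl[~pos] = trunc(config.cl_neg_mean, config.cl_neg_sd,
                     config.cl_low, config.changepoint_cl, (~pos).sum())
    cl[pos] = trunc(config.cl_pos_mean, config.cl_pos_sd,
                    config.changepoint_cl, config.cl_high, pos.sum())
    return cl


def sample_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Seeded cohort table: id, cl, age, sex, split, fold.

    CL follows ``config.cl_distribution`` (see :func:`_sample_cl`), age is
    normal, sex Bernoulli; the train/validation/test split follows
    ``config.split_fractions`` (defaulting to 109/12/13 proportions).
    ``fold`` is left unassigned (pd.NA) — cross-validation folds are
    planned separately.
    """
    n = config.n_subjects
    rng = np.random.default_rng([int(config.seed) % 2**31, zlib.crc32(b"cohort")])
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             zip(COHORT_COLUMNS, [str, float, float, str, str, "Int64"])})
    ids = [f"sub-{i:04d}" for i in range(n)]
    cl = _sample_cl(rng, n, config)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = np.where(rng.random(n) < config.p_female, "F", "M")

    f_train, f_val, f_test = config.split_fractions
    n_test = int(round(f_test * n))
    n_val = int(round(f_val * n))
    n_train = n - n_test - n_val
    if min(n_train, n_val, n_test) < 0:
        raise ValueError(f"split fractions {config.split_fractions} invalid for n={n}")
    split = np.array(["train"] * n_train + ["validation"] * n_val + ["test"] * n_test)
    rng.shuffle(split)

    return pd.DataFrame({
        "id": ids, "cl": cl, "age": age, "sex": sex, "split": split,
        "fold": pd.array([pd.NA] * n, dtype="Int64"),
    })


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def subject_seed(master_seed: int, subject_id: str) -> list[int]:
    """Seed-sequence entropy for one subject, independent of cohort order."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    return [int(master_seed) % 2**31, int.from_bytes(digest[:4], "little")]


def region_baseline_map(atlas: Atlas, config: SyntheticConfig) -> np.ndarray:
    """Deterministic per-region baseline multipliers (anatomical contrast).

    Real spatially-normalised brains are not homogeneous: regions differ in
    baseline tracer uptake, and that contrast is what lets a convolutional
    network form location-specific features at all (a translation-equivariant
    model cannot tell apart two voxels whose whole neighbourhoods are
    statistically identical).  Each label gets a multiplier
    1 + contrast * u(label), with u(label) in [-1, 1] hashed from the region
    name — fixed across subjects, seeds and cohorts.
    """
    mult = np.ones(atlas.shape)
    c = config.region_baseline_contrast
    for lab, name in atlas.name_map.items():
        u = (zlib.crc32(name.encode()) % 10000) / 5000.0 - 1.0
        mult[atlas.labels == lab] = 1.0 + c * u
    return mult


def render_volume(subject, atlas: Atlas, config: SyntheticConfig) -> Volume:
    """Render one subject's phantom SUV volume.

    In-mask value = baseline + effect_low * g_low(cl) inside the effect_low
    region + effect_high * g_high(cl) inside the effect_high regions +
    per-subject regional offsets + N(0, noise_sd), truncated at 0.
    Out-of-mask voxels are exactly 0.  ``subject`` is a cohort-table row
    (anything with ``id`` and ``cl``).

    The regional offsets — one per effect system, N(0, subject_offset_ratio
    * noise_sd), constant over the region's voxels — emulate between-subject
    biological heterogeneity: unlike i.i.d. voxel noise they do not average
    away over a region, so each region is only informative about CL where
    its planted CL-response has appreciable slope.  They scale with
    ``noise_sd`` and therefore vanish in noiseless analytic checks.
    """
    if tuple(atlas.shape) != tuple(config.grid_shape):
        raise ValueError(f"atlas grid {atlas.shape} != config grid {config.grid_shape}")
    cl = float(subject["cl"] if not hasattr(subject, "cl") else subject.cl)
    sid = str(subject["id"] if not hasattr(subject, "id") else subject.id)

    rng = np.random.default_rng(subject_seed(config.seed, sid))
    offset_sd = config.subject_offset_ratio * config.noise_sd
    b_low, b_high = (rng.normal(0.0, offset_sd, size=2) if offset_sd > 0
                     else (0.0, 0.0))

    def role(name):
        return atlas.role_mask(name) if name in atlas.roles else \
            np.zeros(atlas.shape, dtype=bool)

    data = np.full(atlas.shape, config.baseline, dtype=np.float64)
    if config.region_baseline_contrast > 0:
        data *= region_baseline_map(atlas, config)
    data[role("effect_low")] += \
        config.effect_low_region * float(g_low(cl, config)) + b_low
    high = role("effect_high_left") | role("effect_high_right")
    data[high] += config.effect_high_region * float(g_high(cl, config)) + b_high
    # CL-independent off-target uptake: keeps the image maximum (and hence
    # the [0,1] scaling denominator) independent of amyloid burden
    data[role("hot")] += config.hot_region_offset

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=atlas.shape)
    data = np.clip(data, 0.0, None)
    data[~atlas.brain_mask] = 0.0
    return Volume(data, config.affine, "SUV", meta={"subject_id": sid, "cl": cl})


def render_cohort(cohort: pd.DataFrame, atlas: Atlas,
                  config: SyntheticConfig) -> list[Volume]:
    """Render every subject's volume, in cohort order."""
    return [render_volume(row, atlas, config) for _, row in cohort.iterrows()]


def generate_dataset(config: SyntheticConfig,
                     regions: list[RegionSpec] | None = None):
    """Convenience: (cohort, atlas, volumes) for one configuration."""
    atlas = generate_atlas(config, regions)
    cohort = sample_cohort(config)
    return cohort, atlas, render_cohort(cohort, atlas, config)


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(cohort: pd.DataFrame, volumes: list[Volume], atlas: Atlas,
                  out_dir, config: SyntheticConfig | None = None) -> dict:
    """Write volumes + atlas as NIfTI-1, cohort as TSV, and a JSON manifest.

    The manifest's ``images`` list has one row per subject volume plus one
    for the atlas, each with path, sha256 and byte size.
    """
    if len(volumes) != len(cohort):
        raise ValueError(f"{len(volumes)} volumes for {len(cohort)} subjects")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    images = []
    for (_, row), vol in zip(cohort.iterrows(), volumes):
        path = out / f"{row['id']}_suv.nii.gz"
        vol.save(path)
        images.append({"path": path.name, "subject": row["id"],
                       "sha256": _sha256(path), "bytes": path.stat().st_size})
    atlas_path = out / "atlas.nii.gz"
    atlas.save(atlas_path)
    images.append({"path": atlas_path.name, "subject": None,
                   "sha256": _sha256(atlas_path), "bytes": atlas_path.stat().st_size})

    cohort_path = out / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False)
    meta = {"name_map": {str(k): v for k, v in atlas.name_map.items()},
            "roles": {k: list(v) for k, v in atlas.roles.items()}}
    if config is not None:
        meta["config"] = asdict(config)
    (out / "atlas.json").write_text(json.dumps(meta, indent=2))

    manifest = {"images": images, "cohort": cohort_path.name, "atlas_meta": "atlas.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sex": str, "split": str})
    df["fold"] = pd.array(df["fold"] if "fold" in df else [pd.NA] * len(df), dtype="Int64")
    return df[COHORT_COLUMNS]
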