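"""Synthetic multimodal study generator.

Generates datasets with the statistical structure the pipeline assumes, so
every stage is exercisable without any download: two diagnostic groups
(default 19 vs 25 subjects), three co-registered modalities on one shared
grid (default 24^3 voxels of 3 mm), per-modality planted group-difference
patterns with a configurable cross-modality overlap, nuisance covariate
effects, Gaussian noise, a block-design BOLD task series (32 s active
blocks of three conditions, 20 s rest, TR 2 s) and a resting series whose
residual variance differs between groups on the resting pattern.

Patterns are spherical blobs with Gaussian-feathered (and truncated) edges;
the default geometry places the three modality blobs well inside the brain
template with disjoint supports, and the ``overlap`` knob linearly
interpolates every pattern toward one shared central blob (identical
patterns at overlap 1).

One integer seed governs all randomness through named independent
substreams (per modality and subject), so adding a subject never perturbs
another subject's data and any single volume can be regenerated in
isolation.  Ground-truth pattern volumes are part of the dataset for
recovery scoring.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .first_level import BlockParadigm, build_task_design
from .grids import VolumeGrid
from .parcellation import AtlasLabels

__all__ = [
    "PatternSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "simulate_subject_table",
    "simulate_structural",
    "simulate_task_series",
    "simulate_rest_series",
    "simulate_motion",
    "ground_truth_patterns",
    "brain_template",
    "make_atlas",
]

MODALITIES = ("structural", "task", "rest")


def _rng(seed: int, *names) -> np.random.Generator:
    """Named independent substream of the master seed."""
    key = zlib.crc32("/".join(str(n) for n in names).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class PatternSpec:
    """Spherical blob with a Gaussian-feathered, truncated edge.

    ``center_frac`` is the blob center as a fraction of the grid extent;
    ``radius_mm`` the flat core radius; ``feather_mm`` the Gaussian edge
    sigma (support truncated at radius + 2.5 sigma); ``amplitude`` scales
    the planted group difference.
    """

    center_frac: tuple[float, float, float]
    radius_mm: float = 7.5
    feather_mm: float = 2.4
    amplitude: float = 1.0


def _default_patterns() -> dict[str, PatternSpec]:
    # three blobs 120 degrees apart, slight z offsets, well inside the brain
    off = 0.26
    c = 0.5
    return {
        "structural": PatternSpec((c, c + off, c + 0.04)),
        "task": PatternSpec((c - off * 0.866, c - off * 0.5, c - 0.04)),
        "rest": PatternSpec((c + off * 0.866, c - off * 0.5, c)),
    }


@dataclass
class SimulationConfig:
    """Study-generating parameters (defaults are the emulated study shape)."""

    seed: int
    n_per_group: tuple[int, int] = (19, 25)
    group_names: tuple[str, str] = ("SCH", "DEP")
    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    patterns: dict[str, PatternSpec] = field(default_factory=_default_patterns)
    shared_pattern: PatternSpec = field(
        default_factory=lambda: PatternSpec((0.5, 0.5, 0.5))
    )
    overlap: float = 0.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"structural": 1.0, "task": 1.0, "rest": 1.0}
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "sex": 0.2, "tiv": 0.0}
    )
    rest_variance_effect: float = 0.5
    task_paradigm: BlockParadigm = field(default_factory=BlockParadigm.default_task)
    rest_n_volumes: int = 187
    template_gm: float = 5.0
    bold_baseline: float = 100.0
    task_activation_baseline: float = 1.0
    brain_radius_frac: float = 0.44
    atlas_n_regions: int = 114

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        self.shape = tuple(int(s) for s in self.shape)
        self.n_per_group = tuple(int(n) for n in self.n_per_group)
        self.group_names = tuple(self.group_names)
        if min(self.n_per_group) < 2:
            raise ValueError("need at least two subjects per group")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sd must be non-negative")
        ext = np.asarray(self.shape) * self.voxel_size_mm
        for name, p in self.patterns.items():
            extent = p.radius_mm + 2.5 * p.feather_mm
            center = np.asarray(p.center_frac) * ext
            if np.any(center - extent < 0) or np.any(center + extent > ext):
                raise ValueError(f"pattern {name!r} extends outside the grid")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        return aff

    def with_overlap(self, overlap: float) -> "SimulationConfig":
        return replace(self, overlap=overlap)


# --------------------------------------------------------------------------
# deterministic spatial structure


def _distance_mm(config: SimulationConfig, center_frac) -> np.ndarray:
    idx = np.indices(config.shape, dtype=float)
    center = np.asarray(center_frac) * np.asarray(config.shape)
    d2 = sum(
        ((idx[a] + 0.5 - center[a]) * config.voxel_size_mm) ** 2 for a in range(3)
    )
    return np.sqrt(d2)


def _blob(config: SimulationConfig, spec: PatternSpec) -> np.ndarray:
    d = _distance_mm(config, spec.center_frac)
    edge = np.clip(d - spec.radius_mm, 0.0, None)
    vals = np.exp(-(edge**2) / (2.0 * spec.feather_mm**2))
    vals[d > spec.radius_mm + 2.5 * spec.feather_mm] = 0.0
    return vals


def brain_template(config: SimulationConfig) -> VolumeGrid:
    """Feathered spherical brain (unit value inside, 0 outside)."""
    radius = config.brain_radius_frac * min(config.shape) * config.voxel_size_mm
    spec = PatternSpec((0.5, 0.5, 0.5), radius_mm=radius,
                       feather_mm=config.voxel_size_mm)
    return VolumeGrid(_blob(config, spec), affine=config.affine, units="template")


def ground_truth_patterns(config: SimulationConfig) -> dict[str, VolumeGrid]:
    """Planted group-difference pattern per modality (peak value 1).

    pattern_m = normalize((1 - overlap) * blob_m + overlap * shared_blob):
    disjoint supports at overlap 0, a single identical pattern at overlap 1.
    """
    shared = _blob(config, config.shared_pattern)
    out = {}
    for name, spec in config.patterns.items():
        raw = (1.0 - config.overlap) * _blob(config, spec) + config.overlap * shared
        peak = raw.max()
        if peak > 0:
            raw = raw / peak
        out[name] = VolumeGrid(raw, affine=config.affine, units=f"{name} pattern")
    return out


def _nuisance_map(config: SimulationConfig) -> np.ndarray:
    # covariate effects load on a broad off-center blob, distinct from the
    # group-difference patterns
    spec = PatternSpec((0.5, 0.5, 0.62), radius_mm=12.0, feather_mm=3.0)
    return _blob(config, spec)


# --------------------------------------------------------------------------
# subjects


def simulate_subject_table(config: SimulationConfig) -> pd.DataFrame:
    """Subject table: groups in block order, ages 25-60, TIV ~ N(1500, 120)."""
    rows = []
    for gi, (gname, n) in enumerate(zip(config.group_names, config.n_per_group)):
        for k in range(n):
            sid = f"sub-{gi + 1:d}{k + 1:03d}"
            rng = _rng(config.seed, "subject", sid)
            rows.append(
                {
                    "subject_id": sid,
                    "group": gname,
                    "age": float(np.round(rng.uniform(25.0, 60.0), 1)),
                    "sex": ("F", "M")[int(rng.integers(0, 2))],
                    "tiv": float(np.round(rng.normal(1500.0, 120.0), 1)),
                }
            )
    return pd.DataFrame(rows)


def _subject_row(config: SimulationConfig, index: int) -> pd.Series:
    return simulate_subject_table(config).iloc[index]


def _group_sign(config: SimulationConfig, group: str) -> float:
    return 1.0 if group == config.group_names[0] else -1.0


# --------------------------------------------------------------------------
# per-subject volumes


def simulate_structural(config: SimulationConfig, index: int) -> VolumeGrid:
    """Gray-matter-like map: template + group effect + covariate effects + noise.

    Values are floored at zero (gray-matter maps are non-negative); at the
    default template amplitude the floor is almost never reached.
    """
    row = _subject_row(config, index)
    g = _group_sign(config, row["group"])
    pattern = ground_truth_patterns(config)["structural"].data
    spec = config.patterns["structural"]
    nuis = _nuisance_map(config)
    z_age = (row["age"] - 42.5) / 10.0
    z_tiv = (row["tiv"] - 1500.0) / 120.0
    sex01 = 1.0 if row["sex"] == "M" else 0.0
    eff = config.covariate_effects
    mean = (
        config.template_gm * brain_template(config).data
        + 0.5 * g * spec.amplitude * pattern
        + eff.get("age", 0.0) * z_age * nuis
        + eff.get("sex", 0.0) * (sex01 - 0.5) * nuis
        + eff.get("tiv", 0.0) * z_tiv * brain_template(config).data
    )
    rng = _rng(config.seed, "structural", row["subject_id"])
    noisy = mean + config.noise_sd["structural"] * rng.standard_normal(config.shape)
    return VolumeGrid(np.clip(noisy, 0.0, None), affine=config.affine,
                      units="GM volume (a.u.)")


def _task_regressor(config: SimulationConfig) -> np.ndarray:
    design = build_task_design(config.task_paradigm, motion=None)
    return design.values[:, design.condition_columns].sum(axis=1)


def simulate_task_series(config: SimulationConfig, index: int) -> np.ndarray:
    """Block-design BOLD series, shape (x, y, z, t), float32.

    Activation amplitude on the task pattern is
    ``baseline + 0.5 * group_sign * amplitude``, so the groups differ in how
    strongly the planted region responds to the task.
    """
    row = _subject_row(config, index)
    g = _group_sign(config, row["group"])
    pattern = ground_truth_patterns(config)["task"].data.astype(np.float32)
    spec = config.patterns["task"]
    amp = config.task_activation_baseline + 0.5 * g * spec.amplitude
    x = _task_regressor(config).astype(np.float32)
    rng = _rng(config.seed, "task", row["subject_id"])
    t = config.task_paradigm.n_volumes
    series = rng.standard_normal(config.shape + (t,), dtype=np.float32)
    series *= np.float32(config.noise_sd["task"])
    series += np.float32(config.bold_baseline)
    series += amp * pattern[..., None] * x[None, None, None, :]
    return series


def simulate_rest_series(config: SimulationConfig, index: int) -> np.ndarray:
    """Resting BOLD series, shape (x, y, z, t), float32.

    Pure noise around the baseline whose standard deviation is modulated by
    the group on the resting pattern, so the residual-mean-square feature
    carries the group signal.
    """
    row = _subject_row(config, index)
    g = _group_sign(config, row["group"])
    pattern = ground_truth_patterns(config)["rest"].data.astype(np.float32)
    sd = np.float32(config.noise_sd["rest"]) * (
        1.0 + np.float32(0.5 * g * config.rest_variance_effect) * pattern
    )
    rng = _rng(config.seed, "rest", row["subject_id"])
    series = rng.standard_normal(config.shape + (config.rest_n_volumes,), dtype=np.float32)
    series *= sd[..., None]
    series += np.float32(config.bold_baseline)
    return series


def simulate_motion(config: SimulationConfig, index: int, modality: str) -> np.ndarray:
    """Six smooth small-amplitude motion traces (random walk), one row per volume."""
    row = _subject_row(config, index)
    t = (config.task_paradigm.n_volumes if modality == "task"
         else config.rest_n_volumes)
    rng = _rng(config.seed, "motion", modality, row["subject_id"])
    steps = rng.normal(0.0, 0.01, size=(t, 6))
    walk = np.cumsum(steps, axis=0)
    # light smoothing keeps the traces physically plausible
    kernel = np.ones(5) / 5.0
    return np.column_stack([np.convolve(walk[:, j], kernel, mode="same") for j in range(6)])


# --------------------------------------------------------------------------
# atlas


def make_atlas(shape, n_regions: int, seed: int, affine: np.ndarray | None = None) -> AtlasLabels:
    """Nearest-seed-point tessellation of the grid into contiguous regions."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    shape = tuple(int(s) for s in shape)
    n_vox = int(np.prod(shape))
    if n_regions > n_vox:
        raise ValueError("more regions than voxels requested")
    rng = _rng(seed, "atlas")
    flat = rng.choice(n_vox, size=n_regions, replace=False)
    seeds = np.column_stack(np.unravel_index(np.sort(flat), shape)).astype(float)
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    _, nearest = cKDTree(seeds).query(coords)
    labels = (nearest + 1).reshape(shape).astype(np.int32)
    vol = VolumeGrid(labels, affine=np.eye(4) if affine is None else affine)
    names = {i + 1: f"region_{i + 1:03d}" for i in range(n_regions)}
    return AtlasLabels(vol, names)


# --------------------------------------------------------------------------
# full dataset


@dataclass
class SyntheticDataset:
    """A complete in-memory synthetic study (optionally mirrored on disk)."""

    config: SimulationConfig
    subject_table: pd.DataFrame
    structural: list[VolumeGrid]
    task_series: list[np.ndarray]
    rest_series: list[np.ndarray]
    task_motion: list[np.ndarray]
    rest_motion: list[np.ndarray]
    patterns: dict[str, VolumeGrid]
    atlas: AtlasLabels
    root: Path | None = None


def simulate_dataset(config: SimulationConfig, out_dir=None) -> SyntheticDataset:
    """Generate the full study; with ``out_dir`` also write the on-disk layout.

    The on-disk layout is NIfTI volumes per subject and modality, the subject
    table as CSV (with per-modality path columns), whitespace-delimited
    motion tables, the atlas (NIfTI + CSV) and ground-truth pattern volumes
    under ``truth/``.
    """
    table = simulate_subject_table(config)
    n = config.n_subjects
    structural = [simulate_structural(config, i) for i in range(n)]
    task = [simulate_task_series(config, i) for i in range(n)]
    rest = [simulate_rest_series(config, i) for i in range(n)]
    task_motion = [simulate_motion(config, i, "task") for i in range(n)]
    rest_motion = [simulate_motion(config, i, "rest") for i in range(n)]
    patterns = ground_truth_patterns(config)
    atlas = make_atlas(config.shape, config.atlas_n_regions, config.seed,
                       affine=config.affine)
    ds = SyntheticDataset(
        config=config,
        subject_table=table,
        structural=structural,
        task_series=task,
        rest_series=rest,
        task_motion=task_motion,
        rest_motion=rest_motion,
        patterns=patterns,
        atlas=atlas,
    )
    if out_dir is not None:
        ds.root = _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SyntheticDataset, root: Path) -> Path:
    import nibabel as nib

    root.mkdir(parents=True, exist_ok=True)
    (root / "truth").mkdir(exist_ok=True)
    table = ds.subject_table.copy()
    paths: dict[str, list[str]] = {m: [] for m in MODALITIES}
    aff = ds.config.affine
    for i, sid in enumerate(table["subject_id"]):
        sub = root / sid
        sub.mkdir(exist_ok=True)
        ds.structural[i].save(sub / "structural.nii.gz")
        nib.save(nib.Nifti1Image(ds.task_series[i], aff), sub / "task.nii.gz")
        nib.save(nib.Nifti1Image(ds.rest_series[i], aff), sub / "rest.nii.gz")
        np.savetxt(sub / "task_motion.txt", ds.task_motion[i], fmt="%.6f")
        np.savetxt(sub / "rest_motion.txt", ds.rest_motion[i], fmt="%.6f")
        paths["structural"].append(str(sub / "structural.nii.gz"))
        paths["task"].append(str(sub / "task.nii.gz"))
        paths["rest"].append(str(sub / "rest.nii.gz"))
    for m in MODALITIES:
        table[m] = paths[m]
    table.to_csv(root / "subjects.csv", index=False)
    for name, vol in ds.patterns.items():
        vol.save(root / "truth" / f"pattern_{name}.nii.gz")
    ds.atlas.save(root / "atlas.nii.gz", root / "atlas_regions.csv")
    return root
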