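"""Shared fixtures: tiny grids and a reduced simulation profile.

The reduced profile keeps the full study structure (two groups, three
modalities, block paradigm, planted patterns with an overlap knob) on a
16^3 grid with a two-cycle paradigm so that multi-seed structural checks
stay fast; the full-size default configuration is exercised once per
session by the ``default_study`` fixture.
"""

from __future__ import annotations

import numpy as np
import pytest

from mlmfuse import (
    BlockParadigm,
    PatternSpec,
    PipelineConfig,
    SimulationConfig,
    run_study,
)


def make_volume(data, voxel=1.0):
    from mlmfuse import VolumeGrid

    aff = np.eye(4)
    aff[:3, :3] *= voxel
    return VolumeGrid(np.asarray(data, dtype=float), affine=aff)


def short_paradigm(n_cycles: int = 2) -> BlockParadigm:
    block, cycle = 52.0, 156.0
    onsets = {
        cond: [i * cycle + k * block for i in range(n_cycles)]
        for k, cond in enumerate(("DS", "DN", "PS"))
    }
    return BlockParadigm(onsets=onsets, n_volumes=int(n_cycles * cycle / 2.0))


def small_sim_config(seed: int, overlap: float = 0.0,
                     n_per_group=(5, 6), grid: int = 16) -> SimulationConfig:
    """Reduced study: 16^3 grid, 5 mm-core blobs, two paradigm cycles."""
    patterns = {
        "structural": PatternSpec((0.50, 0.74, 0.54), radius_mm=5.0, feather_mm=1.5),
        "task": PatternSpec((0.29, 0.38, 0.46), radius_mm=5.0, feather_mm=1.5),
        "rest": PatternSpec((0.71, 0.38, 0.50), radius_mm=5.0, feather_mm=1.5),
    }
    shared = PatternSpec((0.5, 0.5, 0.5), radius_mm=5.0, feather_mm=1.5)
    return SimulationConfig(
        seed=seed,
        n_per_group=tuple(n_per_group),
        shape=(grid,) * 3,
        patterns=patterns,
        shared_pattern=shared,
        overlap=overlap,
        task_paradigm=short_paradigm(),
        rest_n_volumes=60,
        atlas_n_regions=30,
    )


@pytest.fixture(scope="session")
def default_study():
    """Full-size default study (19 vs 25 subjects, 24^3 grid, overlap 0)."""
    config = PipelineConfig(simulate=SimulationConfig(seed=42))
    return run_study(config)


@pytest.fixture(scope="session")
def small_study():
    """One reduced-profile study shared across structural checks."""
    return run_study(PipelineConfig(simulate=small_sim_config(seed=7)))


def small_design_helper(rng, n: int = 120):
    """Compact block design with motion, for GLM calibration checks."""
    from mlmfuse import build_task_design

    block, cycle = 10.0, 30.0
    onsets = {c: [i * cycle + k * block for i in range(3)]
              for k, c in enumerate(("DS", "DN", "PS"))}
    p = BlockParadigm(onsets=onsets, duration=8.0, rest_duration=2.0, n_volumes=n)
    motion = rng.normal(size=(n, 6)).cumsum(axis=0) * 0.01
    return build_task_design(p, motion=motion)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
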