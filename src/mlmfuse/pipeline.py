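"""End-to-end study orchestration.

``run_study`` drives the whole analysis in memory: obtain per-subject
volumes (simulated subject-by-subject, or loaded from an on-disk layout),
extract the three first-level feature maps, build one shared analysis mask,
fit the stage-1 MLM per modality, fuse the three signatures in stage 2
(both the image-space and the dual load-space route), and summarize the
combined eigen-images per atlas region.  ``run_pipeline`` wraps it with
logging and a machine-readable results bundle on disk.

Feature extraction is streamed one subject at a time so the default study
size (44 subjects x three modalities, 4D series included) stays within a
small memory footprint.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .first_level import (
    build_task_design,
    fit_glm,
    omnibus_f_contrast,
    resting_feature_map,
    task_feature_map,
    vbm_feature_map,
)
from .fusion import FusionResults, ModalityFusion
from .grids import Mask, VolumeGrid, compute_mask, stack_volumes
from .mlm import MLM, MLMResults, build_mlm_design
from .parcellation import AtlasLabels, rank_regions, region_means
from .subjects import read_subject_table, subjects_to_frame

__all__ = ["PipelineConfig", "StudyResult", "run_study", "run_pipeline"]

log = logging.getLogger("mlmfuse")

#: fixed modality order used in all outputs
MODALITY_ORDER = ("rest", "task", "structural")


@dataclass
class PipelineConfig:
    """One config drives simulate -> features -> MLM x3 -> fusion -> regions.

    Exactly one of ``simulate`` (a :class:`~mlmfuse.simulate.SimulationConfig`)
    or ``subject_table`` (path to an on-disk study layout) must be given.
    """

    simulate: sim.SimulationConfig | None = None
    subject_table: str | None = None
    covariates: tuple[str, ...] = ("age", "sex", "tiv")
    task_paradigm: "object | None" = None  # BlockParadigm for loaded studies
    task_feature: str = "fmap"  # or "effects"
    fwhm_mm: float = 8.0
    mask_threshold: float | None = None
    atlas: str = "synthetic"  # or "<labels.nii>,<regions.csv>"
    atlas_n_regions: int = 114
    top_k_regions: int = 20
    out_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.subject_table is None):
            raise ValueError("exactly one of {simulate, subject_table} must be set")
        if self.simulate is None and self.seed is None:
            self.seed = 0

    @property
    def effective_seed(self) -> int:
        return self.simulate.seed if self.simulate is not None else int(self.seed or 0)


@dataclass
class StudyResult:
    """In-memory results bundle of one pipeline run."""

    config: PipelineConfig
    subject_table: pd.DataFrame
    mask: Mask
    stage1: dict[str, MLMResults]
    fusion: FusionResults
    fusion_scores_route: FusionResults
    atlas: AtlasLabels
    region_summaries: dict[str, pd.DataFrame]
    summary: dict


def _series_matrix(series4d: np.ndarray) -> np.ndarray:
    """(x, y, z, t) -> (t, voxels) with row-major voxel order."""
    t = series4d.shape[-1]
    return np.asarray(series4d, dtype=float).reshape(-1, t).T


def _volume_from_vector(vec: np.ndarray, shape, affine, units="") -> VolumeGrid:
    return VolumeGrid(vec.reshape(shape), affine=affine, units=units)


def _simulated_features(config: PipelineConfig):
    sc = config.simulate
    assert sc is not None
    table = sim.simulate_subject_table(sc)
    shape, affine = sc.shape, sc.affine
    feats: dict[str, list[VolumeGrid]] = {m: [] for m in MODALITY_ORDER}
    for i in range(sc.n_subjects):
        gm = sim.simulate_structural(sc, i)
        smoothed, _ = vbm_feature_map(gm, fwhm_mm=config.fwhm_mm)
        feats["structural"].append(smoothed)

        task4d = sim.simulate_task_series(sc, i)
        motion = sim.simulate_motion(sc, i, "task")
        design = build_task_design(sc.task_paradigm, motion=motion)
        fit = fit_glm(_series_matrix(task4d), design)
        fmap = task_feature_map(fit, omnibus_f_contrast(design), mode="fmap")
        feats["task"].append(_volume_from_vector(fmap, shape, affine, "omnibus F"))
        del task4d

        rest4d = sim.simulate_rest_series(sc, i)
        rms = resting_feature_map(_series_matrix(rest4d),
                                  motion=sim.simulate_motion(sc, i, "rest"))
        feats["rest"].append(_volume_from_vector(rms, shape, affine, "residual MS"))
        del rest4d
    return table, feats


def _loaded_features(config: PipelineConfig):
    import nibabel as nib

    records = read_subject_table(config.subject_table)
    table = subjects_to_frame(records)
    feats: dict[str, list[VolumeGrid]] = {m: [] for m in MODALITY_ORDER}
    root = Path(config.subject_table).parent
    for rec in records:
        def p(name):
            raw = Path(rec.modality_paths[name])
            return raw if raw.is_absolute() else root / raw

        gm = VolumeGrid.load(p("structural"))
        smoothed, _ = vbm_feature_map(gm, fwhm_mm=config.fwhm_mm)
        feats["structural"].append(smoothed)

        img = nib.load(str(p("task")))
        series = _series_matrix(np.asanyarray(img.dataobj))
        motion_path = p("task").parent / "task_motion.txt"
        motion = np.loadtxt(motion_path) if motion_path.exists() else None
        from .first_level import BlockParadigm

        # a series whose length disagrees with the paradigm is rejected by
        # the paradigm invariants (no silent trimming)
        paradigm = config.task_paradigm or BlockParadigm(n_volumes=series.shape[0])
        if paradigm.n_volumes != series.shape[0]:
            raise ValueError(
                f"task series of {rec.subject_id} has {series.shape[0]} volumes "
                f"but the paradigm expects {paradigm.n_volumes}"
            )
        design = build_task_design(paradigm, motion=motion)
        fit = fit_glm(series, design)
        fmap = task_feature_map(fit, omnibus_f_contrast(design), mode="fmap")
        feats["task"].append(
            _volume_from_vector(fmap, img.shape[:3], np.asarray(img.affine), "omnibus F")
        )

        img = nib.load(str(p("rest")))
        series = _series_matrix(np.asanyarray(img.dataobj))
        motion_path = p("rest").parent / "rest_motion.txt"
        motion = np.loadtxt(motion_path) if motion_path.exists() else None
        rms = resting_feature_map(series, motion=motion)
        feats["rest"].append(
            _volume_from_vector(rms, img.shape[:3], np.asarray(img.affine), "residual MS")
        )
    return table, feats


def _build_mask(config: PipelineConfig, feats: dict[str, list[VolumeGrid]]) -> Mask:
    """Brain mask from the structural mean, tightened to finite/varying features."""
    struct = feats["structural"]
    if config.mask_threshold is not None:
        thr = config.mask_threshold
    elif config.simulate is not None:
        thr = 0.2 * config.simulate.template_gm
    else:
        thr = 0.0
    keep = compute_mask(struct, threshold=thr, strategy="mean-above-threshold").data
    for m in MODALITY_ORDER:
        keep &= compute_mask(feats[m], strategy="finite-and-varying").data
    if not keep.any():
        raise ValueError("analysis mask is empty after combining modalities")
    return Mask(data=keep, affine=struct[0].affine)


def run_study(config: PipelineConfig) -> StudyResult:
    """Run the full two-stage analysis and return the in-memory bundle."""
    log.info("stage features: extracting per-subject feature maps")
    if config.simulate is not None:
        table, feats = _simulated_features(config)
    else:
        table, feats = _loaded_features(config)

    log.info("stage mask: building shared analysis mask")
    mask = _build_mask(config, feats)
    log.info("mask voxels: %d", mask.n_voxels)

    log.info("stage mlm: stage-1 MLM per modality")
    design = build_mlm_design(table, covariates=config.covariates)
    stage1: dict[str, MLMResults] = {}
    for m in MODALITY_ORDER:
        Y = stack_volumes(feats[m], mask, subject_ids=table["subject_id"])
        stage1[m] = MLM(Y, design).fit()
        log.info("  %s: eigenvalue %.4g", m, stage1[m].eigenvalues[0])

    log.info("stage fusion: stage-2 across modalities")
    fusion_model = ModalityFusion.from_mlm_results(stage1)
    fusion = fusion_model.fit("images")
    fusion_scores = fusion_model.fit("scores")

    log.info("stage parcellation: region summaries")
    if config.atlas == "synthetic":
        atlas = sim.make_atlas(mask.shape, config.atlas_n_regions,
                               config.effective_seed, affine=mask.affine)
    else:
        vol_path, table_path = (s.strip() for s in config.atlas.split(","))
        atlas = AtlasLabels.load(vol_path, table_path)
    region_summaries = {}
    for k in range(fusion.n_components):
        summary_k = region_means(fusion.component_volume(k), atlas, mask)
        region_summaries[f"component_{k + 1}"] = summary_k

    summary = _summary_dict(config, table, mask, stage1, fusion, fusion_scores)
    return StudyResult(
        config=config,
        subject_table=table,
        mask=mask,
        stage1=stage1,
        fusion=fusion,
        fusion_scores_route=fusion_scores,
        atlas=atlas,
        region_summaries=region_summaries,
        summary=summary,
    )


def _summary_dict(config, table, mask, stage1, fusion, fusion_scores) -> dict:
    groups = table["group"].value_counts().to_dict()
    duality_gap = float(
        np.max(np.abs(np.sort(fusion.eigenvalues) - np.sort(fusion_scores.eigenvalues)))
    )
    return {
        "n_subjects": int(len(table)),
        "groups": {str(k): int(v) for k, v in groups.items()},
        "mask_voxels": int(mask.n_voxels),
        "covariates": list(config.covariates),
        "seed": int(config.effective_seed),
        "stage1": {
            m: {
                "eigenvalues": [float(x) for x in r.eigenvalues],
                "variance_fractions": [float(x) for x in r.variance_fractions],
                "n_informative": int(r.n_informative),
            }
            for m, r in stage1.items()
        },
        "stage2": {
            "eigenvalues": [float(x) for x in fusion.eigenvalues],
            "variance_fractions": [float(x) for x in fusion.variance_fractions],
            "n_informative": int(fusion.n_informative),
            "modality_names": list(fusion.modality_names),
            "contributions": [[float(x) for x in row]
                              for row in fusion.modality_contributions],
            "contribution_shares": [[float(x) for x in row]
                                    for row in fusion.contribution_shares],
            "duality_max_eigenvalue_gap": duality_gap,
        },
    }


def run_pipeline(config: PipelineConfig) -> StudyResult:
    """Run the study and write the results bundle under ``config.out_dir``."""
    if config.out_dir is None:
        raise ValueError("out_dir is required for run_pipeline")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    stream = logging.StreamHandler(sys.stderr)
    for h in (handler, stream):
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(logging.INFO)
    stage = "features"
    try:
        result = run_study(config)
        stage = "write"
        result.mask.save(out / "mask.nii.gz")
        result.subject_table.to_csv(out / "subjects.csv", index=False)
        for m, r in result.stage1.items():
            r.save(out / "stage1", prefix=m)
        result.fusion.save(out / "stage2")
        for name, df in result.region_summaries.items():
            df.to_csv(out / f"regions_{name}.csv", index=False)
            rank_regions(df, min(config.top_k_regions, len(df))).to_csv(
                out / f"regions_{name}_top.csv", index=False
            )
        (out / "summary.json").write_text(
            json.dumps(result.summary, indent=2, sort_keys=True)
        )
        log.info("pipeline finished: %s", out / "summary.json")
        return result
    except Exception as exc:
        (out / "failed").mkdir(exist_ok=True)
        (out / "failed" / "stage.txt").write_text(f"{stage}: {exc}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        log.removeHandler(stream)
        handler.close()
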