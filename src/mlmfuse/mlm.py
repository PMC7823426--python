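"""Stage-1 multivariate linear method (MLM).

The MLM extracts, from one modality's subjects x voxels feature matrix Y,
the spatial pattern (eigen-image) that best expresses the modeled
difference between the two diagnostic groups, after adjusting both the data
and the group indicator for nuisance covariates (intercept, age, sex, TIV).

Fixed algorithm:

1. ``Y_adj = Y - X_n pinv(X_n) Y`` — residualize on the nuisance block.
2. ``g_adj = g - X_n pinv(X_n) g`` — residualize the +/-1 group code.
3. ``Y_hat = P_{g_adj} Y_adj`` — project onto the adjusted group direction
   (the constraint operationalized by the group-difference F test).
4. SVD of ``Y_hat``: right singular vectors are the eigen-images, squared
   singular values the eigenvalues; predicted subject scores are
   ``U @ diag(s)`` and empirical scores the projection of ``Y_adj`` onto the
   eigen-images.
5. The sign of each component is fixed so that the mean predicted score of
   the first group in ``group_order`` is non-negative.

For a two-level group factor the contrast space has rank one, so at most one
component is informative — the per-modality "brain signature".

The model object follows the statsmodels convention:
``MLM(Y, design).fit()`` returns an :class:`MLMResults` carrying eigen-images,
eigenvalues, variance fractions, scores and a :meth:`~MLMResults.summary`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Mask, MaskedMatrix, VolumeGrid, unmask
from .subjects import SubjectRecord, subjects_to_frame

__all__ = [
    "MLMDesign",
    "MLM",
    "MLMResults",
    "build_mlm_design",
    "fit_mlm",
    "informative_components",
    "correlation_map",
]

#: relative tolerance under which an eigenvalue counts as null
REL_TOL = 1e-6
#: absolute floor for the leading eigenvalue
ABS_FLOOR = 1e-12


@dataclass
class MLMDesign:
    """Two-group contrast plus nuisance covariates for the MLM.

    ``group_indicator`` is coded +1 for ``group_order[0]`` and -1 for
    ``group_order[1]``; continuous nuisance covariates are z-scored and sex is
    binary coded, with an intercept always present.
    """

    group_indicator: np.ndarray
    nuisance: np.ndarray
    group_order: tuple[str, str]
    nuisance_labels: list[str] = field(default_factory=list)
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.group_indicator = np.asarray(self.group_indicator, dtype=float).ravel()
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        n, q = self.nuisance.shape
        if self.group_indicator.size != n:
            raise ValueError("group indicator length must match nuisance rows")
        if n < q + 2:
            raise ValueError(f"need at least q+2={q + 2} subjects, got {n}")
        if not (np.any(self.group_indicator > 0) and np.any(self.group_indicator < 0)):
            raise ValueError("both group levels must be present")
        if not np.allclose(self.nuisance[:, 0], 1.0):
            raise ValueError("nuisance block must start with an intercept column")

    @property
    def n_subjects(self) -> int:
        return self.group_indicator.size


def build_mlm_design(
    subjects: "list[SubjectRecord] | pd.DataFrame",
    covariates: tuple[str, ...] = ("age", "sex", "tiv"),
    group_order: tuple[str, str] | None = None,
) -> MLMDesign:
    """Build the group contrast + nuisance design from a subject table.

    Continuous covariates are z-scored (population sd); sex is coded 0/1 by
    order of first appearance.  Column order is deterministic: intercept
    first, then the covariates in the requested order.
    """
    df = subjects if isinstance(subjects, pd.DataFrame) else subjects_to_frame(subjects)
    groups = df["group"].astype(str).tolist()
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError(f"only one group level present: {levels}")
    if len(levels) > 2:
        raise ValueError(f"more than two group levels: {levels}")
    order = tuple(group_order) if group_order else (levels[0], levels[1])
    if set(order) != set(levels):
        raise ValueError(f"group_order {order} does not match observed levels {levels}")
    g = np.where(np.array(groups) == order[0], 1.0, -1.0)

    n = len(df)
    cols = [np.ones(n)]
    labels = ["intercept"]
    ids = df["subject_id"].astype(str).tolist() if "subject_id" in df else None
    for name in covariates:
        if name not in df.columns:
            raise ValueError(f"covariate {name!r} not present in the subject table")
        raw = df[name]
        bad = raw.isna()
        if bad.any():
            who = (ids or [str(i) for i in range(n)])
            missing = [who[i] for i in np.flatnonzero(bad.to_numpy())]
            raise ValueError(f"missing {name!r} value for subject(s): {missing}")
        if name == "sex":
            sex_levels = list(dict.fromkeys(raw.astype(str)))
            if len(sex_levels) > 2:
                raise ValueError(f"sex has more than two levels: {sex_levels}")
            col = np.array([float(sex_levels.index(s)) for s in raw.astype(str)])
        else:
            col = raw.to_numpy(dtype=float)
            if not np.isfinite(col).all():
                raise ValueError(f"non-finite {name!r} values in subject table")
            sd = col.std()
            if sd == 0:
                raise ValueError(f"covariate {name!r} is constant; drop it")
            col = (col - col.mean()) / sd
        cols.append(col)
        labels.append(name)
    return MLMDesign(
        group_indicator=g,
        nuisance=np.column_stack(cols),
        group_order=order,  # type: ignore[arg-type]
        nuisance_labels=labels,
        subject_ids=ids,
    )


def informative_components(eigenvalues, rel_tol: float = REL_TOL,
                           abs_floor: float = ABS_FLOOR) -> int:
    """Number of eigenvalues that are non-null relative to the largest."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        return 0
    if np.any(ev < -abs_floor):
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(ev) > abs_floor):
        raise ValueError("eigenvalues must be sorted in descending order")
    if ev[0] <= abs_floor:
        return 0
    return int(np.sum(ev > rel_tol * ev[0]))


class MLM:
    """Stage-1 MLM model for one modality.

    Parameters
    ----------
    endog
        Subjects x voxels feature matrix (:class:`MaskedMatrix` or array);
        row order must match the design's subject order.
    design
        :class:`MLMDesign` with the two-group contrast and nuisance block.
    standardize
        If True, voxel-wise z-scoring of Y before the decomposition
        (off by default; the decomposition is run on raw adjusted features).
    """

    def __init__(self, endog, design: MLMDesign, standardize: bool = False):
        if isinstance(endog, MaskedMatrix):
            self.mask: Mask | None = endog.mask
            Y = endog.values
        else:
            self.mask = None
            Y = np.asarray(endog, dtype=float)
        if Y.ndim != 2:
            raise ValueError("endog must be 2D (subjects x voxels)")
        if Y.shape[0] != design.n_subjects:
            raise ValueError(
                f"endog has {Y.shape[0]} rows but design has {design.n_subjects} subjects"
            )
        if not np.isfinite(Y).all():
            raise ValueError("endog contains non-finite values")
        self.endog = Y
        self.design = design
        self.standardize = standardize

    @classmethod
    def from_subjects(cls, endog, subjects, covariates=("age", "sex", "tiv"), **kwargs):
        return cls(endog, build_mlm_design(subjects, covariates), **kwargs)

    def fit(self) -> "MLMResults":
        Y = self.endog
        if self.standardize:
            sd = Y.std(axis=0)
            sd[sd == 0] = 1.0
            Y = (Y - Y.mean(axis=0)) / sd
        Xn = self.design.nuisance
        g = self.design.group_indicator
        pinv_n = np.linalg.pinv(Xn)
        Y_adj = Y - Xn @ (pinv_n @ Y)
        g_adj = g - Xn @ (pinv_n @ g)
        g_norm = np.linalg.norm(g_adj)
        if g_norm < 1e-10 * max(np.linalg.norm(g), 1.0):
            raise ValueError(
                "group indicator is confounded with the nuisance block "
                "(no adjusted group variation left)"
            )
        # rank-1 contrast space: the projection of Y_adj onto g_adj is an
        # outer product, so its SVD is available in closed form.
        coef = (g_adj @ Y_adj) / (g_norm**2)  # per-voxel slope on g_adj
        coef_norm = np.linalg.norm(coef)
        s = g_norm * coef_norm
        eigenvalues = np.array([s**2])
        if s > ABS_FLOOR:
            v = coef / coef_norm
            u = g_adj / g_norm
            predicted = (u * s)[:, None]
            empirical = (Y_adj @ v)[:, None]
            eigen_images = v[None, :]
            # sign convention: mean predicted score of group_order[0] >= 0
            if predicted[g > 0, 0].mean() < 0:
                eigen_images = -eigen_images
                predicted = -predicted
                empirical = -empirical
            fractions = np.array([1.0])
        else:
            eigen_images = np.zeros((1, Y.shape[1]))
            predicted = np.zeros((Y.shape[0], 1))
            empirical = np.zeros((Y.shape[0], 1))
            fractions = np.array([0.0])
        return MLMResults(
            model=self,
            eigen_images=eigen_images,
            eigenvalues=eigenvalues,
            variance_fractions=fractions,
            predicted_scores=predicted,
            empirical_scores=empirical,
            adjusted_data=Y_adj,
        )


@dataclass
class MLMResults:
    """Results of a stage-1 MLM fit.

    ``eigen_images`` rows have unit Euclidean norm (a fully null component is
    stored as a zero row), ``eigenvalues`` are the squared singular values of
    the contrast-space projection, and ``variance_fractions`` partition the
    captured group-difference variance across components.
    """

    model: MLM
    eigen_images: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    predicted_scores: np.ndarray
    empirical_scores: np.ndarray
    adjusted_data: np.ndarray

    @property
    def design(self) -> MLMDesign:
        return self.model.design

    @property
    def mask(self) -> Mask | None:
        return self.model.mask

    @property
    def n_components(self) -> int:
        return self.eigen_images.shape[0]

    @property
    def n_informative(self) -> int:
        return informative_components(self.eigenvalues)

    def correlation_image(self, component: int = 0) -> np.ndarray:
        """Per-voxel correlation of the adjusted data with a component score."""
        return correlation_map(self.adjusted_data, self.empirical_scores[:, component])

    def eigen_image_volume(self, component: int = 0, correlation: bool = False) -> VolumeGrid:
        if self.mask is None:
            raise ValueError("no mask attached to this fit")
        vec = (
            self.correlation_image(component)
            if correlation
            else self.eigen_images[component]
        )
        return unmask(vec, self.mask)

    def scores_frame(self) -> pd.DataFrame:
        d = self.design
        df = pd.DataFrame(
            {
                "group": np.where(d.group_indicator > 0, d.group_order[0], d.group_order[1]),
                "empirical": self.empirical_scores[:, 0],
                "predicted": self.predicted_scores[:, 0],
            }
        )
        if d.subject_ids is not None:
            df.insert(0, "subject_id", d.subject_ids)
        return df

    def summary(self) -> str:
        d = self.design
        lines = [
            "Stage-1 MLM results",
            "=" * 60,
            f"subjects:             {d.n_subjects} "
            f"({d.group_order[0]}: {int(np.sum(d.group_indicator > 0))}, "
            f"{d.group_order[1]}: {int(np.sum(d.group_indicator < 0))})",
            f"voxels:               {self.eigen_images.shape[1]}",
            f"nuisance covariates:  {', '.join(d.nuisance_labels)}",
            f"informative comps:    {self.n_informative}",
            "",
            "component   eigenvalue   variance fraction",
        ]
        for k in range(self.n_components):
            lines.append(
                f"{k + 1:9d}   {self.eigenvalues[k]:10.4g}   {self.variance_fractions[k]:17.4f}"
            )
        sf = self.scores_frame()
        means = sf.groupby("group", sort=False)["empirical"].mean()
        lines += ["", "mean empirical score by group:"]
        for name, val in means.items():
            lines.append(f"  {name}: {val:+.4f}")
        return "\n".join(lines)

    def save(self, outdir, prefix: str = "mlm") -> None:
        """Write eigen-images (NIfTI), scores (CSV) and metadata (JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.mask is not None:
            for k in range(self.n_components):
                self.eigen_image_volume(k).save(outdir / f"{prefix}_eigenimage_{k + 1}.nii.gz")
                if self.eigenvalues[k] > ABS_FLOOR:
                    self.eigen_image_volume(k, correlation=True).save(
                        outdir / f"{prefix}_corrmap_{k + 1}.nii.gz"
                    )
        self.scores_frame().to_csv(outdir / f"{prefix}_scores.csv", index=False)
        meta = {
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_informative": self.n_informative,
            "group_order": list(self.design.group_order),
            "nuisance": self.design.nuisance_labels,
            "rel_tol": REL_TOL,
        }
        (outdir / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def fit_mlm(Y, design: MLMDesign, standardize: bool = False) -> MLMResults:
    """Functional wrapper: ``MLM(Y, design).fit()``."""
    return MLM(Y, design, standardize=standardize).fit()


def correlation_map(Y_adj, scores) -> np.ndarray:
    """Per-voxel Pearson correlation with a component score vector.

    Zero-variance voxels are mapped to 0 (with a warning); constant scores
    are an error.
    """
    Y = Y_adj.values if isinstance(Y_adj, MaskedMatrix) else np.asarray(Y_adj, dtype=float)
    s = np.asarray(scores, dtype=float).ravel()
    if s.size != Y.shape[0]:
        raise ValueError("scores length must equal the number of subjects")
    s_c = s - s.mean()
    s_norm = np.linalg.norm(s_c)
    if s_norm == 0:
        raise ValueError("component scores are constant")
    Yc = Y - Y.mean(axis=0)
    v_norm = np.linalg.norm(Yc, axis=0)
    n_flat = int(np.sum(v_norm == 0))
    if n_flat:
        warnings.warn(
            f"{n_flat} zero-variance voxel(s) mapped to correlation 0", RuntimeWarning
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (s_c @ Yc) / (s_norm * v_norm)
    return np.where(v_norm == 0, 0.0, corr)
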