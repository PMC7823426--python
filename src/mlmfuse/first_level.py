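"""Per-subject first-level feature extraction.

Three feature images feed the stage-1 multivariate decomposition, one per
modality:

* **task fMRI** — an ordinary-least-squares GLM of the block-design time
  series with boxcar regressors convolved with the canonical double-gamma
  HRF plus six rigid-body motion covariates; the subject-level feature is
  the omnibus F map over all active conditions, with the contrast
  orthogonalized against the motion effect (an ``effects`` mode returning
  the per-condition effect maps is also available).
* **resting fMRI** — the residual mean square map after a nuisance-only GLM
  (intercept plus optional motion), i.e. the per-voxel residual variance of
  the resting series.
* **structural MRI** — the gray-matter map smoothed with an 8 mm FWHM
  Gaussian, with total intracranial volume (TIV) derived from the tissue
  maps when available.

The GLM here is deliberately plain OLS: no autocorrelation whitening, drift
model or slice-timing handling.  Series are assumed realigned/normalized and
dummy-scan-trimmed upstream; a length mismatch with the paradigm is an error,
never a silent trim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import VolumeGrid, smooth_gaussian

__all__ = [
    "BlockParadigm",
    "DesignMatrix",
    "GLMFit",
    "FContrast",
    "canonical_hrf",
    "build_task_design",
    "fit_glm",
    "omnibus_f_contrast",
    "task_feature_map",
    "resting_feature_map",
    "vbm_feature_map",
]

DEFAULT_CONDITIONS = ("DS", "DN", "PS")


@dataclass
class BlockParadigm:
    """Block-design paradigm: alternating active blocks separated by rest.

    The default paradigm cycles the three active conditions (DS, DN, PS),
    each 32 s block followed by a 20 s rest fixation, the whole cycle
    repeated four times, at TR 2 s.
    """

    condition_names: tuple[str, ...] = DEFAULT_CONDITIONS
    onsets: dict[str, list[float]] = field(default_factory=dict)
    duration: float = 32.0
    rest_duration: float = 20.0
    tr: float = 2.0
    n_volumes: int = 312

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if not self.onsets:
            self.onsets = self._default_onsets()
        total = self.n_volumes * self.tr
        for cond in self.condition_names:
            ons = self.onsets.get(cond, [])
            if any(o < 0 for o in ons):
                raise ValueError(f"negative onset for condition {cond}")
            if list(ons) != sorted(ons) or len(set(ons)) != len(ons):
                raise ValueError(f"onsets must be strictly increasing for {cond}")
            if any(o + self.duration > total + 1e-9 for o in ons):
                raise ValueError(
                    f"block of condition {cond} extends beyond the acquisition "
                    f"({self.n_volumes} volumes x {self.tr} s)"
                )

    def _default_onsets(self, n_cycles: int = 4) -> dict[str, list[float]]:
        block = self.duration + self.rest_duration
        cycle = block * len(self.condition_names)
        return {
            cond: [c * cycle + k * block for c in range(n_cycles)]
            for k, cond in enumerate(self.condition_names)
        }

    @classmethod
    def default_task(cls) -> "BlockParadigm":
        return cls()

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def boxcar(self, condition: str) -> np.ndarray:
        """Condition indicator sampled at the volume acquisition times."""
        t = self.frame_times
        box = np.zeros(self.n_volumes)
        for onset in self.onsets.get(condition, []):
            box[(t >= onset - 1e-9) & (t < onset + self.duration - 1e-9)] = 1.0
        return box


@dataclass
class DesignMatrix:
    """GLM design: condition regressors, optional motion block, intercept."""

    values: np.ndarray
    labels: list[str]
    condition_columns: list[int]
    nuisance_columns: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design values must be 2D")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values))


@dataclass
class GLMFit:
    """OLS fit of a design to a time x voxels series."""

    betas: np.ndarray  # n_regressors x n_voxels
    residual_variance: np.ndarray  # per-voxel RSS / dof
    dof: int
    design: DesignMatrix


@dataclass
class FContrast:
    """k x n_regressors contrast matrix for a joint F test."""

    contrast_rows: np.ndarray

    def __post_init__(self) -> None:
        self.contrast_rows = np.atleast_2d(np.asarray(self.contrast_rows, dtype=float))
        if np.linalg.matrix_rank(self.contrast_rows) < self.contrast_rows.shape[0]:
            raise ValueError("contrast rows must be linearly independent")

    @property
    def k(self) -> int:
        return self.contrast_rows.shape[0]


def canonical_hrf(
    tr: float,
    length: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, sampled at ``tr``.

    h(t) = Gamma(peak_delay/peak_disp, peak_disp).pdf(t)
         - Gamma(undershoot_delay/undershoot_disp, undershoot_disp).pdf(t) / ratio

    With the default parameters the response peaks near 6 s with an
    undershoot near 16 s.  The closed form is sampled directly at the frame
    times (no discrete renormalization), so kernels sampled at different TRs
    agree exactly at shared time points.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if length <= 0:
        raise ValueError("length must be > 0")
    t = np.arange(0.0, length, tr)
    h = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    h = h - stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp) / ratio
    return h


def _collinear_labels(values: np.ndarray, labels: list[str]) -> list[str]:
    # flag columns whose R diagonal is (near) zero in a pivoted-free QR
    _, r = np.linalg.qr(values)
    diag = np.abs(np.diag(r))
    tol = max(values.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [labels[i] for i in range(len(diag)) if diag[i] <= tol]


def build_task_design(paradigm: BlockParadigm, motion: np.ndarray | None = None) -> DesignMatrix:
    """Boxcar-convolved-with-HRF condition columns + motion + intercept."""
    hrf = canonical_hrf(paradigm.tr)
    cols, labels = [], []
    for cond in paradigm.condition_names:
        box = paradigm.boxcar(cond)
        cols.append(np.convolve(box, hrf)[: paradigm.n_volumes])
        labels.append(cond)
    condition_columns = list(range(len(cols)))
    nuisance_columns = []
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (paradigm.n_volumes, 6):
            raise ValueError(
                f"motion table must be {paradigm.n_volumes} x 6, got {motion.shape}"
            )
        for j in range(6):
            nuisance_columns.append(len(cols))
            cols.append(motion[:, j])
            labels.append(f"motion_{j + 1}")
    nuisance_columns.append(len(cols))
    cols.append(np.ones(paradigm.n_volumes))
    labels.append("intercept")
    values = np.column_stack(cols)
    if np.linalg.matrix_rank(values) < values.shape[1]:
        bad = _collinear_labels(values, labels)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(values, labels, condition_columns, nuisance_columns)


def fit_glm(series: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares fit of ``design`` to every voxel of ``series``.

    ``series`` is time x voxels.  Each voxel is solved independently (the
    joint matrix solve is algebraically identical).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if not np.isfinite(series).all():
        raise ValueError("series contains non-finite values")
    X = design.values
    if series.shape[0] != X.shape[0]:
        raise ValueError(
            f"series has {series.shape[0]} volumes but design has {X.shape[0]}"
        )
    rank = design.rank
    if rank < X.shape[1]:
        bad = _collinear_labels(X, design.labels)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    dof = series.shape[0] - rank
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    betas, _, _, _ = np.linalg.lstsq(X, series, rcond=None)
    resid = series - X @ betas
    rss = np.einsum("tv,tv->v", resid, resid)
    return GLMFit(betas=betas, residual_variance=rss / dof, dof=dof, design=design)


def omnibus_f_contrast(design: DesignMatrix) -> FContrast:
    """F contrast over all conditions, orthogonal to the nuisance effect.

    Row j starts from the selector of condition j and subtracts the
    nuisance-block projection of that condition column, so that the tested
    design-space directions ``X @ c_j`` have zero inner product with every
    nuisance column (for an orthogonal design the rows reduce to plain
    selectors).
    """
    if not design.condition_columns:
        raise ValueError("design has no condition columns")
    X = design.values
    Xn = X[:, design.nuisance_columns]
    Xc = X[:, design.condition_columns]
    coef, _, _, _ = np.linalg.lstsq(Xn, Xc, rcond=None)  # q x k
    rows = np.zeros((len(design.condition_columns), design.n_regressors))
    for i, j in enumerate(design.condition_columns):
        rows[i, j] = 1.0
        for qi, q in enumerate(design.nuisance_columns):
            rows[i, q] = -coef[qi, i]
    return FContrast(contrast_rows=rows)


def task_feature_map(fit: GLMFit, contrast: FContrast, mode: str = "fmap") -> np.ndarray:
    """Per-voxel omnibus F statistic (or contrast effect maps).

    F = (c'b)' [C (X'X)^+ C']^{-1} (c'b) / (k * residual_variance), the
    standard contrast quadratic form.  Voxels with zero residual variance get
    +inf and a warning (they are expected to be excluded by the mask).

    Returns a length n_voxels vector in ``fmap`` mode or a k x n_voxels
    array in ``effects`` mode.
    """
    C = contrast.contrast_rows
    if C.shape[1] != fit.design.n_regressors:
        raise ValueError("contrast is not compatible with the fitted design")
    cb = C @ fit.betas  # k x V
    if mode == "effects":
        return cb
    if mode != "fmap":
        raise ValueError(f"unknown task feature mode: {mode!r}")
    # The tested design-space directions B = X C' are orthogonal to the
    # nuisance columns by construction, so the contrast quadratic form
    # (C b)' [C (X'X)^+ C']^{-1} (C b) equals the extra sum of squares
    # || P_B y ||^2 — computed here through an orthonormal basis of B,
    # which stays stable when regressor scales differ by orders of
    # magnitude (tiny motion columns vs unit boxcars).
    X = fit.design.values
    B = X @ C.T  # n_volumes x k
    Q, _ = np.linalg.qr(B)
    fitted = X @ fit.betas
    proj = Q.T @ fitted  # k x V
    quad = np.einsum("kv,kv->v", proj, proj)
    k = contrast.k
    n_zero = int(np.sum(fit.residual_variance == 0))
    if n_zero:
        warnings.warn(
            f"{n_zero} voxel(s) have zero residual variance; F set to +inf there "
            "(exclude them with the analysis mask)",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = quad / (k * fit.residual_variance)
    f = np.where(fit.residual_variance == 0, np.inf, f)
    return f


def resting_feature_map(series: np.ndarray, motion: np.ndarray | None = None) -> np.ndarray:
    """Residual mean square per voxel after a nuisance-only GLM.

    The resting model has nothing to convolve: intercept plus (optionally)
    the six motion parameters.  The returned map is RSS/dof per voxel — the
    residual-variance feature of the resting modality.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    n = series.shape[0]
    cols = []
    labels = []
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n, 6):
            raise ValueError(f"motion table must be {n} x 6, got {motion.shape}")
        cols.extend(motion.T)
        labels.extend(f"motion_{j + 1}" for j in range(6))
    cols.append(np.ones(n))
    labels.append("intercept")
    X = np.column_stack(cols)
    design = DesignMatrix(X, labels, condition_columns=[],
                          nuisance_columns=list(range(X.shape[1])))
    return fit_glm(series, design).residual_variance


def vbm_feature_map(
    gm: VolumeGrid,
    fwhm_mm=(8.0, 8.0, 8.0),
    tissue_maps: list[VolumeGrid] | None = None,
) -> tuple[VolumeGrid, float | None]:
    """Smoothed gray-matter feature map, plus TIV when tissue maps are given.

    TIV (ml) = voxel volume (mm^3) x sum over all supplied tissue maps
    (GM + WM + CSF) / 1000.  Without tissue maps the TIV must come from the
    subject table and ``None`` is returned.
    """
    if np.any(np.asarray(gm.data) < 0):
        raise ValueError("gray-matter map contains negative values")
    smoothed = smooth_gaussian(gm, fwhm_mm)
    tiv = None
    if tissue_maps:
        total = sum(float(np.asarray(m.data).sum()) for m in tissue_maps)
        tiv = gm.voxel_volume * total / 1000.0
    return smoothed, tiv
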