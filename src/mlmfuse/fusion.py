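"""Stage-2 MLM: cross-modality fusion of stage-1 signatures.

Stage 1 returns one unit-norm discriminative eigen-image per modality.
Stage 2 decomposes the M x n_voxels matrix of these signatures into up to M
combined components: the right singular vectors are the combined
eigen-images, the left singular vectors give each modality's contribution
weight to each component, and the squared singular values (normalized)
partition the group-difference variance across components — the quantity
reported as "variance explained by each component".

Because stage-1 signatures already live in the group-difference space, the
group contrast is not re-applied here; with three modalities up to three
components can be informative, and they are exactly three whenever the
modality signatures are linearly independent.

The decomposition has the usual SVD duality: the image space (voxels) and
the load space (components/subjects) are two coordinate systems of the same
object, one obtained from the other by a matrix transformation.  The
``scores`` route therefore eigendecomposes the small M x M Gram matrix and
reconstructs the eigen-images through the dual transform, expressing fused
subject loads through the supplied stage-1 subject scores; its spectrum,
contributions and images agree with the image-space route (up to
per-component sign, and up to rotation inside exactly degenerate
eigenspaces).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Mask, VolumeGrid, unmask
from .mlm import ABS_FLOOR, MLMResults, informative_components

__all__ = [
    "FusionInput",
    "ModalityFusion",
    "FusionResults",
    "fuse_signatures",
    "fuse_from_scores",
]

DEFAULT_MODALITIES = ("rest", "task", "structural")

UNIT_NORM_ATOL = 1e-8


@dataclass
class FusionInput:
    """Input bundle for stage-2 fusion.

    ``signatures`` holds one unit-norm stage-1 eigen-image per modality
    (M x n_voxels, shared mask); ``subject_scores`` optionally carries the
    n x M stage-1 empirical subject scores.
    """

    signatures: np.ndarray
    modality_names: tuple[str, ...] = DEFAULT_MODALITIES
    subject_scores: np.ndarray | None = None
    mask: Mask | None = None

    def __post_init__(self) -> None:
        self.signatures = np.atleast_2d(np.asarray(self.signatures, dtype=float))
        M = self.signatures.shape[0]
        if M < 2:
            raise ValueError("fusion needs at least two modality signatures")
        if len(self.modality_names) != M:
            raise ValueError("one modality name per signature row is required")
        norms = np.linalg.norm(self.signatures, axis=1)
        zero = norms <= ABS_FLOOR
        if zero.any():
            warnings.warn(
                "modality signature(s) with no informative component: "
                f"{[self.modality_names[i] for i in np.flatnonzero(zero)]}; "
                "fusion proceeds on the remaining rank",
                RuntimeWarning,
            )
        bad = ~zero & (np.abs(norms - 1.0) > UNIT_NORM_ATOL)
        if bad.any():
            raise ValueError(
                "signature rows must have unit Euclidean norm: "
                f"{[self.modality_names[i] for i in np.flatnonzero(bad)]}"
            )
        if self.subject_scores is not None:
            self.subject_scores = np.asarray(self.subject_scores, dtype=float)
            if self.subject_scores.ndim != 2 or self.subject_scores.shape[1] != M:
                raise ValueError("subject_scores must be n_subjects x n_modalities")

    @property
    def n_modalities(self) -> int:
        return self.signatures.shape[0]


class ModalityFusion:
    """Stage-2 fusion model over per-modality stage-1 signatures.

    ``ModalityFusion(signatures, ...).fit()`` decomposes in image space;
    ``fit(method="scores")`` runs the dual load-space route.
    """

    def __init__(self, signatures, modality_names=None, subject_scores=None, mask=None):
        if isinstance(signatures, FusionInput):
            self.input = signatures
        else:
            signatures = np.atleast_2d(np.asarray(signatures, dtype=float))
            if modality_names is None:
                modality_names = DEFAULT_MODALITIES[: signatures.shape[0]]
            self.input = FusionInput(
                signatures=signatures,
                modality_names=tuple(modality_names),
                subject_scores=subject_scores,
                mask=mask,
            )

    @classmethod
    def from_mlm_results(cls, results: dict[str, MLMResults]) -> "ModalityFusion":
        """Assemble fusion input from named stage-1 results (shared mask)."""
        names = tuple(results.keys())
        if len(names) < 2:
            raise ValueError("fusion needs at least two stage-1 results")
        masks = [r.mask for r in results.values()]
        ref = masks[0]
        if ref is not None:
            for name, m in zip(names, masks):
                if m is None or not (
                    m.shape == ref.shape and np.array_equal(m.data, ref.data)
                ):
                    raise ValueError(f"mask mismatch across signatures (modality {name!r})")
        rows, score_cols = [], []
        for name, r in results.items():
            if r.n_informative == 0:
                rows.append(np.zeros(r.eigen_images.shape[1]))
            else:
                rows.append(r.eigen_images[0])
            score_cols.append(r.empirical_scores[:, 0])
        return cls(
            np.vstack(rows),
            modality_names=names,
            subject_scores=np.column_stack(score_cols),
            mask=ref,
        )

    def fit(self, method: str = "images") -> "FusionResults":
        if method == "images":
            return self._fit_images()
        if method == "scores":
            return self._fit_scores()
        raise ValueError(f"unknown fusion method: {method!r}")

    # -- image-space route -------------------------------------------------
    def _fit_images(self) -> "FusionResults":
        A = self.input.signatures
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        eigenvalues = s**2
        U, Vt = _fix_signs(U, Vt)
        return self._package(eigenvalues, U, Vt, method="images")

    # -- load-space (dual) route -------------------------------------------
    def _fit_scores(self) -> "FusionResults":
        if self.input.subject_scores is None:
            raise ValueError("subject_scores are required for the scores route")
        Z = self.input.subject_scores
        if np.any(Z.std(axis=0) == 0):
            raise ValueError("subject score columns must be non-constant")
        A = self.input.signatures
        gram = A @ A.T  # M x M — the load-space representation of the fusion
        w, U = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1]
        eigenvalues = np.clip(w[order], 0.0, None)
        U = U[:, order]
        # dual transform back to image space: V_k = A' u_k / s_k
        Vt = np.zeros((U.shape[1], A.shape[1]))
        for k in range(U.shape[1]):
            if eigenvalues[k] > ABS_FLOOR:
                Vt[k] = (U[:, k] @ A) / np.sqrt(eigenvalues[k])
        U, Vt = _fix_signs(U, Vt)
        return self._package(eigenvalues, U, Vt, method="scores")

    def _package(self, eigenvalues, U, Vt, method: str) -> "FusionResults":
        total = eigenvalues.sum()
        fractions = eigenvalues / total if total > ABS_FLOOR else np.zeros_like(eigenvalues)
        loads = None
        if self.input.subject_scores is not None:
            Z = self.input.subject_scores
            norms = np.linalg.norm(Z, axis=0)
            norms[norms == 0] = 1.0
            loads = (Z / norms) @ U
        return FusionResults(
            model=self,
            method=method,
            eigenvalues=eigenvalues,
            variance_fractions=fractions,
            modality_contributions=U,
            combined_eigen_images=Vt,
            subject_loads=loads,
        )


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per component, make the largest-magnitude modality contribution positive."""
    U = U.copy()
    Vt = Vt.copy()
    for k in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]
    return U, Vt


@dataclass
class FusionResults:
    """Results of the stage-2 fusion.

    ``modality_contributions`` are the signed weights (columns of unit norm);
    :attr:`contribution_shares` gives the squared-normalized shares, a
    probability vector per component.  ``variance_fractions`` sum to 1 over
    the (non-null) components.
    """

    model: ModalityFusion
    method: str
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    modality_contributions: np.ndarray  # M x K, signed
    combined_eigen_images: np.ndarray  # K x n_voxels
    subject_loads: np.ndarray | None = None

    @property
    def modality_names(self) -> tuple[str, ...]:
        return self.model.input.modality_names

    @property
    def mask(self) -> Mask | None:
        return self.model.input.mask

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    @property
    def n_informative(self) -> int:
        return informative_components(self.eigenvalues)

    @property
    def contribution_shares(self) -> np.ndarray:
        shares = self.modality_contributions**2
        totals = shares.sum(axis=0)
        totals[totals == 0] = 1.0
        return shares / totals

    def contributions_frame(self) -> pd.DataFrame:
        cols = [f"component_{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.modality_contributions, index=list(self.modality_names),
                            columns=cols)

    def component_volume(self, component: int = 0) -> VolumeGrid:
        if self.mask is None:
            raise ValueError("no mask attached to this fusion")
        return unmask(self.combined_eigen_images[component], self.mask)

    def summary(self) -> str:
        lines = [
            "Stage-2 MLM fusion results",
            "=" * 60,
            f"modalities:         {', '.join(self.modality_names)}",
            f"method:             {self.method}",
            f"informative comps:  {self.n_informative} (max {self.n_components})",
            "",
            "component   eigenvalue   variance fraction",
        ]
        for k in range(self.n_components):
            lines.append(
                f"{k + 1:9d}   {self.eigenvalues[k]:10.4g}   {self.variance_fractions[k]:17.4f}"
            )
        lines += ["", "modality contributions (signed):",
                  self.contributions_frame().round(4).to_string()]
        return "\n".join(lines)

    def save(self, outdir, prefix: str = "fusion") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.mask is not None:
            for k in range(self.n_components):
                self.component_volume(k).save(outdir / f"{prefix}_component_{k + 1}.nii.gz")
        self.contributions_frame().to_csv(outdir / f"{prefix}_contributions.csv")
        pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "variance_fraction": self.variance_fractions,
            },
            index=[f"component_{k + 1}" for k in range(self.n_components)],
        ).to_csv(outdir / f"{prefix}_spectrum.csv")


def fuse_signatures(input, modality_names=None, subject_scores=None, mask=None) -> FusionResults:
    """Image-space fusion of the stage-1 signatures (functional wrapper)."""
    return ModalityFusion(input, modality_names, subject_scores, mask).fit("images")


def fuse_from_scores(input, modality_names=None, subject_scores=None, mask=None) -> FusionResults:
    """Load-space (dual) fusion route; requires stage-1 subject scores."""
    return ModalityFusion(input, modality_names, subject_scores, mask).fit("scores")
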