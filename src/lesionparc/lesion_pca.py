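"""Varimax-rotated PCA of the patients x voxels abnormality matrix.

The lesion cohort is decomposed into orthogonally rotated principal
components whose voxel loadings, back-projected into brain space and
z-thresholded, form a data-driven parcellation of lesion covariance (in
real stroke data these track the vascular territories).  Model order is
estimated from the eigenvalue spectrum with the minimum-description-length
(MDL) and Kullback information (KIC) criteria, and order stability is
assessed by patient subsampling.

The entry point follows the statsmodels convention: ``LesionPCA(matrix)``
is the model, ``.fit(k)`` returns a :class:`LesionPCAResults` object that
carries eigenvalues, rotated loadings, patient scores and the
map-rendering methods.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rotation import varimax_criterion, varimax_rotation
from .volumes import BrainMask, Volume, extract_clusters


# ---------------------------------------------------------------------------
# Lesion matrix
# ---------------------------------------------------------------------------


@dataclass
class LesionMatrix:
    """Patients x in-mask voxels matrix with a map back to voxel space.

    ``values`` holds the (optionally column-centred) data; ``column_means``
    records the centring so a zero-lesion patient can be reconstructed.
    """

    values: np.ndarray
    column_means: np.ndarray
    voxel_indices: np.ndarray  # (n_voxels, 3) int
    patient_ids: list[str]
    affine: np.ndarray
    grid_shape: tuple[int, int, int]
    centered: bool = True

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("lesion matrix contains non-finite values")
        if self.values.shape[0] < 3:
            raise ValueError(
                f"need at least 3 patients, got {self.values.shape[0]}"
            )
        if self.values.shape[1] != self.voxel_indices.shape[0]:
            raise ValueError("column count does not match the voxel index map")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_volume(self, column_values: np.ndarray, role: str = "scalar") -> Volume:
        """Scatter a per-voxel vector back into a volume on the grid."""
        data = np.zeros(self.grid_shape, dtype=float)
        data[tuple(self.voxel_indices.T)] = np.asarray(column_values, dtype=float)
        return Volume(data, self.affine, role)

    def uncentered(self) -> np.ndarray:
        return self.values + self.column_means

    def voxel_mm(self, rows=None) -> np.ndarray:
        """mm coordinates of (a subset of) the in-mask voxels."""
        idx = self.voxel_indices if rows is None else np.atleast_2d(
            self.voxel_indices[rows]
        )
        return idx.astype(float) @ self.affine[:3, :3].T + self.affine[:3, 3]


def assemble_lesion_matrix(
    volumes: Sequence[Volume],
    mask: BrainMask,
    patient_ids: Sequence[str] | None = None,
    center: bool = True,
) -> LesionMatrix:
    """Stack per-patient volumes into a patients x in-mask voxels matrix."""
    idx = mask.indices
    grid = mask.volume.grid_shape
    rows = []
    for v in volumes:
        if not mask.volume.same_grid(v):
            raise ValueError("lesion volume grid does not match the brain mask")
        rows.append(np.asarray(v.data, dtype=float)[tuple(idx.T)])
    X = np.asarray(rows)
    if not np.all(np.isfinite(X)):
        raise ValueError("lesion volumes contain non-finite values")
    if patient_ids is None:
        patient_ids = [f"patient_{i:03d}" for i in range(len(volumes))]
    means = X.mean(axis=0) if center else np.zeros(X.shape[1])
    return LesionMatrix(
        values=X - means,
        column_means=means,
        voxel_indices=idx,
        patient_ids=list(patient_ids),
        affine=mask.volume.affine,
        grid_shape=grid,
        centered=center,
    )


# ---------------------------------------------------------------------------
# Model-order estimation (eigenvalue-sphericity information criteria)
# ---------------------------------------------------------------------------


@dataclass
class OrderEstimate:
    k_mdl: int
    k_kic: int
    mdl_curve: np.ndarray  # index = candidate order
    kic_curve: np.ndarray
    eigenvalues: np.ndarray


def _criterion_curves(eigenvalues: np.ndarray, n_obs: int) -> tuple[np.ndarray, np.ndarray]:
    """MDL and KIC curves over candidate order k = 0 .. p-2.

    Both criteria score the sphericity of the trailing p-k eigenvalues:
    L(k) = N (p-k) log(arith_mean / geom_mean) of the tail, with penalties
      MDL(k) = L(k) + 0.5 * k (2p - k) * log N     (Wax-Kailath MDL)
      KIC(k) = 2 L(k) + 3 * (k (2p - k) + 1)       (Kullback penalty 3m)
    where N is the number of observations and k(2p-k) the free signal
    parameters.
    """
    lam = np.clip(np.sort(eigenvalues)[::-1], 1e-300, None)
    p = len(lam)
    ks = np.arange(0, p - 1)
    mdl = np.empty(len(ks))
    kic = np.empty(len(ks))
    for k in ks:
        tail = lam[k:]
        am = tail.mean()
        gm = np.exp(np.mean(np.log(tail)))
        ll = n_obs * (p - k) * np.log(am / gm)
        mdl[k] = ll + 0.5 * k * (2 * p - k) * np.log(n_obs)
        kic[k] = 2.0 * ll + 3.0 * (k * (2 * p - k) + 1)
    return mdl, kic


def estimate_order(matrix: LesionMatrix | np.ndarray) -> OrderEstimate:
    """Estimate the number of lesion components supported by the data.

    Computed on the patients-direction covariance spectrum (the n x n Gram
    matrix of the centred data, whose nonzero eigenvalues equal those of
    the voxel covariance); the number of observations is the voxel count.
    Ties in a criterion are broken toward the smaller order.
    """
    X = matrix.values if isinstance(matrix, LesionMatrix) else np.asarray(matrix)
    n, v = X.shape
    if n < 4:
        raise ValueError("order estimation needs at least 4 patients")
    lam = np.linalg.eigvalsh(X @ X.T / v)[::-1]
    lam = np.clip(lam, 0.0, None)
    if np.ptp(lam) < 1e-12 * max(lam.max(), 1e-300):
        warnings.warn("degenerate spectrum: all eigenvalues equal; k = 0")
        flat = np.zeros(n - 1)
        return OrderEstimate(0, 0, flat, flat, lam)
    mdl, kic = _criterion_curves(lam, v)
    return OrderEstimate(int(np.argmin(mdl)), int(np.argmin(kic)), mdl, kic, lam)


# ---------------------------------------------------------------------------
# PCA + varimax
# ---------------------------------------------------------------------------


@dataclass
class LesionPCAResults:
    """Varimax-rotated component solution of a lesion matrix."""

    k: int
    eigenvalues: np.ndarray          # all PCA eigenvalues (descending)
    loadings: np.ndarray             # voxels x k, rotated
    rotation: np.ndarray             # k x k orthogonal
    scores: np.ndarray               # patients x k
    variance_explained: np.ndarray   # fraction of total variance, per comp.
    matrix: LesionMatrix

    @property
    def component_ids(self) -> list[str]:
        return [f"comp_{i + 1:02d}" for i in range(self.k)]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.matrix.patient_ids, columns=self.component_ids
        )

    def component_z(self, j: int) -> Volume:
        """Loadings of component ``j`` standardised across in-mask voxels."""
        col = self.loadings[:, j]
        sd = col.std(ddof=0)
        if sd < 1e-12:
            raise ValueError(f"component {j} has constant loadings (zero SD)")
        return self.matrix.to_volume((col - col.mean()) / sd, role="zscore")

    def component_maps(
        self,
        z_cut: float = 3.29,
        min_cluster_voxels: int = 500,
        connectivity: int = 26,
    ) -> list[tuple[Volume, Volume, pd.DataFrame]]:
        """Per component: (z volume, |z|-thresholded mask, cluster table).

        The two-sided cut-off defaults to |z| > 3.29 (two-tailed p < 0.001)
        and clusters must exceed ``min_cluster_voxels`` voxels.
        """
        out = []
        for j in range(self.k):
            z = self.component_z(j)
            mask, table = extract_clusters(
                z, z_cut, min_cluster_voxels, connectivity, two_sided=True
            )
            out.append((z, mask, table))
        return out

    def summary(self) -> str:
        lines = [
            f"Lesion PCA: {self.k} varimax-rotated components, "
            f"{self.matrix.n_patients} patients x {self.matrix.n_voxels} voxels",
            f"{'component':>10} {'eigenvalue':>12} {'var_explained':>14}",
        ]
        for j in range(self.k):
            lines.append(
                f"{self.component_ids[j]:>10} "
                f"{self.rotated_eigenvalues[j]:>12.4f} "
                f"{self.variance_explained[j]:>14.4%}"
            )
        return "\n".join(lines)

    @property
    def rotated_eigenvalues(self) -> np.ndarray:
        return self.scores.var(axis=0, ddof=1)


class LesionPCA:
    """Principal component model of a lesion abnormality matrix."""

    def __init__(self, matrix: LesionMatrix):
        self.matrix = matrix

    def estimate_order(self) -> OrderEstimate:
        return estimate_order(self.matrix)

    def fit(self, k: int | None = None) -> LesionPCAResults:
        """Extract the top-k components and varimax-rotate the voxel
        loadings (Kaiser row-normalised); patient scores are the centred
        data projected on the rotated loadings.  With ``k=None`` the MDL
        estimate is used.  Components are ordered by post-rotation
        explained variance and signed so the largest-|loading| voxel of
        each is positive.
        """
        X = self.matrix.values
        n, v = X.shape
        if k is None:
            k = self.estimate_order().k_mdl
        if not 1 <= k <= min(n - 1, v):
            raise ValueError(
                f"k must lie in [1, {min(n - 1, v)}], got {k}"
            )
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        eigenvalues = s ** 2 / (n - 1)
        L = Vt[:k].T  # unit-norm principal directions, voxels x k
        R = varimax_rotation(L, kaiser=True)
        L_rot = L @ R
        scores = X @ L_rot
        # order by post-rotation explained variance, fix signs
        var = scores.var(axis=0, ddof=1)
        order = np.argsort(var, kind="stable")[::-1]
        L_rot = L_rot[:, order]
        R = R[:, order]
        scores = scores[:, order]
        signs = np.sign(L_rot[np.argmax(np.abs(L_rot), axis=0), np.arange(k)])
        signs[signs == 0] = 1.0
        L_rot *= signs
        R *= signs
        scores *= signs
        total_var = eigenvalues.sum()
        return LesionPCAResults(
            k=k,
            eigenvalues=eigenvalues,
            loadings=L_rot,
            rotation=R,
            scores=scores,
            variance_explained=scores.var(axis=0, ddof=1) / total_var,
            matrix=self.matrix,
        )


def pca_varimax(matrix: LesionMatrix, k: int) -> LesionPCAResults:
    """Functional alias for ``LesionPCA(matrix).fit(k)``."""
    return LesionPCA(matrix).fit(k)


# ---------------------------------------------------------------------------
# Subsampling stability
# ---------------------------------------------------------------------------


def stability_analysis(
    matrix: LesionMatrix,
    sample_sizes: Sequence[int],
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Model-order stability under random patient subsampling.

    For each sample size, ``reps`` subsamples are drawn without
    replacement (each re-centred) and the order re-estimated.  Returns a
    long table (sample_size, rep, k_mdl, k_kic); the per-size median is a
    ``groupby`` away.  Sizes below 4 are skipped with a warning;
    deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    raw = matrix.uncentered()
    n = matrix.n_patients
    rows = []
    for size in sample_sizes:
        if size < 4:
            warnings.warn(f"sample size {size} < 4 skipped")
            continue
        if size > n:
            raise ValueError(f"sample size {size} exceeds {n} available patients")
        for rep in range(reps):
            sel = rng.choice(n, size=size, replace=False)
            sub = raw[sel]
            sub = sub - sub.mean(axis=0)
            est = estimate_order(sub)
            rows.append(
                dict(sample_size=size, rep=rep, k_mdl=est.k_mdl, k_kic=est.k_kic)
            )
    return pd.DataFrame(rows, columns=["sample_size", "rep", "k_mdl", "k_kic"])


def stability_medians(table: pd.DataFrame) -> pd.DataFrame:
    return (
        table.groupby("sample_size")[["k_mdl", "k_kic"]]
        .median()
        .rename(columns={"k_mdl": "median_k_mdl", "k_kic": "median_k_kic"})
        .reset_index()
    )
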