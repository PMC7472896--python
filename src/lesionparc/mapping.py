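"""Lesion-symptom mapping: three routes from behaviour to brain.

1. ``vbcm`` - voxel-based correlational methodology: at every in-mask
   voxel the continuous abnormality signal is regressed on all behavioural
   factors jointly; per-factor t statistics are converted to partial r and
   cluster-level family-wise error is controlled by a permutation
   max-cluster-size test (the same error-control target as Monte-Carlo
   cluster-extent correction, without a smoothness estimate).
2. ``component_behaviour_correlations`` - Pearson correlations between
   lesion-component scores and behavioural factor scores, Bonferroni
   corrected over the full component x factor family.
3. ``stepwise_regression`` + ``regression_component_map`` - classical
   forward-entry / backward-removal stepwise selection of lesion
   components predicting each factor, with the selected components'
   beta-weighted loading maps rendered back into brain space.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .lesion_pca import LesionMatrix, LesionPCAResults
from .volumes import Volume, extract_clusters, _structure


@dataclass
class MappingConfig:
    """Thresholds shared by the mapping procedures."""

    voxel_p: float = 0.001
    cluster_alpha: float = 0.01
    n_permutations: int = 1000
    bonferroni_family_alpha: float = 0.05
    stepwise_p_enter: float = 0.05
    stepwise_p_remove: float = 0.10
    regression_map_z_cut: float = 3.29
    regression_map_min_cluster: int = 200
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_p", "cluster_alpha", "bonferroni_family_alpha",
                     "stepwise_p_enter", "stepwise_p_remove"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie strictly between 0 and 1")
        if self.stepwise_p_enter > self.stepwise_p_remove:
            raise ValueError("stepwise_p_enter must not exceed stepwise_p_remove")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class MappingResult:
    """Statistic / p / significance volumes plus the cluster table."""

    statistic: Volume
    p: Volume
    significant: Volume
    clusters: pd.DataFrame
    method: str


# ---------------------------------------------------------------------------
# VBCM
# ---------------------------------------------------------------------------


def _voxelwise_glm(D: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistics of each non-intercept regressor at every voxel.

    D: patients x (1 + f) design with leading intercept; X: patients x
    voxels.  Returns (f x voxels t array, residual df).
    """
    n, p = D.shape
    G = D.T @ D
    Ginv = np.linalg.inv(G)
    B = Ginv @ (D.T @ X)             # p x v
    fitted = D @ B
    rss = np.sum((X - fitted) ** 2, axis=0)
    df = n - p
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(Ginv)[1:], sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[1:] / se, 0.0)
    return t, df


def _suprathreshold_clusters(
    sig_cols: np.ndarray, matrix: LesionMatrix, connectivity: int
) -> tuple[np.ndarray, int]:
    """Label suprathreshold in-mask columns in 3-D; returns (labels per
    column, n clusters)."""
    vol = np.zeros(matrix.grid_shape, dtype=bool)
    vol[tuple(matrix.voxel_indices[sig_cols].T)] = True
    labels, n = ndimage.label(vol, structure=_structure(connectivity))
    return labels[tuple(matrix.voxel_indices.T)], n


def _max_cluster_size(sig_cols: np.ndarray, matrix: LesionMatrix,
                      connectivity: int) -> int:
    if not sig_cols.any():
        return 0
    col_labels, n = _suprathreshold_clusters(sig_cols, matrix, connectivity)
    return int(np.bincount(col_labels[col_labels > 0]).max())


def vbcm(
    lesion_matrix: LesionMatrix,
    factor_scores: pd.DataFrame,
    config: MappingConfig | None = None,
) -> dict[str, MappingResult]:
    """Voxel-based correlational mapping of every behavioural factor.

    All factors enter one multiple regression per voxel (valid because
    rotated factor scores are near-orthogonal; a warning is raised
    otherwise).  Per factor, voxels at two-sided p < ``voxel_p`` form
    clusters; a cluster survives if its size is extreme relative to the
    permutation null of maximum cluster size (factor rows permuted jointly,
    ``n_permutations`` draws, cluster-level alpha ``cluster_alpha``).
    """
    config = config or MappingConfig()
    F = factor_scores.to_numpy(dtype=float)
    n, f = F.shape
    if n != lesion_matrix.n_patients:
        raise ValueError("factor scores and lesion matrix patient counts differ")
    if n < 10:
        raise ValueError("VBCM requires at least 10 patients")
    if np.any(F.std(axis=0, ddof=1) < 1e-12):
        raise ValueError("zero-variance behavioural factor")
    if f > 1:
        r = np.corrcoef(F, rowvar=False)
        off = np.abs(r[~np.eye(f, dtype=bool)])
        if off.max() >= 0.3:
            warnings.warn(
                f"factor scores are not near-orthogonal (max |r| = {off.max():.2f})"
            )
    X = lesion_matrix.values
    D = np.column_stack([np.ones(n), F])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design (collinear factors)")
    t, df = _voxelwise_glm(D, X)
    partial_r = t / np.sqrt(t ** 2 + df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    sup = p < config.voxel_p

    # permutation null of max cluster size, per factor
    rng = np.random.default_rng(config.seed)
    null_max = np.zeros((f, config.n_permutations), dtype=int)
    for b in range(config.n_permutations):
        perm = rng.permutation(n)
        Db = np.column_stack([np.ones(n), F[perm]])
        tb, dfb = _voxelwise_glm(Db, X)
        pb = 2.0 * stats.t.sf(np.abs(tb), dfb)
        supb = pb < config.voxel_p
        for j in range(f):
            null_max[j, b] = _max_cluster_size(
                supb[j], lesion_matrix, config.connectivity
            )

    results: dict[str, MappingResult] = {}
    for j, name in enumerate(factor_scores.columns):
        col_labels, n_clu = _suprathreshold_clusters(
            sup[j], lesion_matrix, config.connectivity
        )
        keep_cols = np.zeros(lesion_matrix.n_voxels, dtype=bool)
        if n_clu:
            sizes = np.bincount(col_labels[col_labels > 0], minlength=n_clu + 1)
            for lab in range(1, n_clu + 1):
                p_cluster = (1 + np.sum(null_max[j] >= sizes[lab])) / (
                    config.n_permutations + 1
                )
                if p_cluster <= config.cluster_alpha:
                    keep_cols |= col_labels == lab
        stat_vol = lesion_matrix.to_volume(partial_r[j], role="statistic")
        p_vol = lesion_matrix.to_volume(p[j], role="p")
        sig_vol = lesion_matrix.to_volume(keep_cols.astype(float), role="binary")
        sig_vol = Volume(
            np.asarray(sig_vol.data).astype(np.uint8), sig_vol.affine, "binary"
        )
        masked_stat = lesion_matrix.to_volume(
            np.where(keep_cols, partial_r[j], 0.0), role="statistic"
        )
        _, table = extract_clusters(
            masked_stat, 0.0, 0, config.connectivity, two_sided=True
        )
        results[str(name)] = MappingResult(
            statistic=stat_vol, p=p_vol, significant=sig_vol,
            clusters=table, method="vbcm",
        )
    return results


# ---------------------------------------------------------------------------
# Component-factor correlations
# ---------------------------------------------------------------------------


def component_behaviour_correlations(
    component_scores: pd.DataFrame,
    factor_scores: pd.DataFrame,
    config: MappingConfig | None = None,
) -> pd.DataFrame:
    """Pearson r between every lesion component and behavioural factor.

    Significance is Bonferroni-controlled at ``bonferroni_family_alpha``
    over the full components x factors family.
    """
    config = config or MappingConfig()
    C = component_scores.to_numpy(dtype=float)
    F = factor_scores.to_numpy(dtype=float)
    if C.shape[0] != F.shape[0]:
        raise ValueError("patient counts differ")
    n = C.shape[0]
    for arr, label in ((C, "component"), (F, "factor")):
        if np.any(arr.std(axis=0, ddof=1) < 1e-12):
            raise ValueError(f"constant {label} score column")
    Cz = (C - C.mean(0)) / C.std(0, ddof=1)
    Fz = (F - F.mean(0)) / F.std(0, ddof=1)
    r = Cz.T @ Fz / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(df / np.maximum(1e-300, 1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    n_tests = r.size
    threshold = config.bonferroni_family_alpha / n_tests
    rows = []
    for i, comp in enumerate(component_scores.columns):
        for j, fac in enumerate(factor_scores.columns):
            rows.append(
                dict(component=str(comp), factor=str(fac), r=float(r[i, j]),
                     p=float(p[i, j]), significant=bool(p[i, j] < threshold))
            )
    out = pd.DataFrame(rows)
    out.attrs["per_test_alpha"] = threshold
    return out


# ---------------------------------------------------------------------------
# Stepwise regression
# ---------------------------------------------------------------------------


@dataclass
class StepwiseModel:
    response: str
    selected: list[str]
    betas: pd.Series            # standardized coefficients, final fit
    f_statistic: float
    df: tuple[int, int]
    adjusted_r2: float
    steps: list[dict]

    @property
    def is_empty(self) -> bool:
        return len(self.selected) == 0

    def to_json(self) -> str:
        return json.dumps(
            dict(
                response=self.response, selected=self.selected,
                betas={k: float(v) for k, v in self.betas.items()},
                f_statistic=self.f_statistic, df=list(self.df),
                adjusted_r2=self.adjusted_r2, steps=self.steps,
            ),
            indent=1,
        )


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(np.sum((y - y.mean()) ** 2))
    D = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return float(np.sum((y - D @ beta) ** 2))


def _partial_f_p(y: np.ndarray, X_base: np.ndarray, x_new: np.ndarray) -> float:
    """p-value of the partial F test for adding one predictor."""
    n = len(y)
    rss0 = _ols_rss(y, X_base)
    X_full = np.column_stack([X_base, x_new]) if X_base.size else x_new[:, None]
    rss1 = _ols_rss(y, X_full)
    df2 = n - X_full.shape[1] - 1
    if df2 <= 0 or rss1 <= 0:
        return 0.0 if rss1 < rss0 else 1.0
    F = (rss0 - rss1) / (rss1 / df2)
    return float(stats.f.sf(max(F, 0.0), 1, df2))


def stepwise_select(
    y: np.ndarray,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> tuple[list[str], list[dict]]:
    """Forward-entry / backward-removal selection on partial-F p-values.

    Candidates enter when their partial-F p is the smallest and
    <= ``p_enter``; included predictors leave when their removal p is the
    largest and >= ``p_remove``.  Iterated to a fixed point.  Entry stops
    when fewer than two residual degrees of freedom would remain.
    """
    names = list(candidates.columns)
    Xall = candidates.to_numpy(dtype=float)
    n = len(y)
    selected: list[str] = []
    log: list[dict] = []
    seen_states = set()
    for _ in range(max_steps):
        changed = False
        state = tuple(sorted(selected))
        if state in seen_states:
            break
        seen_states.add(state)
        base = Xall[:, [names.index(s) for s in selected]]
        # entry
        if n - (len(selected) + 1) - 1 >= 2:
            best, best_p = None, None
            for c in names:
                if c in selected:
                    continue
                pv = _partial_f_p(y, base, Xall[:, names.index(c)])
                if best_p is None or pv < best_p:
                    best, best_p = c, pv
            if best is not None and best_p <= p_enter:
                selected.append(best)
                log.append(dict(action="enter", term=best, p=float(best_p)))
                changed = True
        # removal
        if selected:
            base = Xall[:, [names.index(s) for s in selected]]
            worst, worst_p = None, None
            for i, c in enumerate(selected):
                rest = np.delete(base, i, axis=1)
                pv = _partial_f_p(y, rest, base[:, i])
                if worst_p is None or pv > worst_p:
                    worst, worst_p = c, pv
            if worst is not None and worst_p >= p_remove:
                selected.remove(worst)
                log.append(dict(action="remove", term=worst, p=float(worst_p)))
                changed = True
        if not changed:
            break
    return selected, log


def _final_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, tuple[int, int], float]:
    """Standardized betas, overall F, df and adjusted R^2 of the final set."""
    n, p = X.shape
    ys = (y - y.mean()) / y.std(ddof=1)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    D = np.column_stack([np.ones(n), Xs])
    beta, *_ = np.linalg.lstsq(D, ys, rcond=None)
    fitted = D @ beta
    rss = float(np.sum((ys - fitted) ** 2))
    tss = float(np.sum((ys - ys.mean()) ** 2))
    df1, df2 = p, n - p - 1
    r2 = 1.0 - rss / tss
    F = (tss - rss) / df1 / (rss / df2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / df2
    return beta[1:], float(F), (df1, df2), float(adj)


def stepwise_regression(
    factor_scores: pd.DataFrame,
    component_scores: pd.DataFrame,
    config: MappingConfig | None = None,
) -> dict[str, StepwiseModel]:
    """Stepwise regression of every behavioural factor on the lesion
    component scores.  An empty model (no candidate meets entry) is a
    valid outcome."""
    config = config or MappingConfig()
    if factor_scores.shape[0] != component_scores.shape[0]:
        raise ValueError("patient counts differ")
    out: dict[str, StepwiseModel] = {}
    for fac in factor_scores.columns:
        y = factor_scores[fac].to_numpy(dtype=float)
        selected, log = stepwise_select(
            y, component_scores, config.stepwise_p_enter, config.stepwise_p_remove
        )
        if selected:
            X = component_scores[selected].to_numpy(dtype=float)
            betas, F, df, adj = _final_fit(y, X)
            model = StepwiseModel(
                response=str(fac), selected=selected,
                betas=pd.Series(betas, index=selected),
                f_statistic=F, df=df, adjusted_r2=adj, steps=log,
            )
        else:
            model = StepwiseModel(
                response=str(fac), selected=[], betas=pd.Series(dtype=float),
                f_statistic=float("nan"), df=(0, len(y) - 1),
                adjusted_r2=float("nan"), steps=log,
            )
        out[str(fac)] = model
    return out


# ---------------------------------------------------------------------------
# Back-projection of selected components
# ---------------------------------------------------------------------------


def regression_component_map(
    solution: LesionPCAResults,
    model: StepwiseModel,
    config: MappingConfig | None = None,
) -> MappingResult:
    """Render a stepwise model into brain space.

    The voxel map is the standardized-beta-weighted sum of the selected
    components' rotated loading maps, z-scored across in-mask voxels and
    thresholded two-sided at ``regression_map_z_cut`` with the
    ``regression_map_min_cluster`` extent rule.
    """
    config = config or MappingConfig()
    if model.is_empty:
        raise ValueError("cannot map an empty stepwise model")
    comp_index = {cid: i for i, cid in enumerate(solution.component_ids)}
    vec = np.zeros(solution.matrix.n_voxels)
    for cid, beta in model.betas.items():
        if cid not in comp_index:
            raise KeyError(f"unknown component id {cid!r}")
        vec += float(beta) * solution.loadings[:, comp_index[cid]]
    sd = vec.std(ddof=0)
    if sd < 1e-12:
        raise ValueError("regression map is constant (zero SD)")
    z = (vec - vec.mean()) / sd
    z_vol = solution.matrix.to_volume(z, role="zscore")
    sig, table = extract_clusters(
        z_vol, config.regression_map_z_cut, config.regression_map_min_cluster,
        config.connectivity, two_sided=True,
    )
    p = 2.0 * stats.norm.sf(np.abs(z))
    return MappingResult(
        statistic=z_vol,
        p=solution.matrix.to_volume(p, role="p"),
        significant=sig,
        clusters=table,
        method="pca-regression",
    )
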