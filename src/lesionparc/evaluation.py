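"""Ground-truth simulation framework for quantifying spatial error.

The central question: when a mapping method flags voxels as related to a
behavioural deficit, how far is the flagged region from the true critical
substrate?  Ground truths are planted at three granularities - a single
voxel, an anatomical-atlas region, or a PCA-derived vascular-territory
region - deficit labels are simulated (deterministically for voxel
truths; by a damage-fraction / deficit-probability rule for region
truths), mass-univariate Fisher-exact mapping with FDR correction
recovers a significant set, and the Euclidean displacement between its
centre of mass and the truth's reference point measures spatial error.
A second experiment compares inference methods (mass-univariate, sparse
CCA at fixed and cross-validated sparseness, PCA plus stepwise
regression, PCA plus Bonferroni correlations) by Dice overlap with the
truth region.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lesion_pca import LesionMatrix, LesionPCA, LesionPCAResults
from .mapping import (
    MappingConfig,
    component_behaviour_correlations,
    regression_component_map,
    stepwise_regression,
)
from .synth import ParcellationAtlas
from .volumes import Volume, centre_of_mass_mm, euclidean_displacement


# ---------------------------------------------------------------------------
# Fisher-exact mass-univariate mapping
# ---------------------------------------------------------------------------

_fisher_cache: dict[tuple[int, int, int, int], float] = {}


def _fisher_p(n: int, K: int, d: int, a: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table with total n, deficit
    margin K, damaged margin d and damaged-and-deficit count a."""
    key = (n, K, d, a)
    p = _fisher_cache.get(key)
    if p is None:
        table = [[a, d - a], [K - a, n - K - (d - a)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        _fisher_cache[key] = p
    return p


@dataclass
class MassUnivariateResult:
    p_values: np.ndarray       # per in-mask voxel (columns of the matrix)
    significant: np.ndarray    # boolean, BH-FDR at q
    n_damaged: np.ndarray
    q: float

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def fisher_mass_univariate(
    lesion_matrix: LesionMatrix | np.ndarray,
    deficit_labels: np.ndarray,
    fdr_q: float = 0.01,
) -> MassUnivariateResult:
    """Per-voxel 2x2 Fisher exact test of damage against deficit.

    ``lesion_matrix`` holds binary damage indicators (patients x voxels);
    two-sided p-values are corrected across voxels by Benjamini-Hochberg
    step-up at ``fdr_q``.
    """
    X = lesion_matrix.values if isinstance(lesion_matrix, LesionMatrix) else np.asarray(lesion_matrix)
    X = X > 0
    y = np.asarray(deficit_labels).astype(bool)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise ValueError("labels must be one binary value per patient")
    if y.all() or not y.any():
        raise ValueError("deficit labels are single-class; association undefined")
    n = len(y)
    K = int(y.sum())
    d = X.sum(axis=0).astype(int)
    a = y.astype(np.int64) @ X.astype(np.int64)
    pairs = np.stack([d, a], axis=1)
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    p_uniq = np.array([_fisher_p(n, K, int(dd), int(aa)) for dd, aa in uniq])
    p = p_uniq[inv]
    return MassUnivariateResult(
        p_values=p, significant=bh_fdr(p, fdr_q), n_damaged=d, q=fdr_q
    )


def bh_fdr(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.min(p) < 0 or np.max(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# Welch t test and Dice
# ---------------------------------------------------------------------------


def welch_ttest(sample_a, sample_b) -> tuple[float, float, float]:
    """Unequal-variance t test; returns (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 0 (with a warning) if both empty."""
    if isinstance(mask_a, Volume) and isinstance(mask_b, Volume):
        if not mask_a.same_grid(mask_b):
            raise ValueError("mask grids differ")
        a, b = np.asarray(mask_a.data) > 0, np.asarray(mask_b.data) > 0
    else:
        a = np.asarray(mask_a) > 0
        b = np.asarray(mask_b) > 0
        if a.shape != b.shape:
            raise ValueError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 0 by convention")
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


# ---------------------------------------------------------------------------
# Ground truths and the displacement experiment
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthSpec:
    """One simulated critical substrate and its deficit rule."""

    kind: str                      # "voxel" | "region" | "component"
    location: object               # voxel column index, or boolean column mask
    damage_fraction: float = 0.2
    deficit_prob: float = 0.9
    min_damaged_patients: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("voxel", "region", "component"):
            raise ValueError(f"unknown ground-truth kind {self.kind!r}")
        if self.kind != "voxel":
            if not 0 < self.damage_fraction <= 1:
                raise ValueError("damage_fraction must lie in (0, 1]")
            loc = np.asarray(self.location)
            if loc.dtype == bool and loc.sum() == 0:
                raise ValueError("region mask is empty")


def component_regions(
    solution: LesionPCAResults,
    z_cut: float = 3.29,
    min_cluster_voxels: int = 500,
    connectivity: int = 26,
) -> dict[str, np.ndarray]:
    """Column-space region masks derived from a component solution.

    Each component's region is its |z| > ``z_cut`` suprathreshold set
    after the cluster-extent rule; components whose thresholded map is
    empty are dropped.
    """
    out: dict[str, np.ndarray] = {}
    maps = solution.component_maps(z_cut, min_cluster_voxels, connectivity)
    idx = solution.matrix.voxel_indices
    for cid, (_, mask, _) in zip(solution.component_ids, maps):
        cols = np.asarray(mask.data)[tuple(idx.T)] > 0
        if cols.any():
            out[cid] = cols
    return out


def atlas_regions(
    atlas: ParcellationAtlas, matrix: LesionMatrix
) -> dict[str, np.ndarray]:
    """Boolean column masks over the lesion matrix for each atlas label."""
    lab = np.asarray(atlas.labels.data)[tuple(matrix.voxel_indices.T)]
    return {
        atlas.names.get(l, f"label_{l:02d}"): lab == l for l in atlas.label_ids
    }


@dataclass
class DisplacementSummary:
    model: str
    mean_mm: float
    sd_mm: float
    n_localized: int
    n_nonlocalized: int
    n_ineligible: int


def displacement_experiment(
    lesions: LesionMatrix,
    model: str | Mapping[str, np.ndarray],
    *,
    damage_fraction: float = 0.2,
    deficit_prob: float = 0.9,
    min_damaged_patients: int = 3,
    fdr_q: float = 0.01,
    n_truths: int | None = None,
    n_repeats: int = 1,
    largest_cluster_only: bool = True,
    seed: int = 0,
    model_tag: str | None = None,
) -> tuple[pd.DataFrame, DisplacementSummary]:
    """Centre-of-mass displacement error under one lesion model.

    ``model`` is either the string ``"voxel"`` (every eligible voxel in
    turn is the critical substrate, with deterministic deficit = damage)
    or a mapping of region id -> boolean column mask (atlas regions or
    component regions; labels then follow the damage-fraction /
    deficit-probability rule, redrawn ``n_repeats`` times per region).
    Truths with at most ``min_damaged_patients`` damaged patients are
    ineligible; eligible truths whose map has no significant voxel are
    recorded as non-localized and excluded from the mean.
    """
    X = lesions.values > 0
    rng = np.random.default_rng(seed)
    rows = []
    n_ineligible = 0

    if isinstance(model, str):
        if model != "voxel":
            raise ValueError(f"unknown lesion model {model!r}")
        tag = model_tag or "voxel"
        d = X.sum(axis=0)
        eligible = np.flatnonzero(d > min_damaged_patients)
        n_ineligible = lesions.n_voxels - len(eligible)
        if len(eligible) == 0:
            raise ValueError("no eligible voxel ground truths")
        if n_truths is not None and n_truths < len(eligible):
            eligible = rng.choice(eligible, size=n_truths, replace=False)
            eligible.sort()
        truth_iter = [
            (f"voxel_{j}", X[:, j].astype(np.int8), lesions.voxel_mm(int(j))[0])
            for j in eligible
        ]
    else:
        tag = model_tag or "region"
        truth_iter = []
        for rid, cols in model.items():
            cols = np.asarray(cols, dtype=bool)
            frac = X[:, cols].mean(axis=1)
            damaged = frac >= damage_fraction
            if damaged.sum() <= min_damaged_patients:
                n_ineligible += 1
                continue
            ref = lesions.voxel_mm(np.flatnonzero(cols)).mean(axis=0)
            for rep in range(n_repeats):
                labels = (damaged & (rng.random(len(damaged)) < deficit_prob)
                          ).astype(np.int8)
                truth_iter.append((f"{rid}_rep{rep}", labels, ref))
        if not truth_iter:
            raise ValueError("no eligible region ground truths")

    for truth_id, labels, ref in truth_iter:
        if labels.all() or not labels.any():
            rows.append(dict(
                truth_id=truth_id, eligible=True, localized=False,
                n_significant=0, displacement_mm=np.nan,
                ref_x_mm=ref[0], ref_y_mm=ref[1], ref_z_mm=ref[2],
                com_x_mm=np.nan, com_y_mm=np.nan, com_z_mm=np.nan,
            ))
            continue
        res = fisher_mass_univariate(X, labels, fdr_q=fdr_q)
        if res.n_significant == 0:
            rows.append(dict(
                truth_id=truth_id, eligible=True, localized=False,
                n_significant=0, displacement_mm=np.nan,
                ref_x_mm=ref[0], ref_y_mm=ref[1], ref_z_mm=ref[2],
                com_x_mm=np.nan, com_y_mm=np.nan, com_z_mm=np.nan,
            ))
            continue
        sig_data = np.zeros(lesions.grid_shape, dtype=np.uint8)
        sig_data[tuple(lesions.voxel_indices[res.significant].T)] = 1
        sig_vol = Volume(sig_data, lesions.affine, "binary")
        com = centre_of_mass_mm(sig_vol, largest_cluster_only=largest_cluster_only)
        disp = euclidean_displacement(com, ref)
        rows.append(dict(
            truth_id=truth_id, eligible=True, localized=True,
            n_significant=res.n_significant, displacement_mm=disp,
            ref_x_mm=ref[0], ref_y_mm=ref[1], ref_z_mm=ref[2],
            com_x_mm=com[0], com_y_mm=com[1], com_z_mm=com[2],
        ))

    records = pd.DataFrame(rows)
    localized = records[records["localized"]]
    summary = DisplacementSummary(
        model=tag,
        mean_mm=float(localized["displacement_mm"].mean()) if len(localized) else float("nan"),
        sd_mm=float(localized["displacement_mm"].std(ddof=1)) if len(localized) > 1 else float("nan"),
        n_localized=int(len(localized)),
        n_nonlocalized=int(len(records) - len(localized)),
        n_ineligible=int(n_ineligible),
    )
    return records, summary


# ---------------------------------------------------------------------------
# Sparse CCA
# ---------------------------------------------------------------------------


@dataclass
class SparseCCAConfig:
    sparseness: float = 0.045
    cv_grid_bounds: tuple[float, float] = (0.005, 0.9)
    cv_grid_size: int = 12
    cv_folds: int = 5
    max_iter: int = 100
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sparseness <= 1:
            raise ValueError("sparseness must lie in (0, 1]")
        lo, hi = self.cv_grid_bounds
        if not (0 < lo <= hi <= 1):
            raise ValueError("cv_grid_bounds must lie within (0, 1]")


@dataclass
class SparseCCAResult:
    weights: np.ndarray
    significant: np.ndarray      # nonzero-weight mask over columns
    canonical_correlation: float
    sparseness: float
    converged: bool
    cv_table: pd.DataFrame | None = None


def _scca_fit(
    Xc: np.ndarray, yc: np.ndarray, sparseness: float, max_iter: int, tol: float
) -> tuple[np.ndarray, bool]:
    """Rank-1 penalized decomposition between voxel matrix and label
    vector: alternate normalized updates with hard-thresholding that
    retains the top ceil(sparseness * v) absolute weights."""
    v = Xc.shape[1]
    keep = int(math.ceil(sparseness * v))
    w = Xc.T @ yc
    nrm = np.linalg.norm(w)
    if nrm == 0:
        return np.zeros(v), True
    w = w / nrm
    converged = False
    for _ in range(max_iter):
        u = yc  # behaviour side is one-dimensional: canonical variate = labels
        s = float(np.sign(u @ (Xc @ w)) or 1.0)
        w_new = Xc.T @ (u * s)
        if keep < v:
            # retain exactly `keep` entries (ties broken by index order)
            drop = np.argpartition(np.abs(w_new), v - keep)[: v - keep]
            w_new[drop] = 0.0
        nrm = np.linalg.norm(w_new)
        if nrm == 0:
            return np.zeros(v), True
        w_new /= nrm
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        warnings.warn("sparse CCA did not converge; returning last iterate")
    return w, converged


def sparse_cca(
    lesion_matrix: LesionMatrix | np.ndarray,
    deficit_labels: np.ndarray,
    config: SparseCCAConfig | None = None,
    cross_validate: bool = False,
) -> SparseCCAResult:
    """Sparse canonical correlation between lesions and a deficit label.

    With ``cross_validate`` the sparseness is chosen on a log-spaced grid
    within ``cv_grid_bounds`` by mean held-out correlation between the
    projected lesion scores and the labels; otherwise the fixed
    ``config.sparseness`` is used.
    """
    config = config or SparseCCAConfig()
    X = lesion_matrix.values if isinstance(lesion_matrix, LesionMatrix) else np.asarray(lesion_matrix)
    X = np.asarray(X, dtype=float)
    y = np.asarray(deficit_labels, dtype=float)
    if np.std(y) == 0:
        raise ValueError("deficit labels are constant")
    Xc = X - X.mean(axis=0)
    yc = (y - y.mean())
    yc = yc / np.linalg.norm(yc)

    cv_table = None
    sparseness = config.sparseness
    if cross_validate:
        lo, hi = config.cv_grid_bounds
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), config.cv_grid_size))
        rng = np.random.default_rng(config.seed)
        n = len(y)
        order = rng.permutation(n)
        folds = np.array_split(order, config.cv_folds)
        rows = []
        for s in grid:
            cors = []
            for f in range(config.cv_folds):
                test = folds[f]
                train = np.concatenate([folds[g] for g in range(config.cv_folds) if g != f])
                Xt = X[train] - X[train].mean(axis=0)
                yt = y[train] - y[train].mean()
                if np.linalg.norm(yt) == 0:
                    continue
                w, _ = _scca_fit(Xt, yt / np.linalg.norm(yt), s,
                                 config.max_iter, config.tol)
                proj = X[test] @ w
                if np.std(proj) == 0 or np.std(y[test]) == 0:
                    continue
                cors.append(abs(np.corrcoef(proj, y[test])[0, 1]))
            rows.append(dict(sparseness=float(s),
                             mean_cv_correlation=float(np.mean(cors)) if cors else 0.0))
        cv_table = pd.DataFrame(rows)
        sparseness = float(cv_table.loc[cv_table["mean_cv_correlation"].idxmax(),
                                        "sparseness"])

    w, converged = _scca_fit(Xc, yc, sparseness, config.max_iter, config.tol)
    proj = Xc @ w
    if np.std(proj) > 0:
        cc = float(abs(np.corrcoef(proj, y)[0, 1]))
    else:
        cc = 0.0
    return SparseCCAResult(
        weights=w, significant=w != 0, canonical_correlation=cc,
        sparseness=sparseness, converged=converged, cv_table=cv_table,
    )


# ---------------------------------------------------------------------------
# Method comparison by Dice
# ---------------------------------------------------------------------------

METHOD_TAGS = (
    "mass-univariate", "sparse-cca-fixed", "sparse-cca-cv",
    "pca-regression", "pca-correlation",
)


def method_comparison_experiment(
    lesions: LesionMatrix,
    truth_regions: Mapping[str, np.ndarray],
    *,
    pca_k: int | None = None,
    damage_fraction: float = 0.2,
    deficit_prob: float = 0.9,
    fdr_q: float = 0.01,
    scca_config: SparseCCAConfig | None = None,
    mapping_config: MappingConfig | None = None,
    component_z_cut: float = 3.29,
    component_min_cluster: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dice spatial error of five inference methods on region truths.

    Per truth region: deficit labels are simulated by the damage-fraction /
    deficit-probability rule, then five significant-voxel masks are
    produced - (a) Fisher mass-univariate with BH-FDR, (b) sparse CCA at
    the fixed sparseness, (c) sparse CCA with cross-validated sparseness,
    (d) lesion-PCA components selected by stepwise regression of the
    labels and rendered through the regression map, (e) lesion-PCA
    components passing Bonferroni-corrected correlation, rendered as the
    union of their thresholded maps - and each mask is scored by Dice
    against the truth region.  Returns exactly
    ``len(truth_regions) x 5`` records.
    """
    scca_config = scca_config or SparseCCAConfig()
    mapping_config = mapping_config or MappingConfig(
        regression_map_z_cut=component_z_cut,
        regression_map_min_cluster=component_min_cluster,
    )
    rng = np.random.default_rng(seed)
    X = lesions.values > 0

    solution = LesionPCA(lesions).fit(pca_k)
    comp_cols = component_regions(
        solution, component_z_cut, component_min_cluster,
        mapping_config.connectivity,
    )
    comp_scores = solution.scores_frame()

    rows = []
    for rid, cols in truth_regions.items():
        cols = np.asarray(cols, dtype=bool)
        frac = X[:, cols].mean(axis=1)
        damaged = frac >= damage_fraction
        labels = (damaged & (rng.random(len(damaged)) < deficit_prob)).astype(float)
        if labels.std() == 0:
            warnings.warn(f"region {rid}: single-class labels; empty masks recorded")
            masks = {tag: np.zeros(lesions.n_voxels, dtype=bool)
                     for tag in METHOD_TAGS}
        else:
            masks = {}
            mu = fisher_mass_univariate(X, labels.astype(np.int8), fdr_q=fdr_q)
            masks["mass-univariate"] = mu.significant
            masks["sparse-cca-fixed"] = sparse_cca(
                lesions, labels, scca_config, cross_validate=False
            ).significant
            masks["sparse-cca-cv"] = sparse_cca(
                lesions, labels, scca_config, cross_validate=True
            ).significant

            step = stepwise_regression(
                pd.DataFrame({"deficit": labels}, index=lesions.patient_ids),
                comp_scores, mapping_config,
            )["deficit"]
            if step.is_empty:
                masks["pca-regression"] = np.zeros(lesions.n_voxels, dtype=bool)
            else:
                res = regression_component_map(solution, step, mapping_config)
                masks["pca-regression"] = (
                    np.asarray(res.significant.data)[tuple(lesions.voxel_indices.T)] > 0
                )

            cors = component_behaviour_correlations(
                comp_scores,
                pd.DataFrame({"deficit": labels}, index=lesions.patient_ids),
                mapping_config,
            )
            sig_comps = cors.loc[cors["significant"], "component"].tolist()
            union = np.zeros(lesions.n_voxels, dtype=bool)
            for cid in sig_comps:
                if cid in comp_cols:
                    union |= comp_cols[cid]
            masks["pca-correlation"] = union

        for tag in METHOD_TAGS:
            rows.append(dict(
                truth_id=rid, method=tag,
                dice=dice(masks[tag], cols),
                n_significant=int(masks[tag].sum()),
                n_damaged=int(damaged.sum()),
            ))
    return pd.DataFrame(rows)
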