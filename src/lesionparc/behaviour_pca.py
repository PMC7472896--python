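"""Varimax-rotated principal-component decomposition of a test battery.

Reduces a patients x tests score table (percentage scale) to orthogonal
behavioural factors: components of the tests x tests correlation matrix
with eigenvalue above a retention threshold (default 1.0, the Kaiser
rule) are varimax rotated, and per-patient factor scores are obtained by
the regression method.  This is component-based "factor analysis" (PCA of
the correlation matrix), not common-factor maximum likelihood.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rotation import varimax_rotation


@dataclass
class BehaviourMatrix:
    """Patients x tests scores on a 0-100 percentage scale."""

    scores: pd.DataFrame
    max_scores: dict[str, float | None] | None = None  # provenance only

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                "behaviour matrix contains missing or non-finite scores "
                "(missing data are not supported)"
            )
        if vals.min() < -1e-9 or vals.max() > 100 + 1e-9:
            raise ValueError("behaviour scores must lie in [0, 100]")

    @property
    def n_patients(self) -> int:
        return self.scores.shape[0]

    @property
    def test_names(self) -> list[str]:
        return list(self.scores.columns)


GROUP_MAX = "group-max"


def to_percentages(
    raw_scores: pd.DataFrame, max_scores: Mapping[str, float | str | None]
) -> BehaviourMatrix:
    """Convert raw test scores to percentages of the maximum available.

    Tests whose declared maximum is the ``"group-max"`` sentinel (or None)
    are scaled by the observed column maximum instead.
    """
    out = {}
    maxima: dict[str, float | None] = {}
    for test in raw_scores.columns:
        if test not in max_scores:
            raise KeyError(f"no maximum declared for test {test!r}")
        mx = max_scores[test]
        col = raw_scores[test].to_numpy(dtype=float)
        if mx is None or mx == GROUP_MAX:
            mx_val = float(np.max(col))
            if mx_val <= 0:
                raise ValueError(
                    f"test {test!r}: group maximum is non-positive (degenerate)"
                )
            maxima[test] = None
        else:
            mx_val = float(mx)
            if mx_val <= 0:
                raise ValueError(f"test {test!r}: declared maximum must be positive")
            if np.max(col) > mx_val + 1e-9:
                raise ValueError(
                    f"test {test!r}: raw score exceeds the declared maximum"
                )
            maxima[test] = mx_val
        out[test] = 100.0 * col / mx_val
    return BehaviourMatrix(
        pd.DataFrame(out, index=raw_scores.index), max_scores=maxima
    )


@dataclass
class BehaviourFactorResults:
    """Rotated factor solution of a behavioural battery."""

    n_factors: int
    loadings: pd.DataFrame        # tests x factors, rotated
    eigenvalues: np.ndarray       # of the correlation matrix, descending
    factor_scores: pd.DataFrame   # patients x factors, regression method
    communalities: pd.Series
    retention_eigenvalue: float

    def summary(self, bold_threshold: float = 0.5) -> str:
        """Loading table with |loading| >= 0.5 marked in bold, mirroring
        the conventional presentation of battery factor solutions."""
        lines = [
            f"Behaviour PCA: {self.n_factors} factors retained "
            f"(eigenvalue > {self.retention_eigenvalue:g})",
            "\t".join(["task"] + list(self.loadings.columns)),
        ]
        for test, row in self.loadings.iterrows():
            cells = [
                f"**{v:.3f}**" if abs(v) >= bold_threshold else f"{v:.3f}"
                for v in row
            ]
            lines.append("\t".join([str(test)] + cells))
        return "\n".join(lines)


class BehaviourFactorModel:
    """PCA-based factor model of a behavioural score matrix."""

    def __init__(self, matrix: BehaviourMatrix):
        self.matrix = matrix

    def fit(self, retention_eigenvalue: float = 1.0) -> BehaviourFactorResults:
        """Correlation-matrix PCA with Kaiser retention and varimax.

        Retained loadings (eigenvector * sqrt(eigenvalue)) are varimax
        rotated with Kaiser row-normalisation; regression-method factor
        scores are ``Z @ R^-1 @ L`` with Z the standardised data and R the
        correlation matrix.  Factors are ordered by rotated explained
        variance, signed so each factor's largest-|loading| test is
        positive.
        """
        df = self.matrix.scores
        n, t = df.shape
        if n < 10:
            raise ValueError(f"need at least 10 patients, got {n}")
        vals = df.to_numpy(dtype=float)
        sd = vals.std(axis=0, ddof=1)
        if np.any(sd < 1e-12):
            bad = [df.columns[i] for i in np.flatnonzero(sd < 1e-12)]
            raise ValueError(f"constant test column(s): {bad}")
        Z = (vals - vals.mean(axis=0)) / sd
        R = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        keep = eigval > retention_eigenvalue
        k = int(keep.sum())
        if k == 0:
            raise ValueError("no component exceeds the retention eigenvalue")
        L = eigvec[:, :k] * np.sqrt(eigval[:k])
        T = varimax_rotation(L, kaiser=True)
        L_rot = L @ T
        # order by rotated sum of squared loadings, then fix signs
        ssl = (L_rot ** 2).sum(axis=0)
        order_k = np.argsort(ssl, kind="stable")[::-1]
        L_rot = L_rot[:, order_k]
        signs = np.sign(L_rot[np.argmax(np.abs(L_rot), axis=0), np.arange(k)])
        signs[signs == 0] = 1.0
        L_rot *= signs

        try:
            Rinv_L = np.linalg.solve(R, L_rot)
        except np.linalg.LinAlgError:
            warnings.warn("singular correlation matrix; applying ridge 1e-8")
            Rinv_L = np.linalg.solve(R + 1e-8 * np.eye(t), L_rot)
        scores = Z @ Rinv_L
        factor_names = [f"factor_{j + 1}" for j in range(k)]
        return BehaviourFactorResults(
            n_factors=k,
            loadings=pd.DataFrame(L_rot, index=df.columns, columns=factor_names),
            eigenvalues=eigval,
            factor_scores=pd.DataFrame(scores, index=df.index, columns=factor_names),
            communalities=pd.Series(
                (L_rot ** 2).sum(axis=1), index=df.columns, name="communality"
            ),
            retention_eigenvalue=retention_eigenvalue,
        )


def behaviour_factor_analysis(
    matrix: BehaviourMatrix, retention_eigenvalue: float = 1.0
) -> BehaviourFactorResults:
    """Functional alias for ``BehaviourFactorModel(matrix).fit(...)``."""
    return BehaviourFactorModel(matrix).fit(retention_eigenvalue)
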