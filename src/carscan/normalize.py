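"""Matrix normalization for accessibility and expression data.

The association model downstream assumes approximately Gaussian, doubly
standardized inputs.  This module provides the pieces: a rank-based
inverse-normal transform, alternating row/column standardization
("bi-standardization"), removal of the leading principal component (which
in real accessibility data tracks a batch effect rather than biology),
replicate averaging for microarray-style designs, and RNA-seq count
preprocessing (mean filter, log1p, classic quantile normalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import RawAccessibilityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AccessibilityMatrix",
    "ExpressionMatrix",
    "inverse_normal_transform",
    "iterative_bistandardize",
    "remove_leading_pc",
    "normalize_accessibility",
    "average_replicates",
    "normalize_expression",
    "preprocess_rnaseq",
    "covariance_diagnostics",
]


@dataclass
class _LabelledMatrix:
    values: np.ndarray
    row_ids: list[str]
    cell_line_ids: list[str]
    tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.cell_line_ids)):
            raise ValueError("values shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.cell_line_ids)

    def to_tsv(self, path: str | Path, index_label: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label=index_label)
        meta = Path(str(path) + ".meta")
        meta.write_text(f"tag={self.tag}\n")


@dataclass
class AccessibilityMatrix(_LabelledMatrix):
    """Motif x cell-line matrix of (normalized) accessibility scores.

    ``tag`` records the normalization state: raw | int | bistandardized |
    pc_removed | final.  In the final state every row is a permutation of
    the inverse-normal grid.
    """

    @property
    def motif_ids(self) -> list[str]:
        return self.row_ids

    def to_tsv(self, path: str | Path, index_label: str = "motif") -> None:
        super().to_tsv(path, index_label)

    @classmethod
    def from_tsv(cls, path: str | Path, tag: str = "final") -> "AccessibilityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), tag=tag)


@dataclass
class ExpressionMatrix(_LabelledMatrix):
    """Gene x cell-line expression matrix; final state is bistandardized."""

    @property
    def gene_ids(self) -> list[str]:
        return self.row_ids

    def to_tsv(self, path: str | Path, index_label: str = "gene") -> None:
        super().to_tsv(path, index_label)

    @classmethod
    def from_tsv(cls, path: str | Path, tag: str = "final") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), tag=tag)


def inverse_normal_transform(v: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (rankit offset).

    Entry j maps to ``Phi^-1((rbar_j - 0.5) / n)`` where ``rbar_j`` is the
    average rank of entry j (ties share their average rank).  Strictly
    rank-preserving on untied entries; the result is the closest thing to a
    Gaussian sample with the observed ordering.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if not np.isfinite(v).all():
        raise ValueError("non-finite entries")
    if np.ptp(v) == 0:
        raise ValueError("constant vector: all ranks tied, no normal ordering exists")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / v.size)


def iterative_bistandardize(
    M: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Alternately standardize rows then columns until both hold at once.

    Each sweep subtracts the row means and divides by the row standard
    deviations (population convention, /n), then does the same for
    columns.  Convergence is declared when every row/column mean is within
    ``tol`` of 0 and every sd within ``tol`` of 1.  Non-convergence after
    ``max_iter`` sweeps warns rather than fails.
    """
    M = np.array(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a matrix with >=2 rows and >=2 columns")

    def _deviation(A: np.ndarray) -> float:
        rm, cm = A.mean(axis=1), A.mean(axis=0)
        rs, cs = A.std(axis=1), A.std(axis=0)
        return max(
            np.abs(rm).max(), np.abs(cm).max(),
            np.abs(rs - 1).max(), np.abs(cs - 1).max(),
        )

    for it in range(max_iter):
        if _deviation(M) < tol:
            logger.debug("bistandardization converged after %d sweeps", it)
            return M
        rs = M.std(axis=1, keepdims=True)
        if (rs == 0).any():
            bad = int(np.argmax(rs.ravel() == 0))
            raise ValueError(f"row {bad} has zero standard deviation")
        M = (M - M.mean(axis=1, keepdims=True)) / rs
        cs = M.std(axis=0, keepdims=True)
        if (cs == 0).any():
            bad = int(np.argmax(cs.ravel() == 0))
            raise ValueError(f"column {bad} has zero standard deviation")
        M = (M - M.mean(axis=0, keepdims=True)) / cs
    if _deviation(M) >= tol:
        logger.warning(
            "bistandardization did not reach tol=%.1e in %d sweeps (deviation %.2e)",
            tol, max_iter, _deviation(M),
        )
    return M


def remove_leading_pc(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Project out the leading principal component of the column covariance.

    The covariance is taken across columns (cell lines): ``C = M.T M / p``
    for the p x n matrix M.  Each row is replaced by its component
    orthogonal to the leading eigenvector v, so every output row satisfies
    ``r . v = 0``.  Returns (deflated matrix, v, leading eigenvalue).
    """
    M = np.asarray(M, dtype=float)
    C = M.T @ M / M.shape[0]
    evals, evecs = np.linalg.eigh(C)
    lead, second = evals[-1], evals[-2]
    if abs(lead - second) < 1e-10 * max(abs(lead), 1.0):
        logger.warning("degenerate leading eigenvalues (%g ~ %g): eigenvector not unique",
                       lead, second)
    v = evecs[:, -1]
    out = M - np.outer(M @ v, v)
    return out, v, float(lead)


def normalize_accessibility(
    raw: RawAccessibilityMatrix, *, remove_pc: bool = True
) -> AccessibilityMatrix:
    """Full accessibility normalization pipeline.

    Stages, in order: per-motif inverse-normal transform of the raw
    counts; bi-standardization; removal of the leading principal component
    (optional — disabling it yields the plain mixed-model variant); a final
    per-motif inverse-normal transform so each row meets the Gaussian
    assumption of the association model exactly.
    """
    M = np.asarray(raw.values, dtype=float)
    M = np.apply_along_axis(inverse_normal_transform, 1, M)
    M = iterative_bistandardize(M)
    if remove_pc:
        M, _, _ = remove_leading_pc(M)
    M = np.apply_along_axis(inverse_normal_transform, 1, M)
    return AccessibilityMatrix(M, list(raw.motif_ids), list(raw.cell_line_ids), tag="final")


def average_replicates(
    expr: pd.DataFrame, experiment_to_cell_line: Mapping[str, str]
) -> pd.DataFrame:
    """Average replicate experiment columns into one column per cell line.

    Every experiment column must map to exactly one cell line; a cell line
    appearing in the map with no experiment present raises.
    """
    missing = [e for e in expr.columns if e not in experiment_to_cell_line]
    if missing:
        raise ValueError(f"experiments with no cell-line mapping: {missing}")
    groups: dict[str, list[str]] = {}
    for exp in expr.columns:
        groups.setdefault(experiment_to_cell_line[exp], []).append(exp)
    empty = set(experiment_to_cell_line.values()) - set(groups)
    if empty:
        raise ValueError(f"cell lines with zero experiments: {sorted(empty)}")
    out = {cl: expr[cols].mean(axis=1) for cl, cols in groups.items()}
    return pd.DataFrame(out)


def normalize_expression(expr: pd.DataFrame) -> ExpressionMatrix:
    """Bistandardize a gene x cell-line expression table.

    Constant gene rows carry no cross-cell-line information and would make
    standardization impossible; they are dropped with a log message.
    """
    values = expr.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        dropped = list(expr.index[constant])
        logger.info("dropping %d constant gene rows: %s", len(dropped), dropped[:10])
        expr = expr.loc[~constant]
        values = values[~constant]
    M = iterative_bistandardize(values)
    return ExpressionMatrix(M, list(expr.index.astype(str)),
                            list(expr.columns.astype(str)), tag="final")


def preprocess_rnaseq(counts: pd.DataFrame, min_mean: float = 50.0) -> pd.DataFrame:
    """Filter, log-transform and quantile-normalize an RNA-seq count table.

    Genes with mean count <= ``min_mean`` (strictly "above" survives) are
    dropped; counts become log(count + 1); each sample is then mapped onto
    the mean order-statistic distribution (classic quantile normalization).
    Ties within a sample receive the mean of the reference quantiles they
    span.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    keep = values.mean(axis=1) > min_mean
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes survive the mean-count filter")
    logged = np.log(values[keep] + 1.0)
    n_genes = logged.shape[0]
    # reference distribution: mean of the per-sample order statistics
    reference = np.sort(logged, axis=0).mean(axis=1)
    out = np.empty_like(logged)
    for j in range(logged.shape[1]):
        col = logged[:, j]
        ranks = stats.rankdata(col, method="average")  # 1..n, ties averaged
        # interpolate the reference at (possibly fractional) rank positions
        out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), reference)
    return pd.DataFrame(out, index=counts.index[keep], columns=counts.columns)


def covariance_diagnostics(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cell-line covariance spectrum and squared correlation matrix.

    Useful before deciding whether to deflate the leading principal
    component: a spectrum with one dominant eigenvalue whose eigenvector
    does not track biology indicates a batch effect.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a matrix with >=2 columns")
    C = M.T @ M / M.shape[0]
    evals = np.linalg.eigvalsh(C)[::-1]
    corr = np.corrcoef(M, rowvar=False)
    return evals, corr**2
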