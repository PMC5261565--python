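"""Linear mixed model association between motif accessibility and expression.

The model for one motif accessibility vector y (length n cell lines) and one
gene expression vector x_i is

    y = x_i * beta_i + delta_i + eps_i,
    eps_i   ~ N(0, sigma_r^2 * I_n),
    delta_i ~ N(0, sigma_e^2 * C_e),

where C_e = (1/p) * sum_i x_i x_i^T is the cell-line covariance of the
standardized expression matrix.  The random effect delta absorbs
confounding shared between accessibility and expression (cell-line
relatedness, batch structure): cell lines with globally similar
transcriptomes are allowed correlated accessibility residuals, which is
what deflates the type-I error of the naive regression.

Estimation works in the eigenbasis of C_e = U S U^T.  After rotating
y and the fixed-effect design by U^T the covariance is diagonal,
sigma_r^2 * (lambda * S_j + 1) with lambda = sigma_e^2 / sigma_r^2, so beta
and the overall scale profile out analytically and only the variance ratio
lambda needs a 1-D search (log-spaced grid, then bounded refinement).  The
fixed effect is tested with a likelihood ratio test against the beta = 0
null (variance components re-estimated) on a chi^2_1 reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .normalize import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCovariance",
    "LmmFit",
    "AssociationMatrix",
    "expression_covariance",
    "fit_lmm",
    "lrt_pvalue",
    "associate_motif",
    "ols_pvalues",
    "associate_all",
]

_LOG_LAMBDA_LO = -5.0
_LOG_LAMBDA_HI = 5.0
_SIGMA_FLOOR = 1e-300  # keeps the profiled log-likelihood finite when y is noiseless


@dataclass
class ExpressionCovariance:
    """Eigendecomposed cell-line covariance of the expression matrix."""

    C_e: np.ndarray          # (n, n) symmetric PSD
    U: np.ndarray            # orthonormal eigenvectors, columns
    S: np.ndarray            # eigenvalues, descending, clipped at 0
    n: int                   # cell lines
    p: int                   # genes used
    cell_line_ids: list[str] | None = None


@dataclass
class LmmFit:
    """Maximum-likelihood fit of the mixed model for one (y, x) pair."""

    beta: float              # fixed effect for the tested regressor (0 for the null)
    sigma2_r: float          # residual variance
    sigma2_e: float          # confounder variance scale
    loglik: float
    converged: bool
    coefficients: np.ndarray | None = None  # all fixed effects incl. covariates


def expression_covariance(X: ExpressionMatrix) -> ExpressionCovariance:
    """Compute C_e = (1/p) X~^T X~ across genes and its eigendecomposition."""
    V = np.asarray(X.values, dtype=float)
    if not np.isfinite(V).all():
        raise ValueError("expression matrix contains non-finite entries")
    p, n = V.shape
    C = V.T @ V / p
    evals, evecs = np.linalg.eigh(C)  # ascending
    order = np.argsort(evals)[::-1]
    S = np.clip(evals[order], 0.0, None)
    U = evecs[:, order]
    return ExpressionCovariance(C_e=C, U=U, S=S, n=n, p=p,
                                cell_line_ids=list(X.cell_line_ids))


def _profile_negloglik(
    log_lam: float, y_rot: np.ndarray, X_rot: np.ndarray | None, S: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Negative profiled log-likelihood at variance ratio exp(log_lam).

    Returns (-loglik, beta_vector, sigma2_r).  With weights
    w_j = 1 / (lambda S_j + 1), beta solves the weighted normal equations
    and sigma_r^2 is the weighted mean squared residual.
    """
    lam = np.exp(log_lam)
    d = lam * S + 1.0
    w = 1.0 / d
    n = y_rot.size
    if X_rot is None or X_rot.shape[1] == 0:
        beta = np.zeros(0)
        resid = y_rot
    else:
        Xw = X_rot * w[:, None]
        A = X_rot.T @ Xw
        b = Xw.T @ y_rot
        beta = np.linalg.solve(A, b)
        resid = y_rot - X_rot @ beta
    s2 = max(float(np.sum(w * resid**2) / n), _SIGMA_FLOOR)
    ll = -0.5 * n * np.log(2 * np.pi) - 0.5 * n * np.log(s2) \
         - 0.5 * float(np.sum(np.log(d))) - 0.5 * n
    return -ll, beta, s2


def fit_lmm(
    y: np.ndarray,
    x: np.ndarray | None,
    cov: ExpressionCovariance,
    covariates: Sequence[np.ndarray] | None = None,
    *,
    intercept: bool = False,
    n_grid: int = 64,
) -> LmmFit:
    """Fit the mixed model by maximum likelihood (spectral profile search).

    Parameters
    ----------
    y:
        Accessibility vector across cell lines.
    x:
        Tested regressor (gene expression vector), or None for the null
        model (beta fixed at 0).
    cov:
        Eigendecomposed expression covariance shared by all fits.
    covariates:
        Optional extra fixed-effect vectors (e.g. the accessibility of the
        same motif in another assay) profiled jointly with x.
    intercept:
        Add a constant column.  Off by default: the pipeline feeds doubly
        standardized y and x, which are already centred.
    n_grid:
        Number of log-spaced grid points for the variance-ratio search.
    """
    y = np.asarray(y, dtype=float)
    n = cov.n
    if y.size != n:
        raise ValueError(f"y has length {y.size}, expected {n}")
    cols: list[np.ndarray] = []
    if intercept:
        cols.append(np.ones(n))
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x.size != n:
            raise ValueError(f"x has length {x.size}, expected {n}")
        cols.append(x)
    if covariates:
        for c in covariates:
            c = np.asarray(c, dtype=float)
            if c.size != n:
                raise ValueError("covariate length mismatch")
            cols.append(c)

    X = np.column_stack(cols) if cols else None
    if X is not None and X.shape[1] > 1:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear fixed-effect design (including covariates)")

    y_rot = cov.U.T @ y
    X_rot = cov.U.T @ X if X is not None else None
    S = cov.S

    grid = np.linspace(_LOG_LAMBDA_LO * np.log(10), _LOG_LAMBDA_HI * np.log(10), n_grid)
    nlls = np.array([_profile_negloglik(g, y_rot, X_rot, S)[0] for g in grid])
    best = int(np.argmin(nlls))

    # the profile likelihood in log-lambda can be multimodal: refine every
    # local minimum of the grid, keep the overall best
    local_minima = [i for i in range(n_grid)
                    if (i == 0 or nlls[i] <= nlls[i - 1])
                    and (i == n_grid - 1 or nlls[i] <= nlls[i + 1])]
    log_lam, best_nll = grid[best], nlls[best]
    converged = True
    for i in local_minima:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        try:
            res = optimize.minimize_scalar(
                lambda g: _profile_negloglik(g, y_rot, X_rot, S)[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-8},
            )
        except Exception:  # pragma: no cover - scipy failure fallback
            converged = False
            continue
        if not res.success:
            converged = False
            continue
        if res.fun < best_nll:
            log_lam, best_nll = float(res.x), float(res.fun)

    nll, beta_vec, s2r = _profile_negloglik(log_lam, y_rot, X_rot, S)
    lam = np.exp(log_lam)
    beta_idx = 1 if intercept else 0
    beta = float(beta_vec[beta_idx]) if (x is not None and beta_vec.size) else 0.0
    return LmmFit(
        beta=beta,
        sigma2_r=float(s2r),
        sigma2_e=float(lam * s2r),
        loglik=-nll,
        converged=converged,
        coefficients=beta_vec if beta_vec.size else None,
    )


def lrt_pvalue(alt: LmmFit, null: LmmFit, df: int = 1) -> float:
    """Likelihood ratio test of the fixed effect, chi^2 reference.

    The statistic 2*(loglik_alt - loglik_null) is clipped at 0: the null is
    nested, so a negative value can only be numerical slack (warned about
    when it exceeds 1e-6).
    """
    stat = 2.0 * (alt.loglik - null.loglik)
    if stat < -1e-6:
        logger.warning("alternative fit worse than null by %g; clipping LRT to 0", -stat)
    stat = max(stat, 0.0)
    return float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0


def associate_motif(
    y: np.ndarray,
    X: ExpressionMatrix,
    cov: ExpressionCovariance,
    *,
    null_fit: LmmFit | None = None,
    n_grid: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Associate one accessibility vector with every gene.

    The beta = 0 null depends only on y, so it is fitted once and reused
    for every gene's likelihood ratio test.  Returns (p-values, betas)
    aligned with ``X.gene_ids``.
    """
    V = np.asarray(X.values, dtype=float)
    if V.shape[1] != cov.n:
        raise ValueError("expression matrix / covariance cell-line mismatch")
    if null_fit is None:
        null_fit = fit_lmm(y, None, cov, n_grid=n_grid)
    pvals = np.empty(V.shape[0])
    betas = np.empty(V.shape[0])
    for i in range(V.shape[0]):
        alt = fit_lmm(y, V[i], cov, n_grid=n_grid)
        pvals[i] = lrt_pvalue(alt, null_fit)
        betas[i] = alt.beta
    return pvals, betas


def ols_pvalues(y: np.ndarray, X: ExpressionMatrix) -> np.ndarray:
    """Per-gene simple linear regression p-values (no confounder control).

    The comparator that demonstrates p-value inflation: a t-test on the
    slope of y on each gene, no intercept (inputs are centred upstream).
    """
    y = np.asarray(y, dtype=float)
    V = np.asarray(X.values, dtype=float)
    n = y.size
    xtx = np.sum(V**2, axis=1)
    beta = V @ y / xtx
    rss = np.sum(y**2) - beta**2 * xtx
    dof = n - 1
    se = np.sqrt(np.clip(rss, 0, None) / dof / xtx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return 2.0 * stats.t.sf(np.abs(t), dof)


@dataclass
class AssociationMatrix:
    """Motif x gene association p-values and effect sizes."""

    pvalues: pd.DataFrame    # motifs x genes, entries in (0, 1]
    betas: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.pvalues.index.equals(self.betas.index) or \
           not self.pvalues.columns.equals(self.betas.columns):
            raise ValueError("pvalues and betas must share index/columns")

    @property
    def motif_ids(self) -> list[str]:
        return list(self.pvalues.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.pvalues.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.pvalues.stack().rename("p").reset_index()
        long.columns = ["motif", "gene", "p"]
        long["beta"] = self.betas.stack().to_numpy()
        return long

    def to_tsv(self, wide_path: str | Path, long_path: str | Path | None = None) -> None:
        self.pvalues.to_csv(wide_path, sep="\t", index_label="motif")
        if long_path is not None:
            self.to_long().to_csv(long_path, sep="\t", index=False)

    def qq_data(self, motif: str) -> pd.DataFrame:
        """Observed vs expected -log10 p for one motif (QQ-plot table)."""
        p = np.sort(self.pvalues.loc[motif].to_numpy())
        m = p.size
        expected = (np.arange(1, m + 1) - 0.5) / m
        return pd.DataFrame({
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(p),
        })


def associate_all(
    A, X: ExpressionMatrix, cov: ExpressionCovariance | None = None, *, n_grid: int = 64
) -> AssociationMatrix:
    """LMM association p-values and betas for every motif x gene pair.

    ``A`` is an AccessibilityMatrix (or anything with ``values``,
    ``row_ids``/``motif_ids`` and ``cell_line_ids``); its cell lines must
    match the expression matrix exactly and in order.
    """
    a_cells = list(A.cell_line_ids)
    x_cells = list(X.cell_line_ids)
    if a_cells != x_cells:
        only_a = sorted(set(a_cells) - set(x_cells))
        only_x = sorted(set(x_cells) - set(a_cells))
        raise ValueError(
            "cell-line ids differ between accessibility and expression: "
            f"accessibility-only={only_a}, expression-only={only_x}, "
            f"order_mismatch={only_a == [] and only_x == []}"
        )
    if cov is None:
        cov = expression_covariance(X)
    motif_ids = list(getattr(A, "motif_ids", None) or A.row_ids)
    P = np.empty((len(motif_ids), len(X.gene_ids)))
    B = np.empty_like(P)
    for i, y in enumerate(np.asarray(A.values, dtype=float)):
        null_fit = fit_lmm(y, None, cov, n_grid=n_grid)
        P[i], B[i] = associate_motif(y, X, cov, null_fit=null_fit, n_grid=n_grid)
    genes = list(X.gene_ids)
    return AssociationMatrix(
        pvalues=pd.DataFrame(P, index=motif_ids, columns=genes),
        betas=pd.DataFrame(B, index=motif_ids, columns=genes),
    )
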