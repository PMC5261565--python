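"""Packaged simulation studies used to validate the method.

Two study designs, both fully determined by a seed:

* :func:`null_calibration` — type-I error of the mixed-model test versus
  naive regression under shared confounding, on independent null
  motif-gene pairs.
* :func:`planted_recovery` — end-to-end CAR-rank recovery of a planted
  regulator (accessibility normalization, association against all TF
  genes, subfamily aggregation, ranking).

These are the experiments the test suite and the reproduction script
run; they are part of the package so the numbers they produce are
regenerable from a seed alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import associate_motif, expression_covariance, fit_lmm, lrt_pvalue, ols_pvalues
from .normalize import ExpressionMatrix, inverse_normal_transform, normalize_expression
from .ranking import subfamily_car_rank, subfamily_pvalue_matrix
from .simulate import simulate_matrices

__all__ = ["null_calibration", "planted_recovery"]


def null_calibration(
    n_pairs: int = 2000,
    n_cells: int = 100,
    confounder_strength: float = 1.0,
    seed: int = 17,
) -> pd.DataFrame:
    """Mixed-model vs naive-regression p-values on independent null pairs.

    Each pair is a freshly simulated confounded dataset (no planted
    effect): one motif accessibility vector tested against one null gene,
    with the expression covariance estimated from the full simulated gene
    panel, exactly as in the real pipeline.  Returns a frame with columns
    ``lmm_p`` and ``ols_p``; under correct calibration the ``lmm_p``
    column is uniform while ``ols_p`` is inflated by the shared
    confounding.
    """
    rows = np.empty((n_pairs, 2))
    for rep in range(n_pairs):
        acc, expr, _, _ = simulate_matrices(
            n_cells=n_cells, n_motifs=1, n_tf_genes=12, n_genes=150,
            car_fraction=0.0, effect_size=0.0,
            confounder_strength=confounder_strength,
            seed=(seed * 100_003 + rep) % (2**31 - 1),
        )
        X = normalize_expression(expr)
        cov = expression_covariance(X)
        y = inverse_normal_transform(np.asarray(acc.values[0], float))
        x = np.asarray(X.values)[X.gene_ids.index("G000")]
        null = fit_lmm(y, None, cov)
        alt = fit_lmm(y, x, cov)
        rows[rep, 0] = lrt_pvalue(alt, null)
        rows[rep, 1] = ols_pvalues(y, X)[X.gene_ids.index("G000")]
    return pd.DataFrame(rows, columns=["lmm_p", "ols_p"])


def planted_recovery(
    n_replicates: int = 25,
    effect_size: float = 0.8,
    n_cells: int = 100,
    seed: int = 37,
) -> pd.DataFrame:
    """CAR rank of a single planted regulator subfamily, per replicate.

    Each replicate simulates a cohort with 12 motifs (one per TF
    subfamily, 48 TF genes, 150 additional genes), plants the CAR effect
    on exactly one motif, runs accessibility normalization and the
    mixed-model association against every TF gene, aggregates to
    subfamily level and records the planted subfamily's CAR rank.
    Returns a frame with columns ``replicate``, ``subfamily``,
    ``car_rank`` and ``domain_size``.
    """
    out = []
    for rep in range(n_replicates):
        acc, expr, sfmap, truth = simulate_matrices(
            n_cells=n_cells, n_motifs=12, n_tf_genes=48, n_genes=150,
            car_fraction=1 / 12, effect_size=effect_size,
            seed=(seed * 99_991 + rep) % (2**31 - 1),
        )
        X = normalize_expression(expr)
        cov = expression_covariance(X)
        tf_genes = [g for g in X.gene_ids if g in sfmap.tf_to_subfamily]
        tf_idx = [X.gene_ids.index(g) for g in tf_genes]
        X_tf = ExpressionMatrix(np.asarray(X.values)[tf_idx], tf_genes,
                                X.cell_line_ids, tag="final")
        P = np.empty((len(acc.row_ids), len(tf_genes)))
        B = np.empty_like(P)
        for i, y_raw in enumerate(np.asarray(acc.values, float)):
            y = inverse_normal_transform(y_raw)
            null = fit_lmm(y, None, cov)
            P[i], B[i] = associate_motif(y, X_tf, cov, null_fit=null)
        from .lmm import AssociationMatrix

        assoc = AssociationMatrix(
            pvalues=pd.DataFrame(P, index=acc.row_ids, columns=tf_genes),
            betas=pd.DataFrame(B, index=acc.row_ids, columns=tf_genes),
        )
        corrected = subfamily_pvalue_matrix(assoc, sfmap)
        table = subfamily_car_rank(corrected, sfmap, assoc)
        planted_sub = truth.planted_subfamilies[0]
        out.append({
            "replicate": rep,
            "subfamily": planted_sub,
            "car_rank": int(table.subfamily.loc[planted_sub, "car_rank"]),
            "domain_size": len(corrected.columns),
        })
    return pd.DataFrame(out)
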