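"""Associate one motif's accessibility with gene expression.

Simulates a confounded cohort with one planted regulator, then contrasts
the mixed model (random effect = expression covariance) against naive
per-gene regression for the planted motif.
"""

import numpy as np

from carscan import (
    associate_motif,
    expression_covariance,
    inverse_normal_transform,
    normalize_expression,
    ols_pvalues,
    simulate_matrices,
)

acc, expr, sfmap, truth = simulate_matrices(
    n_cells=100, n_motifs=4, car_fraction=0.25, effect_size=0.8, seed=19,
)
planted = truth.planted[0]
print(f"Planted regulator: motif {planted['motif']} <- TF {planted['tf']} "
      f"(effect size {planted['alpha']})")

X = normalize_expression(expr)
cov = expression_covariance(X)

i = acc.row_ids.index(planted["motif"])
y = inverse_normal_transform(np.asarray(acc.values[i], float))

pvals, betas = associate_motif(y, X, cov)
order = np.argsort(pvals)
print("\nTop 3 genes by mixed-model p-value:")
for j in order[:3]:
    print(f"  {X.gene_ids[j]:>6}  p = {pvals[j]:.2e}  beta = {betas[j]:+.2f}")

ols = ols_pvalues(y, X)
print(f"\nGenes with p < 0.05:  mixed model {np.sum(pvals < 0.05)}, "
      f"naive regression {np.sum(ols < 0.05)}  (of {len(pvals)} genes)")
print("The planted TF tops the mixed-model list; naive regression calls many")
print("false positives because the shared confounders correlate everything.")
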