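"""Subfamily-level CAR ranks from an association matrix, end to end.

Simulates a cohort with one planted regulator subfamily, associates every
motif with every TF gene, aggregates to TF subfamilies with the
size-corrected minimum p-value and prints the CAR rank table.
"""

import numpy as np

from carscan import (
    AccessibilityMatrix,
    associate_all,
    enrichment_curve,
    inverse_normal_transform,
    normalize_expression,
    simulate_matrices,
    subfamily_car_rank,
    subfamily_pvalue_matrix,
)

acc, expr, sfmap, truth = simulate_matrices(
    n_cells=100, n_motifs=6, n_tf_genes=24, car_fraction=1 / 6,
    effect_size=0.9, seed=37,
)
print("Planted CAR subfamily:", truth.planted_subfamilies[0])

X = normalize_expression(expr)
A = AccessibilityMatrix(
    np.apply_along_axis(inverse_normal_transform, 1, np.asarray(acc.values, float)),
    acc.row_ids, acc.cell_line_ids, tag="final",
)
assoc = associate_all(A, X)

corrected = subfamily_pvalue_matrix(assoc, sfmap)
table = subfamily_car_rank(corrected, sfmap, assoc)
print("\nCAR rank table (1 = own TF subfamily is the strongest association):")
print(table.subfamily[["car_rank", "own_corrected_p", "top_gene"]])

# with only 6 motif subfamilies over a 6-subfamily domain, 10-fold
# enrichment is unattainable by construction; 2-fold illustrates the curve
curve, threshold, frac = enrichment_curve(
    table.subfamily["car_rank"].tolist(), domain_size=len(corrected.columns),
    k_fold=2.0,
)
print(f"\n2-fold enrichment threshold: rank <= {threshold}; "
      f"{frac:.0%} of motif subfamilies fall below it.")
print("A low CAR rank means the motif's accessibility tracks the expression")
print("of its own (homologous) TF subfamily better than any other subfamily.")
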