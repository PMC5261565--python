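"""Validate motif calls in open-chromatin peaks against ChIP-seq binding.

Computes the bound-motif enrichment ratio (motif frequency in TF-bound
vs unbound DHS peaks) and the ChIP-guided motif p-value cutoffs at three
target validation rates.
"""

import tempfile
from pathlib import Path

from carscan import (
    UNREACHABLE,
    annotate_peaks,
    bound_motif_enrichment,
    read_bed,
    simulate_bed_fixture,
    tpr_guided_cutoff,
)

with tempfile.TemporaryDirectory() as tmp:
    fx = Path(tmp) / "fixture"
    man = simulate_bed_fixture(fx, n_cells=1, n_peaks=200, n_motifs=1,
                               instances_per_motif=400, seed=61)
    dhs = read_bed(fx / "peaks" / "cell0.bed", score_column=5)
    chip = read_bed(fx / "chip" / "motif0.bed", score_column=5)
    inst = read_bed(fx / "motifs" / "motif0.bed", score_column=5)

    ratio = bound_motif_enrichment(dhs, chip, inst)
    print(f"Bound-motif enrichment ratio: {ratio:.2f}")
    print("(>1 means the motif occurs more often in ChIP-bound DHS peaks)")

    annotated = annotate_peaks(dhs, chip, inst, scan_ceiling=5e-5)
    n_with = sum(a.best_motif_p is not None for a in annotated)
    print(f"\n{n_with} of {len(annotated)} peaks carry a motif below the ceiling.")
    for tpr in (0.3, 0.5, 0.7):
        c = tpr_guided_cutoff(annotated, tpr)
        label = "unreachable" if c is UNREACHABLE else f"{c:.1e}"
        print(f"  target validation rate {tpr}: motif p cutoff {label}")
    print("\nA cutoff is the loosest motif-match p-value at which the chosen")
    print("fraction of motif-bearing peaks still overlaps a ChIP-seq peak.")
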