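"""Synthetic data with the statistical structure the method assumes.

Two generators, deliberately decoupled:

* :func:`simulate_matrices` builds matrix-level data — gene expression and
  motif accessibility driven by *shared* latent confounders, with CAR
  effects planted for a chosen fraction of motifs and TFs grouped into
  correlated subfamilies.  Sharing the latent factors between the two
  modalities is the point: it makes naive regression anti-conservative
  while the mixed model, whose random effect carries the expression
  covariance, stays calibrated.
* :func:`simulate_bed_fixture` builds interval-level data — per-cell-line
  peak BEDs, motif-instance BEDs and ChIP BEDs on a toy genome, together
  with a brute-force expected-count table so the counting pipeline can be
  verified end to end.

All randomness flows from one seeded generator; the parameters and seed
are serialized in a :class:`SimulationTruth` so any dataset can be
regenerated byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, RawAccessibilityMatrix
from .normalize import AccessibilityMatrix
from .ranking import SubfamilyMap

__all__ = ["SimulationTruth", "simulate_matrices", "simulate_bed_fixture"]


@dataclass
class SimulationTruth:
    """Ground truth and full parameterization of a simulated dataset."""

    seed: int
    params: dict
    planted: list[dict] = field(default_factory=list)  # {motif, tf, subfamily, alpha}
    confounder_loadings: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "planted": self.planted,
        }
        if self.confounder_loadings is not None:
            payload["confounder_loadings"] = {
                k: np.asarray(v).tolist() for k, v in self.confounder_loadings.items()
            }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @property
    def planted_motifs(self) -> list[str]:
        return [d["motif"] for d in self.planted]

    @property
    def planted_subfamilies(self) -> list[str]:
        return [d["subfamily"] for d in self.planted]


def simulate_matrices(
    n_cells: int = 100,
    n_genes: int = 150,
    n_tf_genes: int = 48,
    n_motifs: int = 12,
    n_confounders: int = 4,
    car_fraction: float = 0.25,
    effect_size: float = 0.8,
    confounder_strength: float = 1.0,
    seed: int = 0,
    *,
    subfamily_size: int = 4,
    subfamily_cor: float = 0.6,
    noise_sd: float = 1.0,
    as_counts: bool = False,
):
    """Generate coupled expression and accessibility matrices.

    Latent confounders z_k ~ N(0, 1) per cell line drive both modalities:
    gene g gets x_g = gamma_g . z + noise, motif m gets
    y_m = alpha * x_tf(m) * [m planted] + w_m . z + noise.  TF genes are
    grouped into subfamilies of ``subfamily_size`` sharing an extra latent
    factor (loading ``subfamily_cor``), mimicking the correlated
    expression of homologous TFs.  The loading scales put the confounder
    component at variance ``confounder_strength**2`` regardless of
    ``n_confounders``.

    Returns ``(accessibility, expression_df, subfamily_map, truth)``.
    ``accessibility`` is an :class:`AccessibilityMatrix` tagged "raw" (real
    scores), or a :class:`RawAccessibilityMatrix` of monotone-discretized
    counts when ``as_counts`` is set.  ``n_genes`` counts non-TF genes;
    the expression table has ``n_tf_genes + n_genes`` rows, TFs first.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if not (0 <= car_fraction <= 1):
        raise ValueError("car_fraction must lie in [0, 1]")
    if n_tf_genes < n_motifs:
        raise ValueError("need at least one TF gene per motif")
    rng = np.random.default_rng(seed)

    cells = [f"C{j:03d}" for j in range(n_cells)]
    tf_ids = [f"TF{g:03d}" for g in range(n_tf_genes)]
    other_ids = [f"G{g:03d}" for g in range(n_genes)]
    n_subfamilies = int(np.ceil(n_tf_genes / subfamily_size))
    if n_motifs > n_subfamilies:
        raise ValueError("need at least one subfamily per motif")
    tf_to_sub = {t: f"SF{g // subfamily_size:03d}" for g, t in enumerate(tf_ids)}

    z = rng.standard_normal((n_confounders, n_cells))
    load_sd = confounder_strength / np.sqrt(n_confounders)

    gamma_tf = rng.normal(0.0, load_sd, size=(n_tf_genes, n_confounders))
    gamma_other = rng.normal(0.0, load_sd, size=(n_genes, n_confounders))
    sub_factor = rng.standard_normal((n_subfamilies, n_cells))

    X_tf = gamma_tf @ z
    for g, t in enumerate(tf_ids):
        f = g // subfamily_size
        X_tf[g] += subfamily_cor * sub_factor[f]
    X_tf += rng.normal(0.0, noise_sd, size=X_tf.shape)
    X_other = gamma_other @ z + rng.normal(0.0, noise_sd, size=(n_genes, n_cells))
    expr = pd.DataFrame(
        np.vstack([X_tf, X_other]), index=tf_ids + other_ids, columns=cells
    )

    # one motif per subfamily, annotated to that subfamily's first TF
    motif_ids = [f"M{m:03d}" for m in range(n_motifs)]
    motif_to_tf = {motif_ids[m]: tf_ids[m * subfamily_size] for m in range(n_motifs)}
    sfmap = SubfamilyMap(motif_to_tf=motif_to_tf, tf_to_subfamily=tf_to_sub)

    n_planted = int(round(car_fraction * n_motifs))
    planted_idx = rng.choice(n_motifs, size=n_planted, replace=False) if n_planted else []
    w = rng.normal(0.0, load_sd, size=(n_motifs, n_confounders))
    Y = w @ z + rng.normal(0.0, noise_sd, size=(n_motifs, n_cells))
    planted = []
    for m in planted_idx:
        tf = motif_to_tf[motif_ids[m]]
        Y[m] += effect_size * X_tf[tf_ids.index(tf)]
        planted.append({
            "motif": motif_ids[m], "tf": tf,
            "subfamily": tf_to_sub[tf], "alpha": effect_size,
        })
    planted.sort(key=lambda d: d["motif"])

    truth = SimulationTruth(
        seed=seed,
        params={
            "n_cells": n_cells, "n_genes": n_genes, "n_tf_genes": n_tf_genes,
            "n_motifs": n_motifs, "n_confounders": n_confounders,
            "car_fraction": car_fraction, "effect_size": effect_size,
            "confounder_strength": confounder_strength,
            "subfamily_size": subfamily_size, "subfamily_cor": subfamily_cor,
            "noise_sd": noise_sd, "as_counts": as_counts,
        },
        planted=planted,
        confounder_loadings={"gene_loadings": gamma_tf, "motif_loadings": w},
    )

    if as_counts:
        # rank-preserving map of real scores to plausible peak counts
        counts = np.rint(400.0 * np.exp(0.5 * (Y - Y.mean()) / max(Y.std(), 1e-12)))
        counts = np.clip(counts, 0, None).astype(np.int64)
        acc = RawAccessibilityMatrix(counts, motif_ids, cells)
    else:
        acc = AccessibilityMatrix(Y, motif_ids, cells, tag="raw")
    return acc, expr, sfmap, truth


def _write_bed(path: Path, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.score:g}\n")


def _random_intervals(
    rng: np.random.Generator,
    genome: dict[str, int],
    n: int,
    min_len: int,
    max_len: int,
    score_draw,
) -> list[GenomicInterval]:
    chroms = list(genome)
    sizes = np.array([genome[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = []
    for _ in range(n):
        c = chroms[rng.choice(len(chroms), p=probs)]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, genome[c] - length))
        out.append(GenomicInterval(c, start, start + length, score=float(score_draw(rng))))
    return out


def simulate_bed_fixture(
    out_dir: str | Path,
    n_cells: int = 3,
    genome: dict[str, int] | None = None,
    n_peaks: int = 60,
    n_motifs: int = 4,
    instances_per_motif: int = 120,
    seed: int = 0,
) -> dict:
    """Write a small BED-level fixture plus its brute-force count table.

    Produces ``peaks/<cell>.bed`` (narrowPeak-like scores in column 5),
    ``motifs/<motif>.bed`` (score column = -log10 match p),
    ``chip/<motif>.bed`` ChIP peaks, and ``expected_counts.tsv`` computed
    by an all-pairs overlap scan independent of the counting pipeline.
    Returns a manifest dict with the paths and the expected-count frame.
    """
    genome = genome or {"chr1": 100_000, "chr2": 60_000}
    if min(genome.values()) < 1000:
        raise ValueError("chromosome lengths must be >= 1 kb")
    # crude feasibility guard: average interval must fit many times over
    if n_peaks * 1000 > 10 * sum(genome.values()):
        raise ValueError("requested peak density exceeds the toy genome")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    (out_dir / "peaks").mkdir(parents=True, exist_ok=True)
    (out_dir / "motifs").mkdir(exist_ok=True)
    (out_dir / "chip").mkdir(exist_ok=True)

    cells = [f"cell{j}" for j in range(n_cells)]
    peak_sets: dict[str, list[GenomicInterval]] = {}
    for cl in cells:
        peaks = _random_intervals(rng, genome, n_peaks, 200, 800,
                                  lambda r: r.uniform(1, 100))
        _write_bed(out_dir / "peaks" / f"{cl}.bed", peaks)
        peak_sets[cl] = peaks

    motifs = [f"motif{m}" for m in range(n_motifs)]
    inst_sets: dict[str, list[GenomicInterval]] = {}
    for m in motifs:
        inst = _random_intervals(rng, genome, instances_per_motif, 8, 20,
                                 lambda r: r.uniform(5, 8))  # -log10 p in [5, 8]
        _write_bed(out_dir / "motifs" / f"{m}.bed", inst)
        inst_sets[m] = inst
        chip = _random_intervals(rng, genome, max(n_peaks // 2, 1), 150, 600,
                                 lambda r: r.uniform(1, 50))
        _write_bed(out_dir / "chip" / f"{m}.bed", chip)

    # independent all-pairs oracle for the expected counts
    expected = pd.DataFrame(0, index=motifs, columns=cells, dtype=int)
    for m in motifs:
        for cl in cells:
            n = 0
            for p in peak_sets[cl]:
                if any(p.overlaps(i) for i in inst_sets[m]):
                    n += 1
            expected.loc[m, cl] = n
    expected.to_csv(out_dir / "expected_counts.tsv", sep="\t", index_label="motif")

    truth = SimulationTruth(
        seed=seed,
        params={
            "n_cells": n_cells, "genome": genome, "n_peaks": n_peaks,
            "n_motifs": n_motifs, "instances_per_motif": instances_per_motif,
        },
    )
    truth.to_json(out_dir / "truth.json")
    return {
        "dir": out_dir,
        "cells": cells,
        "motifs": motifs,
        "expected_counts": expected,
    }
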