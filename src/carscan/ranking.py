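"""CAR ranks at the gene and TF-subfamily level.

A motif's association p-values across all genes are converted into a *CAR
rank*: the rank of the annotated TF's p-value among all genes.  Because
homologous TFs share similar binding motifs, ranks are also aggregated to
TF subfamilies (homology clusters): for each (motif subfamily, TF
subfamily) pair the smallest p-value among the member pairs is multiplied
by the number of such pairs — a Bonferroni-style size correction — and the
subfamily CAR rank is the rank of the motif's own TF subfamily among all
TF-subfamily columns.  Low CAR ranks mark candidate chromatin
accessibility regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lmm import AssociationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SubfamilyMap",
    "CarRankTable",
    "gene_level_rank",
    "subfamily_pvalue_matrix",
    "subfamily_car_rank",
    "enrichment_curve",
    "bonferroni_scan",
]


@dataclass
class SubfamilyMap:
    """Motif -> TF and TF -> subfamily assignments (TFClass-style).

    Each motif is annotated to one TF; the motif's subfamily is the
    subfamily of its annotated TF.  Subfamilies partition their members.
    """

    motif_to_tf: dict[str, str]
    tf_to_subfamily: dict[str, str]
    subfamily_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m, t in self.motif_to_tf.items() if t not in self.tf_to_subfamily]
        if missing:
            raise ValueError(f"motifs annotated to TFs without a subfamily: {missing}")

    def motif_subfamily(self, motif: str) -> str:
        return self.tf_to_subfamily[self.motif_to_tf[motif]]

    @property
    def subfamilies(self) -> list[str]:
        return sorted(set(self.tf_to_subfamily.values()))

    def members(self, subfamily: str) -> list[str]:
        return sorted(t for t, s in self.tf_to_subfamily.items() if s == subfamily)

    def motifs_in_subfamily(self, subfamily: str) -> list[str]:
        return sorted(m for m in self.motif_to_tf if self.motif_subfamily(m) == subfamily)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubfamilyMap":
        """Read a mapping table with columns motif, tf, subfamily.

        A row may leave ``motif`` empty (subfamily membership of a TF with
        no motif in the catalogue); duplicated TF rows must agree on the
        subfamily.
        """
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"motif", "tf", "subfamily"}
        if not required.issubset(df.columns):
            raise ValueError(f"mapping table needs columns {sorted(required)}")
        tf_to_sub: dict[str, str] = {}
        motif_to_tf: dict[str, str] = {}
        for _, row in df.iterrows():
            tf, sub = row["tf"], row["subfamily"]
            if tf in tf_to_sub and tf_to_sub[tf] != sub:
                raise ValueError(f"TF {tf} assigned to two subfamilies")
            tf_to_sub[tf] = sub
            if row["motif"]:
                motif_to_tf[row["motif"]] = tf
        return cls(motif_to_tf, tf_to_sub)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        tf_with_motif = set()
        for m, t in sorted(self.motif_to_tf.items()):
            rows.append({"motif": m, "tf": t, "subfamily": self.tf_to_subfamily[t]})
            tf_with_motif.add(t)
        for t, s in sorted(self.tf_to_subfamily.items()):
            if t not in tf_with_motif:
                rows.append({"motif": "", "tf": t, "subfamily": s})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _competition_rank(values: np.ndarray, idx: int, ties: str = "min") -> int:
    """Rank of values[idx], 1-based; ties share the minimum rank."""
    v = values[idx]
    if ties == "min":
        return 1 + int(np.sum(values < v))
    if ties == "average":
        smaller = int(np.sum(values < v))
        tied = int(np.sum(values == v))
        return smaller + (tied + 1) / 2
    raise ValueError(f"unknown tie rule {ties!r}")


def gene_level_rank(
    pvalues: pd.Series | Mapping[str, float], target_gene: str, ties: str = "min"
) -> int:
    """Rank of the target gene's p-value among all genes (1 = best)."""
    s = pd.Series(pvalues)
    if target_gene not in s.index:
        raise KeyError(f"gene {target_gene!r} not in the p-value vector")
    vals = s.to_numpy(float)
    return _competition_rank(vals, s.index.get_loc(target_gene), ties)


def subfamily_pvalue_matrix(
    assoc: AssociationMatrix, sfmap: SubfamilyMap
) -> pd.DataFrame:
    """Size-corrected minimum p per (motif subfamily, TF subfamily) pair.

    Entry (M, T) = min{p(m, t): m in M, t in T} * |M x T pairs present|.
    Values may exceed 1; only their ranks are consumed downstream.  Pairs
    with no member present in the association matrix are NaN and excluded
    from ranking.
    """
    unmapped_m = [m for m in assoc.motif_ids if m not in sfmap.motif_to_tf]
    if unmapped_m:
        raise ValueError(f"motifs without subfamily annotation: {unmapped_m}")
    tf_genes = [g for g in assoc.gene_ids if g in sfmap.tf_to_subfamily]
    if not tf_genes:
        raise ValueError("no TF gene of the association matrix is mapped")

    motif_sub = pd.Series({m: sfmap.motif_subfamily(m) for m in assoc.motif_ids})
    tf_sub = pd.Series({t: sfmap.tf_to_subfamily[t] for t in tf_genes})
    msubs = sorted(motif_sub.unique())
    tsubs = sorted(tf_sub.unique())
    P = assoc.pvalues[tf_genes]

    out = pd.DataFrame(np.nan, index=msubs, columns=tsubs)
    for M in msubs:
        rows = motif_sub.index[motif_sub == M]
        block_rows = P.loc[rows]
        for T in tsubs:
            cols = tf_sub.index[tf_sub == T]
            block = block_rows[cols]
            n_pairs = block.size
            if n_pairs == 0:
                continue
            out.loc[M, T] = float(block.min().min()) * n_pairs
    return out


@dataclass
class CarRankTable:
    """Subfamily-level CAR ranks plus the per-motif gene-level ranks."""

    subfamily: pd.DataFrame   # index: motif subfamily; columns: car_rank, own_corrected_p, top_gene, name
    gene_level: pd.DataFrame  # index: motif; columns: tf, gene_rank, p

    def to_tsv(self, subfamily_path: str | Path, gene_path: str | Path | None = None) -> None:
        self.subfamily.to_csv(subfamily_path, sep="\t", index_label="subfamily")
        if gene_path is not None:
            self.gene_level.to_csv(gene_path, sep="\t", index_label="motif")


def subfamily_car_rank(
    corrected: pd.DataFrame,
    sfmap: SubfamilyMap,
    assoc: AssociationMatrix | None = None,
    ties: str = "min",
) -> CarRankTable:
    """CAR rank of each motif subfamily's own TF subfamily.

    For each motif subfamily the corrected p-values across all TF
    subfamilies are competition-ranked (NaN columns excluded); the CAR
    rank is the rank of the motif's own TF subfamily.  When the
    association matrix is supplied, the top-associated gene within the own
    subfamily and per-motif gene-level ranks are recorded alongside.
    """
    rows = []
    for M in corrected.index:
        own = M  # a motif subfamily is identified by its annotated TF subfamily
        if own not in corrected.columns:
            raise KeyError(f"own TF subfamily {own!r} missing from corrected matrix")
        vals = corrected.loc[M].dropna()
        if own not in vals.index:
            raise KeyError(f"own subfamily {own!r} has no defined corrected p for {M!r}")
        rank = _competition_rank(vals.to_numpy(float), vals.index.get_loc(own), ties)
        top_gene = ""
        if assoc is not None:
            members = [g for g in sfmap.members(own) if g in assoc.gene_ids]
            motifs = [m for m in sfmap.motifs_in_subfamily(M) if m in assoc.motif_ids]
            if members and motifs:
                block = assoc.pvalues.loc[motifs, members]
                top_gene = block.min(axis=0).idxmin()
        rows.append({
            "subfamily": M,
            "name": sfmap.subfamily_names.get(M, M),
            "car_rank": rank,
            "own_corrected_p": float(corrected.loc[M, own]),
            "top_gene": top_gene,
        })
    sub_df = pd.DataFrame(rows).set_index("subfamily")

    gene_rows = []
    if assoc is not None:
        for m in assoc.motif_ids:
            tf = sfmap.motif_to_tf.get(m)
            if tf is None or tf not in assoc.gene_ids:
                continue
            pv = assoc.pvalues.loc[m]
            gene_rows.append({
                "motif": m,
                "tf": tf,
                "gene_rank": gene_level_rank(pv, tf, ties),
                "p": float(pv[tf]),
            })
    gene_df = pd.DataFrame(gene_rows).set_index("motif") if gene_rows else \
        pd.DataFrame(columns=["tf", "gene_rank", "p"])
    return CarRankTable(subfamily=sub_df, gene_level=gene_df)


def enrichment_curve(
    car_ranks: Sequence[int], domain_size: int, k_fold: float = 10.0
) -> tuple[pd.DataFrame, int | None, float]:
    """Cumulative CAR-rank curve and the k-fold enrichment threshold.

    The curve gives, for each rank cutoff r, the fraction of tested
    subfamilies with CAR rank <= r; enrichment(r) is that fraction over
    the uniform expectation r / domain_size.  The threshold is the largest
    r still k-fold enriched (k-fold enrichment = (k-1)/k false discovery
    proportion under uniformity, so k=10 is a 10% FDR cutoff).  Returns
    (curve, threshold or None, fraction of subfamilies at or below it).
    """
    ranks = np.asarray(list(car_ranks), dtype=float)
    if ranks.size == 0:
        raise ValueError("empty rank list")
    if (ranks < 1).any() or (ranks > domain_size).any():
        raise ValueError("ranks must lie in [1, domain_size]")
    r = np.arange(1, domain_size + 1)
    observed = np.array([(ranks <= ri).mean() for ri in r])
    expected = r / domain_size
    enrichment = observed / expected
    curve = pd.DataFrame({"rank": r, "observed_fraction": observed,
                          "enrichment": enrichment})
    hit = np.nonzero(enrichment >= k_fold)[0]
    if hit.size == 0:
        logger.warning("no rank cutoff achieves %.1f-fold enrichment", k_fold)
        return curve, None, 0.0
    threshold = int(r[hit[-1]])
    return curve, threshold, float(observed[hit[-1]])


def bonferroni_threshold(n_motifs: int, n_genes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (#motifs x #genes) for the full scan."""
    if n_motifs < 1 or n_genes < 1:
        raise ValueError("need at least one motif and one gene")
    return alpha / (n_motifs * n_genes)


def bonferroni_scan(assoc: AssociationMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """All motif-gene pairs below the family-wise Bonferroni threshold.

    The threshold is alpha divided by the total number of tests (#motifs x
    #genes).  Hits carry the sign of the effect size so repressive
    (negative-beta) associations are visible.
    """
    threshold = bonferroni_threshold(len(assoc.motif_ids), len(assoc.gene_ids), alpha)
    P = assoc.pvalues.to_numpy()
    B = assoc.betas.to_numpy()
    ii, jj = np.nonzero(P < threshold)
    rows = [{
        "motif": assoc.motif_ids[i],
        "gene": assoc.gene_ids[j],
        "p": float(P[i, j]),
        "beta": float(B[i, j]),
        "sign": int(np.sign(B[i, j])),
    } for i, j in zip(ii, jj)]
    out = pd.DataFrame(rows, columns=["motif", "gene", "p", "beta", "sign"])
    out.attrs["threshold"] = threshold
    return out.sort_values("p").reset_index(drop=True) if len(out) else out
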