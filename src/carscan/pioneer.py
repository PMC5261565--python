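"""Enrichment of annotated pioneer TF subfamilies among low CAR ranks.

Pioneer TFs can bind nucleosomal DNA and open chromatin, so a curated
pioneer list is a positive set for any chromatin-accessibility-regulator
caller.  Tests provided: a hypergeometric tail at a rank cutoff, a
rank-sum permutation test (permutations draw from the non-pioneer
subfamilies), a variance-matched variant that controls for the bias of
the method toward TFs with variable expression, plus max-rank combination
with an external score list and precision-recall evaluation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import ExpressionMatrix, inverse_normal_transform
from .ranking import SubfamilyMap

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "load_reference_pioneer_ranks",
    "hypergeometric_enrichment",
    "ranksum_permutation",
    "subfamily_max_variance",
    "variance_matched_permutation",
    "combine_rank_lists",
    "precision_recall",
]


@dataclass
class EnrichmentResult:
    """Outcome of one enrichment test."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p_value,
            "n_perm": self.n_permutations,
            "seed": self.seed,
        }


def load_reference_pioneer_ranks() -> pd.DataFrame:
    """Published subfamily-level CAR ranks of eight pioneer-annotated TF
    subfamilies from a large-scale ENCODE analysis, shipped as a worked
    reference example (columns: subfamily, top_gene, car_rank)."""
    from importlib.resources import files

    path = files("carscan").joinpath("data/pioneer_car_ranks.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def hypergeometric_enrichment(
    ranks: Mapping[str, int], pioneer_set: Iterable[str], rank_cutoff: int = 10
) -> EnrichmentResult:
    """Upper-tail hypergeometric test for pioneers below a rank cutoff.

    Population = all ranked subfamilies, successes = those with CAR rank
    strictly below ``rank_cutoff``, draws = the pioneer set; the p-value is
    P(X >= observed pioneer successes).
    """
    if rank_cutoff < 1:
        raise ValueError("rank_cutoff must be >= 1")
    pioneers = set(pioneer_set)
    missing = pioneers - set(ranks)
    if missing:
        raise ValueError(f"pioneer subfamilies missing from rank list: {sorted(missing)}")
    N = len(ranks)
    K = sum(1 for r in ranks.values() if r < rank_cutoff)
    n = len(pioneers)
    k = sum(1 for s in pioneers if ranks[s] < rank_cutoff)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(statistic=float(k), p_value=p,
                            n_permutations=0, seed=None, method="hypergeometric")


def _permutation_pvalue(observed: float, perm_stats: np.ndarray, tail: str) -> float:
    """(1 + #as-or-more-extreme) / (n + 1); never exactly 0."""
    if tail == "lower":
        extreme = int(np.sum(perm_stats <= observed))
    elif tail == "upper":
        extreme = int(np.sum(perm_stats >= observed))
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return (1 + extreme) / (len(perm_stats) + 1)


def ranksum_permutation(
    ranks: Mapping[str, int],
    pioneer_set: Iterable[str],
    n_perm: int = 50_000,
    seed: int = 0,
    tail: str = "lower",
) -> EnrichmentResult:
    """Permutation test on the sum of pioneer CAR ranks.

    Each permutation draws |pioneer_set| ranks without replacement from
    the non-pioneer subfamilies and sums them.  The default lower tail
    treats small rank sums (many low ranks) as enrichment; ``tail='upper'``
    gives the literal depletion test.  When the draw space is smaller than
    ``n_perm`` all subsets are enumerated exactly instead of sampled.
    """
    pioneers = sorted(set(pioneer_set))
    if not set(pioneers) <= set(ranks):
        raise ValueError("pioneer set must be a subset of the ranked subfamilies")
    non_pioneer = np.array([r for s, r in ranks.items() if s not in set(pioneers)],
                           dtype=float)
    k = len(pioneers)
    if k >= len(ranks):
        raise ValueError("pioneer set must be a strict subset of subfamilies")
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-value resolution is coarse", n_perm)
    observed = float(sum(ranks[s] for s in pioneers))

    n_subsets = math.comb(len(non_pioneer), k)
    if n_subsets <= n_perm:
        perm_stats = np.array([sum(c) for c in combinations(non_pioneer, k)])
    else:
        rng = np.random.default_rng(seed)
        perm_stats = np.array([
            rng.choice(non_pioneer, size=k, replace=False).sum() for _ in range(n_perm)
        ])
    p = _permutation_pvalue(observed, perm_stats, tail)
    return EnrichmentResult(statistic=observed, p_value=p,
                            n_permutations=len(perm_stats), seed=seed,
                            method=f"ranksum_permutation[{tail}]")


def subfamily_max_variance(X: ExpressionMatrix, sfmap: SubfamilyMap) -> pd.Series:
    """Per-subfamily maximum of normal-transformed TF expression variances.

    Each TF's expression variance across cell lines is computed, the
    variance distribution is mapped to a standard normal by the rank-based
    inverse-normal transform, and each subfamily keeps its largest value —
    a proxy for how detectable the subfamily is to a variance-hungry
    association method.
    """
    tfs = [t for t in sfmap.tf_to_subfamily if t in X.gene_ids]
    if not tfs:
        raise ValueError("no mapped TF has expression data")
    V = pd.DataFrame(X.values, index=X.gene_ids, columns=X.cell_line_ids)
    variances = V.loc[tfs].var(axis=1, ddof=0)
    transformed = pd.Series(inverse_normal_transform(variances.to_numpy()),
                            index=variances.index)
    sub = pd.Series({t: sfmap.tf_to_subfamily[t] for t in tfs})
    return transformed.groupby(sub).max()


def variance_matched_permutation(
    ranks: Mapping[str, int],
    pioneer_set: Iterable[str],
    maxvar: Mapping[str, float],
    n_perm: int = 50_000,
    seed: int = 0,
    tail: str = "lower",
) -> EnrichmentResult:
    """Rank-sum permutation with expression-variance-matched sampling.

    Null draws are stratified on the pioneer set's own maximal-variance
    distribution: half of each permutation sample (the ceiling half for
    odd sizes) comes from non-pioneer subfamilies whose value lies in
    [min, median] of the pioneer values, the other half from [median,
    max], boundaries inclusive.  This keeps the permutation null
    comparable to the pioneers in expression variability.
    """
    pioneers = sorted(set(pioneer_set))
    maxvar = pd.Series(maxvar)
    missing = [s for s in list(ranks) if s not in maxvar.index]
    if missing:
        raise ValueError(f"subfamilies without a variance value: {missing}")
    pv = maxvar[pioneers].to_numpy(float)
    lo_b, med, hi_b = float(pv.min()), float(np.median(pv)), float(pv.max())
    non_pioneer = [s for s in ranks if s not in set(pioneers)]
    low_pool = [s for s in non_pioneer if lo_b <= maxvar[s] <= med]
    high_pool = [s for s in non_pioneer if med <= maxvar[s] <= hi_b]
    k = len(pioneers)
    k_low, k_high = math.ceil(k / 2), k // 2
    for name, pool, need, bounds in (
        ("low", low_pool, k_low, (lo_b, med)),
        ("high", high_pool, k_high, (med, hi_b)),
    ):
        if len(pool) < need:
            raise ValueError(
                f"{name} variance stratum {bounds} has {len(pool)} candidates, "
                f"need {need}"
            )
    observed = float(sum(ranks[s] for s in pioneers))
    rank_arr = {s: float(ranks[s]) for s in non_pioneer}

    n_subsets = math.comb(len(low_pool), k_low) * math.comb(len(high_pool), k_high)
    if n_subsets <= n_perm:
        # exhaustive enumeration; overlapping draws (a subfamily sitting on
        # the median boundary is in both pools) are skipped
        perm_stats = []
        for lows in combinations(low_pool, k_low):
            rest_high = [s for s in high_pool if s not in lows]
            for highs in combinations(rest_high, k_high):
                perm_stats.append(sum(rank_arr[s] for s in lows)
                                  + sum(rank_arr[s] for s in highs))
        perm_stats = np.array(perm_stats)
    else:
        rng = np.random.default_rng(seed)
        perm_stats = np.empty(n_perm)
        low_arr = np.array(low_pool, dtype=object)
        for i in range(n_perm):
            lows = rng.choice(low_arr, size=k_low, replace=False)
            rest = [s for s in high_pool if s not in set(lows)]
            highs = rng.choice(np.array(rest, dtype=object), size=k_high, replace=False)
            perm_stats[i] = sum(rank_arr[s] for s in lows) + sum(rank_arr[s] for s in highs)
    p = _permutation_pvalue(observed, np.asarray(perm_stats, float), tail)
    return EnrichmentResult(statistic=observed, p_value=p,
                            n_permutations=len(perm_stats), seed=seed,
                            method=f"variance_matched_permutation[{tail}]")


def _min_tie_rerank(values: pd.Series) -> pd.Series:
    """Competition (min-tie) re-ranking of a score list, 1-based."""
    v = values.to_numpy(float)
    return pd.Series(
        [1 + int(np.sum(v < x)) for x in v], index=values.index, dtype=int
    )


def combine_rank_lists(
    ranks_a: Mapping[str, float], ranks_b: Mapping[str, float]
) -> pd.Series:
    """Max-rank combination of two rank lists over their shared universe.

    Both lists are re-ranked with the min-tie rule on the intersection of
    subfamilies, then combined per subfamily as the maximum of the two
    ranks: a low combined rank requires both methods to rank it low.
    """
    a, b = pd.Series(ranks_a), pd.Series(ranks_b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("rank lists share no subfamilies")
    if len(shared) < max(len(a), len(b)):
        logger.info("combine_rank_lists: using %d shared of %d/%d subfamilies",
                    len(shared), len(a), len(b))
    ra = _min_tie_rerank(a[shared])
    rb = _min_tie_rerank(b[shared])
    return pd.concat([ra, rb], axis=1).max(axis=1)


def precision_recall(
    scores: Mapping[str, float], truth_set: Iterable[str]
) -> pd.DataFrame:
    """Precision-recall points sweeping thresholds over a rank list.

    ``scores`` are ranks (lower is better).  For every distinct rank value
    t the predicted set is {s: rank(s) <= t}; precision and recall against
    the truth set are emitted per threshold.
    """
    truth = set(truth_set)
    if not truth:
        raise ValueError("truth set is empty")
    s = pd.Series(scores)
    rows = []
    for t in sorted(s.unique()):
        called = set(s.index[s <= t])
        tp = len(called & truth)
        rows.append({
            "threshold": float(t),
            "recall": tp / len(truth),
            "precision": tp / len(called),
        })
    return pd.DataFrame(rows)
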