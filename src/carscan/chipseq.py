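"""ChIP-seq-based validation of motif calls in open-chromatin peaks.

Two ingredients: (1) the bound-motif enrichment ratio — among DHS peaks,
how much more often the motif occurs in peaks bound by the TF (overlap
with a ChIP-seq peak) than in unbound peaks; (2) ChIP-guided motif
p-value cutoffs — the loosest motif-match cutoff at which a target
fraction of motif-bearing peaks still validates against ChIP binding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet, _merge_sorted

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedPeak",
    "UNREACHABLE",
    "bound_motif_enrichment",
    "annotate_peaks",
    "tpr_guided_cutoff",
    "median_cutoff",
]


@dataclass
class AnnotatedPeak:
    """A DHS peak annotated with ChIP binding and its best motif match."""

    interval: GenomicInterval
    bound: bool
    best_motif_p: float | None  # smallest overlapping motif-match p below the ceiling

    def __post_init__(self) -> None:
        if self.best_motif_p is not None and not (0 < self.best_motif_p):
            raise ValueError("best_motif_p must be positive when present")


class _Unreachable:
    """Sentinel: no motif cutoff reaches the requested validation rate."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNREACHABLE"

    def __bool__(self) -> bool:
        return False


UNREACHABLE = _Unreachable()


def _overlap_flags(peaks: IntervalSet, other: IntervalSet) -> np.ndarray:
    """Boolean flag per peak (in iteration order): overlaps >=1 interval."""
    merged = {c: _merge_sorted(a) for c, a in other.by_chrom().items()}
    flags = np.zeros(len(peaks), dtype=bool)
    for i, iv in enumerate(peaks):
        blocks = merged.get(iv.chrom)
        if blocks is None or len(blocks) == 0:
            continue
        j = int(np.searchsorted(blocks[:, 1], iv.start, side="right"))
        flags[i] = j < len(blocks) and blocks[j, 0] < iv.end
    return flags


def bound_motif_enrichment(
    dhs: IntervalSet, chip: IntervalSet, instances: IntervalSet
) -> float:
    """Ratio of motif-containing fractions: bound vs unbound DHS peaks.

    Peaks are partitioned by ChIP overlap; f_b and f_u are the fractions
    of bound and unbound peaks containing >=1 motif instance.  Returns
    f_b / f_u (inf with a warning when no unbound peak has the motif).
    """
    if len(dhs) == 0:
        raise ValueError("empty DHS peak set")
    bound = _overlap_flags(dhs, chip)
    has_motif = _overlap_flags(dhs, instances)
    n_bound = int(bound.sum())
    if n_bound == 0:
        raise ValueError("no DHS peak is bound by a ChIP-seq peak")
    f_b = has_motif[bound].mean()
    n_unbound = len(dhs) - n_bound
    if n_unbound == 0:
        raise ValueError("every DHS peak is bound; unbound fraction undefined")
    f_u = has_motif[~bound].mean()
    if f_u == 0:
        logger.warning("no unbound peak contains the motif; enrichment is infinite")
        return math.inf
    return float(f_b / f_u)


def annotate_peaks(
    dhs: IntervalSet,
    chip: IntervalSet,
    scored_instances: IntervalSet,
    scan_ceiling: float = 5e-5,
) -> list[AnnotatedPeak]:
    """Annotate each DHS peak with ChIP binding and its best motif p-value.

    Instance scores are -log10 match p-values (the BED convention of the
    motif-instance files); the best motif p per peak is the smallest
    p-value among overlapping instances, recorded only when it is below
    ``scan_ceiling``.
    """
    bound = _overlap_flags(dhs, chip)
    inst_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for iv in scored_instances:
        inst_by_chrom.setdefault(iv.chrom, []).append(
            (iv.start, iv.end, 10.0 ** (-iv.score))
        )
    out: list[AnnotatedPeak] = []
    for i, peak in enumerate(dhs):
        best: float | None = None
        for s, e, p in inst_by_chrom.get(peak.chrom, ()):
            if s < peak.end and peak.start < e and p < scan_ceiling:
                if best is None or p < best:
                    best = p
        out.append(AnnotatedPeak(interval=peak, bound=bool(bound[i]), best_motif_p=best))
    return out


def tpr_guided_cutoff(
    annotated: Sequence[AnnotatedPeak], target_tpr: float
):
    """Largest motif p cutoff keeping the bound fraction >= target_tpr.

    Candidate cutoffs are the observed best-motif p-values, swept in
    ascending order; among peaks with best_motif_p <= cutoff the fraction
    bound must stay at or above the target validation rate.  Returns the
    cutoff, or the :data:`UNREACHABLE` sentinel when even the strictest
    cutoff fails.
    """
    if not (0 < target_tpr < 1):
        raise ValueError("target_tpr must lie in (0, 1)")
    with_motif = [(a.best_motif_p, a.bound) for a in annotated if a.best_motif_p is not None]
    if not with_motif:
        raise ValueError("no annotated peak carries a motif below the scan ceiling")
    with_motif.sort()
    ps = np.array([p for p, _ in with_motif])
    bound = np.array([b for _, b in with_motif], dtype=float)
    frac_bound = np.cumsum(bound) / np.arange(1, len(bound) + 1)
    # evaluate at the last index of each distinct cutoff value
    distinct_last = np.nonzero(np.r_[ps[1:] != ps[:-1], True])[0]
    ok = distinct_last[frac_bound[distinct_last] >= target_tpr]
    if ok.size == 0:
        return UNREACHABLE
    return float(ps[ok[-1]])


def median_cutoff(cutoffs: Sequence[float]) -> float:
    """Median per-experiment cutoff (midpoint convention for even counts)."""
    finite = [c for c in cutoffs if c is not UNREACHABLE and math.isfinite(c)]
    if not finite:
        raise ValueError("no finite cutoffs to take the median of")
    return float(np.median(finite))
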