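"""Genomic intervals, BED I/O and peak/motif-instance overlap counting.

The accessibility of a TF binding motif in a cell line is measured here as
the number of open-chromatin (DHS) peaks that overlap at least one genomic
instance of the motif.  All coordinates follow the BED convention: 0-based,
half-open ``[start, end)``.  Two intervals overlap when they share at least
one base, so abutting intervals do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "RawAccessibilityMatrix",
    "read_bed",
    "trim_peaks",
    "count_peaks_with_motif",
    "build_raw_matrix",
    "filter_motifs",
]


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed into a valid interval."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A scored half-open genomic interval.

    ``score`` carries the peak signal for open-chromatin peaks and the
    −log10 match p-value for motif instances.  Ordering is lexicographic on
    (chrom, start, end), which is the deterministic tie-break used
    throughout the package.
    """

    chrom: str
    start: int
    end: int
    score: float = field(default=0.0, compare=False)
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Intervals are kept sorted by (chrom, start, end); sortedness is
    established once at construction so downstream sweeps can rely on it.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], *, presorted: bool = False):
        ivs = list(intervals)
        if not presorted:
            ivs.sort()
        self._intervals: list[GenomicInterval] = ivs

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @property
    def intervals(self) -> Sequence[GenomicInterval]:
        return self._intervals

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of [start, end) pairs, sorted."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


def read_bed(path: str | Path, score_column: int | None = None) -> IntervalSet:
    """Read a BED3+/narrowPeak file into a sorted :class:`IntervalSet`.

    Parameters
    ----------
    path:
        Tab-separated file, no header, with at least chrom/start/end.
    score_column:
        1-based column index holding the score (e.g. 7 for narrowPeak
        signalValue, 5 for the BED score field).  Lines lacking the column
        get score 0.

    Raises
    ------
    BedParseError
        On a malformed line, naming the offending line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            score = 0.0
            if score_column is not None and len(fields) >= score_column:
                try:
                    score = float(fields[score_column - 1])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: score column {score_column} is not numeric"
                    ) from exc
            name = fields[3] if len(fields) > 3 else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, score=score, name=name)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def trim_peaks(peaks: IntervalSet, n_top: int) -> IntervalSet:
    """Keep the ``n_top`` highest-scoring peaks.

    Cell lines whose peak lists are trimmed to a fixed size (90,000 by
    default in the pipeline) become comparable in total open-chromatin
    coverage.  Ties in score are broken by (chrom, start, end) ascending so
    the result is deterministic.  If fewer than ``n_top`` peaks are
    available all are kept and a warning is logged.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if len(peaks) <= n_top:
        if len(peaks) < n_top:
            logger.warning(
                "requested top %d peaks but only %d available; keeping all",
                n_top,
                len(peaks),
            )
        return IntervalSet(peaks.intervals, presorted=True)
    order = sorted(peaks.intervals, key=lambda iv: (-iv.score, iv.chrom, iv.start, iv.end))
    return IntervalSet(order[:n_top])


def _merge_sorted(pairs: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting sorted [start, end) pairs."""
    if len(pairs) == 0:
        return pairs
    merged = [pairs[0].copy()]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append(np.array([s, e]))
    return np.asarray(merged)


def count_peaks_with_motif(peaks: IntervalSet, instances: IntervalSet) -> int:
    """Count peaks overlapping >=1 motif instance by >=1 base.

    Each peak is counted at most once no matter how many instances it
    contains.  Instances are merged per chromosome into disjoint sorted
    blocks; a peak ``[s, e)`` then overlaps some instance iff the first
    merged block ending after ``s`` starts before ``e`` — a single binary
    search per peak.
    """
    inst_by_chrom = {c: _merge_sorted(a) for c, a in instances.by_chrom().items()}
    total = 0
    for chrom, peak_arr in peaks.by_chrom().items():
        blocks = inst_by_chrom.get(chrom)
        if blocks is None or len(blocks) == 0:
            continue
        ends = blocks[:, 1]
        idx = np.searchsorted(ends, peak_arr[:, 0], side="right")
        valid = idx < len(blocks)
        hits = np.zeros(len(peak_arr), dtype=bool)
        hits[valid] = blocks[idx[valid], 0] < peak_arr[valid, 1]
        total += int(hits.sum())
    return total


@dataclass
class RawAccessibilityMatrix:
    """Motif x cell-line matrix of raw peak-overlap counts."""

    values: np.ndarray  # (n_motifs, n_cell_lines) non-negative ints
    motif_ids: list[str]
    cell_line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.motif_ids), len(self.cell_line_ids)):
            raise ValueError("values shape does not match id lists")
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.motif_ids, columns=self.cell_line_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="motif")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RawAccessibilityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))


def build_raw_matrix(
    peak_sets: Mapping[str, IntervalSet],
    motif_catalog: Mapping[str, IntervalSet],
    n_top: int = 90_000,
) -> RawAccessibilityMatrix:
    """Assemble the raw accessibility count matrix.

    Entry (m, c) is the number of the top-``n_top`` peaks of cell line *c*
    that overlap an instance of motif *m*.  Row and column order follow the
    mapping insertion order and are recorded on the result.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least 2 cell lines")
    if len(motif_catalog) < 1:
        raise ValueError("need at least 1 motif")
    cell_lines = list(peak_sets)
    motifs = list(motif_catalog)
    trimmed: dict[str, IntervalSet] = {}
    for cl, ps in peak_sets.items():
        if len(ps) == 0:
            raise ValueError(f"cell line {cl!r} has an empty peak set")
        trimmed[cl] = trim_peaks(ps, n_top)
    values = np.zeros((len(motifs), len(cell_lines)), dtype=np.int64)
    for j, cl in enumerate(cell_lines):
        for i, m in enumerate(motifs):
            values[i, j] = count_peaks_with_motif(trimmed[cl], motif_catalog[m])
    return RawAccessibilityMatrix(values, motifs, cell_lines)


def filter_motifs(
    raw: RawAccessibilityMatrix, min_mean_peaks: float = 150.0
) -> RawAccessibilityMatrix:
    """Drop motifs present in fewer than ``min_mean_peaks`` peaks on average.

    Motifs with little open-chromatin overlap carry mostly counting noise;
    the pipeline default keeps motifs found in at least 150 peaks averaged
    across cell lines (boundary inclusive).
    """
    if min_mean_peaks < 0:
        raise ValueError("min_mean_peaks must be >= 0")
    means = raw.values.mean(axis=1)
    keep = means >= min_mean_peaks
    if not keep.any():
        raise ValueError("all motifs removed by the mean-peak filter")
    dropped = [m for m, k in zip(raw.motif_ids, keep) if not k]
    if dropped:
        logger.info("filter_motifs dropped %d motifs: %s", len(dropped), dropped)
    return RawAccessibilityMatrix(
        raw.values[keep],
        [m for m, k in zip(raw.motif_ids, keep) if k],
        list(raw.cell_line_ids),
    )
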