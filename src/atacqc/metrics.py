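"""Constant-memory streaming accumulators for QC counts and distributions.

One pass over a coordinate-sorted stream updates per-category read
counters for every read, and — for passing reads only — fragment-length,
alignment-length, MAPQ and GC histograms plus an event-based genome-wide
depth histogram.  Depth uses +1/-1 events at alignment starts/ends,
flushed per reference sequence, so memory stays O(active events) rather
than O(genome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .filtering import FilterCriteria, FilterVerdict, nominal_fragment_length
from .io_formats import CATEGORIES, AlignedRead, ReferenceCatalog

__all__ = [
    "ReadCategoryCounts",
    "SummaryStats",
    "QCState",
    "QCReport",
    "accumulate",
    "depth_from_events",
    "finalize",
    "summary_from_histogram",
]

MAX_FRAGMENT_TRACKED = 2000  # longer fragments pool in the final bin


@dataclass
class ReadCategoryCounts:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    duplicate: int = 0
    secondary: int = 0
    supplementary: int = 0
    qc_fail: int = 0
    proper_pair: int = 0
    passing: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SummaryStats:
    """Moments and order statistics computed from a histogram alone."""

    mean: Optional[float]
    sd: Optional[float]
    median: Optional[float]
    min: Optional[float]
    max: Optional[float]
    n: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summary_from_histogram(
    counts: np.ndarray, values: Optional[np.ndarray] = None
) -> SummaryStats:
    """Summary statistics of a distribution stored as (value -> count).

    ``values`` defaults to the bin indices.  The median uses the lower-bin
    convention for even total mass: it is the smallest value at which the
    cumulative mass reaches half the total.  All statistics are None on an
    empty histogram.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if values is None:
        values = np.arange(len(counts), dtype=np.float64)
    else:
        values = np.asarray(values, dtype=np.float64)
    n = int(counts.sum())
    if n == 0:
        return SummaryStats(mean=None, sd=None, median=None, min=None, max=None, n=0)
    nz = np.nonzero(counts)[0]
    mean = float(np.dot(values, counts) / n)
    var = float(np.dot((values - mean) ** 2, counts) / n)
    cum = np.cumsum(counts)
    median_idx = int(np.searchsorted(cum, (n + 1) // 2 if n % 2 else n // 2, side="left"))
    return SummaryStats(
        mean=mean,
        sd=math.sqrt(var),
        median=float(values[median_idx]),
        min=float(values[nz[0]]),
        max=float(values[nz[-1]]),
        n=n,
    )


class QCState:
    """Streaming accumulator state for one sample."""

    def __init__(
        self,
        catalog: ReferenceCatalog,
        criteria: FilterCriteria,
        max_fragment_tracked: int = MAX_FRAGMENT_TRACKED,
    ) -> None:
        self.catalog = catalog
        self.criteria = criteria
        self.max_fragment_tracked = max_fragment_tracked
        self.counts: dict[str, ReadCategoryCounts] = {
            c: ReadCategoryCounts() for c in CATEGORIES
        }
        self.fragment_hist = np.zeros(max_fragment_tracked + 2, dtype=np.int64)
        self.alignment_hist = np.zeros(max_fragment_tracked + 2, dtype=np.int64)
        self.mapq_hist = np.zeros(256, dtype=np.int64)
        self.gc_hist = np.zeros(101, dtype=np.int64)  # GC percent, 0..100
        self.depth_hist: dict[int, int] = {}
        self.bases_covered = 0
        self.reads_streamed = 0
        self._events: list[tuple[int, int]] = []
        self._current_ref: Optional[str] = None
        self._last_start = -1
        self.effective_genome = self._effective_genome()

    def _effective_genome(self) -> int:
        crit = self.criteria
        cat = self.catalog
        if crit.target_regions is not None:
            return crit.target_regions.merged_length()
        names = cat.names if not crit.nuclear_only else [
            e.name for e in cat.entries if e.category == "nuclear"
        ]
        if crit.target_sequences is not None:
            wanted = {n.casefold() for n in crit.target_sequences}
            names = [n for n in names if n.casefold() in wanted]
        size = sum(cat.length_of(n) for n in names)
        if crit.blacklist is not None:
            for n in names:
                size -= crit.blacklist.merged_length(n)
        return max(size, 0)

    # -- depth event handling -------------------------------------------------

    def _flush_depth(self) -> None:
        if self._current_ref is None or not self._events:
            self._events = []
            return
        hist, covered = depth_from_events(
            self._events, self.catalog.length_of(self._current_ref)
        )
        for d, bases in hist.items():
            self.depth_hist[d] = self.depth_hist.get(d, 0) + bases
        self.bases_covered += covered
        self._events = []

    def finish_stream(self) -> None:
        self._flush_depth()
        self._current_ref = None


def depth_from_events(
    events: list[tuple[int, int]], reference_length: int
) -> tuple[dict[int, int], int]:
    """Depth histogram contribution of one reference sequence.

    ``events`` are (position, +1/-1) pairs at passing-read alignment starts
    and ends.  Returns ({depth d >= 1: bases at depth d}, bases covered).
    Uncovered positions are accounted for globally via
    ``effective_genome - bases_covered`` at finalization.
    """
    if not events:
        return {}, 0
    arr = np.asarray(events, dtype=np.int64)
    pos = np.clip(arr[:, 0], 0, reference_length)
    delta = arr[:, 1]
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    # Collapse duplicate positions, then sweep.
    upos, idx = np.unique(pos, return_index=True)
    sums = np.add.reduceat(delta, idx)
    depth = np.cumsum(sums)
    if depth[-1] != 0 or np.any(depth < 0):
        raise RuntimeError("depth sweep inconsistency: negative or non-zero final depth")
    seg_len = np.diff(upos)
    seg_depth = depth[:-1]
    keep = (seg_len > 0) & (seg_depth > 0)
    hist: dict[int, int] = {}
    covered = 0
    for d, ln in zip(seg_depth[keep], seg_len[keep]):
        d = int(d)
        hist[d] = hist.get(d, 0) + int(ln)
        covered += int(ln)
    return hist, covered


def accumulate(state: QCState, read: AlignedRead, verdict: FilterVerdict) -> QCState:
    """Fold one read into the streaming state.

    Category counters are updated for every read; histograms and depth
    events only for passing reads.  Each passing fragment contributes one
    fragment-length observation (positive-TLEN mate only).  Raises if the
    stream is not coordinate-sorted.
    """
    state.reads_streamed += 1
    cat = state.counts[verdict.category]
    cat.total += 1
    if read.unmapped:
        cat.unmapped += 1
    else:
        cat.mapped += 1
        if read.reference_name != state._current_ref:
            if (
                state._current_ref is not None
                and read.reference_name in state.catalog.names
                and state.catalog.names.index(read.reference_name)
                < state.catalog.names.index(state._current_ref)
            ):
                raise ValueError("input not coordinate-sorted (reference order violated)")
            state._flush_depth()
            state._current_ref = read.reference_name
            state._last_start = -1
        elif read.start < state._last_start:
            raise ValueError("input not coordinate-sorted")
        state._last_start = read.start
    if read.duplicate:
        cat.duplicate += 1
    if read.secondary:
        cat.secondary += 1
    if read.supplementary:
        cat.supplementary += 1
    if read.qc_fail:
        cat.qc_fail += 1
    if read.proper_pair:
        cat.proper_pair += 1

    if not verdict.passed:
        return state
    cat.passing += 1

    flen = nominal_fragment_length(read)
    if flen is not None and read.template_length > 0:
        state.fragment_hist[min(flen, state.max_fragment_tracked + 1)] += 1
    state.alignment_hist[min(read.aligned_length, state.max_fragment_tracked + 1)] += 1
    state.mapq_hist[min(read.mapq, 255)] += 1
    if read.gc_count is not None and read.query_length > 0:
        state.gc_hist[round(100 * read.gc_count / read.query_length)] += 1
    state._events.append((read.start, +1))
    state._events.append((read.end, -1))
    return state


@dataclass
class QCReport:
    """Finalized, serializable QC summary for one sample.

    The JSON document is the superset: every number in the text rendering
    is derivable from this structure.
    """

    tool: str
    version: str
    timestamp: str
    input_path: str
    parameters: dict
    catalog: dict
    category_counts: dict
    category_percent_total: dict  # denominator: total reads streamed
    type_percent_mapped: dict  # denominator: mapped reads
    passing_total: int
    stats: dict  # SummaryStats per histogram, as dicts
    histograms: dict  # raw histogram arrays (lists)
    effective_genome: int
    bases_covered: int
    coverage_fraction: Optional[float]
    mean_depth: Optional[float]
    reads_streamed: int
    frip: Optional[float] = None
    tes: Optional[float] = None
    tss_pileup: Optional[dict] = None
    peak_pileup: Optional[dict] = None
    footprint: Optional[dict] = None
    periodicity: Optional[float] = None
    grid: Optional[list] = None
    single_end: bool = False


def finalize(
    state: QCState,
    criteria: FilterCriteria,
    catalog: ReferenceCatalog,
    input_path: str = "",
    single_end: bool = False,
) -> QCReport:
    """Close the stream and produce the finalized report skeleton.

    Percentages are emitted with both denominators stated: category
    percentages relative to total reads streamed, read-type percentages
    relative to mapped reads.  Signal analytics (FRiP, TES, pileups,
    periodicity, grid) are attached by the pipeline afterwards.
    """
    import datetime

    from . import __version__

    state.finish_stream()

    total = state.reads_streamed
    mapped = sum(c.mapped for c in state.counts.values())
    category_counts = {c: state.counts[c].as_dict() for c in CATEGORIES}
    pct_total = {
        c: (100.0 * state.counts[c].total / total) if total else None for c in CATEGORIES
    }
    type_counts = {
        k: sum(getattr(state.counts[c], k) for c in CATEGORIES)
        for k in ("duplicate", "secondary", "supplementary", "qc_fail", "proper_pair", "passing")
    }
    pct_mapped = {
        k: (100.0 * v / mapped) if mapped else None for k, v in type_counts.items()
    }

    frag_stats = summary_from_histogram(state.fragment_hist)
    align_stats = summary_from_histogram(state.alignment_hist)
    mapq_stats = summary_from_histogram(state.mapq_hist)
    gc_stats = summary_from_histogram(state.gc_hist)

    depth_zero = max(state.effective_genome - state.bases_covered, 0)
    if state.effective_genome > 0:
        max_d = max(state.depth_hist, default=0)
        depth_counts = np.zeros(max_d + 1, dtype=np.int64)
        depth_counts[0] = depth_zero
        for d, b in state.depth_hist.items():
            depth_counts[d] = b
        depth_stats = summary_from_histogram(depth_counts)
        coverage_fraction = state.bases_covered / state.effective_genome
        mean_depth = depth_stats.mean
        depth_hist_out = {int(k): int(v) for k, v in sorted(state.depth_hist.items())}
        depth_hist_out[0] = int(depth_zero)
    else:
        depth_stats = summary_from_histogram(np.zeros(1, dtype=np.int64))
        coverage_fraction = None
        mean_depth = None
        depth_hist_out = {}

    if single_end:
        frag_stats = summary_from_histogram(np.zeros(1, dtype=np.int64))

    return QCReport(
        tool="atacqc",
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        input_path=str(input_path),
        parameters=criteria.describe(),
        catalog=catalog.summary(),
        category_counts=category_counts,
        category_percent_total=pct_total,
        type_percent_mapped=pct_mapped,
        passing_total=type_counts["passing"],
        stats={
            "fragment_length": frag_stats.as_dict(),
            "alignment_length": align_stats.as_dict(),
            "mapq": mapq_stats.as_dict(),
            "gc_percent": gc_stats.as_dict(),
            "depth": depth_stats.as_dict(),
        },
        histograms={
            "fragment_length": state.fragment_hist.tolist(),
            "alignment_length": state.alignment_hist.tolist(),
            "mapq": state.mapq_hist.tolist(),
            "gc_percent": state.gc_hist.tolist(),
            "depth": {str(k): v for k, v in sorted(depth_hist_out.items())},
        },
        effective_genome=state.effective_genome,
        bases_covered=state.bases_covered,
        coverage_fraction=coverage_fraction,
        mean_depth=mean_depth,
        reads_streamed=total,
        single_end=single_end,
    )
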