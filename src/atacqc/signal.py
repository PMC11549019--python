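"""Positional signal analytics.

Implements the 5' resizing and Tn5-offset transform, anchored pileup
profiles (TSS / peak-center / TF binding site), the TSS enrichment score
(TES), fraction of reads in peaks (FRiP), single-base insertion footprint
profiles, fragment-length periodicity detection, and the filter-parameter
grid search.

Tn5 creates staggered nicks 9 bp apart; shifting plus-strand 5' ends by
+4 and minus-strand 5' ends by -5 places coordinates at the center of the
transposition event (the standard ATAC-seq convention).  The offsets are
configurable.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .filtering import (
    FilterCriteria,
    FilterVerdict,
    evaluate_read,
    nominal_fragment_length,
)
from .io_formats import AlignedRead, ReferenceCatalog, RegionSet, stream_alignments

__all__ = [
    "TN5_OFFSETS",
    "PileupProfile",
    "PileupAccumulator",
    "GridResult",
    "effective_interval",
    "pileup",
    "tss_enrichment_score",
    "frip",
    "footprint_profile",
    "fragment_periodicity",
    "parameter_grid_search",
]

TN5_OFFSETS = (4, -5)  # (plus-strand shift, minus-strand shift)

TES_SMOOTH_BP = 25
TES_FLANK_FRACTION = 0.1
PERIODICITY_RANGE = (40, 250)
PERIODICITY_BAND = (5.0, 20.0)
PERIODICITY_MIN_MASS = 1000
PERIODICITY_PROMINENCE = 10.0  # peak power / median band power required to call a period
DEFAULT_TSS_RADIUS = 1000
DEFAULT_FOOTPRINT_RADIUS = 100


@dataclass
class PileupProfile:
    """Mean per-position event density around a set of anchors.

    ``values[radius]`` is the density at the anchor base itself; minus-
    strand anchors are flipped so downstream is always to the right.
    """

    anchor_role: str
    radius: int
    values: np.ndarray  # length 2*radius + 1, mean events per anchor
    n_anchors: int
    resize: Optional[int]
    tn5_shifted: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != 2 * self.radius + 1:
            raise ValueError("profile length must be 2*radius + 1")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def as_dict(self) -> dict:
        return {
            "anchor_role": self.anchor_role,
            "radius": self.radius,
            "n_anchors": self.n_anchors,
            "resize": self.resize,
            "tn5_shifted": self.tn5_shifted,
            "values": self.values.tolist(),
        }


def effective_interval(
    read: AlignedRead,
    resize: Optional[int],
    tn5: bool,
    offsets: tuple[int, int] = TN5_OFFSETS,
    reference_length: Optional[int] = None,
) -> tuple[Optional[str], int, int]:
    """Resize a read around its (optionally Tn5-shifted) 5' end.

    The 5' end is ``start`` on the plus strand and ``end - 1`` on the minus
    strand.  The returned window has width ``resize``, centered on the
    shifted 5' base and left-biased by one base when ``resize`` is even,
    clipped to [0, reference_length).  ``resize=None`` returns the
    unmodified alignment interval.
    """
    if read.unmapped:
        raise ValueError("effective_interval requires a mapped read")
    if resize is None:
        return read.reference_name, read.start, read.end
    if resize < 1:
        raise ValueError("resize must be >= 1")
    if read.strand == "+":
        five = read.start
        if tn5:
            five += offsets[0]
    else:
        five = read.end - 1
        if tn5:
            five += offsets[1]
    start = five - resize // 2
    end = start + resize
    if reference_length is not None:
        start = max(start, 0)
        end = min(end, reference_length)
        end = max(end, start)
    return read.reference_name, start, end


class PileupAccumulator:
    """Streaming accumulator: total event-base coverage per anchor-relative
    position, averaged over anchors at finalization."""

    def __init__(self, anchors: RegionSet, radius: int, anchor_role: str,
                 resize: Optional[int] = None, tn5_shifted: bool = False,
                 known_chroms: Optional[set[str]] = None) -> None:
        if len(anchors) == 0:
            raise ValueError("pileup requires at least one anchor")
        if radius < 1:
            raise ValueError("radius must be >= 1")
        self.radius = radius
        self.anchor_role = anchor_role
        self.resize = resize
        self.tn5_shifted = tn5_shifted
        self.totals = np.zeros(2 * radius + 1, dtype=np.float64)
        self._anchors: dict[str, tuple[list[int], list[str]]] = {}
        self.n_anchors = 0
        skipped = 0
        for chrom, pos, strand in anchors.anchor_points():
            if known_chroms is not None and chrom not in known_chroms:
                skipped += 1
                continue
            positions, strands = self._anchors.setdefault(chrom, ([], []))
            positions.append(pos)
            strands.append(strand)
            self.n_anchors += 1
        if skipped:
            warnings.warn(
                f"{skipped} {anchor_role} anchor(s) on sequences absent from the "
                "reference catalog were skipped"
            )
        if self.n_anchors == 0:
            raise ValueError("no usable anchors after catalog filtering")
        for chrom, (positions, strands) in self._anchors.items():
            order = sorted(range(len(positions)), key=positions.__getitem__)
            self._anchors[chrom] = (
                [positions[i] for i in order],
                [strands[i] for i in order],
            )

    def anchor_windows(self, chrom: str, start: int, end: int) -> Iterator[tuple[int, str]]:
        """Anchors whose +/- radius window overlaps [start, end)."""
        got = self._anchors.get(chrom)
        if got is None:
            return
        positions, strands = got
        lo = bisect_left(positions, start - self.radius)
        hi = bisect_right(positions, end - 1 + self.radius)
        for i in range(lo, hi):
            yield positions[i], strands[i]

    def add_interval(self, chrom: Optional[str], start: int, end: int) -> None:
        if chrom is None or end <= start:
            return
        r = self.radius
        for apos, astrand in self.anchor_windows(chrom, start, end):
            lo = max(start, apos - r)
            hi = min(end, apos + r + 1)
            if hi <= lo:
                continue
            if astrand == "-":
                # flip the local axis: relative position p becomes -p
                a, b = apos - (hi - 1), apos - lo
                self.totals[a + r : b + r + 1] += 1
            else:
                self.totals[lo - apos + r : hi - apos + r] += 1

    def finalize(self) -> PileupProfile:
        return PileupProfile(
            anchor_role=self.anchor_role,
            radius=self.radius,
            values=self.totals / self.n_anchors,
            n_anchors=self.n_anchors,
            resize=self.resize,
            tn5_shifted=self.tn5_shifted,
        )


def pileup(
    intervals: Iterable[tuple[Optional[str], int, int]],
    anchors: RegionSet,
    radius: int,
    anchor_role: str = "tss",
    resize: Optional[int] = None,
    tn5_shifted: bool = False,
    known_chroms: Optional[set[str]] = None,
) -> PileupProfile:
    """Mean per-position coverage of the given intervals around anchors.

    For TSS anchors, the anchor base is the BED start on the plus strand
    and end-1 on the minus strand; unstranded anchors use the midpoint.
    Minus-strand anchors are axis-flipped so downstream is to the right.
    """
    acc = PileupAccumulator(
        anchors, radius, anchor_role, resize=resize, tn5_shifted=tn5_shifted,
        known_chroms=known_chroms,
    )
    for chrom, start, end in intervals:
        acc.add_interval(chrom, start, end)
    return acc.finalize()


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge correction (window shrinks at the
    boundaries so edge values are means over the available positions)."""
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def tss_enrichment_score(
    profile: PileupProfile,
    flank_fraction: float = TES_FLANK_FRACTION,
    smooth_bp: int = TES_SMOOTH_BP,
) -> Optional[float]:
    """TSS enrichment score: signal-to-background ratio of the pileup.

    TES = max of the profile smoothed with a centered ``smooth_bp`` moving
    average, divided by the background, the mean of the outer
    ``flank_fraction`` of positions on each side of the window.  Returns
    None (with a warning) when the background is zero.  A flat profile has
    TES exactly 1.0, and the score is invariant to positive scaling.
    """
    if not (0 < flank_fraction <= 0.5):
        raise ValueError("flank_fraction must be in (0, 0.5]")
    values = profile.values
    n = len(values)
    if n < smooth_bp:
        raise ValueError(
            f"profile radius too small for a {smooth_bp}-bp smoothing window"
        )
    n_flank = max(1, int(round(flank_fraction * n)))
    background = float(np.concatenate([values[:n_flank], values[-n_flank:]]).mean())
    if background == 0.0:
        warnings.warn("TES undefined: zero background signal in the flanks")
        return None
    if np.all(values == values[0]):
        # a constant profile scores exactly 1 (avoids smoothing round-off)
        return 1.0
    smoothed = _centered_moving_average(values, smooth_bp)
    return float(smoothed.max() / background)


def frip(
    verdicts: Iterable[tuple[AlignedRead, FilterVerdict]],
    peaks: RegionSet,
) -> Optional[float]:
    """Fraction of passing reads overlapping >= 1 peak by >= 1 bp.

    Overlap is tested on the unresized alignment interval.  Returns None
    (with a warning) when no read passes.
    """
    if len(peaks) == 0:
        raise ValueError("FRiP requires a non-empty peak set")
    passing = 0
    in_peaks = 0
    for read, verdict in verdicts:
        if not verdict.passed or read.unmapped:
            continue
        passing += 1
        if peaks.overlaps(read.reference_name, read.start, read.end):
            in_peaks += 1
    if passing == 0:
        warnings.warn("FRiP undefined: zero passing reads")
        return None
    return in_peaks / passing


def footprint_profile(
    reads: Iterable[AlignedRead],
    sites: RegionSet,
    radius: int = DEFAULT_FOOTPRINT_RADIUS,
    offsets: tuple[int, int] = TN5_OFFSETS,
    known_chroms: Optional[set[str]] = None,
) -> PileupProfile:
    """Average single-base Tn5 insertion frequency around binding sites.

    Each read contributes the single Tn5-shifted base of its own 5' end,
    so a properly paired fragment contributes two insertion events (one
    per mate).  Resizing is forced to 1 bp and the Tn5 shift is forced on.
    """
    intervals = (
        effective_interval(r, resize=1, tn5=True, offsets=offsets)
        for r in reads
        if not r.unmapped
    )
    return pileup(
        intervals, sites, radius, anchor_role="tfbs", resize=1, tn5_shifted=True,
        known_chroms=known_chroms,
    )


def fragment_periodicity(
    fragment_hist: Union[np.ndarray, Sequence[int]],
    length_range: tuple[int, int] = PERIODICITY_RANGE,
    band: tuple[float, float] = PERIODICITY_BAND,
    min_mass: int = PERIODICITY_MIN_MASS,
    prominence: float = PERIODICITY_PROMINENCE,
    detrend_window: int = 21,
    nfft: int = 1 << 15,
) -> Optional[float]:
    """Dominant fragment-length period (bp) within a spectral band.

    The histogram is restricted to ``length_range``, detrended by dividing
    by a centered ``detrend_window``-bp moving average and subtracting 1,
    and the zero-padded power spectrum is searched within ``band`` (min,
    max period in bp).  The spectral peak is refined by quadratic
    interpolation.  Returns None when the in-range mass is below
    ``min_mass`` or no peak exceeds ``prominence`` times the median band
    power (no dominant periodicity).
    """
    hist = np.asarray(fragment_hist, dtype=np.float64)
    lo, hi = length_range
    if hi >= len(hist):
        hist = np.concatenate([hist, np.zeros(hi + 1 - len(hist))])
    seg = hist[lo : hi + 1]
    mass = seg.sum()
    if mass < min_mass:
        warnings.warn(
            f"periodicity undefined: only {int(mass)} fragments in "
            f"[{lo}, {hi}] (need >= {min_mass})"
        )
        return None
    trend = _centered_moving_average(seg, detrend_window)
    with np.errstate(divide="ignore", invalid="ignore"):
        detrended = np.where(trend > 0, seg / trend - 1.0, 0.0)
    detrended -= detrended.mean()
    spectrum = np.abs(np.fft.rfft(detrended, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0)
    pmin, pmax = band
    in_band = (freqs >= 1.0 / pmax) & (freqs <= 1.0 / pmin)
    if not np.any(in_band):
        return None
    band_idx = np.nonzero(in_band)[0]
    band_power = spectrum[band_idx]
    peak_local = int(np.argmax(band_power))
    peak = band_idx[peak_local]
    med = float(np.median(band_power))
    if spectrum[peak] <= 0 or (med > 0 and spectrum[peak] / med < prominence):
        return None
    if med == 0 and spectrum[peak] == 0:
        return None
    # quadratic interpolation of the spectral peak
    if 0 < peak < len(spectrum) - 1:
        y0, y1, y2 = spectrum[peak - 1], spectrum[peak], spectrum[peak + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    freq = freqs[peak] + shift * (freqs[1] - freqs[0])
    return float(1.0 / freq)


@dataclass
class GridResult:
    """Filter-parameter grid-search result: one row per retained
    (min_mapq, min_fragment, max_fragment) combination."""

    rows: list[dict]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def parameter_grid_search(
    bam_path,
    grid: tuple[Sequence[int], Sequence[int], Sequence[int]],
    tss: RegionSet,
    catalog: ReferenceCatalog,
    restrict: Optional[Union[str, RegionSet]] = None,
    base_criteria: Optional[FilterCriteria] = None,
    radius: int = DEFAULT_TSS_RADIUS,
    resize: Optional[int] = 100,
    tn5: bool = True,
    offsets: tuple[int, int] = TN5_OFFSETS,
) -> GridResult:
    """Sweep (min_mapq, min_fragment, max_fragment) combinations in one pass.

    A read's verdict under each combination is independent, so a single
    stream feeds per-combination passing counts and TSS pileups; results
    equal running the full pipeline once per combination.  Combinations
    with min_fragment > max_fragment are skipped with a warning.
    """
    mapqs, min_flens, max_flens = grid
    combos = []
    for m, lo, hi in product(mapqs, min_flens, max_flens):
        if lo > hi:
            warnings.warn(f"skipping grid combination min_fragment {lo} > max_fragment {hi}")
            continue
        combos.append((m, lo, hi))
    if not combos:
        raise ValueError("empty parameter grid")

    M = np.array([c[0] for c in combos])
    LO = np.array([c[1] for c in combos])
    HI = np.array([c[2] for c in combos])
    n_combo = len(combos)

    if base_criteria is None:
        base_criteria = FilterCriteria()
    # Neutral thresholds: non-grid checks come from the base criteria.
    import dataclasses as _dc

    neutral = _dc.replace(base_criteria, min_mapq=0, min_fragment=0,
                          max_fragment=FilterCriteria.__dataclass_fields__["max_fragment"].default)

    anchor_acc = PileupAccumulator(tss, radius, "tss", resize=resize, tn5_shifted=tn5)
    width = 2 * radius + 1
    totals = np.zeros((n_combo, width), dtype=np.float64)
    passing = np.zeros(n_combo, dtype=np.int64)

    ref_lengths = {e.name: e.length for e in catalog.entries}
    for read in stream_alignments(bam_path, catalog, restrict=restrict):
        verdict = evaluate_read(read, neutral, catalog)
        if not verdict.passed:
            continue
        flen = nominal_fragment_length(read)
        mask = M <= read.mapq
        if flen is not None:
            mask = mask & (LO <= flen) & (flen <= HI)
        if not mask.any():
            continue
        passing[mask] += 1
        chrom, s, e = effective_interval(
            read, resize=resize, tn5=tn5, offsets=offsets,
            reference_length=ref_lengths.get(read.reference_name),
        )
        r = radius
        for apos, astrand in anchor_acc.anchor_windows(chrom, s, e):
            lo_ = max(s, apos - r)
            hi_ = min(e, apos + r + 1)
            if hi_ <= lo_:
                continue
            if astrand == "-":
                a, b = apos - (hi_ - 1), apos - lo_
                totals[mask, a + r : b + r + 1] += 1
            else:
                totals[mask, lo_ - apos + r : hi_ - apos + r] += 1

    rows = []
    for i, (m, lo, hi) in enumerate(combos):
        prof = PileupProfile(
            anchor_role="tss", radius=radius,
            values=totals[i] / anchor_acc.n_anchors,
            n_anchors=anchor_acc.n_anchors, resize=resize, tn5_shifted=tn5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tes = tss_enrichment_score(prof)
        rows.append(
            {
                "min_mapq": int(m),
                "min_fragment": int(lo),
                "max_fragment": int(hi),
                "passing": int(passing[i]),
                "tes": tes,
            }
        )
    return GridResult(rows=rows)
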