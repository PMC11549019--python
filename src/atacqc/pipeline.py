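"""Single-pass pipeline: stream, filter, accumulate, analyze, report.

Ties the modules together: one coordinate-ordered pass over the BAM feeds
the category counters and histograms, the depth events, the FRiP tally,
the TSS/peak pileup and the footprint accumulator, and (optionally) the
filtered-BAM writer.  Everything downstream (TES, periodicity) is computed
from the accumulated state.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterator, Optional, Union

import pysam

from .filtering import FilterCriteria, evaluate_read
from .io_formats import (
    AlignedRead,
    RegionSet,
    load_reference_catalog,
    parse_bed,
    stream_alignments,
    write_filtered_bam,
)
from .metrics import QCReport, QCState, accumulate, finalize
from .signal import (
    DEFAULT_FOOTPRINT_RADIUS,
    DEFAULT_TSS_RADIUS,
    TN5_OFFSETS,
    PileupAccumulator,
    effective_interval,
    fragment_periodicity,
    tss_enrichment_score,
)

__all__ = ["run_qc"]


def _as_region_set(value, role: str) -> Optional[RegionSet]:
    if value is None or isinstance(value, RegionSet):
        return value
    return parse_bed(value, role=role)


def run_qc(
    bam_path: Union[str, Path],
    criteria: Optional[FilterCriteria] = None,
    mito_names=None,
    plastid_names=None,
    tss: Optional[Union[RegionSet, str, Path]] = None,
    peaks: Optional[Union[RegionSet, str, Path]] = None,
    footprint_sites: Optional[Union[RegionSet, str, Path]] = None,
    tss_radius: int = DEFAULT_TSS_RADIUS,
    footprint_radius: int = DEFAULT_FOOTPRINT_RADIUS,
    tn5_offsets: tuple[int, int] = TN5_OFFSETS,
    restrict: Optional[Union[str, RegionSet]] = None,
    filtered_bam: Optional[Union[str, Path]] = None,
    command_line: str = "",
) -> QCReport:
    """Run full QC on one BAM and return the finalized report."""
    bam_path = str(bam_path)
    if criteria is None:
        criteria = FilterCriteria()

    tss = _as_region_set(tss, "tss")
    peaks = _as_region_set(peaks, "peaks")
    footprint_sites = _as_region_set(footprint_sites, "tfbs")

    with pysam.AlignmentFile(bam_path, "rb") as af:
        catalog = load_reference_catalog(af.header, mito_names, plastid_names)
        header = af.header
    known = set(catalog.names)
    ref_lengths = {e.name: e.length for e in catalog.entries}

    state = QCState(catalog, criteria)

    anchors = tss if criteria.pileup_anchor == "tss" else peaks
    pile_acc = None
    if anchors is not None and len(anchors) > 0:
        pile_acc = PileupAccumulator(
            anchors,
            tss_radius,
            anchor_role=criteria.pileup_anchor,
            resize=criteria.resize,
            tn5_shifted=criteria.tn5_shift,
            known_chroms=known,
        )
    foot_acc = None
    if criteria.footprint and footprint_sites is not None and len(footprint_sites) > 0:
        foot_acc = PileupAccumulator(
            footprint_sites,
            footprint_radius,
            anchor_role="tfbs",
            resize=1,
            tn5_shifted=True,
            known_chroms=known,
        )

    stats = {"frip_passing": 0, "frip_in_peaks": 0, "any_paired": False}

    def passing_reads() -> Iterator[AlignedRead]:
        for read in stream_alignments(bam_path, catalog, restrict=restrict):
            if read.paired:
                stats["any_paired"] = True
            verdict = evaluate_read(read, criteria, catalog)
            accumulate(state, read, verdict)
            if not verdict.passed:
                continue
            if peaks is not None and len(peaks) > 0:
                stats["frip_passing"] += 1
                if peaks.overlaps(read.reference_name, read.start, read.end):
                    stats["frip_in_peaks"] += 1
            if pile_acc is not None:
                chrom, s, e = effective_interval(
                    read,
                    resize=criteria.resize,
                    tn5=criteria.tn5_shift,
                    offsets=tn5_offsets,
                    reference_length=ref_lengths.get(read.reference_name),
                )
                pile_acc.add_interval(chrom, s, e)
            if foot_acc is not None:
                chrom, s, e = effective_interval(
                    read, resize=1, tn5=True, offsets=tn5_offsets,
                    reference_length=ref_lengths.get(read.reference_name),
                )
                foot_acc.add_interval(chrom, s, e)
            yield read

    written = None
    if filtered_bam is not None:
        written = write_filtered_bam(
            filtered_bam, header, passing_reads(), command_line=command_line
        )
    else:
        for _ in passing_reads():
            pass

    single_end = not stats["any_paired"] and state.reads_streamed > 0
    report = finalize(state, criteria, catalog, input_path=bam_path,
                      single_end=single_end)

    if peaks is not None and len(peaks) > 0:
        report.frip = (
            stats["frip_in_peaks"] / stats["frip_passing"]
            if stats["frip_passing"]
            else None
        )
        if stats["frip_passing"] == 0:
            warnings.warn("FRiP undefined: zero passing reads")
    if pile_acc is not None:
        profile = pile_acc.finalize()
        key = "tss_pileup" if criteria.pileup_anchor == "tss" else "peak_pileup"
        setattr(report, key, profile.as_dict())
        if criteria.pileup_anchor == "tss":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report.tes = tss_enrichment_score(profile)
    if foot_acc is not None:
        report.footprint = foot_acc.finalize().as_dict()
    if not single_end:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.periodicity = fragment_periodicity(state.fragment_hist)
    if written is not None and written != report.passing_total:
        raise RuntimeError(
            f"internal inconsistency: wrote {written} reads but counted "
            f"{report.passing_total} passing"
        )
    return report
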