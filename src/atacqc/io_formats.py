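"""SAM/BAM and BED input/output.

Builds the reference catalog from a BAM header, streams alignments in a
single coordinate-ordered pass (optionally restricted to a sequence or a
region set), parses BED interval files, and writes filtered BAMs.

All internal coordinates are 0-based half-open (BAM and BED native).
1-based samtools-style region strings ("Chr1:100-200") are converted on
parse and never appear internally.
"""

from __future__ import annotations

import re
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam

__all__ = [
    "CATEGORIES",
    "DEFAULT_MITO_NAMES",
    "DEFAULT_PLASTID_NAMES",
    "ReferenceCatalog",
    "AlignedRead",
    "RegionSet",
    "load_reference_catalog",
    "stream_alignments",
    "parse_bed",
    "parse_region_string",
    "write_filtered_bam",
]

CATEGORIES = ("nuclear", "mitochondrial", "plastid")

# Common organelle sequence names across assemblies (matched case-insensitively).
DEFAULT_MITO_NAMES = ("chrM", "MT", "ChrM", "mitochondria")
DEFAULT_PLASTID_NAMES = ("chrC", "Pt", "ChrC", "chloroplast")


class BedFormatError(ValueError):
    """A malformed line in a BED file."""


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    length: int
    category: str


@dataclass
class ReferenceCatalog:
    """Reference sequences from a BAM header, each assigned to exactly one
    of the nuclear / mitochondrial / plastid categories.

    A category may hold any number of sequences (including zero), which
    supports incomplete assemblies with several organellar scaffolds.
    """

    entries: list[CatalogEntry]
    _by_name: dict[str, CatalogEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference sequence names in header")
        for e in self.entries:
            if e.length <= 0:
                raise ValueError(f"reference {e.name!r} has non-positive length")
        self._by_name = {e.name: e for e in self.entries}

    def category_of(self, name: Optional[str]) -> str:
        """Category of a reference; unmapped reads (name None) count as nuclear."""
        if name is None:
            return "nuclear"
        return self._by_name[name].category

    def length_of(self, name: str) -> int:
        return self._by_name[name].length

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for e in self.entries:
            out[e.category] += 1
        return out

    def genome_size(self, category: Optional[str] = None) -> int:
        return sum(
            e.length for e in self.entries if category is None or e.category == category
        )

    def summary(self) -> dict:
        return {
            "n_sequences": len(self.entries),
            "counts": self.counts(),
            "genome_size": self.genome_size(),
            "nuclear_size": self.genome_size("nuclear"),
            "sequences": [
                {"name": e.name, "length": e.length, "category": e.category}
                for e in self.entries
            ],
        }


@dataclass
class AlignedRead:
    """One alignment record, with the original pysam segment retained so
    that a filtered BAM can be written with every field and tag intact."""

    query_name: str
    reference_name: Optional[str]
    start: int  # 0-based inclusive; -1 for unmapped
    end: int  # 0-based exclusive (reference-consuming CIGAR span)
    strand: str  # "+" or "-"
    mapq: int
    paired: bool
    proper_pair: bool
    mate_unmapped: bool
    reverse: bool
    secondary: bool
    supplementary: bool
    duplicate: bool
    qc_fail: bool
    unmapped: bool
    first_in_pair: bool
    template_length: int
    aligned_length: int
    gc_count: Optional[int]  # None when the record stores no sequence ("*")
    query_length: int
    segment: Optional[pysam.AlignedSegment] = field(
        default=None, repr=False, compare=False
    )

    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment) -> "AlignedRead":
        unmapped = seg.is_unmapped
        start = -1 if unmapped else seg.reference_start
        end = -1 if unmapped else seg.reference_end
        seq = seg.query_sequence
        if seq is None:
            gc: Optional[int] = None
            qlen = seg.query_length or 0
        else:
            gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
            qlen = len(seq)
        return cls(
            query_name=seg.query_name or "",
            reference_name=None if unmapped else seg.reference_name,
            start=start,
            end=end if end is not None else start,
            strand="-" if seg.is_reverse else "+",
            mapq=seg.mapping_quality,
            paired=seg.is_paired,
            proper_pair=seg.is_proper_pair,
            mate_unmapped=seg.is_paired and seg.mate_is_unmapped,
            reverse=seg.is_reverse,
            secondary=seg.is_secondary,
            supplementary=seg.is_supplementary,
            duplicate=seg.is_duplicate,
            qc_fail=seg.is_qcfail,
            unmapped=unmapped,
            first_in_pair=seg.is_paired and seg.is_read1,
            template_length=seg.template_length,
            aligned_length=0 if unmapped else (end or start) - start,
            gc_count=gc,
            query_length=qlen,
            segment=seg,
        )


@dataclass
class RegionSet:
    """A named set of genomic intervals (BED convention: 0-based half-open).

    Overlap queries run in O(log n) per lookup against per-chromosome
    sorted, merged interval lists.
    """

    name: str
    intervals: list[tuple[str, int, int, str]]
    _merged: dict[str, tuple[list[int], list[int]]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for chrom, start, end, strand in self.intervals:
            if start >= end:
                raise ValueError(
                    f"region set {self.name!r}: invalid interval {chrom}:{start}-{end}"
                )
            if strand not in ("+", "-", "."):
                raise ValueError(f"region set {self.name!r}: bad strand {strand!r}")
        self._build()

    def _build(self) -> None:
        per: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.intervals:
            per.setdefault(chrom, []).append((start, end))
        for chrom, ivs in per.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._merged[chrom] = (
                [m[0] for m in merged],
                [m[1] for m in merged],
            )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._merged)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval by >= 1 bp."""
        got = self._merged.get(chrom)
        if got is None or end <= start:
            return False
        starts, ends = got
        i = bisect_right(starts, end - 1) - 1
        return i >= 0 and ends[i] > start

    def merged_intervals(self, chrom: str) -> list[tuple[int, int]]:
        got = self._merged.get(chrom)
        if got is None:
            return []
        return list(zip(got[0], got[1]))

    def merged_length(self, chrom: Optional[str] = None) -> int:
        chroms = [chrom] if chrom is not None else list(self._merged)
        total = 0
        for c in chroms:
            got = self._merged.get(c)
            if got:
                total += sum(e - s for s, e in zip(got[0], got[1]))
        return total

    def anchor_points(self) -> list[tuple[str, int, str]]:
        """One anchor base per interval: BED start for '+', end-1 for '-',
        the interval midpoint for unstranded intervals."""
        out = []
        for chrom, start, end, strand in self.intervals:
            if strand == "+":
                pos = start
            elif strand == "-":
                pos = end - 1
            else:
                pos = (start + end - 1) // 2
            out.append((chrom, pos, strand))
        return out


def load_reference_catalog(
    bam_header,
    mito_names: Optional[Sequence[str]] = None,
    plastid_names: Optional[Sequence[str]] = None,
) -> ReferenceCatalog:
    """Build the reference catalog from a BAM header.

    Name matching is exact string equality after case-folding.  Listed
    organelle names absent from the header raise a warning, not an error,
    so that one name list can serve multiple assemblies.
    """
    if mito_names is None:
        mito_names = DEFAULT_MITO_NAMES
        mito_default = True
    else:
        mito_default = False
    if plastid_names is None:
        plastid_names = DEFAULT_PLASTID_NAMES
        plastid_default = True
    else:
        plastid_default = False

    if isinstance(bam_header, pysam.AlignmentHeader):
        refs = list(zip(bam_header.references, bam_header.lengths))
    elif isinstance(bam_header, dict):
        refs = [(sq["SN"], sq["LN"]) for sq in bam_header.get("SQ", [])]
    else:  # pysam.AlignmentFile
        refs = list(zip(bam_header.references, bam_header.lengths))
    if not refs:
        raise ValueError("no reference sequences in BAM header")

    mito = {n.casefold() for n in mito_names}
    plastid = {n.casefold() for n in plastid_names}
    overlap = mito & plastid
    if overlap:
        raise ValueError(f"names listed as both mitochondrial and plastid: {overlap}")

    entries = []
    seen: set[str] = set()
    for name, length in refs:
        folded = name.casefold()
        seen.add(folded)
        if folded in mito:
            cat = "mitochondrial"
        elif folded in plastid:
            cat = "plastid"
        else:
            cat = "nuclear"
        entries.append(CatalogEntry(name=name, length=length, category=cat))

    # Only warn about user-supplied names; the built-in defaults are a
    # convenience superset and rarely all present.
    if not mito_default:
        for n in mito_names:
            if n.casefold() not in seen:
                warnings.warn(f"mitochondrial name {n!r} not found in BAM header")
    if not plastid_default:
        for n in plastid_names:
            if n.casefold() not in seen:
                warnings.warn(f"plastid name {n!r} not found in BAM header")

    return ReferenceCatalog(entries=entries)


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region_string(region: str) -> tuple[str, int, int]:
    """Convert a samtools-style 1-based region ("Chr1:100-200") to
    0-based half-open coordinates."""
    m = _REGION_RE.match(region)
    if m is None:
        raise ValueError(f"cannot parse region string {region!r}")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", "")) - 1
    end = int(m.group(3).replace(",", ""))
    if start < 0 or end <= start:
        raise ValueError(f"invalid region coordinates in {region!r}")
    return chrom, start, end


def _check_coordinate_sorted(af: pysam.AlignmentFile, path) -> None:
    hd = af.header.to_dict().get("HD", {})
    if hd.get("SO") != "coordinate":
        raise ValueError(f"{path}: BAM is not coordinate-sorted (SO tag {hd.get('SO')!r})")


def stream_alignments(
    bam_path: Union[str, Path],
    catalog: Optional[ReferenceCatalog] = None,
    restrict: Optional[Union[str, RegionSet]] = None,
) -> Iterator[AlignedRead]:
    """Stream alignments in coordinate order, each exactly once.

    Without ``restrict``, every record in the file is yielded (including
    unmapped reads at the end of the file).  With ``restrict`` — either a
    sequence name / samtools-style region string, or a :class:`RegionSet` —
    only reads overlapping the restriction by >= 1 bp are yielded, which
    requires a BAM index.
    """
    bam_path = str(bam_path)
    with pysam.AlignmentFile(bam_path, "rb") as af:
        _check_coordinate_sorted(af, bam_path)
        if restrict is None:
            for seg in af.fetch(until_eof=True):
                yield AlignedRead.from_pysam(seg)
            return

        if not af.has_index():
            raise ValueError(f"{bam_path}: an index is required for region-restricted streaming")

        if isinstance(restrict, str):
            if ":" in restrict:
                chrom, start, end = parse_region_string(restrict)
                windows = [(chrom, start, end)]
            else:
                if restrict not in af.references:
                    raise ValueError(f"{bam_path}: sequence {restrict!r} not in header")
                windows = [(restrict, 0, af.get_reference_length(restrict))]
        else:
            windows = []
            for chrom in af.references:
                for s, e in restrict.merged_intervals(chrom):
                    windows.append((chrom, s, e))

        prev: dict[str, tuple[int, int]] = {}
        for chrom, wstart, wend in windows:
            pstart, pend = prev.get(chrom, (-1, -1))
            for seg in af.fetch(chrom, wstart, min(wend, af.get_reference_length(chrom))):
                # A read spanning the gap from the previous merged window was
                # already yielded there (windows are disjoint and sorted, and a
                # contiguous read reaching any earlier window covers the
                # immediately preceding one).
                if seg.reference_start < pend and seg.reference_end > pstart:
                    continue
                yield AlignedRead.from_pysam(seg)
            prev[chrom] = (wstart, wend)


_BED_SKIP = ("track", "browser", "#")


def parse_bed(path: Union[str, Path], role: str = "regions") -> RegionSet:
    """Parse a 3+ column BED file into a :class:`RegionSet`.

    Column 6 (strand) is honored when present; blank lines and lines
    starting with ``track``, ``browser`` or ``#`` are skipped.  Malformed
    coordinates raise :class:`BedFormatError` naming the line.
    """
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or any(line.startswith(p) for p in _BED_SKIP):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path} line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise BedFormatError(
                    f"{path} line {lineno}: start >= end ({start} >= {end})"
                )
            strand = "."
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            intervals.append((chrom, start, end, strand))
    return RegionSet(name=role, intervals=intervals)


def write_filtered_bam(
    out_path: Union[str, Path],
    header,
    passing_reads: Iterable[AlignedRead],
    command_line: str = "",
    make_index: bool = True,
) -> int:
    """Write passing reads to a new coordinate-sorted BAM.

    The output header is the input header plus one @PG line recording the
    tool, version, and full parameter string.  All original fields and
    tags of each read are preserved verbatim.  Returns the number of
    reads written.
    """
    from . import __version__

    if isinstance(header, pysam.AlignmentHeader):
        hdr = header.to_dict()
    elif isinstance(header, pysam.AlignmentFile):
        hdr = header.header.to_dict()
    else:
        hdr = dict(header)
    pg = {"ID": "atacqc", "PN": "atacqc", "VN": __version__}
    if command_line:
        pg["CL"] = command_line
    hdr.setdefault("PG", [])
    ids = {p.get("ID") for p in hdr["PG"]}
    if pg["ID"] in ids:
        k = 1
        while f"atacqc.{k}" in ids:
            k += 1
        pg["ID"] = f"atacqc.{k}"
    hdr["PG"] = list(hdr["PG"]) + [pg]

    out_path = str(out_path)
    count = 0
    with pysam.AlignmentFile(out_path, "wb", header=hdr) as out:
        for read in passing_reads:
            if read.segment is None:
                raise ValueError("cannot write an AlignedRead with no underlying record")
            out.write(read.segment)
            count += 1
    if make_index:
        try:
            pysam.index(out_path)
        except pysam.SamtoolsError:  # pragma: no cover - e.g. unsorted edge input
            pass
    return count
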