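"""Per-read filtering: categories, pass/fail verdicts, and mode presets.

Checks are applied in a fixed order (unmapped, secondary, supplementary,
QC-fail, duplicate, proper pair, MAPQ, fragment bounds, organellar origin,
target/blacklist restriction) and every applicable failure reason is
recorded — verdicts are not short-circuited, so reason tallies are
complete.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from .io_formats import AlignedRead, ReferenceCatalog, RegionSet

__all__ = [
    "FAIL_REASONS",
    "MODES",
    "FilterCriteria",
    "FilterVerdict",
    "nominal_fragment_length",
    "evaluate_read",
    "apply_preset",
]

FAIL_REASONS = (
    "unmapped",
    "duplicate",
    "secondary",
    "supplementary",
    "qc_fail",
    "improper_pair",
    "low_mapq",
    "fragment_short",
    "fragment_long",
    "organellar",
    "off_target",
    "blacklisted",
)

MODES = ("default", "nfr", "mono", "chip", "footprint")

UNLIMITED = 2**31 - 1


@dataclass
class FilterCriteria:
    """Thresholds and switches controlling which reads pass QC.

    ``use_all=True`` disables every filter: any mapped, primary,
    non-supplementary read passes regardless of the other settings.

    The signal-processing switches (``tn5_shift``, ``resize``,
    ``pileup_anchor``, ``footprint``) live here so that mode presets can
    configure the whole run in one place.
    """

    min_mapq: int = 0
    min_fragment: int = 0
    max_fragment: int = UNLIMITED
    require_proper_pair: bool = True
    drop_duplicates: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_qc_fail: bool = True
    nuclear_only: bool = True
    use_all: bool = False
    target_regions: Optional[RegionSet] = None
    blacklist: Optional[RegionSet] = None
    target_sequences: Optional[list[str]] = None
    mode: str = "default"
    # Signal-processing switches (set by chip/footprint presets).
    # resize=None disables 5' resizing: the full alignment interval is piled up.
    tn5_shift: bool = True
    resize: Optional[int] = 100
    pileup_anchor: str = "tss"  # "tss" or "peaks"
    footprint: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.min_mapq <= 255):
            raise ValueError("min_mapq must be in [0, 255]")
        if not (0 <= self.min_fragment <= self.max_fragment):
            raise ValueError("need 0 <= min_fragment <= max_fragment")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; valid modes: {', '.join(MODES)}")
        if self.resize is not None and self.resize < 1:
            raise ValueError("resize must be >= 1 (or None to disable resizing)")

    def describe(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_regions"] = None if self.target_regions is None else len(self.target_regions)
        d["blacklist"] = None if self.blacklist is None else len(self.blacklist)
        d["max_fragment"] = None if self.max_fragment >= UNLIMITED else self.max_fragment
        return d


@dataclass
class FilterVerdict:
    """Category plus pass/fail bookkeeping for one read."""

    category: str
    fail_reasons: frozenset[str] = field(default_factory=frozenset)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def nominal_fragment_length(read: AlignedRead) -> Optional[int]:
    """Fragment length of a properly paired read: |TLEN|.

    Undefined (None) for unpaired reads, improper pairs, and records with
    TLEN 0.  Histograms count each fragment once by only accumulating the
    mate with positive TLEN.
    """
    if not read.paired or not read.proper_pair or read.template_length == 0:
        return None
    return abs(read.template_length)


def evaluate_read(
    read: AlignedRead,
    criteria: FilterCriteria,
    catalog: ReferenceCatalog,
) -> FilterVerdict:
    """Assign a category and a pass/fail verdict under the active criteria.

    All applicable fail reasons are accumulated.  With ``use_all`` only
    unmapped, secondary and supplementary records fail (every mapped
    primary read is processed); the category is recorded either way.
    """
    category = catalog.category_of(read.reference_name)
    reasons: set[str] = set()

    if read.unmapped:
        return FilterVerdict(category=category, fail_reasons=frozenset({"unmapped"}))

    if criteria.use_all:
        if read.secondary:
            reasons.add("secondary")
        if read.supplementary:
            reasons.add("supplementary")
        return FilterVerdict(category=category, fail_reasons=frozenset(reasons))

    if criteria.drop_secondary and read.secondary:
        reasons.add("secondary")
    if criteria.drop_supplementary and read.supplementary:
        reasons.add("supplementary")
    if criteria.drop_qc_fail and read.qc_fail:
        reasons.add("qc_fail")
    if criteria.drop_duplicates and read.duplicate:
        reasons.add("duplicate")

    if read.paired:
        if criteria.require_proper_pair and not read.proper_pair:
            reasons.add("improper_pair")
        flen = nominal_fragment_length(read)
        if flen is not None:
            if flen < criteria.min_fragment:
                reasons.add("fragment_short")
            if flen > criteria.max_fragment:
                reasons.add("fragment_long")
    # Single-end data: proper-pair and fragment filters are skipped, not failed.

    if read.mapq < criteria.min_mapq:
        reasons.add("low_mapq")

    if criteria.nuclear_only and category != "nuclear":
        reasons.add("organellar")

    if criteria.target_sequences is not None:
        folded = {n.casefold() for n in criteria.target_sequences}
        if read.reference_name is not None and read.reference_name.casefold() not in folded:
            reasons.add("off_target")
    if criteria.target_regions is not None:
        if not criteria.target_regions.overlaps(read.reference_name, read.start, read.end):
            reasons.add("off_target")
    if criteria.blacklist is not None:
        if criteria.blacklist.overlaps(read.reference_name, read.start, read.end):
            reasons.add("blacklisted")

    return FilterVerdict(category=category, fail_reasons=frozenset(reasons))


# Preset parameter table.  NFR keeps sub-nucleosomal fragments (<= 120 bp);
# mono keeps mononucleosomal fragments (150-250 bp) — the boundary between
# the two populations sits between ~120 and ~150 bp in typical ATAC data.
_PRESETS: dict[str, dict] = {
    "default": {},
    "nfr": {"max_fragment": 120},
    "mono": {"min_fragment": 150, "max_fragment": 250},
    "chip": {"tn5_shift": False, "resize": None, "pileup_anchor": "peaks"},
    "footprint": {"footprint": True, "tn5_shift": True, "resize": 1},
}


def apply_preset(
    mode: str,
    base: FilterCriteria,
    user_overrides: frozenset[str] | set[str] = frozenset(),
) -> FilterCriteria:
    """Return criteria with the mode's preset values applied.

    Fields named in ``user_overrides`` were set explicitly by the user and
    always win over preset values.
    """
    if mode not in _PRESETS:
        raise ValueError(f"unknown mode {mode!r}; valid modes: {', '.join(MODES)}")
    updates = {k: v for k, v in _PRESETS[mode].items() if k not in user_overrides}
    updates["mode"] = mode
    return dataclasses.replace(base, **updates)
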