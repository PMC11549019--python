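import dataclasses

import pytest

from atacqc.filtering import (
    FilterCriteria,
    apply_preset,
    evaluate_read,
    nominal_fragment_length,
)
from atacqc.io_formats import RegionSet, load_reference_catalog

from conftest import make_read

CATALOG = load_reference_catalog(
    {"SQ": [{"SN": "Chr1", "LN": 100_000}, {"SN": "ChrM", "LN": 10_000},
            {"SN": "ChrC", "LN": 10_000}]},
    mito_names=["ChrM"], plastid_names=["ChrC"],
)


class TestNominalFragmentLength:
    def test_absolute_value_of_tlen(self):
        assert nominal_fragment_length(make_read(template_length=-180)) == 180
        assert nominal_fragment_length(make_read(template_length=180)) == 180

    def test_undefined_for_unpaired_improper_or_zero(self):
        assert nominal_fragment_length(make_read(paired=False)) is None
        assert nominal_fragment_length(make_read(proper_pair=False)) is None
        assert nominal_fragment_length(make_read(template_length=0)) is None


class TestEvaluateRead:
    def test_clean_nuclear_proper_pair_passes(self):
        v = evaluate_read(make_read(mapq=42, template_length=120),
                          FilterCriteria(), CATALOG)
        assert v.passed and v.category == "nuclear"

    def test_organellar_read_fails_but_keeps_category(self):
        v = evaluate_read(make_read(reference_name="ChrM"), FilterCriteria(), CATALOG)
        assert v.fail_reasons == {"organellar"}
        assert v.category == "mitochondrial"

    def test_reasons_accumulate_not_short_circuit(self):
        crit = FilterCriteria(min_mapq=40, max_fragment=150)
        v = evaluate_read(make_read(mapq=10, template_length=300), crit, CATALOG)
        assert v.fail_reasons == {"low_mapq", "fragment_long"}

    def test_one_bp_blacklist_overlap_fails(self):
        crit = FilterCriteria(blacklist=RegionSet("bl", [("Chr1", 199, 300, ".")]))
        v = evaluate_read(make_read(start=100, end=200), crit, CATALOG)
        assert "blacklisted" in v.fail_reasons
        crit2 = FilterCriteria(blacklist=RegionSet("bl", [("Chr1", 200, 300, ".")]))
        assert evaluate_read(make_read(start=100, end=200), crit2, CATALOG).passed

    def test_unmapped_read_fails_with_single_reason(self):
        v = evaluate_read(
            make_read(unmapped=True, reference_name=None, start=-1, end=-1),
            FilterCriteria(), CATALOG,
        )
        assert v.fail_reasons == {"unmapped"}

    def test_target_regions_and_sequences(self):
        crit = FilterCriteria(target_regions=RegionSet("t", [("Chr1", 0, 150, ".")]))
        assert evaluate_read(make_read(start=100, end=200), crit, CATALOG).passed
        assert "off_target" in evaluate_read(
            make_read(start=300, end=400), crit, CATALOG
        ).fail_reasons
        crit2 = FilterCriteria(target_sequences=["ChrM"], nuclear_only=False)
        assert "off_target" in evaluate_read(make_read(), crit2, CATALOG).fail_reasons

    def test_single_end_skips_pairing_filters(self):
        crit = FilterCriteria(min_fragment=100, max_fragment=200)
        read = make_read(paired=False, proper_pair=False, template_length=0)
        assert evaluate_read(read, crit, CATALOG).passed

    def test_use_all_passes_every_mapped_primary_read(self):
        crit = FilterCriteria(use_all=True, min_mapq=40)
        bad = make_read(mapq=0, duplicate=True, proper_pair=False,
                        reference_name="ChrM")
        v = evaluate_read(bad, crit, CATALOG)
        assert v.passed and v.category == "mitochondrial"
        assert not evaluate_read(make_read(secondary=True), crit, CATALOG).passed


class TestApplyPreset:
    def test_nfr_caps_fragment_length(self):
        crit = apply_preset("nfr", FilterCriteria())
        assert crit.max_fragment == 120 and crit.mode == "nfr"

    def test_mono_brackets_mononucleosomal_window(self):
        crit = apply_preset("mono", FilterCriteria())
        assert (crit.min_fragment, crit.max_fragment) == (150, 250)

    def test_default_is_identity(self):
        base = FilterCriteria(min_mapq=13, min_fragment=7)
        out = apply_preset("default", base)
        assert dataclasses.replace(out, mode="default") == base

    def test_chip_disables_shift_and_resizing(self):
        crit = apply_preset("chip", FilterCriteria())
        assert not crit.tn5_shift and crit.resize is None
        assert crit.pileup_anchor == "peaks"

    def test_footprint_forces_single_base_shifted(self):
        crit = apply_preset("footprint", FilterCriteria())
        assert crit.footprint and crit.tn5_shift and crit.resize == 1

    def test_user_flags_override_preset(self):
        base = FilterCriteria(max_fragment=500)
        crit = apply_preset("nfr", base, user_overrides={"max_fragment"})
        assert crit.max_fragment == 500

    def test_unknown_mode_lists_valid_ones(self):
        with pytest.raises(ValueError, match="nfr"):
            apply_preset("bogus", FilterCriteria())


def _random_reads(rng, n=400):
    reads = []
    for i in range(n):
        ref = rng.choice(["Chr1", "Chr1", "Chr1", "ChrM"])
        start = int(rng.integers(0, 50_000))
        flen = int(rng.integers(20, 500))
        reads.append(
            make_read(
                query_name=f"r{i}",
                reference_name=ref,
                start=start,
                end=start + 50,
                mapq=int(rng.integers(0, 61)),
                template_length=flen,
                duplicate=bool(rng.random() < 0.1),
                proper_pair=bool(rng.random() > 0.05),
                secondary=bool(rng.random() < 0.05),
            )
        )
    return reads


def _passing_count(reads, crit):
    return sum(evaluate_read(r, crit, CATALOG).passed for r in reads)


def test_threshold_tightening_is_monotone(rng):
    """Raising min_mapq / min_fragment or lowering max_fragment never
    increases the passing count."""
    reads = _random_reads(rng)
    for _ in range(30):
        mq = int(rng.integers(0, 50))
        lo = int(rng.integers(0, 200))
        hi = int(rng.integers(lo, 600))
        loose = FilterCriteria(min_mapq=mq, min_fragment=lo, max_fragment=hi)
        tight_lo = min(lo + int(rng.integers(0, 50)), hi)
        tight_hi = max(hi - int(rng.integers(0, 100)), tight_lo)
        tight = FilterCriteria(
            min_mapq=mq + int(rng.integers(0, 10)),
            min_fragment=tight_lo,
            max_fragment=tight_hi,
        )
        assert _passing_count(reads, tight) <= _passing_count(reads, loose)


def test_use_all_dominates(rng):
    """With use_all, passing count equals mapped primary non-supplementary reads."""
    reads = _random_reads(rng)
    crit = FilterCriteria(use_all=True, min_mapq=40, max_fragment=100)
    expected = sum(1 for r in reads if not (r.unmapped or r.secondary or r.supplementary))
    assert _passing_count(reads, crit) == expected


def test_every_read_lands_in_exactly_one_category(rng):
    reads = _random_reads(rng)
    cats = [evaluate_read(r, FilterCriteria(), CATALOG).category for r in reads]
    assert all(c in ("nuclear", "mitochondrial", "plastid") for c in cats)
    assert len(cats) == len(reads)
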