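import numpy as np
import pysam
import pytest

from atacqc.filtering import FilterCriteria, evaluate_read
from atacqc.io_formats import RegionSet, load_reference_catalog
from atacqc.pipeline import run_qc
from atacqc.signal import (
    PileupProfile,
    effective_interval,
    footprint_profile,
    fragment_periodicity,
    frip,
    parameter_grid_search,
    pileup,
    tss_enrichment_score,
)
from atacqc.synthetic import nucleosomal_length_model, sample_fragment_lengths

from conftest import make_read


class TestEffectiveInterval:
    def test_plus_strand_single_base(self):
        read = make_read(start=100, end=200, strand="+")
        assert effective_interval(read, resize=1, tn5=False) == ("Chr1", 100, 101)

    def test_minus_strand_tn5_shift(self):
        # 5' base of a minus-strand read is end-1 = 199; Tn5 shifts it by -5
        read = make_read(start=100, end=200, strand="-", reverse=True)
        assert effective_interval(read, resize=1, tn5=True) == ("Chr1", 194, 195)

    def test_even_resize_window_is_left_biased_with_exact_width(self):
        read = make_read(start=100, end=200, strand="+")
        chrom, s, e = effective_interval(read, resize=100, tn5=True)
        assert (s, e) == (54, 154)  # centered on 104, one extra base left
        assert e - s == 100

    def test_odd_resize_window_is_symmetric(self):
        read = make_read(start=100, end=200, strand="+")
        chrom, s, e = effective_interval(read, resize=101, tn5=False)
        assert (s, e) == (50, 151)

    def test_clipping_to_reference(self):
        read = make_read(start=3, end=53, strand="+")
        chrom, s, e = effective_interval(read, resize=100, tn5=False, reference_length=60)
        assert s == 0 and e == 53

    def test_none_resize_returns_alignment_interval(self):
        read = make_read(start=100, end=200)
        assert effective_interval(read, resize=None, tn5=True) == ("Chr1", 100, 200)


ANCHORS = RegionSet("tss", [("Chr1", 5000, 5001, "+")])


class TestPileup:
    def test_delta_function_at_anchor(self):
        prof = pileup([("Chr1", 5000, 5001)], ANCHORS, radius=50)
        expected = np.zeros(101)
        expected[50] = 1.0
        np.testing.assert_array_equal(prof.values, expected)

    def test_strand_flip_reverses_profile_exactly(self):
        intervals = [("Chr1", 4950, 4990), ("Chr1", 5005, 5030), ("Chr1", 5000, 5001)]
        plus = pileup(intervals, RegionSet("t", [("Chr1", 5000, 5001, "+")]), radius=60)
        minus = pileup(intervals, RegionSet("t", [("Chr1", 4941, 5001, "-")]), radius=60)
        np.testing.assert_array_equal(minus.values, plus.values[::-1])

    def test_mass_conservation(self, rng):
        anchors = RegionSet("t", [("Chr1", p, p + 1, "+") for p in (2000, 4000, 6000)])
        radius = 100
        intervals = []
        expected_mass = 0
        for _ in range(500):
            s = int(rng.integers(1500, 6500))
            e = s + int(rng.integers(1, 80))
            intervals.append(("Chr1", s, e))
            for a in (2000, 4000, 6000):
                expected_mass += max(0, min(e, a + radius + 1) - max(s, a - radius))
        prof = pileup(intervals, anchors, radius)
        assert prof.values.sum() * prof.n_anchors == pytest.approx(expected_mass)

    def test_zero_anchors_rejected(self):
        with pytest.raises(ValueError):
            pileup([], RegionSet("t", []), radius=10)

    def test_unknown_chromosome_anchors_skipped_with_warning(self):
        anchors = RegionSet("t", [("Chr1", 100, 101, "+"), ("ChrX", 100, 101, "+")])
        with pytest.warns(UserWarning, match="skipped"):
            prof = pileup([("Chr1", 100, 101)], anchors, radius=10,
                          known_chroms={"Chr1"})
        assert prof.n_anchors == 1


class TestTssEnrichmentScore:
    def test_flat_profile_scores_exactly_one(self):
        prof = PileupProfile("tss", 200, np.full(401, 3.7), 10, 100, True)
        assert tss_enrichment_score(prof) == 1.0

    def test_scaling_invariance(self, rng):
        values = rng.random(401) + 0.5
        p1 = PileupProfile("tss", 200, values, 10, 100, True)
        p2 = PileupProfile("tss", 200, values * 17.3, 10, 100, True)
        assert tss_enrichment_score(p1) == pytest.approx(tss_enrichment_score(p2))

    def test_plateau_over_unit_flanks(self):
        # flanks at 1, wide central plateau at 8 -> TES exactly 8
        values = np.zeros(401)
        values[:40] = 1.0
        values[-40:] = 1.0
        values[180:221] = 8.0
        prof = PileupProfile("tss", 200, values, 10, 100, True)
        assert tss_enrichment_score(prof) == pytest.approx(8.0)

    def test_zero_background_returns_null(self):
        values = np.zeros(401)
        values[200] = 5.0
        prof = PileupProfile("tss", 200, values, 10, 100, True)
        with pytest.warns(UserWarning, match="zero background"):
            assert tss_enrichment_score(prof) is None

    def test_radius_too_small_for_smoothing(self):
        prof = PileupProfile("tss", 5, np.ones(11), 1, 100, True)
        with pytest.raises(ValueError, match="smoothing"):
            tss_enrichment_score(prof)

    def test_enriched_fixture_beats_background_removal(self, clean_fixture):
        """TES > 1 on a TSS-enriched library, and grows when organellar and
        low-quality background is filtered more stringently."""
        loose = run_qc(clean_fixture.bam, criteria=FilterCriteria(min_mapq=0),
                       tss=clean_fixture.anchors)
        tight = run_qc(clean_fixture.bam,
                       criteria=FilterCriteria(min_mapq=30, max_fragment=250),
                       tss=clean_fixture.anchors)
        assert loose.tes is not None and loose.tes > 1.0
        assert tight.tes > loose.tes


class TestFrip:
    def _verdicts(self, reads):
        catalog = load_reference_catalog({"SQ": [{"SN": "Chr1", "LN": 100_000}]})
        crit = FilterCriteria()
        return [(r, evaluate_read(r, crit, catalog)) for r in reads]

    def test_peaks_covering_everything_give_one(self):
        reads = [make_read(start=s, end=s + 50) for s in range(0, 5000, 100)]
        peaks = RegionSet("peaks", [("Chr1", 0, 100_000, ".")])
        assert frip(self._verdicts(reads), peaks) == 1.0

    def test_disjoint_peaks_give_zero(self):
        reads = [make_read(start=s, end=s + 50) for s in range(0, 5000, 100)]
        peaks = RegionSet("peaks", [("Chr1", 90_000, 95_000, ".")])
        assert frip(self._verdicts(reads), peaks) == 0.0

    def test_no_passing_reads_returns_null(self):
        reads = [make_read(duplicate=True)]
        peaks = RegionSet("peaks", [("Chr1", 0, 1000, ".")])
        with pytest.warns(UserWarning, match="zero passing"):
            assert frip(self._verdicts(reads), peaks) is None

    def test_monotone_in_growing_peaks(self):
        reads = [make_read(start=s, end=s + 50) for s in range(0, 5000, 100)]
        v = self._verdicts(reads)
        small = RegionSet("p", [("Chr1", 0, 1000, ".")])
        large = RegionSet("p", [("Chr1", 0, 1000, "."), ("Chr1", 2000, 3000, ".")])
        assert frip(v, small) <= frip(v, large)
        assert 0.0 <= frip(v, small) <= 1.0


class TestFootprint:
    def test_single_fragment_two_insertion_events(self):
        sites = RegionSet("tfbs", [("Chr1", 4990, 5011, ".")])  # center 5000
        # plus mate: 5' at start, +4 -> 4990 ; minus mate: 5' at end-1, -5 -> 5010
        reads = [
            make_read(start=4986, end=5040, strand="+"),
            make_read(start=4960, end=5016, strand="-", reverse=True,
                      template_length=-56),
        ]
        prof = footprint_profile(reads, sites, radius=20)
        assert prof.values[20 - 10] == 1.0  # -10 relative to center
        assert prof.values[20 + 10] == 1.0  # +10 relative to center
        assert prof.values.sum() == 2.0

    def test_strand_neutrality_for_symmetric_input(self):
        intervals = [make_read(start=s, end=s + 60, strand="+") for s in range(4800, 5200, 10)]
        plus_sites = RegionSet("t", [("Chr1", 5000, 5001, "+")])
        unstranded = RegionSet("t", [("Chr1", 5000, 5001, ".")])
        p1 = footprint_profile(intervals, plus_sites, radius=50)
        p2 = footprint_profile(intervals, unstranded, radius=50)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_protected_site_shows_central_trough(self, fixtures):
        fx = fixtures["footprint"]
        crit = FilterCriteria(footprint=True, tn5_shift=True, resize=1)
        report = run_qc(fx.bam, criteria=crit, footprint_sites=fx.anchors,
                        footprint_radius=60)
        values = np.asarray(report.footprint["values"])
        center = values[60 - 10 : 60 + 11]
        shoulders = np.concatenate([values[:40], values[-40:]])
        assert center.max() == 0.0
        assert shoulders.mean() > 0.05


class TestFragmentPeriodicity:
    def test_pure_sinusoid_recovers_helical_pitch(self):
        lengths = np.arange(300)
        hist = 1000 * (1 + 0.3 * np.cos(2 * np.pi * lengths / 10.5))
        assert fragment_periodicity(hist) == pytest.approx(10.5, abs=0.2)

    def test_flat_histogram_has_no_dominant_period(self):
        hist = np.full(300, 500.0)
        assert fragment_periodicity(hist) is None

    def test_insufficient_mass_returns_null_with_warning(self):
        hist = np.zeros(300)
        hist[100] = 10
        with pytest.warns(UserWarning, match="periodicity undefined"):
            assert fragment_periodicity(hist) is None

    def test_parameter_recovery_from_sampled_lengths(self):
        rng = np.random.default_rng(99)
        model = nucleosomal_length_model(period=12.0, amplitude=0.3)
        lengths = sample_fragment_lengths(1_000_000, model, rng)
        hist = np.bincount(lengths)
        assert fragment_periodicity(hist) == pytest.approx(12.0, abs=0.2)


class TestGridSearch:
    def test_single_cell_grid_matches_standard_run(self, grid_fixture):
        fx = grid_fixture
        with pysam.AlignmentFile(str(fx.bam)) as af:
            catalog = load_reference_catalog(af.header)
        res = parameter_grid_search(fx.bam, ([20], [30], [200]), fx.anchors, catalog)
        assert len(res) == 1
        row = res.rows[0]
        report = run_qc(
            fx.bam,
            criteria=FilterCriteria(min_mapq=20, min_fragment=30, max_fragment=200),
            tss=fx.anchors,
        )
        assert row["passing"] == report.passing_total
        assert row["tes"] == pytest.approx(report.tes)

    def test_invalid_combinations_skipped_with_warning(self, grid_fixture):
        fx = grid_fixture
        with pysam.AlignmentFile(str(fx.bam)) as af:
            catalog = load_reference_catalog(af.header)
        with pytest.warns(UserWarning, match="skipping"):
            res = parameter_grid_search(
                fx.bam, ([0], [100, 200], [150]), fx.anchors, catalog
            )
        assert len(res) == 1  # (100, 150) kept, (200, 150) dropped

    def test_passing_counts_monotone_in_mapq(self, grid_fixture):
        fx = grid_fixture
        with pysam.AlignmentFile(str(fx.bam)) as af:
            catalog = load_reference_catalog(af.header)
        res = parameter_grid_search(fx.bam, ([0, 10, 20, 30, 40], [10], [250]),
                                    fx.anchors, catalog)
        passing = [r["passing"] for r in res.rows]
        assert passing == sorted(passing, reverse=True)
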