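# Methods

## Model of the data

`atacqc` treats an ATAC-seq sample as a coordinate-sorted stream of
alignments over a reference catalog in which every sequence belongs to
exactly one of three origin categories: nuclear, mitochondrial, or plastid.
Categories are assigned by case-folded exact name matching against user
lists (defaults: `chrM`, `MT`, `ChrM`, `mitochondria` and `chrC`, `Pt`,
`ChrC`, `chloroplast`); a category may hold zero or many sequences, which
supports incomplete assemblies with several organellar scaffolds. A listed
name missing from the header is a warning, not an error, so one name list
can serve many assemblies.

All coordinates are 0-based half-open internally (BAM and BED native);
1-based samtools-style strings appear only at the CLI boundary.

## Filtering

Checks run in a fixed order — unmapped, secondary, supplementary, QC-fail,
duplicate, proper pair, MAPQ, fragment bounds, organellar origin,
target/blacklist — and every applicable failure reason is recorded rather
than short-circuited, so reason tallies are complete. A read passes iff it
collects no reason. Decisions that were genuinely open and how they were
settled:

* **Duplicates** are recognized solely via the SAM duplicate flag (0x400);
  no internal duplicate detection is attempted — upstream markers own that.
* **Region semantics**: a read is on-target / blacklisted if its alignment
  interval overlaps the region set by ≥ 1 bp (any-overlap), matching what
  index-based region queries return.
* **Single-end data**: proper-pair and fragment-length filters are skipped
  (not failed) and fragment statistics are reported as unavailable.
* **`--use-all`** forces every filter off: any mapped primary
  non-supplementary read passes; the origin category is still recorded.
* **Presets**: `nfr` caps fragments at 120 bp and `mono` brackets 150–250
  bp. These thresholds are this package's choice of the conventional
  sub-nucleosomal / mononucleosomal boundary (the two populations separate
  between ~120 and ~150 bp). `chip` disables the Tn5 shift and 5′ resizing
  and anchors the pileup at peaks; `footprint` forces single-base shifted
  insertion counting. Explicit user flags always override preset values.

Fragment length is |TLEN| of a properly paired read and is undefined
otherwise; histograms count each fragment once via the positive-TLEN mate.

## Streaming accumulators

One pass maintains per-category counters for every read and, for passing
reads only: fragment-length, alignment-length, MAPQ and GC-percent
histograms, plus genome-wide depth from +1/−1 events at alignment
starts/ends, swept per reference when the stream leaves it. Memory is
bounded by the active event buffer, never by genome length. Numerical
conventions:

* Depth uses the full alignment footprint, not the 5′-resized interval:
  depth describes sequencing evidence; resizing is a signal transform
  applied only to pileups and footprints.
* The fragment histogram is capped at 2000 bp (overflow pools in a final
  bin) to bound memory.
* Summary statistics come from histograms alone; the median uses the
  lower-bin convention for even masses (deterministic). Empty histograms
  report null statistics.
* Depth statistics and the coverage fraction use the effective genome:
  nuclear length by default, minus merged blacklist span when a blacklist
  is supplied, or the merged target span under region restriction. Mean
  depth therefore includes depth-0 bases. Read footprints extending past a
  target boundary still count their bases, so coverage of a tight target
  can slightly exceed 1; this is reported as-is.
* Category percentages use total streamed reads as denominator; read-type
  percentages use mapped reads. Both denominators are stated in the report.

## Signal analytics

**5′ resizing and Tn5 shift.** The 5′ end is `start` (+ strand) or
`end − 1` (− strand); the Tn5 transposition offset shifts it +4 / −5
(configurable), placing the coordinate at the center of the 9-bp staggered
nick. The effective interval is a window of width `resize` centered on the
shifted base, left-biased by one base for even widths, clipped to the
reference. `resize` defaults to 100 bp for TSS pileups — wide enough for a
stable profile at moderate depth, narrow relative to the 1000 bp default
window. Footprinting forces 1 bp.

**Pileups.** Anchors are single bases: BED start for + intervals, end−1
for −, the midpoint for unstranded ones. Minus-strand anchors flip the
local axis so downstream is always right. The profile is total interval-
base coverage per relative position divided by the number of anchors, so
profile mass × anchors equals total event mass (conservation).

**TES.** The profile is smoothed with a 25-bp centered moving average
(edge-corrected) and its maximum is divided by the background, the mean of
the outer 10% of positions on each side. Both knobs are configurable and
echoed in the JSON. A constant profile scores exactly 1; zero background
yields null. This definition is internal to the package: it is scale-
invariant and needs no external normalization.

**FRiP** counts passing reads whose unresized alignment overlaps any peak
by ≥ 1 bp, over all passing reads; null when nothing passes.

**Footprints.** Every passing read contributes the single shifted base of
its own 5′ end, so a proper pair contributes two insertion events.

**Periodicity.** Within 40–250 bp the histogram is divided by a 21-bp
centered moving average and recentered, then the zero-padded (2¹⁵-point)
power spectrum is searched in the 5–20 bp period band. The peak is refined
by quadratic interpolation and reported only if its power exceeds 10× the
median band power; otherwise the estimate is null ("no dominant
periodicity"), which is the expected outcome for free-DNA libraries. The
estimator needs ≥ 1000 fragments in range.

**Grid search.** Because a read's verdict under one (MAPQ, fragment)
combination is independent of the others, a single pass carries one
passing counter and one pileup per combination; a boolean mask per read
updates all of them. Results are bit-identical to running the full
pipeline once per combination (asserted in tests).

## Synthetic data generator

Fixtures are fully specified by a `SyntheticSpec`: genome (names, lengths,
categories), fragment count, per-category composition, a mixture of read
classes (each with weight, length distribution, MAPQ range, and uniform or
TSS-anchored placement), duplicate/secondary/improper rates, optional
insertion-protection radius around sites, read length, GC content, and a
seed. Identical spec + seed give byte-identical BAMs. Fragment-length
modulation multiplies the base density by `1 + a·cos(2πL/p)` via rejection
sampling, which leaves an analytically known spectral peak at `p` — the
same mechanism believed to produce the ~10.5 bp helical-pitch ripple in
real nucleosome-associated fragments.

What the generator emulates: organellar contamination, nucleosome-free and
mononucleosomal fragment populations, helical-pitch modulation, MAPQ-
stratified mapping noise, free-DNA background, TF-protected footprints,
flag-only duplicates and secondaries. What it does not: sequencing errors,
base-quality structure, alignment ambiguity, real duplicate towers, GC
bias coupled to position, or chromatin-state heterogeneity. Passing tests
on these fixtures therefore validate the bookkeeping, the estimators and
their invariants — not robustness to every artifact of real libraries.

Preset study conditions (sizes chosen to keep the default suite fast while
leaving estimators well inside their operating range):

* `clean` — 20k fragments, 85/10/5% nuclear/mito/plastid; 55% NFR
  (uniform 50–130 bp) + 30% mononucleosomal (normal 160±55, 10.5 bp
  modulation at amplitude 0.35), both TSS-anchored; 15% uniform
  background; 5% duplicates.
* `free-dna` — one uniform 50–300 bp class placed uniformly: low TES, no
  periodicity.
* `organellar-heavy` — 35/50/15% composition.
* `footprint` — 30k fragments on one 100-kb sequence, insertions rejected
  within ±10 bp of 40 site centers.
* `grid` — 81% NFR signal (50–140 bp, MAPQ 40–60, anchored), 4% low-MAPQ
  noise (MAPQ 0–39, uniform), 15% long-fragment noise (160–400 bp,
  uniform): raising the MAPQ cutoff removes only the low-MAPQ class
  (< 5% of reads) and tightening the fragment ceiling toward 150 bp
  strips the long noise.

The one-million-fragment periodicity check uses the nucleosomal mixture at
amplitude 0.3 and runs in under a second.

## Reporting

The JSON document (schema version 1.0) is the superset of the text report;
nullable analytics are explicit nulls, numbers are serialized at full
precision, and two runs with identical inputs differ only in the timestamp.
A structural validator runs on write and on read; readers tolerate unknown
fields. `merge_reports` flattens several documents into a long scalar table
plus histograms/pileups padded to common support, ready for plotting.
The filtered BAM preserves all original fields and tags verbatim and
appends one @PG header line with the tool name, version and command line.

## Known limitations

* CRAM input, duplicate *marking*, peak calling and plot rendering are out
  of scope; `--threads` is accepted for compatibility but execution is
  serial.
* The TES formula, the NFR/mono preset thresholds, and the periodicity
  prominence rule are this package's own documented conventions; other QC
  tools define these quantities differently, so absolute values should be
  compared only within one tool.
* Depth near target-region boundaries counts whole read footprints (see
  above).
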