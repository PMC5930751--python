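# Methods

## Coordinates and data model

All coordinates are internally 0-based half-open (BED convention); GTF
input (1-based inclusive) is converted on read and never stored. A
transcript's TSS is `start` on the plus strand and `end − 1` on the
minus strand. A bidirectional pair is an ordered (minus-strand,
plus-strand) transcript pair on one chromosome with
`0 < tss_plus − tss_minus ≤ 1000`; both TSSs coinciding, or the plus TSS
lying left of the minus TSS, counts as overlapping/convergent and is
never a pair.

Three rules of pair discovery deserve spelling out:

* **Isoform expansion.** Every isoform combination of two genes that
  independently meets the definition is its own pair; downstream
  classification is therefore per transcript, not per gene.
* **Gene-level overlap removal.** If *any* isoform combination of a
  candidate gene pair has `distance ≤ 0`, the entire gene pair is
  dropped: such genes may be driven by two independent promoters inside
  the partner's gene body rather than by one shared element.
* **The distance bound is inclusive at 1000 bp.** The six
  nucleosome-unit bins (`bin = ⌈d/170⌉`) partition 1..1000 into classes
  of size 170, 170, 170, 170, 170, 150; the printed bin edges overlap
  (1–170, 170–340, …) and the ceiling rule resolves a boundary distance
  into the lower bin.

Duplicate pairs — identical `(chrom, tss_minus, tss_plus)` from distinct
transcript ids — collapse to one entry, and discovery output is sorted,
so results are independent of input ordering.

## Expression classes

With per-transcript TPMs `(m, p)` for the minus/plus members:
both below 1 TPM → *symmetric silent*; otherwise the ratio
`max / max(min, 0.1)` decides: strictly greater than 2 → *asymmetric*
(high side = the larger TPM's strand), else *symmetric expressed*.
Choices made where the rules underdetermine behaviour:

* the 0.1 TPM denominator floor makes a (50, 0) pair asymmetric rather
  than undefined; it is configurable and only matters below the silent
  threshold;
* a mixed pair (one TPM < 1, one ≥ 1, ratio ≤ 2, e.g. 1.5 vs 0.9) falls
  to the ratio rule — the silent rule requires *both* members low;
* the 2-fold boundary is strict: a ratio of exactly 2 is symmetric;
* silent pairs are excluded from the side-sum t-tests but kept as the
  "silent" meta-profile category, so the profile figures and the
  statistics stay mutually consistent;
* the unidirectional control set is range-matched (TPM inside the
  [min, max] envelope of pair members), not distribution-matched, and
  sampled uniformly without replacement under an explicit seed.

## Frames, windows, signal mapping

Each pair's frame is `[mid − 2000, mid + 2000)` around the intergenic
midpoint; for odd distances 1 is added before halving, so the midpoint
rounds toward the plus TSS. Frames are chopped into 170 bp sub-windows
whose starts advance by 75 bp — `1 + ⌊(4000 − 170)/75⌋ = 52` per frame —
and offsets are reported at sub-window start relative to the midpoint.
Frames that would cross a chromosome end are dropped, not clipped, so
every aggregated frame has identical layout. Frames are never
strand-flipped: the categories already encode direction.

`map_mean` is the *base-weighted* mean over all bases of a window, with
uncovered bases contributing 0. (Element-wise averaging of overlapping
bedgraph records would change with how a constant region is split into
records; the base-weighted mean is invariant to record fragmentation.)
Meta-profiles sum the per-window means across the pairs of a category
and divide the vector by its own maximum — values are relative within a
category and not comparable across marks or categories.

Per-side cumulative enrichment sums track values inside peaks with
q < 0.05, clipped to the frame, separately over `[frame.start, mid)` and
`[mid, frame.end)`. A peak interval straddling the midpoint is discarded
from *both* sides: the reference point cannot attribute it to one gene
without double counting. A consequence worth knowing: at short
intergenic distances the initiation-mark peaks of the two TSSs merge
into one interval across the midpoint and are discarded, so promoter
marks carry little side-sum information for close pairs *by
construction*; the side-sum statistics are therefore evaluated on an
elongation (gene-body) mark, whose peaks never reach the midpoint.

## Statistics

Group comparisons use a two-sided unpaired t-test; Welch's
unequal-variance form is the default (the safer choice when group
spreads differ), with Student's form selectable. Two completely
degenerate identical groups return t = 0, p = 1. For asymmetric pairs
the groups are the per-pair sums on the high- vs low-expressed side
(`High_exp` / `Low_exp`); for symmetric expressed pairs, left vs right
of the midpoint (`Similar_left` / `Similar_right`). No multiple-testing
correction is applied across marks or cell types. Note the symmetric
comparison treats per-pair left/right values as two independent samples;
when pair-level properties (shared expression level, shared intergenic
distance) influence both sides, the unpaired test is conservative — see
the calibration note below.

## ChIP-qPCR arithmetic

`percent_input` implements the recovery formula exactly as published:
`2^((Ct_input − log2 x) − Ct_ChIP) × 100` for an x% input aliquot. This
differs from the common dilution-adjusted convention (subtracting
`log2(100/x)` instead), under which equal Cts with a 1% aliquot mean 1%
recovery rather than 100%; that variant is available behind
`convention="dilution_adjusted"`. Occupancy is the ratio of specific to
background recovery, and expression fold change is `2^−ΔΔCt`.

## Synthetic-data generator

Gene loci are laid out 45 kb apart on one synthetic chromosome: pair i
gets its minus TSS at `margin + i·spacing` and its plus TSS `d` bp to
the right, with `d` drawn from the six-bin mixture weighted
453:245:120:78:44:34 (the reference genome-wide bin occupancies of 974
pairs); unidirectional control genes (random strand) follow. Gene
lengths are uniform on 2–20 kb so elongation marks extend beyond the
4 kb frame, as in real data. One isoform per gene is generated, so the
discovery round trip is exact.

Designed classes (default mix 319:65:590 over asymmetric / symmetric
expressed / silent, the proportions of the reference embryonic-stem-cell
analysis) are realized with construction margins so the classifier must
recover every label: asymmetric ratios ≥ 1.5 × `asym_fold` (default
`asym_fold` = 3, hence ratios ≥ 4.5 ≫ 2) with the low member ≥ 1.5 TPM;
silent TPMs ≤ 0.5; symmetric expressed members ≥ 2 TPM with within-pair
ratio ≤ 1.3.

Signal model per mark, on top of a flat background (default 1.0, the
natural baseline of a fold-enrichment track): each transcript with
TPM ≥ 1 adds `amplitude_per_log_tpm · log2(1 + TPM)` times a shape —

* *initiation*: a Gaussian bump centered 100 bp downstream of the TSS in
  the direction of transcription, sd 130 bp. The width was chosen so
  that the symmetric category's aggregated profile is genuinely bimodal
  under the default distance mixture: two mirrored bumps at
  ±(d/2 + 100) merge into one mode when the sd approaches half their
  separation, and with ~46% of pairs closer than 170 bp an sd much above
  ~150 bp washes the central dip out entirely (numerically, sd 130 keeps
  the dip in ≈100% of replicate studies at realistic category sizes,
  sd 150 in ~95%, sd 200 in none);
* *elongation*: a plateau over the gene body from 500 bp downstream of
  the TSS to the transcript end, rasterized by bin centers so the
  painted region is exactly mirror-symmetric between strands regardless
  of bin phase (an end-rounding asymmetry of even one 10 bp bin is
  comparable to the noise scale of a side sum and would bias the
  left/right comparison).

Tracks are generated at 10 bp resolution; seeded Gaussian noise
(sd 0.25) is added only within the simulated loci (elsewhere the track
is exactly background, keeping files compact), values are clipped at 0
and run-length encoded into bedgraph records. Peaks are the contiguous
regions where the *noiseless* signal exceeds `background × peak_fold`
(default 2), emitted with q = 0.01 — deriving peaks from the noiseless
signal keeps recovery tests deterministic; noise affects only the track
values. All stages draw from per-stage, per-mark substreams of the
config seed; identical configs give byte-identical output files.

### The symmetric null used for calibration

The type-I check of the symmetric left/right comparison uses a dedicated
null configuration: all pairs symmetric expressed, a single base
expression level (`tpm_sdlog = 0`, with independent per-side jitter up
to ratio 1.3), and one fixed, bin-aligned intergenic distance (120 bp).
Under the generator's *default* mixture, left and right sums share
pair-level structure — the common expression level and the common
distance move both sides together — so the unpaired test is conservative
there (rejection well below nominal); with the homogeneous null the two
samples are genuinely iid and the test's size can be measured. This
mirrors the statistical fact rather than hiding it: on heterogeneous
data the published unpaired design under-rejects, never over-rejects.

### What the generator does not emulate

Real fragment-level coverage and its autocorrelation, mappability and
GC structure, replicate variability, multi-isoform genes, overlapping
neighboring loci, sequence features of bidirectional promoters (CpG
islands, TATA depletion), and any cell-type differences. Passing
recovery tests therefore shows the *pipeline arithmetic* is right under
the designed signal model, not that the biological conclusions would
survive real-data noise.

## Problem sizes used by the tests and the acceptance script

Pair-discovery oracle equivalence: 50 random transcript sets of ≤ 200;
signal-mapping oracle: 100 random track/frame instances (tolerance
1e-9); parameter recovery: one 300-pair study (two marks); calibration:
1000 null replicates of 40 symmetric pairs; power: 200 replicates of 100
asymmetric pairs; determinism: the full 5-stage pipeline twice at 30
pairs. These sizes were chosen as the smallest that make the stochastic
checks stable across seeds.

## Known limitations

* Table-scale genome-wide counts (1070 pre-filter pairs, 974 final, 453
  in bin 1) depend on a specific external pair list and assembly and are
  not reproduced; the generator only matches their *proportions*.
* The meta-profile aggregation sums per-window means across pairs; if
  the original aggregation summed raw per-base signal first, profiles
  would differ by a constant factor per window (max-normalization
  removes most, but not all, of the difference for partially covered
  windows).
* `percent_input`'s published formula is kept verbatim even though its
  dilution handling is unconventional; use the explicit flag for the
  standard convention.
* The "discard straddling peaks" rule interprets "overlapping …
  discarded" at the peak-interval level; a read-level interpretation is
  not representable from bedgraph/narrowPeak inputs.
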