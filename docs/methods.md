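# Methods

## The detection principle

Under standard Illumina chemistry a G-quadruplex folds transiently in a
fraction of the template molecules of a cluster. The stalled molecules
dephase from the rest of the cluster, and the dephasing noise lowers the
base-quality estimates of every subsequent cycle — the base calls
themselves remain correct. On the reference, this appears as a dip in the
per-locus **median** Phred score of the reads of the motif strand,
beginning at the structure's 5′ start and decaying over roughly a read
length (reads that start downstream of the motif start are unaffected, so
the dropped fraction of reads covering a locus shrinks linearly with
distance).

All downstream machinery rests on that median track:

* **Tracks.** For each contig and strand, the median Phred score of all
  aligned (match/mismatch) bases at each locus. Reads are assigned to
  strands by FLAG bit 0x10; secondary and supplementary alignments are
  skipped; soft-clipped, inserted and deleted positions contribute
  nothing. The median of an even count is the lower of the two middle
  values, which keeps the track integer and deterministic. Loci covered by
  fewer than `d_min` reads (default 10) are masked *no-data* and take part
  in neither transitions nor window counts.

* **Scanner.** Scanning proceeds 5′→3′ in the strand's own orientation
  (decreasing coordinates on the minus strand). For each adjacent defined
  pair whose medians differ by at least *M*, the higher base is the *flag
  site* (its value the *flag value*) and the lower base the *start site*.
  A locus in the 75-nt window from the start site is *low-quality* iff
  `flag_value − median ≥ M`; with at least *N* such loci the window is a
  hit. A window truncated by the contig end counts over the available loci
  and still requires the full *N*. Upward transitions also define a start
  site at the (earlier) lower base; in practice only downward transitions
  yield hits.

* **Regions.** Each hit spans its window plus a 35-nt upstream extension
  (the longest canonical G4, so a motif whose start lies upstream of the
  first detectable transition is still covered). Overlapping regions merge;
  merged regions whose G/C content passes the threshold become MG4s and are
  classified by the family grammar below.

## Calibration

Positive regions are 75-nt windows starting 12 nt (the approximate DNA
polymerase footprint) upstream of each predicted canonical motif start, in
strand orientation. After excluding positives ± 300 nt, the remainder is
tiled into 75-nt negative windows. For every (*M*, *N*) in 1–12 × 1–20 the
positive rate and the false-positive rate (on negatives passing the
guanine filter) are measured; the chosen cell maximises the positive rate
subject to FPR < 1%, with ties broken by lower FPR, then higher *M*, then
higher *N*. A region counts as hit iff some hit's start site lies inside
it (scanning the whole track, so transitions at region edges are not
lost). Calibration fails loudly when no admissible cell detects any
positive region. The tie-break matters: when the positive rate saturates,
it walks to the most conservative admissible corner, which is what keeps
the genome-wide false-discovery rate near zero.

### Guanine filter

The Results and Methods of the source literature describe the content
filter in two ways — guanine only, or the G/C ratio. Both are implemented
(`g_mode="G"` evaluates G on the scanned strand, `"GC"` evaluates G+C).
The pipeline default is `GC`: C-rich regions (i-motif faces) demonstrably
survive the published filter into the "other" category, which is only
possible under a G+C reading, and a strand-G filter at 28% deletes real
calls whose 110-nt regions are diluted by flanking sequence. The
per-genome threshold (`g_threshold`) is the nearest-rank 1st percentile of
positive-region content, so 99% of motif-positive segments exceed it; with
fewer than 100 positive regions it falls back to the 0.28 default.

## Structural families

Hierarchy, most stable first; a sequence joins the first family whose
pattern occurs anywhere in it:

1. canonical `(G{3,}N{1,7}){3}G{3,}` (N = any base);
2. long loops — one to three loops of 8–12 nt in the five printed
   arrangements (LSS, SLS, LLS, LSL, LLL);
3. bulges — four tracts with 1–7 nt loops where either exactly one tract
   is `G H{1,7} GG` (H = A/T/C) or two or more tracts are `G H{1,2} GG`;
4. two tracts `(G{2}N{1,12}){3}G{2}`;
5. other — screened, in order, for i-motifs `(C{3,}N{1,7}){3}C{3,}`,
   hairpins (a ≥ 7-bp stem whose exact reverse complement recurs within a
   30-nt loop; existence of any ≥ 7 stem is equivalent to existence of a
   7-mer stem, so the search is exhaustive), and poly-A/T runs ≥ 10 nt.

Motif **prediction** reports maximal matches: for each G-run start the
longest grammar parse is found by memoised search over tract/loop splits,
and overlapping candidate intervals merge into one reported motif
(touching intervals stay separate). N bases never match any pattern
position. The property suite checks this against a brute-force oracle that
enumerates and full-matches every substring.

## The simulator

`simulate.SimConfig` holds the study conditions. Defaults: a 200-kb
single-contig genome of i.i.d. bases at 50% GC; 24 canonical, 2 long-loop,
2 bulged, 2 two-tract implants (drop-bearing), plus 2 i-motifs, 2 poly-A/T
runs and 2 G-rich shuffled null loci (not drop-bearing); implants ≥ 500 nt
apart, each padded by 8 non-G bases so flanking sequence can never extend
a motif. Any canonical motif arising in the background is added to the
truth as drop-bearing, keeping the predicted-motif set and the drop model
consistent (an i-motif implant's complementary face is such a motif).

Reads are single-end error-free 150-mers (CIGAR all-match, FLAG 0/16),
uniform starts, both strands at `depth` per strand (default 30×). Each
read draws a quality level `Normal(37, 2)` held along the read plus
per-base noise `Normal(0, 0.5)`, rounded and clipped to [2, 41] — the
read-to-read component dominates, as in real Illumina data, which is what
makes the median track smooth under the null. A read on a drop-bearing
feature's strand whose span includes the feature's strand-oriented start
is, with probability `p_fold`, reduced by `delta` (default 6) from that
locus to the end of the read; `drop_span` optionally limits the dropped
stretch. Heterozygous loci implant a canonical motif whose final tract is
broken in the reference; each read covering the SNV draws its allele
(binomial, fraction 0.5), and only alternate-allele reads on the motif
strand can fold. Everything is deterministic under the config seed.

### The fold-rate regime — what passing tests do and do not show

For a per-read Bernoulli drop model, the per-locus median of a mixture
with dropped fraction *f* shifts by the `(0.5 − f)/(1 − f)` quantile gap
of the clean read-level distribution. For *f* > 0.5 the median flips
essentially by the full `delta`; for *f* < 0.5 the shift is a fraction of
the read-level spread (≈ 0.57 σ at *f* = 0.3) while the median's sampling
wander is ≈ 1.25 σ/√depth, correlated over a read length — the separation
is ≈ 0.45 √depth standard units *independent of the quality spread*, about
2.5 at 30×. A median statistic therefore cannot reach high sensitivity at
sub-percent false-positive rates in the minority-fold regime at this
depth; the simulation studies and tests that demonstrate full recovery
run at `p_fold = 0.8` (0.9 for the allele-split study, the strong
allele-specific-folder scenario), chosen so the *realized* per-feature
fold fraction exceeds ½ with probability ≈ 0.999 at 30 reads. The
`p_fold = 0.3` condition is also exercised and reported; its low recall is
a property of the median statistic, not of the implementation. Passing
tests show the machinery is correct and calibrated in the regime where
the signal exists; they do not show that 30× suffices for weakly folding
structures in real data.

Scanner parameters transfer across depth imperfectly: the clean-to-drop
median step shrinks by about one Phred unit when track depth halves
(order-statistic positioning), so parameters calibrated on full-depth
tracks overshoot *M* for half-depth allele groups. The allele-split study
therefore uses a fixed `(M=3, N=10)` satisfying `delta ≥ M` and
`drop span ≥ N`, and conditions its accuracy claim on the realized
per-allele motif-strand depth ≥ 15, mirroring its stated precondition.

## Other numerical choices

* Even-count medians take the lower middle; percentiles use nearest rank;
  densities and percentages round only at presentation (2 decimals).
* Interval semantics everywhere: 0-based half-open, plus-strand BED
  coordinates; overlap means ≥ 1 shared bp on the same strand (region
  annotation ignores strand by default, since gene regions are stranded
  but mined G4s come from both strands); merging joins strictly
  overlapping intervals, touching intervals stay separate.
* Motif deltas under genome editing match by identical interval
  (contig, start, end, strand): a shifted motif counts as one loss plus
  one gain rather than silently neither.
* Allele groups keep only reads with an aligned base at the variant;
  third-allele reads are discarded with a log message; a group below
  `r_min` (default 10) reads is *insufficient*. Local tracks span the
  variant ± (window + extension) = ± 110 nt.
* Duplicate reads are counted as-is; mapping quality is filterable but
  unfiltered by default; mate information is ignored (only FLAG 0x10
  determines strand).

## Known limitations

* Sensitivity at minority fold rates is bounded by the median statistic
  (see above); a rank-based lower-quantile statistic would detect
  sub-majority folding but is deliberately out of scope.
* The flag-anchored window count treats a transient upward blip of the
  median as a full low-quality window (the flag sits above the level);
  calibration absorbs this by raising *M*, at a sensitivity cost when the
  quality spread is large.
* The simulator's reads are error-free and single-end with idealised
  uniform coverage; real-data effects — mapping bias, duplicates, indels,
  coverage waves, quality binning — are not modelled, so measured
  recall/FDR are upper bounds on real-data performance.
* Genome-scale counts (hundreds of thousands of calls on a mammalian
  genome at 45×/strand) are out of desk scale and are not reproduced;
  the per-species density and detection-rate arithmetic is validated on
  the published counts instead.
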