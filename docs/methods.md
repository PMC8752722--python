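# Methods

## Pipeline model

A junction read is assumed to have the structure
`barcode · transposon-end · genomic flank`, with the flank starting at the
first genomic base 3′ of the vector terminus on the read's strand. The
insertion point is reported as the 0-based coordinate of that first
genomic base: the leftmost matched base for a + alignment, the rightmost
for a −. All interval arithmetic is 0-based half-open (BED convention);
1-based coordinates appear only in external SAM input, converted on
ingest.

Trimming requires an exact barcode prefix followed by an exact
transposon-end match; quality scores are ignored. No mismatch tolerance
is applied because junction chemistry places these sequences at fixed
offsets and an unmatched prefix is more often a library artifact than a
sequencing error; reads rejected at this stage are counted per category
(`no_barcode`, `no_junction`, `too_short`) rather than silently dropped.

The reference mapper performs exact full-length search of the fragment on
both strands and accepts only fragments with exactly one genome-wide hit
(`ambiguous` otherwise). Exact matching is sufficient for the synthetic
genomes this package generates and keeps the mapper verifiable against a
brute-force scan; mismatch-tolerant alignment of real reads against
GRCh38 is deliberately delegated to an external aligner whose SAM/BED
output enters via `load_alignments`. Aligner mode (local vs end-to-end)
and MAPQ filtering are therefore the caller's choice, not assumed here.

### Minimum fragment length

The default minimum genomic-fragment length is 25 nt, the value at which
randomly generated fragments with empirically matched lengths stop
mapping to a human-scale genome. Because that number is meaningless for a
kilobase-scale synthetic genome, `calibrate_min_length` recomputes it:
for each candidate length L (ascending over the observed length profile)
it draws `n_random` uniform-base fragments with lengths from the profile
conditioned on ≥ L and returns the smallest L with zero hits (unique or
ambiguous both count as a hit). Each candidate's RNG is seeded from
`(seed, L)` so the winning draw is exactly reproducible. If no candidate
reaches zero hits the calibration fails loudly, carrying the per-length
hit counts.

### Clustering

Positions within a chromosome are grouped by single-linkage chaining with
gap ≤ tolerance (default 1 nt, absorbing ±1-nt sequencing jitter). The
pairwise ±1 rule admits several closures; chaining is the only one that
is independent of read order, so `[100, 101, 102]` is one event. The
representative position is the modal member position (ties to the smaller
coordinate), and clustering is strand-collapsed: an insertion is a locus
property, and junction reads from either end of the cargo may map to
either strand. Clone frequency is read count over total read count —
fragment-length (sonic) abundance correction is out of scope. Outgrowth
statistics report the top-1 and cumulative top-k (default k = 10)
frequencies.

### Genomic context, TSS distance, random control, motif

Each unique event — not each read — is classified once at its
representative position, with precedence exon > transcript: inside any
exon ⇒ `exon_transcript`; else inside any transcript span ⇒
`nonexon_transcript`; else `non_transcript`. Coding vs non-coding exons
are not distinguished (a documented extension point). TSS distance is
unsigned and restricted to the event's chromosome; TSS is `tx_start` (+)
or `tx_end − 1` (−). Events on chromosomes with no transcripts are
excluded from median TSS distance (default policy).

The random control resamples each event's position uniformly on its own
chromosome, keeping per-chromosome event counts and read tallies exactly
— the appropriate null when chromosome-level capture efficiency is part
of the observed data. The motif profile counts A/C/G/T at offsets
[−window, +window) around the insertion point; offset −1/0 are the two
bases flanking the junction, where hAT-family transposons show the TA
target-site preference. Events with truncated or N-containing windows are
excluded so that every column sums to the number of contributing events.

## Synthetic-data generator

The generator emulates exactly the features the analysis is sensitive to:

* **Genome** — i.i.d. bases, default GC 0.41 (human-like); default size
  two chromosomes of 300 kb + 200 kb, chosen so that a 38-nt flank is
  essentially always unique while keeping runs in seconds.
* **Annotation** — non-overlapping gene models, exon count 1 + Poisson(3),
  150-bp exons, 800-bp introns, both strands; with the default 60 genes
  the transcript-bp fraction lands near 0.36, comparable to the
  transcribed fraction of the human genome.
* **Clone abundances** — Dirichlet(concentration/n_clones, …). One knob
  spans even (`concentration → ∞`) to oligoclonal (small values); the
  empirical clone-size distribution of engineered products is not
  published, so the Dirichlet is an explicit stand-in, not a fitted
  model.
* **Site placement** — per-position weight 1, × `motif_weight` when the
  two junction-flanking bases are TA, × `transcript_bias` when inside a
  transcript span; sampling is without replacement from the normalised
  pool. An optional `min_separation` (default 0) additionally keeps sites
  on the same chromosome more than that many bp apart; round-trip
  demonstrations use 2 so that distinct clones are guaranteed resolvable
  under ±1-nt clustering.
* **Reads** — one multinomial(reads_total, abundances) draw assigns reads
  to clones; errors are i.i.d. substitutions over the whole read
  (approximating the dominant Illumina error mode; no indels, so the
  exact-match mapper is honest at error rate 0); qualities are constant
  'I' (Q40) because quality-aware trimming is not modelled.

What the generator does **not** emulate — sonication fragment-length
diversity, UMIs, paired-end structure, hybridization-capture bias, PCR
duplicates, repeat families, real gene architecture — bounds what a
passing test shows: the pipeline's decision logic and statistics are
correct under the stated read model, not that a particular wet-lab
library preparation is bias-free.

## Assay arithmetic

Copies per cell is `2 × target/ref` (fractional abundance against the
two-copy RNase P reference); copies per CAR+ cell divides by the CAR+
fraction, with the convention that a 0% CAR+ sample (transposon-only
control) reports 0 rather than raising. Negative copies/cell inputs —
the signature of background subtraction upstream of this package — pass
through the division untouched. Report rounding is 2 dp half-up;
internal values are never rounded. LDH percent cytotoxicity is reported
raw (it can be negative or exceed 100); the denominator must be positive
(`target_max > target_spont`). Tumor volume is `length × width²/2`,
which is asymmetric in its arguments by construction: width is the
smaller caliper axis, squared as the proxy for both short dimensions.

## Problem sizes and determinism

Default study conditions: 50 clones, 2,000 reads, 500-kb genome, 60
genes; context composition checks use 2,000 placed events and binomial
99% intervals; random-control uniformity uses 10⁴ positions over 20 bins
at α = 0.001; the clustering oracle comparison runs 1,000 random
instances of ≤ 200 sites against an adjacency-matrix connected-components
implementation. Every stochastic step takes an explicit integer seed and
the whole pipeline is byte-deterministic under a fixed configuration;
derived seeds are simple offsets of the run seed so that stages are
independently reproducible.

## Known limitations

* Exact-match mapping cannot process error-bearing reads; those paths are
  exercised only through external alignments.
* Abundance estimation by read tally is biased for clones whose flanks
  are poorly mappable; no mappability correction is applied.
* The three-way context classification ignores CDS/UTR structure and
  overlapping-gene subtleties beyond the exon > transcript precedence.
* Between-method significance testing (transposon vs lentivirus panels)
  is out of scope; `compare_samples` reports descriptive mean ± SD only,
  with SD marked unavailable (not 0) for single-sample groups.
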