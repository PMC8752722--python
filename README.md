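# intsite

Integration-site safety analysis for transposon- and virus-engineered cell
products (e.g. CAR-T cells made with a DNA transposon such as *TcBuster*,
*Sleeping Beauty* or *PiggyBac*, or with a lentiviral vector).

When a therapeutic transgene is integrated semi-randomly into T-cell
genomes, two questions decide the safety profile of the product:

1. **Clonal outgrowth** — is any single engineered clone (one integration
   event) over-represented? Junction reads that map to the same genomic
   position ±1 nt are tallied as one clone; the frequency of the top clone
   and the cumulative frequency of the top 10 clones are the outgrowth
   statistics.
2. **Integration preferences** — do insertions favour transcribed DNA,
   exons, or the neighbourhood of transcription start sites (TSS), all of
   which raise the genotoxicity risk? Each integration event is classified
   as exon / non-exon transcript / non-transcript, its unsigned distance to
   the nearest TSS is measured, and a matched in-silico random control
   (same per-chromosome event counts, uniformly resampled positions)
   provides the null profile. Flanking sequences around each insertion
   point are stacked into a position-frequency matrix to verify motif
   preferences such as the TA target dinucleotide of hAT-family
   transposons.

The package implements the full junction-read pipeline (barcode +
transposon-end trimming with a calibrated minimum fragment length, exact
unique-hit mapping for synthetic genomes, SAM/BED ingest of external
alignments for real data), the clonality and context statistics, and the
companion assay arithmetic used in product characterisation:

* ddPCR vector copy number: `copies/cell = 2 × target_conc / ref_conc`
  (two copies of the RNase P reference per genome), and
  `copies/CAR+ cell = copies/cell ÷ CAR+ fraction`;
* LDH cytotoxicity:
  `% = (experimental − effector_spont − target_spont) / (target_max − target_spont) × 100`;
* caliper tumor volume: `V = length × width² / 2` (mm³).

A seeded synthetic-data generator (genome, transcript models, Dirichlet
clone abundances, biased site placement, junction FASTQ) makes every stage
testable end to end without downloads.

## Worked example

Simulate an oligoclonal sample (50 clones, skewed Dirichlet abundances,
2,000 error-free junction reads) and run the full pipeline:

```python
from intsite import PipelineConfig, SimParams, run_pipeline

config = PipelineConfig(
    mode="simulate", sample_id="demo", out_dir="demo_out", seed=11,
    sim=SimParams(n_clones=50, reads_total=2000, concentration=5.0),
)
summary = run_pipeline(config)
```

which prints (abridged):

```json
{
  "n_reads_in": 2000, "n_accepted": 2000, "n_mapped": 2000, "n_events": 27,
  "clonal": {"top1_freq": 0.307, "topk_cum_freq": 0.8785, "k": 10},
  "context": {
    "fractions": {"exon_transcript": 0.037, "nonexon_transcript": 0.296,
                  "non_transcript": 0.667},
    "median_tss_distance": 4165.0
  }
}
```

Reading the numbers: the funnel kept all 2,000 reads (error-free
simulation), but only 27 of 50 clones were detected — with a strongly
skewed abundance profile (`concentration=5`) the rarest clones draw zero
reads. The top clone holds 30.7% of reads and the top 10 hold 87.9%, a
clearly oligoclonal profile (a polyclonal product shows fractions of a
percent). A third of events fall inside transcripts, close to this
genome's transcript-bp fraction, i.e. no transcript preference was
simulated and none is reported; the median event sits 4.2 kb from the
nearest TSS.

The same pipeline runs from a shell (`intsite run --config cfg.yaml`),
and `intsite simulate`, `intsite compare` and `intsite assays
{ddpcr,ldh,tumor}` cover dataset generation, per-group mean ± SD tables
and the assay arithmetic. Real datasets enter either as FASTQ
(`mode: fastq`) or as external aligner output (`mode: alignments`,
SAM/BED).

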