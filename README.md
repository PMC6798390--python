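# annotcompare

Repertoire-wide comparison of automatically predicted and manually
annotated protein-coding gene models.

Genome projects typically annotate protein-coding genes automatically
(e.g. with a MAKER-style pipeline) and then have a research community
manually curate a small fraction of the models — in the i5k pilot insect
genomes, roughly 3.5–7% of gene models were manually revised and a
further 0.3–2.2% added de novo. Comparative studies of gene *structure*
(lengths, exon counts, GC content) usually have to rely on the automatic
models. This package quantifies what manual annotation actually changes
at the repertoire level, so that such studies can judge whether
automatic gene sets are a sound basis for structural comparisons.

## What it computes

Given a genome FASTA, an automatic annotation (AUTO, GFF3), the official
gene set (OGS, GFF3), and a provenance map linking curated models to
their automatic predecessors (TSV), the pipeline:

1. **Partitions** the models into five (sub)sets: AUTO, OGS, MAN-SUB
   (curated models with a predecessor), AUTO-SUB (their distinct
   predecessors), and MAN-ADD (de novo models), with accounting
   percentages (e.g. MAN-SUB as % of OGS).
2. **Extracts structural properties** per gene from the longest
   transcript (maximal summed exon length): unspliced (pre-mRNA) length
   [bp], protein length [aa], exon count, median exon/intron length per
   transcript [bp], and median exon/intron GC content per transcript
   [%]. Exons stand in for coding sequence (UTRs are assumed
   unannotated, so exons ≡ CDS).
3. **Summarises** each set: set-wide medians (including the "median
   median exon length per transcript"), coding and intronic proportions
   of the assembly (Σ exon / Σ intron bp over assembly size), gene and
   exon counts, and assembly GC content without ambiguity (A/C/G/T
   denominator).
4. **Tests distributions**: two-sample Kolmogorov–Smirnov and
   Mann-Whitney-Wilcoxon tests for every set pair and property, each
   family Bonferroni-corrected; exact permutation p-values at small
   sample sizes, asymptotic otherwise.
5. **Measures correlative trends**: Spearman's rank correlation *r* for
   exon count vs. median exon length/GC and intron count vs. median
   intron length/GC, per set.
6. **Classifies subset representativeness**: the full set is subsampled
   without replacement (default 1000 draws of 1000 models), the Spearman
   coefficients of the draws form an interval (min–max by default), and
   each subset's coefficient is classified `inside`, `outside_low`, or
   `outside_high`.

A synthetic-data module generates genome + AUTO/OGS bundles with known
ground truth — configurable exon-count/length distributions, exon GC
offset, curated fractions produced by realistic curation operators
(boundary shifts, exon gain/loss, merges, splits) and short,
receptor-like de novo models — so the entire pipeline is testable
without external data.

## Worked example

```sh
annotcompare simulate --out sim --seed 7 --n-genes 500 \
    --n-scaffolds 3 --scaffold-length 1000000
annotcompare run --genome sim/genome.fasta --auto sim/auto.gff3 \
    --ogs sim/ogs.gff3 --provenance sim/provenance.tsv \
    --out report --seed 7 --replicates 100 --subsample-size 200
```

prints the partition accounting:

```
 n_auto  n_ogs  n_auto_sub  n_man_sub  n_man_add  n_unchanged  auto_sub_pct_of_auto  man_sub_pct_of_ogs  man_add_pct_of_ogs  man_add_pct_of_handled
    500    505          27         27          5          473                   5.4                 5.3                 1.0                    15.6
```

i.e. 27 of 505 official models (5.3%) are curated revisions of 27
automatic predecessors (5.4% of AUTO), 5 models (1.0%) were added de
novo, and de novo models are 15.6% of everything a curator touched.
`report/` then contains the per-set property tables, `set_summaries.tsv`
(medians, coding proportion 27.0% / intronic proportion 21.8% for AUTO
here), `tests.tsv` (KS/W results with raw and Bonferroni-adjusted
p-values), `correlations.tsv`, and `resampling.tsv` with rows such as

```
OGS  exon_count~median_exon_gc  interval=(-0.120, 0.167)  MAN-SUB r=0.387  outside_high
```

meaning the curated subset's exon-count/GC correlation lies above the
interval spanned by 100 random 200-model subsamples of the OGS — the
curated subset is not structurally representative of the full set for
that property combination.

`annotcompare diff report_a/set_summaries.tsv report_b/set_summaries.tsv`
reports signed per-property median differences (by default MAN-SUB minus
AUTO-SUB — the set-wide effect of manual annotation), and
`annotcompare aggregate` stacks per-species summary tables.

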