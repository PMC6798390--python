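# Methods

## Gene sets and provenance

One analysis run covers one species: a genome assembly, its automatic
protein-coding annotation (AUTO), and the official gene set (OGS) that
resulted from community curation of that annotation. The OGS is
partitioned by curation status into MAN-SUB (curated models with an
automatic predecessor), MAN-ADD (de novo models without one), and
unchanged automatic models; AUTO-SUB is the set of distinct
predecessors of MAN-SUB. Provenance travels as an explicit three-column
TSV (`ogs_id  predecessor(s)|NA  manual|denovo|auto`) rather than as
GFF3 attributes, because attribute conventions for recording curation
history vary between annotation projects. A curated model that merged
several automatic models lists its predecessors comma-separated; a
split yields several rows sharing one predecessor. Each predecessor
enters AUTO-SUB once, so `|MAN-SUB| ≥ |AUTO-SUB|` is possible in both
directions; the identity `|OGS| = |MAN-SUB| + |MAN-ADD| + |unchanged|`
holds on every run. Accounting percentages are reported at one decimal,
rounded half away from zero; unrounded values are kept internally.

## Coordinates and structural properties

GFF3 input is 1-based inclusive; internally all intervals are 0-based
half-open; emitted tables are again 1-based where they carry
coordinates. Every property is computed on the longest transcript per
gene, defined as maximal *summed exon length* (mature coding length,
not genomic span), with the lexicographically smallest transcript id
breaking ties. Exon features are used as the exon list; transcripts
carrying only CDS features adopt those (these annotations have no
consistently annotated UTRs, so exon and CDS intervals coincide); if
both are present and disagree, the CDS intervals win with a warning,
since the analysis concerns coding structure.

Per transcript: unspliced length = genomic span (first exon start to
last exon end); introns are the gaps between consecutive exons; protein
length = floor(summed exon bp / 3). No stop codon is subtracted by
default (`subtract_stop=True` subtracts one residue); the convention is
declared rather than inferred, as descriptive-statistics tools differ
here and the comparison between sets is unaffected by a constant
offset. Feature GC is G+C over unambiguous (A/C/G/T) bases of the
interval, strand-insensitive, and undefined (NA) for all-ambiguous
intervals. Single-exon transcripts have undefined intron medians; NA
values are excluded from set-wide medians and correlations, with
exclusion counts logged — silently zeroing them would bias medians
downward.

Set-wide medians use the even-*n* mean-of-central-values convention
(half-integer medians are meaningful outputs). Coding and intronic
proportions sum raw per-gene (longest-transcript) exon and intron
lengths over assembly size, without merging overlapping genes; assembly
size includes ambiguity, while "GC without ambiguity" divides G+C by
determined (A/C/G/T) length only.

## Distribution tests and correction

Every unordered pair of the five (sub)sets is compared per property
(unspliced length, protein length, exon count, median exon length,
median intron length) with a two-sample KS test (sensitive to shape,
spread, and location) and a two-sample Mann-Whitney-Wilcoxon test
(sensitive mainly to location). Gene-structure data are heavily tied
(integer counts and lengths), so small samples are handled by exact
permutation enumeration over all splits of the pooled sample — the
tie-exact analogue of the classical exact tests — whenever the number of
splits is at most 25 000; larger samples use the asymptotic Kolmogorov
distribution at effective size n₁n₂/(n₁+n₂), and the normal
approximation with tie-corrected variance and continuity correction,
respectively. Two-sided p-values throughout; the exact Wilcoxon p is
2·min(lower, upper) tail, capped at 1. Comparisons where a property is
undefined throughout one set (e.g. intron medians of an all-single-exon
subset) yield NA records and do not enter the correction family.

Bonferroni correction is applied per test family: all KS tests of one
invocation form one family, all Wilcoxon tests another (a single
invocation = a single species; species are independent runs and are not
pooled into one family). Significance flags use p_adj ≤ 0.05.

Correlative trends are Spearman's rank coefficients (Pearson on average
ranks) of four combinations: exon count vs. median exon length, exon
count vs. median exon GC, intron count vs. median intron length, intron
count vs. median intron GC; intron combinations use transcripts with at
least one intron. Coefficients are reported without p-values.

## Subsampling representativeness

Curated subsets are far smaller than full sets, so their correlation
coefficients are compared against the sampling spread of same-size
coefficients: the full set is repeatedly subsampled without replacement
(default 1000 replicates of 1000 models; sampling is without
replacement within a replicate, replicates may overlap), each
replicate's Spearman coefficient is computed, and the replicate
coefficients form an interval. The default interval is the min–max
range — consistent with calling a subset value "lower than the interval
minimum" — with a percentile mode (default 2.5–97.5, linear
interpolation) available for robustness against single extreme
replicates. A subset coefficient below/above the interval is classified
`outside_low`/`outside_high`; boundary equality counts as inside; an
undefined coefficient gives NA. Each replicate draws from its own
deterministic child stream of the master seed (NumPy `SeedSequence`
spawning), so replicate *k* is identical regardless of how many
replicates are requested, and identical configurations reproduce
bitwise-identical coefficient vectors.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not sequence-level realism (no codon structure, splice-site motifs, or
repeats — conclusions about real data rest on the structural statistics
only, which is what the tests exercise):

* **Genome**: uniform background composition at a configurable GC
  (default 35%, insect-like); realized GC is checked to within one
  percentage point of target. Ambiguity (N) blocks (default 30 runs of
  600 bp per Mbp, ≈ 1.8% N) are placed in intergenic gaps only, never
  inside a gene locus. Default 8 scaffolds × 1.5 Mb, sized to hold the
  default 2000 genes with ≈ 40% headroom.
* **Gene models**: exon counts follow a geometric distribution
  parameterized by its target median (default 5, matching the published
  insect set-wide medians of 4–6); exon and intron lengths are
  log-normal (default medians 250 bp and 150 bp). The per-gene exon
  length median scales as (median count / count)^0.4, building in the
  negative exon-count/exon-length correlation that real repertoires
  show. Per-gene exon totals are padded to a multiple of 3 so protein
  lengths are integral. Exon bases are re-drawn at background + offset
  GC (default +10 points); introns and intergenic sequence stay at
  background. Genes are non-overlapping, strand random; 10% of
  multi-exon genes carry a shorter second isoform (one internal exon
  dropped) to exercise longest-transcript selection.
* **Curation**: a configurable curated fraction (default 5%, inside the
  published 3.5–6.9% band) of automatic models is perturbed by one
  operator each — boundary shift at the 3′ end (extend or shrink,
  log-normal magnitude, optionally fixed), exon gain, exon loss, merge
  with the right neighbour (one OGS model, two predecessors), or split
  at an exon boundary (two OGS models, one predecessor) — with mix
  probabilities 0.5/0.15/0.15/0.1/0.1; infeasible draws fall back to
  another operator. A de novo fraction (default 1%, inside the published
  0.3–2.2% band) of short, receptor-like models (1–3 exons, ≈ 400 bp
  exons) is placed in free intergenic space, giving MAN-ADD a
  deliberately distinct structural profile. The genome sequence is
  never modified by curation: both annotations describe one assembly.
* **Manifest**: every true property value and curation action is
  recorded (computed by a straight-line recomputation from raw
  intervals, independent of the analysis code), so pipeline outputs can
  be checked against construction.

## Determinism, problem sizes, and degenerate inputs

All randomness flows from a single seed (generator phases and
resampling use fixed-labelled `SeedSequence` children), so a rerun with
the same configuration produces byte-identical statistical tables. The
test suite exercises the pipeline at reduced scale — 200–500-gene
annotations on 1–4 Mb genomes, resampling at 40–200 replicates of
80–200 models, exact-test oracles at n₁+n₂ ≤ 12 (≤ 924 enumerated
splits) — sizes at which every check is exact or well-resolved while the
suite stays fast; the 1000 × 1000 resampling default remains the
documented analysis-scale setting.

Degenerate inputs are errors, not silent repairs: empty FASTA/sample
vectors, overlapping exons within a transcript, orphan mRNAs, features
beyond sequence ends, provenance rows naming unknown models, a
subsample size exceeding the usable table (no clamping), Bonferroni
family smaller than its p-value vector. Zero-variance rank vectors give
NA coefficients.

## Known limitations

* Predecessor links must be supplied; the package does not infer them
  from coordinate overlap.
* Coding/intronic proportions do not union-merge overlapping gene
  models; with the non-overlapping synthetic genes this is exact, and on
  real annotations it can double-count rare overlaps.
* The generator's structural distributions are independent across genes
  and contain no gene families, clustering, or assembly fragmentation;
  passing tests demonstrate correctness of the measurement and inference
  machinery, not realism of any particular genome.
* The KS asymptotic p-value is approximate under heavy ties; at small n
  the exact enumeration sidesteps this, at large n the approximation
  error is negligible relative to the Bonferroni-corrected decision
  threshold.
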