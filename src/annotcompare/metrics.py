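"""Per-transcript structural properties and repertoire-wide summaries.

All values are derived from the longest transcript per gene, where
"longest" means maximal summed exon length (mature coding length), with
the lexicographically smallest transcript id breaking ties.  Five core
properties describe each transcript — unspliced (pre-mRNA) length,
protein length, exon count, median exon length, and median intron
length — plus the per-transcript median GC content of exons and introns
used by the correlation analyses.

Single-exon transcripts have no introns: their intron-based fields are
undefined (NaN) and are excluded from set-wide intron medians and from
intron correlations, never silently zeroed.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .models import GeneModel, GenomeAssembly, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

PROPERTY_COLUMNS = [
    "unspliced_length",
    "protein_length",
    "exon_count",
    "intron_count",
    "median_exon_length",
    "median_intron_length",
    "median_exon_gc",
    "median_intron_gc",
]

# The five distribution-tested properties.
TESTED_PROPERTIES = [
    "unspliced_length",
    "protein_length",
    "exon_count",
    "median_exon_length",
    "median_intron_length",
]


def select_longest_transcript(gene: GeneModel) -> TranscriptModel:
    """Longest transcript = maximal summed exon length; ties broken by
    lexicographically smallest transcript id."""
    longest = max(t.summed_exon_length for t in gene.transcripts)
    candidates = [t for t in gene.transcripts if t.summed_exon_length == longest]
    return min(candidates, key=lambda t: t.transcript_id)


def derive_introns(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Introns are the gaps between consecutive exons (possibly empty)."""
    introns = []
    for a, b in zip(transcript.exons, transcript.exons[1:]):
        introns.append(GenomicInterval(a.seq_id, a.end, b.start, transcript.strand))
    return introns


def feature_gc(interval: GenomicInterval, assembly: GenomeAssembly) -> float:
    """GC percentage of unambiguous bases in an interval; NaN if none.

    Strand-insensitive: G+C is invariant under reverse complement.
    """
    seq = assembly.sequences[interval.seq_id]
    if interval.end > len(seq):
        raise ValueError(
            f"interval {interval.seq_id}:{interval.start}-{interval.end} exceeds "
            f"sequence length {len(seq)}"
        )
    sub = seq[interval.start : interval.end]
    gc = sub.count("G") + sub.count("C")
    at = sub.count("A") + sub.count("T")
    if gc + at == 0:
        return math.nan
    return 100.0 * gc / (gc + at)


def _median(values: Sequence[float]) -> float:
    return float(statistics.median(values)) if values else math.nan


def transcript_properties(
    transcript: TranscriptModel,
    assembly: GenomeAssembly,
    subtract_stop: bool = False,
) -> dict:
    """Compute the property record for one (longest) transcript.

    Protein length is the summed exon length in codons, ``floor(bp / 3)``;
    with ``subtract_stop`` one residue is subtracted for the stop codon.
    """
    exon_lengths = [len(e) for e in transcript.exons]
    total_exonic = sum(exon_lengths)
    if total_exonic == 0:
        raise ValueError(f"transcript {transcript.transcript_id} has zero exonic length")
    introns = derive_introns(transcript)
    intron_lengths = [len(i) for i in introns]

    exon_gcs = [g for g in (feature_gc(e, assembly) for e in transcript.exons) if not math.isnan(g)]
    intron_gcs = [g for g in (feature_gc(i, assembly) for i in introns) if not math.isnan(g)]

    protein_length = total_exonic // 3
    if subtract_stop:
        protein_length -= 1

    return {
        "gene_id": transcript.gene_id,
        "transcript_id": transcript.transcript_id,
        "unspliced_length": transcript.unspliced_length,
        "protein_length": protein_length,
        "exon_count": len(transcript.exons),
        "intron_count": len(introns),
        "median_exon_length": _median(exon_lengths),
        "median_intron_length": _median(intron_lengths),
        "median_exon_gc": _median(exon_gcs),
        "median_intron_gc": _median(intron_gcs),
    }


def properties_table(
    models: Sequence[GeneModel],
    assembly: GenomeAssembly,
    subtract_stop: bool = False,
) -> pd.DataFrame:
    """One property row per gene, computed on its longest transcript."""
    rows = [
        transcript_properties(select_longest_transcript(g), assembly, subtract_stop)
        for g in models
    ]
    df = pd.DataFrame(rows)
    return df.set_index("gene_id", drop=False)


def set_medians(props: pd.DataFrame) -> dict[str, float]:
    """Set-wide median of each property (median of per-transcript medians).

    Undefined per-transcript values (e.g. intron medians of single-exon
    transcripts) are excluded; exclusion counts are logged.
    """
    if len(props) == 0:
        raise ValueError("cannot compute medians of an empty property table")
    out: dict[str, float] = {}
    for col in PROPERTY_COLUMNS:
        values = props[col].dropna()
        n_excluded = len(props) - len(values)
        if n_excluded:
            logger.info("set_medians: %d undefined %s values excluded", n_excluded, col)
        out[col] = float(values.median()) if len(values) else math.nan
    return out


@dataclass
class SetSummary:
    """Annotation-wide summary metrics for one gene (sub)set."""

    set_label: str
    gene_count: int
    total_exon_count: int
    coding_proportion: float
    intronic_proportion: float
    assembly_gc_unambiguous: float
    medians: Mapping[str, float]


def summary_metrics(
    props: pd.DataFrame,
    models: Sequence[GeneModel],
    assembly: GenomeAssembly,
    set_label: str,
) -> SetSummary:
    """Coding/intronic proportions and counts over the longest transcripts.

    Proportions are summed raw exon/intron lengths of each gene's longest
    transcript relative to assembly size; overlapping genes are not merged.
    """
    if assembly.assembly_size == 0:
        raise ValueError("assembly size is zero")
    total_exonic = 0
    total_intronic = 0
    total_exons = 0
    for gene in models:
        t = select_longest_transcript(gene)
        total_exonic += t.summed_exon_length
        total_intronic += t.unspliced_length - t.summed_exon_length
        total_exons += len(t.exons)
    return SetSummary(
        set_label=set_label,
        gene_count=len(models),
        total_exon_count=total_exons,
        coding_proportion=100.0 * total_exonic / assembly.assembly_size,
        intronic_proportion=100.0 * total_intronic / assembly.assembly_size,
        assembly_gc_unambiguous=assembly.gc_unambiguous,
        medians=set_medians(props),
    )


def summaries_frame(summaries: Sequence[SetSummary]) -> pd.DataFrame:
    """Flatten per-set summaries into one tidy table."""
    rows = []
    for s in summaries:
        row = {
            "set_label": s.set_label,
            "gene_count": s.gene_count,
            "total_exon_count": s.total_exon_count,
            "coding_proportion": s.coding_proportion,
            "intronic_proportion": s.intronic_proportion,
            "assembly_gc_unambiguous": s.assembly_gc_unambiguous,
        }
        row.update({f"median_{k}": v for k, v in s.medians.items()})
        rows.append(row)
    return pd.DataFrame(rows)
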