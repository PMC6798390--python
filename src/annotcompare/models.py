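"""Core in-memory containers for genomes, gene models, and provenance.

Coordinates are stored 0-based half-open throughout the package; GFF3
input (1-based inclusive) is converted on parsing and converted back on
output.  Exons double as coding sequence: the annotations this package
targets carry no consistently annotated UTRs, so exon and CDS intervals
are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a genome sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of disjoint exons on one sequence."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    strand: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        seq_ids = {e.seq_id for e in self.exons}
        if len(seq_ids) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans sequences {sorted(seq_ids)}"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def span_start(self) -> int:
        return self.exons[0].start

    @property
    def span_end(self) -> int:
        return self.exons[-1].end

    @property
    def unspliced_length(self) -> int:
        """Genomic span from first exon start to last exon end (pre-mRNA)."""
        return self.span_end - self.span_start

    @property
    def summed_exon_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]
    source_set_label: str = "automatic"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")


@dataclass
class GenomeAssembly:
    """Assembly sequences plus the composition figures every proportion uses.

    ``assembly_size`` counts every base including ambiguity codes;
    ``determined_length`` counts A/C/G/T only and is the denominator of
    ``gc_unambiguous`` (the "GC content without ambiguity").
    """

    sequences: dict[str, str]
    assembly_size: int
    determined_length: int
    gc_count: int

    @property
    def gc_unambiguous(self) -> float:
        if self.determined_length == 0:
            raise ValueError("assembly has no determined (A/C/G/T) nucleotides")
        return 100.0 * self.gc_count / self.determined_length

    @property
    def pct_determined(self) -> float:
        return 100.0 * self.determined_length / self.assembly_size

    def sequence_length(self, seq_id: str) -> int:
        return len(self.sequences[seq_id])


VALID_STATUSES = ("manual", "denovo", "auto")


@dataclass(frozen=True)
class ProvenanceRecord:
    """Link between an official-gene-set model and its automatic predecessor(s).

    A curated model produced by merging adjacent automatic models carries
    several predecessors; a de novo model carries none.
    """

    ogs_gene_id: str
    auto_gene_ids: tuple[str, ...]
    status: str

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise ValueError(f"invalid provenance status {self.status!r}")
        if self.status == "manual" and not self.auto_gene_ids:
            raise ValueError(
                f"manual model {self.ogs_gene_id} lacks an automatic predecessor"
            )
        if self.status == "denovo" and self.auto_gene_ids:
            raise ValueError(
                f"de novo model {self.ogs_gene_id} must not list predecessors"
            )


@dataclass
class ProvenanceMap:
    records: dict[str, ProvenanceRecord] = field(default_factory=dict)

    def add(self, record: ProvenanceRecord) -> None:
        if record.ogs_gene_id in self.records:
            raise ValueError(f"duplicate provenance entry for {record.ogs_gene_id}")
        self.records[record.ogs_gene_id] = record

    def status_of(self, ogs_gene_id: str) -> str:
        rec = self.records.get(ogs_gene_id)
        return rec.status if rec is not None else "auto"

    def predecessors_of(self, ogs_gene_id: str) -> tuple[str, ...]:
        rec = self.records.get(ogs_gene_id)
        return rec.auto_gene_ids if rec is not None else ()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())


def genes_by_id(models: Iterable[GeneModel]) -> Mapping[str, GeneModel]:
    out: dict[str, GeneModel] = {}
    for g in models:
        if g.gene_id in out:
            raise ValueError(f"duplicate gene id {g.gene_id}")
        out[g.gene_id] = g
    return out
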