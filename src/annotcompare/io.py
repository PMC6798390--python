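"""Reading and writing of genomes, annotations, provenance maps, and tables.

FASTA is read through Biopython, GFF3 through gffutils (in-memory sqlite
feature database).  The provenance map — which official-gene-set model
descends from which automatic prediction — travels as an explicit
three-column TSV because curation-attribute conventions inside GFF3 vary
between annotation projects::

    ogs_gene_id <TAB> auto_gene_id[,auto_gene_id...]|NA <TAB> manual|denovo|auto

A merged curated model lists its predecessors comma-separated; a de novo
model has ``NA``.  Models absent from the map count as unchanged
automatic models.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .models import (
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    ProvenanceMap,
    ProvenanceRecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

# IUPAC nucleotide one-letter codes; everything outside A/C/G/T counts as
# ambiguity (towards assembly size but not towards determined length).
_IUPAC = set("ACGTUNRYSWKMBDHV")
_UNAMBIGUOUS = "ACGT"
_INVALID_RE = re.compile(f"[^{''.join(sorted(_IUPAC))}]")


def parse_genome(fasta_path: str | Path) -> GenomeAssembly:
    """Read an assembly FASTA and compute its composition totals.

    Lowercase (soft-masked) bases are treated as uppercase.  Any
    character outside the IUPAC nucleotide alphabet raises, naming the
    offending sequence and position.
    """
    fasta_path = Path(fasta_path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence id {record.id!r} in {fasta_path}")
        seq = str(record.seq).upper()
        bad = _INVALID_RE.search(seq)
        if bad:
            raise ValueError(
                f"non-nucleotide character {bad.group()!r} at position "
                f"{bad.start() + 1} of sequence {record.id!r}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no sequences found in {fasta_path}")

    assembly_size = sum(len(s) for s in sequences.values())
    determined = sum(s.count(b) for s in sequences.values() for b in _UNAMBIGUOUS)
    gc = sum(s.count(b) for s in sequences.values() for b in "GC")
    return GenomeAssembly(
        sequences=sequences,
        assembly_size=assembly_size,
        determined_length=determined,
        gc_count=gc,
    )


def _feature_interval(feature, assembly: GenomeAssembly) -> GenomicInterval:
    if feature.seqid not in assembly.sequences:
        raise ValueError(
            f"feature {feature.id or feature.featuretype} references unknown "
            f"sequence {feature.seqid!r}"
        )
    seq_len = assembly.sequence_length(feature.seqid)
    # GFF3 is 1-based inclusive; internal representation 0-based half-open.
    start, end = feature.start - 1, feature.end
    if end > seq_len:
        raise ValueError(
            f"feature {feature.id or feature.featuretype} on {feature.seqid} "
            f"ends at {end} beyond sequence length {seq_len}"
        )
    return GenomicInterval(feature.seqid, start, end, feature.strand)


def parse_annotation(gff3_path: str | Path, assembly: GenomeAssembly) -> list[GeneModel]:
    """Parse a gene→mRNA→exon/CDS GFF3 annotation against an assembly.

    Exon features are preferred as the transcript's exon list; when a
    transcript carries only CDS features those are adopted as exons (in
    these annotations exons and CDSs are identical because UTRs are not
    annotated).  When both are present and differ, the CDS intervals win
    and a warning is logged, since the analysis concerns coding structure.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="error",
        keep_order=False,
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}

    orphans = [
        f.id
        for f in db.features_of_type("mRNA")
        if not any(p in gene_ids for p in f.attributes.get("Parent", []))
    ]
    if orphans:
        raise ValueError(f"mRNA features without a gene parent: {sorted(orphans)}")

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exon_ivs = [
                _feature_interval(f, assembly)
                for f in db.children(mrna, featuretype="exon", order_by="start")
            ]
            cds_ivs = [
                _feature_interval(f, assembly)
                for f in db.children(mrna, featuretype="CDS", order_by="start")
            ]
            if exon_ivs and cds_ivs:
                if [(e.start, e.end) for e in exon_ivs] != [
                    (c.start, c.end) for c in cds_ivs
                ]:
                    logger.warning(
                        "transcript %s: exon and CDS features differ; using CDS",
                        mrna.id,
                    )
                    chosen = cds_ivs
                else:
                    chosen = exon_ivs
            else:
                chosen = exon_ivs or cds_ivs
            if not chosen:
                raise ValueError(f"transcript {mrna.id} has neither exon nor CDS features")
            transcripts.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    gene_id=gene.id,
                    exons=chosen,
                    strand=mrna.strand,
                )
            )
        if not transcripts:
            raise ValueError(f"gene {gene.id} has no mRNA children")
        genes.append(GeneModel(gene_id=gene.id, transcripts=transcripts))
    if not genes:
        raise ValueError(f"no gene features found in {gff3_path}")
    return genes


def write_annotation(models: Sequence[GeneModel], path: str | Path, source: str = "annotcompare") -> None:
    """Serialize gene models to GFF3 (gene/mRNA/exon + mirrored CDS rows)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for gene in models:
            start = min(t.span_start for t in gene.transcripts)
            end = max(t.span_end for t in gene.transcripts)
            seq_id = gene.transcripts[0].seq_id
            strand = gene.transcripts[0].strand
            fh.write(
                f"{seq_id}\t{source}\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for t in gene.transcripts:
                fh.write(
                    f"{seq_id}\t{source}\tmRNA\t{t.span_start + 1}\t{t.span_end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gene.gene_id}\n"
                )
                for i, exon in enumerate(t.exons, 1):
                    attrs = f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                    fh.write(
                        f"{seq_id}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )
                for i, exon in enumerate(t.exons, 1):
                    attrs = f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"
                    fh.write(
                        f"{seq_id}\t{source}\tCDS\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{t.strand}\t0\t{attrs}\n"
                    )


def parse_provenance(
    tsv_path: str | Path,
    auto_models: Sequence[GeneModel],
    ogs_models: Sequence[GeneModel],
) -> ProvenanceMap:
    """Read and validate the three-column provenance TSV.

    Official-set models absent from the file default to unchanged
    automatic status.
    """
    auto_ids = {g.gene_id for g in auto_models}
    ogs_ids = {g.gene_id for g in ogs_models}
    pmap = ProvenanceMap()
    tsv_path = Path(tsv_path)
    with tsv_path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{tsv_path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            ogs_id, auto_field, status = fields
            if ogs_id not in ogs_ids:
                raise ValueError(
                    f"{tsv_path}:{lineno}: ogs gene {ogs_id!r} not present in the "
                    "official gene set"
                )
            preds: tuple[str, ...]
            if auto_field in ("NA", "", "."):
                preds = ()
            else:
                preds = tuple(auto_field.split(","))
                missing = [p for p in preds if p not in auto_ids]
                if missing:
                    raise ValueError(
                        f"{tsv_path}:{lineno}: predecessor(s) {missing} not present "
                        "in the automatic annotation"
                    )
            pmap.add(ProvenanceRecord(ogs_gene_id=ogs_id, auto_gene_ids=preds, status=status))
    return pmap


def write_provenance(pmap: ProvenanceMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in pmap:
            auto_field = ",".join(rec.auto_gene_ids) if rec.auto_gene_ids else "NA"
            fh.write(f"{rec.ogs_gene_id}\t{auto_field}\t{rec.status}\n")


def write_table(
    records: pd.DataFrame | Iterable[dict],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write a result table as TSV (NA for missing, '.' decimal) or JSON."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    path = Path(path)
    if format == "tsv":
        records.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "json":
        cleaned = records.where(records.notna(), None)
        with path.open("w") as fh:
            json.dump(cleaned.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
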