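import numpy as np
import pytest

from annotcompare.io import parse_annotation, parse_genome, parse_provenance
from annotcompare.models import GenomeAssembly, GenomicInterval, TranscriptModel
from annotcompare.simulate import (
    GeneModelConfig,
    GenomeConfig,
    PerturbationConfig,
    generate_bundle,
)


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    """1 kb deterministic sequence: ACGT repeated (GC exactly 50%)."""
    seq = "ACGT" * 250
    return GenomeAssembly(
        sequences={"chr1": seq},
        assembly_size=1000,
        determined_length=1000,
        gc_count=500,
    )


def make_transcript(exons, tid="t1", gid="g1", seq_id="chr1", strand="+"):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        exons=[GenomicInterval(seq_id, s, e, strand) for s, e in exons],
        strand=strand,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """200-gene synthetic bundle shared by parsing/metric tests."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(
        out,
        seed=11,
        genome_config=GenomeConfig(n_scaffolds=2, scaffold_length_bp=600_000),
        gene_config=GeneModelConfig(n_genes=200),
        perturb_config=PerturbationConfig(),
    )


@pytest.fixture(scope="session")
def small_parsed(small_bundle):
    assembly = parse_genome(small_bundle.genome_path)
    auto = parse_annotation(small_bundle.auto_path, assembly)
    ogs = parse_annotation(small_bundle.ogs_path, assembly)
    prov = parse_provenance(small_bundle.provenance_path, auto, ogs)
    return assembly, auto, ogs, prov


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
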