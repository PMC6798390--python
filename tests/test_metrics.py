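"""Structural property extraction and repertoire summaries."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annotcompare.metrics import (
    derive_introns,
    feature_gc,
    properties_table,
    select_longest_transcript,
    set_medians,
    summary_metrics,
    transcript_properties,
)
from annotcompare.models import GeneModel, GenomeAssembly, GenomicInterval
from tests.conftest import make_transcript


class TestLongestTranscript:
    def test_single_transcript_identity(self):
        t = make_transcript([(0, 100)])
        gene = GeneModel(gene_id="g1", transcripts=[t])
        assert select_longest_transcript(gene) is t

    def test_summed_exon_length_beats_span(self):
        t1 = make_transcript([(0, 100), (500, 700)], tid="t1")  # 300 bp exonic
        t2 = make_transcript([(0, 250)], tid="t2")  # 250 bp exonic
        gene = GeneModel(gene_id="g1", transcripts=[t1, t2])
        assert select_longest_transcript(gene).transcript_id == "t1"

    def test_tie_breaks_to_smallest_id(self):
        t1 = make_transcript([(0, 100)], tid="tB")
        t2 = make_transcript([(200, 300)], tid="tA")
        gene = GeneModel(gene_id="g1", transcripts=[t1, t2])
        assert select_longest_transcript(gene).transcript_id == "tA"

    def test_agrees_with_bruteforce_max(self, rng):
        rng = np.random.default_rng(3)
        for _ in range(20):
            transcripts = []
            for k in range(rng.integers(2, 6)):
                pos, exons = 0, []
                for _ in range(rng.integers(1, 6)):
                    pos += int(rng.integers(1, 200))
                    length = int(rng.integers(10, 400))
                    exons.append((pos, pos + length))
                    pos += length
                transcripts.append(make_transcript(exons, tid=f"t{k}"))
            gene = GeneModel(gene_id="g", transcripts=transcripts)
            best = max(t.summed_exon_length for t in transcripts)
            assert select_longest_transcript(gene).summed_exon_length == best


class TestDeriveIntrons:
    def test_gap_between_exons(self):
        t = make_transcript([(0, 100), (200, 300)])
        introns = derive_introns(t)
        assert [(i.start, i.end) for i in introns] == [(100, 200)]

    def test_single_exon_has_no_introns(self):
        assert derive_introns(make_transcript([(0, 100)])) == []

    def test_gap_lengths_conserve_span(self, rng):
        for _ in range(5):
            pos, exons = 0, []
            for _ in range(rng.integers(2, 8)):
                pos += int(rng.integers(1, 500))
                length = int(rng.integers(1, 500))
                exons.append((pos, pos + length))
                pos += length
            t = make_transcript(exons)
            intron_total = sum(len(i) for i in derive_introns(t))
            assert t.summed_exon_length + intron_total == t.unspliced_length


class TestFeatureGC:
    def test_even_composition(self, toy_assembly):
        assert feature_gc(GenomicInterval("chr1", 0, 4), toy_assembly) == 50.0

    def test_all_ambiguous_is_undefined(self):
        asm = GenomeAssembly({"c": "NNNN"}, 4, 0, 0)
        assert math.isnan(feature_gc(GenomicInterval("c", 0, 4), asm))

    def test_reverse_complement_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        a1 = GenomeAssembly({"c": seq}, 60, 60, seq.count("G") + seq.count("C"))
        a2 = GenomeAssembly({"c": rc}, 60, 60, rc.count("G") + rc.count("C"))
        iv = GenomicInterval("c", 0, 60)
        assert feature_gc(iv, a1) == feature_gc(iv, a2)

    def test_out_of_bounds_rejected(self, toy_assembly):
        with pytest.raises(ValueError, match="exceeds"):
            feature_gc(GenomicInterval("chr1", 990, 1010), toy_assembly)


class TestTranscriptProperties:
    def test_two_exon_arithmetic(self, toy_assembly):
        t = make_transcript([(0, 300), (400, 700)])
        props = transcript_properties(t, toy_assembly)
        assert props["unspliced_length"] == 700
        assert props["exon_count"] == 2
        assert props["intron_count"] == 1
        assert props["median_exon_length"] == 300
        assert props["median_intron_length"] == 100
        assert props["protein_length"] == 200

    def test_odd_median_exon_length(self, toy_assembly):
        t = make_transcript([(0, 90), (100, 220), (300, 450)])  # 90,120,150
        assert transcript_properties(t, toy_assembly)["median_exon_length"] == 120

    def test_single_exon_fields_undefined(self, toy_assembly):
        props = transcript_properties(make_transcript([(0, 99)]), toy_assembly)
        assert props["intron_count"] == 0
        assert math.isnan(props["median_intron_length"])
        assert math.isnan(props["median_intron_gc"])
        assert props["protein_length"] == 33

    def test_stop_codon_flag(self, toy_assembly):
        t = make_transcript([(0, 300)])
        assert transcript_properties(t, toy_assembly, subtract_stop=True)["protein_length"] == 99

    def test_matches_naive_recomputation_on_synthetic_transcripts(self):
        """200 random transcripts: every field vs. straight-line oracle."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGTN"), size=200_000, p=[0.3, 0.2, 0.2, 0.28, 0.02]))
        asm = GenomeAssembly(
            {"c": seq},
            len(seq),
            sum(seq.count(b) for b in "ACGT"),
            seq.count("G") + seq.count("C"),
        )
        for _ in range(200):
            pos, exons = int(rng.integers(0, 1000)), []
            for _ in range(int(rng.integers(1, 9))):
                length = int(rng.integers(5, 600))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(30, 800))
            t = make_transcript(exons, seq_id="c")
            got = transcript_properties(t, asm)

            # independent oracle on raw intervals and the raw string
            exon_lens = [e - s for s, e in exons]
            intron_ivs = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]

            def naive_gc(iv):
                sub = seq[iv[0]: iv[1]]
                det = sum(sub.count(b) for b in "ACGT")
                return 100 * (sub.count("G") + sub.count("C")) / det if det else math.nan

            assert got["unspliced_length"] == exons[-1][1] - exons[0][0]
            assert got["protein_length"] == sum(exon_lens) // 3
            assert got["exon_count"] == len(exons)
            assert got["intron_count"] == len(exons) - 1
            assert got["median_exon_length"] == statistics.median(exon_lens)
            exon_gcs = [g for g in map(naive_gc, exons) if not math.isnan(g)]
            assert got["median_exon_gc"] == pytest.approx(statistics.median(exon_gcs))
            if intron_ivs:
                assert got["median_intron_length"] == statistics.median(
                    [e - s for s, e in intron_ivs]
                )
            else:
                assert math.isnan(got["median_intron_length"])

    @given(
        st.lists(
            st.tuples(st.integers(1, 300), st.integers(1, 300)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_span_conservation_property(self, pieces):
        """Sum of exons plus sum of introns equals the unspliced span."""
        toy_assembly = GenomeAssembly({"chr1": "ACGT" * 250}, 1000, 1000, 500)
        pos, exons = 0, []
        for gap, length in pieces:
            pos += gap
            exons.append((pos, pos + length))
            pos += length
        if exons[-1][1] > 1000:
            return
        t = make_transcript(exons)
        props = transcript_properties(t, toy_assembly)
        intron_total = sum(len(i) for i in derive_introns(t))
        assert t.summed_exon_length + intron_total == props["unspliced_length"]


class TestSetMedians:
    def test_single_record_identity(self, toy_assembly):
        t = make_transcript([(0, 300), (400, 700)])
        df = properties_table([GeneModel("g1", [t])], toy_assembly)
        med = set_medians(df)
        assert med["unspliced_length"] == 700
        assert med["median_exon_length"] == 300

    def test_even_count_interpolates(self):
        df = pd.DataFrame(
            {c: [math.nan, math.nan] for c in
             ["protein_length", "exon_count", "intron_count", "median_exon_length",
              "median_intron_length", "median_exon_gc", "median_intron_gc"]}
            | {"unspliced_length": [4.0, 6.0]}
        )
        assert set_medians(df)["unspliced_length"] == 5.0

    def test_undefined_values_excluded(self):
        df = pd.DataFrame(
            {c: [1.0, 1.0, 1.0] for c in
             ["unspliced_length", "protein_length", "exon_count", "intron_count",
              "median_exon_length", "median_exon_gc", "median_intron_gc"]}
            | {"median_intron_length": [math.nan, 10.0, 20.0]}
        )
        assert set_medians(df)["median_intron_length"] == 15.0

    def test_matches_sort_and_pick_oracle(self, rng):
        values = rng.normal(size=101)
        df = pd.DataFrame(
            {c: values for c in
             ["unspliced_length", "protein_length", "exon_count", "intron_count",
              "median_exon_length", "median_intron_length", "median_exon_gc",
              "median_intron_gc"]}
        )
        expected = sorted(values)[50]
        assert set_medians(df)["unspliced_length"] == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            set_medians(pd.DataFrame())


class TestSummaryMetrics:
    def test_coding_proportion(self):
        seq = "ACGT" * 2500  # 10 kb
        asm = GenomeAssembly({"c": seq}, 10_000, 10_000, 5_000)
        t = make_transcript([(0, 400), (500, 1100)], seq_id="c")  # 1000 bp exonic
        gene = GeneModel("g1", [t])
        df = properties_table([gene], asm)
        s = summary_metrics(df, [gene], asm, "AUTO")
        assert s.coding_proportion == 10.0
        assert s.intronic_proportion == 1.0
        assert s.gene_count == 1
        assert s.total_exon_count == 2

    def test_intron_free_annotation(self, toy_assembly):
        genes = [
            GeneModel(f"g{i}", [make_transcript([(i * 100, i * 100 + 60)], tid=f"t{i}", gid=f"g{i}")])
            for i in range(3)
        ]
        df = properties_table(genes, toy_assembly)
        s = summary_metrics(df, genes, toy_assembly, "AUTO")
        assert s.intronic_proportion == 0.0

    def test_proportions_match_manifest_totals(self, small_bundle, small_parsed):
        assembly, auto, _, _ = small_parsed
        df = properties_table(auto, assembly)
        s = summary_metrics(df, auto, assembly, "AUTO")
        truth = small_bundle.manifest["auto_truth"]
        exonic = sum(r["protein_length"] * 3 for r in truth)  # exon bp is 3x aa
        assert s.coding_proportion == pytest.approx(100 * exonic / assembly.assembly_size)
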