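"""Synthetic genome + annotation bundles with known ground truth.

The generator emulates the inputs of an insect-style annotation
comparison: a multi-scaffold assembly with ambiguity (N) blocks, an
automatic annotation of non-overlapping multi-exon gene models, and an
official gene set derived from it by perturbing a small curated fraction
(boundary shifts, exon gains/losses, merges, splits — the documented
manual-curation actions) plus a small de novo fraction of short,
receptor-like models with a deliberately distinct structural profile.

Everything is driven by one seed and every truth value (exon layouts,
realized per-transcript properties, curation actions) is recorded in a
manifest, so each pipeline stage can be verified against construction.

Structural distributions: exon counts follow a shifted geometric
distribution parameterized by its target median; exon and intron lengths
are log-normal.  The per-gene exon-length median scales as
``(median_count / count) ** coupling`` so that exon-rich genes have
shorter exons — the negative exon-count/exon-length correlation that
real gene repertoires show.  Exon base composition is drawn at the
background GC plus a configurable offset; introns and intergenic
sequence stay at background.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GenomeConfig:
    n_scaffolds: int = 8
    scaffold_length_bp: int = 1_500_000
    gc_background: float = 35.0
    n_run_rate: float = 30.0  # ambiguity blocks per Mbp
    n_run_length: int = 600

    def __post_init__(self) -> None:
        if not 0 < self.gc_background < 100:
            raise ValueError("gc_background must lie strictly between 0 and 100")
        if self.scaffold_length_bp <= 0 or self.n_scaffolds <= 0:
            raise ValueError("scaffold dimensions must be positive")


@dataclass
class GeneModelConfig:
    n_genes: int = 2000
    exon_count_median: int = 5
    exon_length_median: float = 250.0
    exon_length_sigma: float = 0.6
    # per-gene exon-length median ~ (median_count / count) ** coupling
    exon_length_count_coupling: float = 0.4
    intron_length_median: float = 150.0
    intron_length_sigma: float = 0.9
    exon_gc_offset: float = 10.0
    intergenic_median: float = 800.0
    intergenic_sigma: float = 0.7
    isoform_rate: float = 0.1
    min_exon_length: int = 30
    min_intron_length: int = 40

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.exon_count_median < 1:
            raise ValueError("exon_count_median must be >= 1")


@dataclass
class PerturbationConfig:
    manual_fraction: float = 0.05
    denovo_fraction: float = 0.01
    operator_probs: dict = field(
        default_factory=lambda: {
            "boundary_shift": 0.5,
            "exon_add": 0.15,
            "exon_remove": 0.15,
            "merge_adjacent": 0.1,
            "split_model": 0.1,
        }
    )
    shift_median: float = 300.0
    shift_sigma: float = 0.5
    shift_fixed: int | None = None  # overrides the distribution when set
    extend_prob: float = 0.5  # extend vs. shrink on boundary shifts
    denovo_exon_counts: tuple[int, ...] = (1, 2, 3)
    denovo_exon_length_median: float = 400.0
    denovo_exon_length_sigma: float = 0.4
    denovo_intron_length_median: float = 80.0

    def __post_init__(self) -> None:
        for frac in (self.manual_fraction, self.denovo_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        total = sum(self.operator_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"operator probabilities sum to {total}, not 1")


@dataclass
class SimGene:
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, disjoint
    isoform_exons: list[tuple[int, int]] | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class SimGenome:
    seqs: dict[str, np.ndarray]  # dtype S1 arrays
    gc_background: float
    n_intervals: dict[str, list[tuple[int, int]]]

    def sequence(self, seq_id: str) -> str:
        return self.seqs[seq_id].tobytes().decode()


def _geometric_q(target_median: int) -> float:
    """Failure probability of a shifted geometric with the given median.

    P(X <= k) = 1 - q**k; solving the median condition midway between
    the k-1 and k constraints centres the distribution on the target.
    """
    return 0.5 ** (1.0 / (target_median - 0.5))


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size=None):
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def _draw_bases(rng: np.random.Generator, n: int, gc_pct: float) -> np.ndarray:
    gc = min(max(gc_pct, 1.0), 99.0) / 100.0
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def generate_genome(config: GenomeConfig, seed: int) -> SimGenome:
    """Background assembly at the configured GC; realized GC is verified
    to lie within one percentage point of the target."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    seqs: dict[str, np.ndarray] = {}
    for i in range(config.n_scaffolds):
        seqs[f"scaffold_{i + 1}"] = _draw_bases(
            rng, config.scaffold_length_bp, config.gc_background
        )
    total = sum(a.size for a in seqs.values())
    gc = sum(int(np.sum((a == b"G") | (a == b"C"))) for a in seqs.values())
    realized = 100.0 * gc / total
    if abs(realized - config.gc_background) > 1.0:
        raise RuntimeError(
            f"realized GC {realized:.2f}% deviates more than 1 point from "
            f"target {config.gc_background}%"
        )
    return SimGenome(seqs=seqs, gc_background=config.gc_background, n_intervals={s: [] for s in seqs})


def _gene_structure(
    rng: np.random.Generator, cfg: GeneModelConfig
) -> tuple[list[int], list[int]]:
    """Exon and intron length lists for one gene; exon total divisible by 3."""
    q = _geometric_q(cfg.exon_count_median)
    k = int(rng.geometric(1.0 - q))  # support {1, 2, ...}
    ratio = (cfg.exon_count_median / k) ** cfg.exon_length_count_coupling
    exon_median = cfg.exon_length_median * ratio
    exon_lengths = [
        max(cfg.min_exon_length, int(round(v)))
        for v in _lognormal(rng, exon_median, cfg.exon_length_sigma, size=k)
    ]
    remainder = sum(exon_lengths) % 3
    if remainder:
        exon_lengths[-1] += 3 - remainder
    intron_lengths = [
        max(cfg.min_intron_length, int(round(v)))
        for v in _lognormal(rng, cfg.intron_length_median, cfg.intron_length_sigma, size=k - 1)
    ]
    return exon_lengths, intron_lengths


def generate_auto_annotation(
    genome: SimGenome,
    config: GeneModelConfig,
    seed: int,
    genome_config: GenomeConfig | None = None,
) -> list[SimGene]:
    """Place non-overlapping gene models and imprint exon composition.

    Ambiguity blocks are inserted into intergenic gaps afterwards so
    they never fall inside a gene locus.  Exon intervals are rewritten
    at background + offset GC; the genome object is modified in place.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    scaffold_ids = list(genome.seqs)
    tail_margin = 5_000

    genes: list[SimGene] = []
    scaffold_idx = 0
    cursor = 0
    gi = 0
    while gi < config.n_genes:
        if scaffold_idx >= len(scaffold_ids):
            raise RuntimeError(
                f"placed only {gi} of {config.n_genes} genes; use longer or "
                "more scaffolds"
            )
        seq_id = scaffold_ids[scaffold_idx]
        seq_len = genome.seqs[seq_id].size
        gap = int(round(_lognormal(rng, config.intergenic_median, config.intergenic_sigma)))
        exon_lengths, intron_lengths = _gene_structure(rng, config)
        span = sum(exon_lengths) + sum(intron_lengths)
        start = cursor + max(gap, 1)
        if start + span > seq_len - tail_margin:
            scaffold_idx += 1
            cursor = 0
            continue
        exons = []
        pos = start
        for j, el in enumerate(exon_lengths):
            exons.append((pos, pos + el))
            pos += el
            if j < len(intron_lengths):
                pos += intron_lengths[j]
        strand = "+" if rng.random() < 0.5 else "-"
        gene = SimGene(
            gene_id=f"AUTOg{gi + 1:05d}", seq_id=seq_id, strand=strand, exons=exons
        )
        if len(exons) >= 3 and rng.random() < config.isoform_rate:
            drop = int(rng.integers(1, len(exons) - 1))  # internal exon
            gene.isoform_exons = exons[:drop] + exons[drop + 1 :]
        genes.append(gene)
        cursor = pos
        gi += 1

    # imprint exon GC
    for gene in genes:
        for s, e in gene.exons:
            genome.seqs[gene.seq_id][s:e] = _draw_bases(
                rng, e - s, genome.gc_background + config.exon_gc_offset
            )

    _place_n_runs(genome, genes, genome_config, rng)
    return genes


def _place_n_runs(
    genome: SimGenome,
    genes: Sequence[SimGene],
    genome_config: GenomeConfig | None,
    rng: np.random.Generator,
) -> None:
    if genome_config is None or genome_config.n_run_rate <= 0:
        return
    total_mbp = sum(a.size for a in genome.seqs.values()) / 1e6
    n_runs = int(round(genome_config.n_run_rate * total_mbp))
    run_len = genome_config.n_run_length
    gaps = _intergenic_gaps(genome, genes, margin=100)
    big = [g for g in gaps if g[2] - g[1] >= run_len + 2]
    rng.shuffle(big)
    for seq_id, lo, hi in big[:n_runs]:
        offset = int(rng.integers(lo + 1, hi - run_len))
        genome.seqs[seq_id][offset : offset + run_len] = b"N"
        genome.n_intervals[seq_id].append((offset, offset + run_len))


def _intergenic_gaps(
    genome: SimGenome, genes: Sequence[SimGene], margin: int = 100
) -> list[tuple[str, int, int]]:
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in genome.seqs}
    for g in genes:
        occupied[g.seq_id].append((g.start, g.end))
    for s, runs in genome.n_intervals.items():
        occupied[s].extend(runs)
    gaps = []
    for seq_id, ivs in occupied.items():
        ivs = sorted(ivs)
        prev = 0
        for s, e in ivs:
            if s - prev > 2 * margin:
                gaps.append((seq_id, prev + margin, s - margin))
            prev = max(prev, e)
        seq_len = genome.seqs[seq_id].size
        if seq_len - prev > 2 * margin:
            gaps.append((seq_id, prev + margin, seq_len - margin))
    return gaps


# ---------------------------------------------------------------------------
# perturbation into the official gene set


@dataclass
class CurationAction:
    operator: str
    auto_gene_ids: tuple[str, ...]
    ogs_gene_ids: tuple[str, ...]
    detail: str = ""


def _shift_amount(rng: np.random.Generator, cfg: PerturbationConfig) -> int:
    if cfg.shift_fixed is not None:
        return int(cfg.shift_fixed)
    return max(3, int(round(_lognormal(rng, cfg.shift_median, cfg.shift_sigma))))


def _boundary_shift(
    gene: SimGene,
    rng: np.random.Generator,
    cfg: PerturbationConfig,
    seq_len: int,
    min_exon: int = 30,
) -> tuple[list[tuple[int, int]], str]:
    exons = list(gene.exons)
    delta = _shift_amount(rng, cfg)
    extend = rng.random() < cfg.extend_prob
    # 3' end in genomic terms: right edge on + strand, left edge on -
    if gene.strand == "+":
        s, e = exons[-1]
        if extend:
            e = min(e + delta, seq_len)
        else:
            e = max(e - delta, s + min_exon)
        exons[-1] = (s, e)
    else:
        s, e = exons[0]
        if extend:
            s = max(s - delta, 0)
        else:
            s = min(s + delta, e - min_exon)
        exons[0] = (s, e)
    return exons, f"{'extend' if extend else 'shrink'}:{delta}"


def _exon_add(
    gene: SimGene, rng: np.random.Generator, cfg: PerturbationConfig, seq_len: int
) -> tuple[list[tuple[int, int]], str] | None:
    exons = list(gene.exons)
    new_len = max(30, int(round(_lognormal(rng, cfg.denovo_exon_length_median, 0.4))))
    introns = [(a[1], b[0]) for a, b in zip(exons, exons[1:])]
    wide = [i for i, (s, e) in enumerate(introns) if e - s >= new_len + 80]
    if wide:
        i = int(rng.choice(wide))
        s, e = introns[i]
        off = int(rng.integers(s + 40, e - 40 - new_len))
        exons.insert(i + 1, (off, off + new_len))
        return exons, f"internal:{new_len}"
    tail = exons[-1][1] + 80
    if tail + new_len < seq_len:
        exons.append((tail, tail + new_len))
        return exons, f"appended:{new_len}"
    return None


def _exon_remove(
    gene: SimGene, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], str] | None:
    if len(gene.exons) < 2:
        return None
    exons = list(gene.exons)
    i = int(rng.integers(0, len(exons)))
    del exons[i]
    return exons, f"removed_index:{i}"


def perturb_to_ogs(
    auto_genes: Sequence[SimGene],
    genome: SimGenome,
    config: PerturbationConfig,
    seed: int,
) -> tuple[list[SimGene], list[tuple[str, str, str]], list[CurationAction]]:
    """Derive the official gene set from the automatic annotation.

    Returns OGS gene models, provenance rows
    ``(ogs_id, comma-joined predecessors or NA, status)``, and the log of
    curation actions.  The genome sequence itself is never modified: the
    official set re-annotates the same assembly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    genes = sorted(auto_genes, key=lambda g: (g.seq_id, g.start))
    n = len(genes)
    n_manual = int(round(config.manual_fraction * n))
    n_denovo = int(round(config.denovo_fraction * n))

    selected = set(rng.choice(n, size=n_manual, replace=False)) if n_manual else set()
    consumed: set[int] = set()
    operators = list(config.operator_probs)
    probs = np.array([config.operator_probs[o] for o in operators])

    ogs: list[SimGene] = []
    provenance: list[tuple[str, str, str]] = []
    actions: list[CurationAction] = []
    next_id = 1

    def new_ogs_gene(prefix: str, seq_id: str, strand: str, exons) -> SimGene:
        nonlocal next_id
        g = SimGene(f"{prefix}{next_id:05d}", seq_id, strand, sorted(exons))
        next_id += 1
        return g

    for i, gene in enumerate(genes):
        if i in consumed:
            continue
        if i not in selected:
            ogs.append(SimGene(gene.gene_id, gene.seq_id, gene.strand, list(gene.exons), gene.isoform_exons))
            continue

        seq_len = genome.seqs[gene.seq_id].size
        # weighted first choice, then remaining operators as fallbacks for
        # genes where the drawn operator is infeasible (e.g. merge with no
        # neighbour)
        first = str(rng.choice(operators, p=probs))
        rest = [o for o in operators if o != first]
        rng.shuffle(rest)
        applied = False
        for op in [first] + rest:
            if applied:
                break
            if op == "boundary_shift":
                exons, detail = _boundary_shift(gene, rng, config, seq_len)
                g = new_ogs_gene("OGSm", gene.seq_id, gene.strand, exons)
                ogs.append(g)
                provenance.append((g.gene_id, gene.gene_id, "manual"))
                actions.append(CurationAction(op, (gene.gene_id,), (g.gene_id,), detail))
                applied = True
            elif op == "exon_add":
                res = _exon_add(gene, rng, config, seq_len)
                if res is None:
                    continue
                exons, detail = res
                g = new_ogs_gene("OGSm", gene.seq_id, gene.strand, exons)
                ogs.append(g)
                provenance.append((g.gene_id, gene.gene_id, "manual"))
                actions.append(CurationAction(op, (gene.gene_id,), (g.gene_id,), detail))
                applied = True
            elif op == "exon_remove":
                res = _exon_remove(gene, rng)
                if res is None:
                    continue
                exons, detail = res
                g = new_ogs_gene("OGSm", gene.seq_id, gene.strand, exons)
                ogs.append(g)
                provenance.append((g.gene_id, gene.gene_id, "manual"))
                actions.append(CurationAction(op, (gene.gene_id,), (g.gene_id,), detail))
                applied = True
            elif op == "merge_adjacent":
                j = i + 1
                if (
                    j >= n
                    or j in consumed
                    or genes[j].seq_id != gene.seq_id
                ):
                    continue
                neighbor = genes[j]
                consumed.add(j)
                selected.discard(j)
                exons = list(gene.exons) + list(neighbor.exons)
                g = new_ogs_gene("OGSm", gene.seq_id, gene.strand, exons)
                ogs.append(g)
                provenance.append(
                    (g.gene_id, f"{gene.gene_id},{neighbor.gene_id}", "manual")
                )
                actions.append(
                    CurationAction(op, (gene.gene_id, neighbor.gene_id), (g.gene_id,))
                )
                applied = True
            elif op == "split_model":
                if len(gene.exons) < 2:
                    continue
                cut = int(rng.integers(1, len(gene.exons)))
                g1 = new_ogs_gene("OGSm", gene.seq_id, gene.strand, gene.exons[:cut])
                g2 = new_ogs_gene("OGSm", gene.seq_id, gene.strand, gene.exons[cut:])
                ogs.extend([g1, g2])
                provenance.append((g1.gene_id, gene.gene_id, "manual"))
                provenance.append((g2.gene_id, gene.gene_id, "manual"))
                actions.append(
                    CurationAction(op, (gene.gene_id,), (g1.gene_id, g2.gene_id), f"cut:{cut}")
                )
                applied = True
        if not applied:
            # no operator feasible for this gene: fall back to boundary shift
            exons, detail = _boundary_shift(gene, rng, config, seq_len)
            g = new_ogs_gene("OGSm", gene.seq_id, gene.strand, exons)
            ogs.append(g)
            provenance.append((g.gene_id, gene.gene_id, "manual"))
            actions.append(
                CurationAction("boundary_shift", (gene.gene_id,), (g.gene_id,), detail)
            )

    # de novo additions: short receptor-like models in free intergenic space
    gaps = _intergenic_gaps(genome, list(genes) + ogs, margin=200)
    rng.shuffle(gaps)
    placed = 0
    for seq_id, lo, hi in gaps:
        if placed >= n_denovo:
            break
        k = int(rng.choice(config.denovo_exon_counts))
        exon_lengths = [
            max(30, int(round(v)))
            for v in _lognormal(
                rng, config.denovo_exon_length_median, config.denovo_exon_length_sigma, size=k
            )
        ]
        rem = sum(exon_lengths) % 3
        if rem:
            exon_lengths[-1] += 3 - rem
        intron_lengths = [
            max(40, int(round(_lognormal(rng, config.denovo_intron_length_median, 0.4))))
            for _ in range(k - 1)
        ]
        span = sum(exon_lengths) + sum(intron_lengths)
        if hi - lo <= span + 2:
            continue
        start = int(rng.integers(lo, hi - span))
        exons = []
        pos = start
        for j, el in enumerate(exon_lengths):
            exons.append((pos, pos + el))
            pos += el
            if j < k - 1:
                pos += intron_lengths[j]
        strand = "+" if rng.random() < 0.5 else "-"
        g = new_ogs_gene("OGSa", seq_id, strand, exons)
        ogs.append(g)
        provenance.append((g.gene_id, "NA", "denovo"))
        actions.append(CurationAction("denovo_add", (), (g.gene_id,)))
        placed += 1
    if placed < n_denovo:
        raise RuntimeError(
            f"placed only {placed} of {n_denovo} de novo models; not enough "
            "intergenic space"
        )

    ogs.sort(key=lambda g: (g.seq_id, g.start))
    return ogs, provenance, actions


# ---------------------------------------------------------------------------
# truth properties and serialization


def true_properties(gene: SimGene, genome: SimGenome) -> dict:
    """Straight-line recomputation of the transcript property record from
    raw exon intervals and the sequence arrays (manifest ground truth)."""
    exons = gene.exons
    exon_lengths = [e - s for s, e in exons]
    introns = [(a[1], b[0]) for a, b in zip(exons, exons[1:])]
    intron_lengths = [e - s for s, e in introns]
    arr = genome.seqs[gene.seq_id]

    def gc_pct(s: int, e: int) -> float:
        seg = arr[s:e]
        gc = int(np.sum((seg == b"G") | (seg == b"C")))
        det = gc + int(np.sum((seg == b"A") | (seg == b"T")))
        return 100.0 * gc / det if det else math.nan

    exon_gcs = [g for g in (gc_pct(s, e) for s, e in exons) if not math.isnan(g)]
    intron_gcs = [g for g in (gc_pct(s, e) for s, e in introns) if not math.isnan(g)]
    return {
        "gene_id": gene.gene_id,
        "unspliced_length": exons[-1][1] - exons[0][0],
        "protein_length": sum(exon_lengths) // 3,
        "exon_count": len(exons),
        "intron_count": len(introns),
        "median_exon_length": float(statistics.median(exon_lengths)),
        "median_intron_length": float(statistics.median(intron_lengths)) if intron_lengths else math.nan,
        "median_exon_gc": float(statistics.median(exon_gcs)) if exon_gcs else math.nan,
        "median_intron_gc": float(statistics.median(intron_gcs)) if intron_gcs else math.nan,
    }


def write_fasta(genome: SimGenome, path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for seq_id, arr in genome.seqs.items():
            fh.write(f">{seq_id}\n")
            s = arr.tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gff3(genes: Sequence[SimGene], path: str | Path, source: str) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            tid = f"{gene.gene_id}-RA"
            fh.write(
                f"{gene.seq_id}\t{source}\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            transcripts = [(tid, gene.exons)]
            if gene.isoform_exons:
                transcripts.append((f"{gene.gene_id}-RB", gene.isoform_exons))
            for t_id, exons in transcripts:
                fh.write(
                    f"{gene.seq_id}\t{source}\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t"
                    f"{gene.strand}\t.\tID={t_id};Parent={gene.gene_id}\n"
                )
                for j, (s, e) in enumerate(exons, 1):
                    fh.write(
                        f"{gene.seq_id}\t{source}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                        f"ID={t_id}.exon{j};Parent={t_id}\n"
                    )
                for j, (s, e) in enumerate(exons, 1):
                    fh.write(
                        f"{gene.seq_id}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t"
                        f"ID={t_id}.cds{j};Parent={t_id}\n"
                    )


def write_provenance_rows(rows: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ogs_id, auto_field, status in rows:
            fh.write(f"{ogs_id}\t{auto_field}\t{status}\n")


@dataclass
class SyntheticBundle:
    genome_path: Path
    auto_path: Path
    ogs_path: Path
    provenance_path: Path
    manifest_path: Path
    manifest: dict


def generate_bundle(
    out_dir: str | Path,
    seed: int,
    genome_config: GenomeConfig | None = None,
    gene_config: GeneModelConfig | None = None,
    perturb_config: PerturbationConfig | None = None,
) -> SyntheticBundle:
    """End-to-end synthetic dataset: FASTA + AUTO/OGS GFF3 + provenance +
    JSON manifest of ground truth."""
    genome_config = genome_config or GenomeConfig()
    gene_config = gene_config or GeneModelConfig()
    perturb_config = perturb_config or PerturbationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = generate_genome(genome_config, seed)
    auto_genes = generate_auto_annotation(genome, gene_config, seed, genome_config)
    ogs_genes, provenance, actions = perturb_to_ogs(auto_genes, genome, perturb_config, seed)

    genome_path = out / "genome.fasta"
    auto_path = out / "auto.gff3"
    ogs_path = out / "ogs.gff3"
    prov_path = out / "provenance.tsv"
    manifest_path = out / "manifest.json"

    write_fasta(genome, genome_path)
    write_gff3(auto_genes, auto_path, source="auto_sim")
    write_gff3(ogs_genes, ogs_path, source="ogs_sim")
    write_provenance_rows(provenance, prov_path)

    manifest = {
        "seed": seed,
        "configs": {
            "genome": asdict(genome_config),
            "genes": asdict(gene_config),
            "perturbation": asdict(perturb_config),
        },
        "auto_truth": [true_properties(g, genome) for g in auto_genes],
        "ogs_truth": [true_properties(g, genome) for g in ogs_genes],
        "actions": [asdict(a) for a in actions],
        "n_intervals": {s: list(map(list, v)) for s, v in genome.n_intervals.items()},
    }
    with manifest_path.open("w") as fh:
        json.dump(manifest, fh)

    return SyntheticBundle(
        genome_path=genome_path,
        auto_path=auto_path,
        ogs_path=ogs_path,
        provenance_path=prov_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )
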