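"""End-to-end orchestration: parse → partition → properties → statistics.

One invocation analyses one species: a genome, its automatic annotation,
its official gene set, and the provenance map linking the two.  The run
emits the full table suite (accounting, per-set properties, medians and
summary metrics, distribution tests, correlations, resampling
classifications) plus a metadata record sufficient to reproduce the run.
All randomness flows from the single configured seed, so identical
configurations produce byte-identical statistical tables.
"""

from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .io import (
    parse_annotation,
    parse_genome,
    parse_provenance,
    write_table,
)
from .metrics import (
    properties_table,
    summaries_frame,
    summary_metrics,
)
from .models import genes_by_id
from .partition import accounting, build_partition, subset_properties
from .resampling import ResamplingConfig, representativeness, resampling_frame
from .stats import compare_all, correlate_all, correlations_frame, tests_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: Path
    auto: Path
    ogs: Path
    provenance: Path
    out_dir: Path
    seed: int = 0
    alpha: float = 0.05
    test_method: str = "auto"
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    run_resampling: bool = True
    label: str = "run"

    def __post_init__(self) -> None:
        for p in (self.genome, self.auto, self.ogs, self.provenance):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class RunReport:
    accounting: pd.DataFrame
    properties: Mapping[str, pd.DataFrame]
    summaries: pd.DataFrame
    tests: pd.DataFrame
    correlations: pd.DataFrame
    resampling: pd.DataFrame
    metadata: dict


def _stage(name: str):
    logger.info("stage: %s", name)


def run_analysis(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _stage("parse")
    try:
        assembly = parse_genome(config.genome)
        auto_models = parse_annotation(config.auto, assembly)
        ogs_models = parse_annotation(config.ogs, assembly)
        provenance = parse_provenance(config.provenance, auto_models, ogs_models)
    except Exception as exc:
        raise RuntimeError(f"stage 'parse' failed: {exc}") from exc

    _stage("partition")
    partition = build_partition(auto_models, ogs_models, provenance)
    acct = accounting(partition)
    acct_frame = pd.DataFrame(
        [
            {
                "n_auto": acct.n_auto,
                "n_ogs": acct.n_ogs,
                "n_auto_sub": acct.n_auto_sub,
                "n_man_sub": acct.n_man_sub,
                "n_man_add": acct.n_man_add,
                "n_unchanged": len(partition.unchanged_ids),
                **acct.rounded(),
            }
        ]
    )

    _stage("properties")
    auto_props = properties_table(auto_models, assembly)
    ogs_props = properties_table(ogs_models, assembly)
    tables = subset_properties(partition, auto_props, ogs_props)
    models_by_label = {
        "AUTO": list(genes_by_id(auto_models).values()),
        "OGS": list(genes_by_id(ogs_models).values()),
    }
    auto_by_id = genes_by_id(auto_models)
    ogs_by_id = genes_by_id(ogs_models)
    models_by_label["AUTO-SUB"] = [auto_by_id[i] for i in sorted(partition.auto_sub_ids)]
    models_by_label["MAN-SUB"] = [ogs_by_id[i] for i in sorted(partition.man_sub_ids)]
    models_by_label["MAN-ADD"] = [ogs_by_id[i] for i in sorted(partition.man_add_ids)]

    _stage("summaries")
    summaries = summaries_frame(
        [
            summary_metrics(tables[label], models_by_label[label], assembly, label)
            for label in tables
            if len(tables[label]) > 0
        ]
    )

    _stage("tests")
    nonempty = {k: v for k, v in tables.items() if len(v) > 0}
    tests = tests_frame(
        compare_all(nonempty, method=config.test_method), alpha=config.alpha
    )
    correlations = correlations_frame(correlate_all(nonempty))

    _stage("resampling")
    if config.run_resampling:
        res = []
        res += representativeness(
            "AUTO", tables["AUTO"], {"AUTO-SUB": tables["AUTO-SUB"]}, config.resampling
        )
        ogs_subsets = {
            k: tables[k] for k in ("MAN-SUB", "MAN-ADD") if len(tables[k]) > 0
        }
        res += representativeness("OGS", tables["OGS"], ogs_subsets, config.resampling)
        resampling_table = resampling_frame(res)
    else:
        resampling_table = pd.DataFrame(
            columns=[
                "full_set_label", "pair", "interval_low", "interval_high",
                "full_set_r", "subset_label", "subset_r", "classification",
            ]
        )

    metadata = {
        "label": config.label,
        "seed": config.seed,
        "alpha": config.alpha,
        "test_method": config.test_method,
        "resampling": {
            "n_replicates": config.resampling.n_replicates,
            "n_subsample": config.resampling.n_subsample,
            "interval_mode": config.resampling.interval_mode,
            "enabled": config.run_resampling,
        },
        "inputs": {
            "genome": str(config.genome),
            "auto": str(config.auto),
            "ogs": str(config.ogs),
            "provenance": str(config.provenance),
        },
        "assembly": {
            "assembly_size": assembly.assembly_size,
            "determined_length": assembly.determined_length,
            "gc_unambiguous": assembly.gc_unambiguous,
        },
        "versions": {"annotcompare": __version__, "python": platform.python_version()},
    }

    _stage("write")
    write_table(acct_frame, out / "partition_accounting.tsv")
    for label, table in tables.items():
        safe = label.lower().replace("-", "_")
        write_table(table.reset_index(drop=True), out / f"properties_{safe}.tsv")
    write_table(summaries, out / "set_summaries.tsv")
    write_table(tests, out / "tests.tsv")
    write_table(correlations, out / "correlations.tsv")
    write_table(resampling_table, out / "resampling.tsv")
    with (out / "run_metadata.json").open("w") as fh:
        json.dump(metadata, fh, indent=1)

    return RunReport(
        accounting=acct_frame,
        properties=tables,
        summaries=summaries,
        tests=tests,
        correlations=correlations,
        resampling=resampling_table,
        metadata=metadata,
    )


def diff_medians(
    medians_a: Mapping[str, float] | pd.Series,
    medians_b: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Signed per-property median differences, b minus a.

    The headline use is MAN-SUB minus AUTO-SUB: how manual annotation
    shifted the set-wide medians.  Properties missing on either side
    yield NA with a warning.
    """
    a = pd.Series(dict(medians_a), dtype=float)
    b = pd.Series(dict(medians_b), dtype=float)
    keys = list(dict.fromkeys(list(a.index) + list(b.index)))
    out = {}
    for k in keys:
        if k not in a.index or k not in b.index:
            logger.warning("diff_medians: property %r missing on one side", k)
            out[k] = math.nan
        else:
            out[k] = float(b[k] - a[k])
    return pd.Series(out)


def diff_reports(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    set_a: str = "AUTO-SUB",
    set_b: str = "MAN-SUB",
) -> pd.Series:
    """Median differences between one set in report A and one in report B.

    Passing the same report twice compares two of its sets (the default
    compares curated models against their predecessors).
    """
    def _row(summaries: pd.DataFrame, label: str) -> pd.Series:
        rows = summaries[summaries["set_label"] == label]
        if len(rows) != 1:
            raise ValueError(f"set label {label!r} not present exactly once")
        row = rows.iloc[0]
        return row[[c for c in summaries.columns if c.startswith("median_")]]

    return diff_medians(_row(summaries_a, set_a), _row(summaries_b, set_b))
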