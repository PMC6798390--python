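"""Five-way gene-set partition and its accounting percentages.

The comparison operates on two full sets and three subsets:

* ``AUTO`` — every automatically predicted gene model;
* ``OGS`` — the official gene set, a non-redundant merge of curated,
  de novo, and unchanged automatic models;
* ``MAN-SUB`` — curated official models that have an automatic
  predecessor;
* ``AUTO-SUB`` — the distinct predecessors of the MAN-SUB models
  (a predecessor shared by several curated models — a split — is
  counted once);
* ``MAN-ADD`` — de novo curated models without a predecessor.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .models import GeneModel, ProvenanceMap

SET_LABELS = ["AUTO", "OGS", "AUTO-SUB", "MAN-SUB", "MAN-ADD"]


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with halves away from zero (report convention), e.g. 0.25 -> 0.3."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(value)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_negate() if value < 0 else d)


@dataclass
class GeneSetPartition:
    auto_ids: set[str]
    ogs_ids: set[str]
    auto_sub_ids: set[str]
    man_sub_ids: set[str]
    man_add_ids: set[str]
    predecessor_map: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not (self.man_sub_ids | self.man_add_ids) <= self.ogs_ids:
            raise ValueError("curated/de novo ids must be official-set ids")
        if self.man_sub_ids & self.man_add_ids:
            raise ValueError("a model cannot be both curated and de novo")
        if not self.auto_sub_ids <= self.auto_ids:
            raise ValueError("predecessor ids must be automatic-set ids")
        flat = {a for preds in self.predecessor_map.values() for a in preds}
        if flat != self.auto_sub_ids:
            raise ValueError("predecessor map values must equal AUTO-SUB")
        if set(self.predecessor_map) != self.man_sub_ids:
            raise ValueError("predecessor map keys must equal MAN-SUB")

    @property
    def unchanged_ids(self) -> set[str]:
        return self.ogs_ids - self.man_sub_ids - self.man_add_ids

    def ids_of(self, label: str) -> set[str]:
        return {
            "AUTO": self.auto_ids,
            "OGS": self.ogs_ids,
            "AUTO-SUB": self.auto_sub_ids,
            "MAN-SUB": self.man_sub_ids,
            "MAN-ADD": self.man_add_ids,
        }[label]


def build_partition(
    auto_models: Sequence[GeneModel],
    ogs_models: Sequence[GeneModel],
    provenance: ProvenanceMap,
) -> GeneSetPartition:
    """Partition the official gene set by curation status.

    Many-to-one and one-to-many predecessor links (merges and splits of
    gene models during curation) are retained in the predecessor map,
    but each predecessor enters AUTO-SUB once.
    """
    auto_ids = {g.gene_id for g in auto_models}
    ogs_ids_list = [g.gene_id for g in ogs_models]
    ogs_ids = set(ogs_ids_list)
    if len(ogs_ids) != len(ogs_ids_list):
        dupes = sorted({i for i in ogs_ids_list if ogs_ids_list.count(i) > 1})
        raise ValueError(f"duplicate official-set gene ids: {dupes}")

    man_sub: set[str] = set()
    man_add: set[str] = set()
    pred_map: dict[str, tuple[str, ...]] = {}
    for rec in provenance:
        if rec.ogs_gene_id not in ogs_ids:
            raise ValueError(f"provenance id {rec.ogs_gene_id} not in official set")
        if rec.status == "manual":
            missing = [a for a in rec.auto_gene_ids if a not in auto_ids]
            if missing:
                raise ValueError(
                    f"predecessor(s) {missing} of {rec.ogs_gene_id} absent from "
                    "the automatic set"
                )
            man_sub.add(rec.ogs_gene_id)
            pred_map[rec.ogs_gene_id] = rec.auto_gene_ids
        elif rec.status == "denovo":
            man_add.add(rec.ogs_gene_id)

    auto_sub = {a for preds in pred_map.values() for a in preds}
    return GeneSetPartition(
        auto_ids=auto_ids,
        ogs_ids=ogs_ids,
        auto_sub_ids=auto_sub,
        man_sub_ids=man_sub,
        man_add_ids=man_add,
        predecessor_map=pred_map,
    )


@dataclass
class PartitionAccounting:
    """Set sizes and the headline percentages of the accounting report.

    ``man_add_pct_of_handled`` is the de novo share of everything that
    passed through a curator's hands (MAN-ADD / (MAN-ADD + MAN-SUB)).
    Percentages are reported rounded to one decimal, half away from
    zero; unrounded values are retained.
    """

    n_auto: int
    n_ogs: int
    n_auto_sub: int
    n_man_sub: int
    n_man_add: int
    auto_sub_pct_of_auto: float
    man_sub_pct_of_ogs: float
    man_add_pct_of_ogs: float
    man_add_pct_of_handled: float

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {
            "auto_sub_pct_of_auto": round_half_away(self.auto_sub_pct_of_auto, ndigits),
            "man_sub_pct_of_ogs": round_half_away(self.man_sub_pct_of_ogs, ndigits),
            "man_add_pct_of_ogs": round_half_away(self.man_add_pct_of_ogs, ndigits),
            "man_add_pct_of_handled": round_half_away(self.man_add_pct_of_handled, ndigits),
        }


def accounting_from_counts(
    n_auto: int, n_ogs: int, n_auto_sub: int, n_man_sub: int, n_man_add: int
) -> PartitionAccounting:
    """Accounting percentages straight from the five set sizes."""
    if n_ogs == 0:
        raise ValueError("official gene set is empty")
    if n_auto == 0:
        raise ValueError("automatic gene set is empty")
    handled = n_man_sub + n_man_add
    return PartitionAccounting(
        n_auto=n_auto,
        n_ogs=n_ogs,
        n_auto_sub=n_auto_sub,
        n_man_sub=n_man_sub,
        n_man_add=n_man_add,
        auto_sub_pct_of_auto=100.0 * n_auto_sub / n_auto,
        man_sub_pct_of_ogs=100.0 * n_man_sub / n_ogs,
        man_add_pct_of_ogs=100.0 * n_man_add / n_ogs,
        man_add_pct_of_handled=(100.0 * n_man_add / handled) if handled else 0.0,
    )


def accounting(partition: GeneSetPartition) -> PartitionAccounting:
    return accounting_from_counts(
        n_auto=len(partition.auto_ids),
        n_ogs=len(partition.ogs_ids),
        n_auto_sub=len(partition.auto_sub_ids),
        n_man_sub=len(partition.man_sub_ids),
        n_man_add=len(partition.man_add_ids),
    )


def subset_properties(
    partition: GeneSetPartition,
    auto_props: pd.DataFrame,
    ogs_props: pd.DataFrame,
) -> Mapping[str, pd.DataFrame]:
    """Slice the per-annotation property tables into the five set tables."""
    tables: dict[str, pd.DataFrame] = {}
    for label, source in [
        ("AUTO", auto_props),
        ("OGS", ogs_props),
        ("AUTO-SUB", auto_props),
        ("MAN-SUB", ogs_props),
        ("MAN-ADD", ogs_props),
    ]:
        ids = sorted(partition.ids_of(label))
        missing = [i for i in ids if i not in source.index]
        if missing:
            raise KeyError(
                f"gene ids in partition set {label} missing from the property "
                f"table: {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        tables[label] = source.loc[ids]
    return tables
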