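"""Distribution tests and rank correlations over gene-set property tables.

Every unordered pair of gene (sub)sets is compared per structural
property with a two-sample Kolmogorov-Smirnov test (sensitive to shape,
spread, and location) and a two-sample Mann-Whitney-Wilcoxon test
(sensitive mainly to location), each Bonferroni-corrected within its own
test family.  Small-sample p-values come from exact permutation
enumeration over all splits of the pooled data — ties and all — mirroring
the exact-test behaviour of R's ``ks.test``/``wilcox.test`` at small n;
larger samples fall back to the classical asymptotic approximations.

Correlative trends are measured with Spearman's rank correlation for the
four canonical property combinations (exon/intron count against the
per-transcript median length and GC content of exons/introns).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import TESTED_PROPERTIES

# Largest number of pooled splits enumerated exactly before switching to
# the asymptotic approximation.
MAX_EXACT_SPLITS = 25_000

CORRELATION_PAIRS = [
    ("exon_count", "median_exon_length"),
    ("exon_count", "median_exon_gc"),
    ("intron_count", "median_intron_length"),
    ("intron_count", "median_intron_gc"),
]


@dataclass(frozen=True)
class TestResult:
    test_name: str  # "KS" or "W"
    set_a: str
    set_b: str
    property: str
    statistic: float
    p_raw: float
    p_adj: float
    n1: int
    n2: int


@dataclass(frozen=True)
class CorrelationRecord:
    set_label: str
    pair: str
    r: float
    n: int


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    return arr


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| over the pooled observed values (ties allowed)."""
    xs, ys = np.sort(x), np.sort(y)
    pooled = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, pooled, side="right") / xs.size
    cdf_y = np.searchsorted(ys, pooled, side="right") / ys.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _split_indices(n: int, n1: int):
    return itertools.combinations(range(n), n1)


def _use_exact(n1: int, n2: int, method: str) -> bool:
    if method == "exact":
        return True
    if method == "asymptotic":
        return False
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    return comb(n1 + n2, n1) <= MAX_EXACT_SPLITS


def ks_two_sample(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample KS test; (D, two-sided p).

    ``method='exact'`` enumerates every split of the pooled sample, which
    is valid under ties; ``'asymptotic'`` uses the Kolmogorov distribution
    with effective size n1*n2/(n1+n2); ``'auto'`` picks exact whenever the
    enumeration stays below ``MAX_EXACT_SPLITS`` splits.
    """
    x, y = _as_array(x, "x"), _as_array(y, "y")
    n1, n2 = x.size, y.size
    d_obs = _ks_statistic(x, y)
    if _use_exact(n1, n2, method):
        pooled = np.concatenate([x, y])
        hits = total = 0
        for idx in _split_indices(n1 + n2, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            d = _ks_statistic(pooled[mask], pooled[~mask])
            hits += d >= d_obs - 1e-12
            total += 1
        p = hits / total
    else:
        en = n1 * n2 / (n1 + n2)
        p = float(sps.kstwobign.sf(math.sqrt(en) * d_obs))
    return d_obs, min(max(p, 0.0), 1.0)


def _rank_sum(ranks: np.ndarray, mask: np.ndarray) -> float:
    return float(ranks[mask].sum())


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample (Mann-Whitney-)Wilcoxon test; (rank-sum W of x, two-sided p).

    Average ranks handle ties.  Exact mode enumerates the permutation
    distribution of the rank sum (two-sided p = 2 * min(lower, upper)
    tail, capped at 1); asymptotic mode uses the normal approximation
    with tie-corrected variance and continuity correction.
    """
    x, y = _as_array(x, "x"), _as_array(y, "y")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())

    if np.all(pooled == pooled[0]):
        return w_obs, 1.0

    if _use_exact(n1, n2, method):
        n = n1 + n2
        sums = []
        for idx in _split_indices(n, n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            sums.append(_rank_sum(ranks, mask))
        sums = np.asarray(sums)
        lower = np.mean(sums <= w_obs + 1e-12)
        upper = np.mean(sums >= w_obs - 1e-12)
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        _, p = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(p)
    return w_obs, min(max(p, 0.0), 1.0)


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: each p becomes min(1, m*p) for family size m."""
    p_values = list(p_values)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < len(p_values):
        raise ValueError(
            f"family size m={m} smaller than the {len(p_values)} p-values it covers"
        )
    return [min(1.0, m * p) for p in p_values]


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation (Pearson correlation of average ranks).

    Pairs with an undefined member are dropped; returns NaN when either
    ranked vector has zero variance or fewer than two pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2:
        return math.nan
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return math.nan
    return float(sps.spearmanr(x, y).statistic)


def compare_all(
    sets: Mapping[str, pd.DataFrame],
    properties: Sequence[str] = tuple(TESTED_PROPERTIES),
    method: str = "auto",
) -> list[TestResult]:
    """KS and Wilcoxon tests for every unordered set pair and property.

    Each test family (all KS tests, all Wilcoxon tests of one invocation)
    is Bonferroni-corrected by its own size.
    """
    if len(sets) < 2:
        raise ValueError("need at least two gene sets to compare")
    labels = list(sets)
    raw: list[tuple[str, str, str, str, float, float, int, int]] = []
    for la, lb in itertools.combinations(labels, 2):
        for prop in properties:
            for table, lab in ((sets[la], la), (sets[lb], lb)):
                if prop not in table.columns:
                    raise KeyError(f"property {prop!r} absent from set {lab}")
            x = sets[la][prop].dropna().to_numpy(dtype=float)
            y = sets[lb][prop].dropna().to_numpy(dtype=float)
            if x.size == 0 or y.size == 0:
                # property undefined throughout one set (e.g. intron medians
                # of an all-single-exon subset): NA record, outside the family
                raw.append(("KS", la, lb, prop, math.nan, math.nan, x.size, y.size))
                raw.append(("W", la, lb, prop, math.nan, math.nan, x.size, y.size))
                continue
            d, p_ks = ks_two_sample(x, y, method=method)
            w, p_w = wilcoxon_rank_sum(x, y, method=method)
            raw.append(("KS", la, lb, prop, d, p_ks, x.size, y.size))
            raw.append(("W", la, lb, prop, w, p_w, x.size, y.size))

    results: list[TestResult] = []
    for family in ("KS", "W"):
        fam = [r for r in raw if r[0] == family]
        defined = [r for r in fam if not math.isnan(r[5])]
        adj = dict(
            zip(
                [id(r) for r in defined],
                bonferroni([r[5] for r in defined], m=len(defined)),
            )
        ) if defined else {}
        for r in fam:
            name, la, lb, prop, stat, p, n1, n2 = r
            results.append(
                TestResult(name, la, lb, prop, stat, p, adj.get(id(r), math.nan), n1, n2)
            )
    return results


def correlate_all(
    sets: Mapping[str, pd.DataFrame],
    pairs: Sequence[tuple[str, str]] = tuple(CORRELATION_PAIRS),
) -> list[CorrelationRecord]:
    """Spearman r of each property combination in each set.

    Intron-based pairs are computed over transcripts with at least one
    intron; sets with fewer than two usable pairs yield an NA record.
    """
    records: list[CorrelationRecord] = []
    for label, table in sets.items():
        for xcol, ycol in pairs:
            sub = table
            if xcol == "intron_count":
                sub = sub[sub["intron_count"] >= 1]
            x = sub[xcol].to_numpy(dtype=float)
            y = sub[ycol].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            n = int(keep.sum())
            r = spearman_rho(x, y) if n >= 2 else math.nan
            records.append(CorrelationRecord(label, f"{xcol}~{ycol}", r, n))
    return records


def tests_frame(results: Sequence[TestResult], alpha: float = 0.05) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    df["significant"] = df["p_adj"] <= alpha
    return df


def correlations_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
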