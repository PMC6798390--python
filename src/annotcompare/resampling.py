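"""Subsampling-based representativeness intervals for correlation coefficients.

Gene subsets chosen for manual curation are tiny against the full gene
set, so their Spearman coefficients cannot be compared to the full-set
coefficient directly.  Instead the full set is repeatedly subsampled
without replacement at a fixed size (default 1000 draws of 1000 models),
the correlation of each subsample is computed, and the spread of those
coefficients forms an interval.  A subset whose coefficient falls inside
the interval is structurally representative of the full set for that
property combination; one that falls below or above is not.

Membership may overlap between replicates — sampling is without
replacement only within a replicate.  The default interval is the
min–max range of the resampled coefficients (a value can then be called
"lower than the interval minimum"); a percentile mode is available for
robustness against single extreme replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import CORRELATION_PAIRS, spearman_rho


@dataclass
class ResamplingConfig:
    n_replicates: int = 1000
    n_subsample: int = 1000
    seed: int = 0
    interval_mode: str = "range"  # "range" or "percentile"
    percentile_bounds: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_subsample < 2:
            raise ValueError("n_subsample must be >= 2")
        if self.interval_mode not in ("range", "percentile"):
            raise ValueError(f"unknown interval_mode {self.interval_mode!r}")


@dataclass
class ResamplingResult:
    full_set_label: str
    pair: str
    r_samples: np.ndarray
    interval: tuple[float, float]
    full_set_r: float
    subset_r: dict[str, float] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)


def _usable_pairs(table: pd.DataFrame, xcol: str, ycol: str) -> tuple[np.ndarray, np.ndarray]:
    sub = table
    if xcol == "intron_count":
        sub = sub[sub["intron_count"] >= 1]
    x = sub[xcol].to_numpy(dtype=float)
    y = sub[ycol].to_numpy(dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def subsample_r(
    full_table: pd.DataFrame,
    pair: tuple[str, str],
    config: ResamplingConfig,
) -> np.ndarray:
    """Spearman r of ``n_replicates`` fixed-size subsamples without replacement.

    Each replicate draws from its own deterministic child stream of the
    master seed, so replicate k is identical no matter how many
    replicates are requested.
    """
    xcol, ycol = pair
    x, y = _usable_pairs(full_table, xcol, ycol)
    n = x.size
    if n < config.n_subsample:
        raise ValueError(
            f"table provides {n} usable pairs for {xcol}~{ycol}, fewer than the "
            f"subsample size {config.n_subsample}; lower n_subsample"
        )
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    out = np.empty(config.n_replicates)
    for k, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        idx = rng.choice(n, size=config.n_subsample, replace=False)
        out[k] = spearman_rho(x[idx], y[idx])
    return out


def interval(r_samples: np.ndarray, config: ResamplingConfig) -> tuple[float, float]:
    """Interval of the resampled coefficients per the configured mode."""
    r_samples = np.asarray(r_samples, dtype=float)
    if r_samples.size == 0:
        raise ValueError("no resampled coefficients")
    if config.interval_mode == "range":
        return float(np.min(r_samples)), float(np.max(r_samples))
    lo, hi = config.percentile_bounds
    low, high = np.percentile(r_samples, [lo, hi], method="linear")
    return float(low), float(high)


def classify(subset_r: float, bounds: tuple[float, float]) -> str:
    """Classify a subset coefficient against an interval.

    Boundary equality counts as inside; an undefined coefficient yields
    an NA classification.
    """
    if subset_r is None or math.isnan(subset_r):
        return "NA"
    low, high = bounds
    if subset_r < low:
        return "outside_low"
    if subset_r > high:
        return "outside_high"
    return "inside"


def representativeness(
    full_label: str,
    full_table: pd.DataFrame,
    subset_tables: Mapping[str, pd.DataFrame],
    config: ResamplingConfig,
    pairs: Sequence[tuple[str, str]] = tuple(CORRELATION_PAIRS),
) -> list[ResamplingResult]:
    """Full resampling procedure for one full set against its subsets."""
    results = []
    for i, pair in enumerate(pairs):
        # distinct, stable seed per pair so pairs are independent streams
        cfg = ResamplingConfig(
            n_replicates=config.n_replicates,
            n_subsample=config.n_subsample,
            seed=int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)),
            interval_mode=config.interval_mode,
            percentile_bounds=config.percentile_bounds,
        )
        samples = subsample_r(full_table, pair, cfg)
        bounds = interval(samples, cfg)
        fx, fy = _usable_pairs(full_table, *pair)
        res = ResamplingResult(
            full_set_label=full_label,
            pair=f"{pair[0]}~{pair[1]}",
            r_samples=samples,
            interval=bounds,
            full_set_r=spearman_rho(fx, fy),
        )
        for label, table in subset_tables.items():
            sx, sy = _usable_pairs(table, *pair)
            r = spearman_rho(sx, sy) if sx.size >= 2 else math.nan
            res.subset_r[label] = r
            res.classification[label] = classify(r, bounds)
        results.append(res)
    return results


def resampling_frame(results: Sequence[ResamplingResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        base = {
            "full_set_label": res.full_set_label,
            "pair": res.pair,
            "interval_low": res.interval[0],
            "interval_high": res.interval[1],
            "full_set_r": res.full_set_r,
        }
        if not res.subset_r:
            rows.append({**base, "subset_label": "NA", "subset_r": math.nan, "classification": "NA"})
        for label in res.subset_r:
            rows.append(
                {
                    **base,
                    "subset_label": label,
                    "subset_r": res.subset_r[label],
                    "classification": res.classification[label],
                }
            )
    return pd.DataFrame(rows)
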