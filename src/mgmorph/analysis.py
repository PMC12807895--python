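"""Cell-level classification and cohort summaries.

A *reactive* microglia is an operational call made with three simple
thresholds: CD68-positive area >= 35% of the cell, branching index >= 1
(at least one skeleton branch point), and a nucleus centroid strictly less
than 25 μm from another nucleus centroid.  Cells with no neighbor distance
(isolated nuclei) are never reactive.

The decile analysis sorts all cells by one morphometric feature, partitions
them into ten near-equal contiguous groups and reports the mean CD68 area
fraction and mean Iba1 intensity per group and genotype — a
nonparametric look at how marker expression co-varies with morphology.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_REACTIVE_COLUMNS = (
    "cd68_area_fraction",
    "branching_index",
    "min_nucleus_neighbor_um",
)


class SchemaError(KeyError):
    """The feature table lacks a column an operation needs."""


def _require(table: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")


def classify_reactive(
    table: pd.DataFrame,
    cd68_min_pct: float = 35.0,
    bi_min: int = 1,
    clump_um: float = 25.0,
) -> pd.Series:
    """Boolean reactive flag per cell.

    ``cd68_area_fraction`` is stored in [0, 1] and compared against
    ``cd68_min_pct`` percent (inclusive); ``branching_index >= bi_min``
    (inclusive); ``min_nucleus_neighbor_um < clump_um`` (strict, NaN => not
    reactive).
    """
    _require(table, REQUIRED_REACTIVE_COLUMNS)
    cd68_ok = table["cd68_area_fraction"] * 100.0 >= cd68_min_pct
    bi_ok = table["branching_index"] >= bi_min
    neighbor = table["min_nucleus_neighbor_um"]
    clump_ok = neighbor.notna() & (neighbor < clump_um)
    return (cd68_ok & bi_ok & clump_ok).rename("reactive")


def decile_partition(values: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Decile index (1..n_bins) per row under a stable ascending sort.

    Group sizes are ``ceil(N/n)`` for the first ``N mod n`` groups and
    ``floor(N/n)`` for the rest; ties keep input order (stable sort).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} rows, got {n}")
    if np.isnan(values).any():
        raise ValueError("sort feature contains missing values")
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    out = np.empty(n, dtype=int)
    start = 0
    for i, size in enumerate(sizes, start=1):
        out[order[start : start + size]] = i
        start += size
    return out


def decile_analysis(
    table: pd.DataFrame, sort_feature: str, n_bins: int = 10
) -> pd.DataFrame:
    """Mean CD68 fraction and Iba1 intensity per decile x genotype.

    Returns a tidy frame with columns ``sort_feature, decile, genotype,
    mean_cd68_area_fraction, mean_iba1_mean, n``.
    """
    _require(table, [sort_feature, "cd68_area_fraction", "iba1_mean_au", "genotype"])
    deciles = decile_partition(table[sort_feature].to_numpy(), n_bins)
    work = table.assign(decile=deciles)
    grouped = (
        work.groupby(["decile", "genotype"], observed=True)
        .agg(
            mean_cd68_area_fraction=("cd68_area_fraction", "mean"),
            mean_iba1_mean=("iba1_mean_au", "mean"),
            n=("cd68_area_fraction", "size"),
        )
        .reset_index()
    )
    grouped.insert(0, "sort_feature", sort_feature)
    return grouped


def summarize_by_region(
    table: pd.DataFrame, statistic: str = "median"
) -> pd.DataFrame:
    """Per-(animal, region) summary of every numeric feature.

    The default (median) is the robust animal-level reduction used for group
    comparisons; empty groups are simply absent.
    """
    _require(table, ["animal_id", "region"])
    numeric = table.select_dtypes(include=[np.number, bool]).columns
    grouped = table.groupby(["animal_id", "region"], observed=True)[list(numeric)]
    if statistic == "median":
        out = grouped.median(numeric_only=True)
    elif statistic == "mean":
        out = grouped.mean(numeric_only=True)
    else:
        raise ValueError(f"unsupported statistic {statistic!r}")
    return out.reset_index()


_PROFILE_FEATURES = (
    "area_um2",
    "hull_area_um2",
    "skeleton_length_um",
    "critical_radius_um",
    "circularity",
    "solidity",
    "branch_thickness_um",
    "iba1_mean_au",
    "cd68_area_fraction",
)


def reactive_profile(
    table: pd.DataFrame,
    region: Optional[str] = "CA1",
    features: Sequence[str] = _PROFILE_FEATURES,
) -> pd.DataFrame:
    """Reactive vs. homeostatic feature summary for one region.

    Returns one row per feature with per-group median and quartiles and the
    directional median delta (reactive − homeostatic).  Hypothesis testing is
    deliberately left to external statistics packages.
    """
    _require(table, ["reactive"])
    work = table
    if region is not None:
        _require(table, ["region"])
        work = table[table["region"] == region]
    features = [f for f in features if f in work.columns]
    reactive = work[work["reactive"].astype(bool)]
    homeo = work[~work["reactive"].astype(bool)]
    if reactive.empty:
        logger.info("no reactive cells in region %r", region)
    rows: List[dict] = []
    for feat in features:
        r = reactive[feat].dropna()
        h = homeo[feat].dropna()
        row = {
            "feature": feat,
            "n_reactive": len(r),
            "n_homeostatic": len(h),
            "reactive_median": r.median() if len(r) else np.nan,
            "reactive_q1": r.quantile(0.25) if len(r) else np.nan,
            "reactive_q3": r.quantile(0.75) if len(r) else np.nan,
            "homeostatic_median": h.median() if len(h) else np.nan,
            "homeostatic_q1": h.quantile(0.25) if len(h) else np.nan,
            "homeostatic_q3": h.quantile(0.75) if len(h) else np.nan,
        }
        row["delta_median"] = row["reactive_median"] - row["homeostatic_median"]
        rows.append(row)
    return pd.DataFrame(rows)
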