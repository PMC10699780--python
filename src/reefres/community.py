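"""Benthic community composition, Bray-Curtis recovery distance, and recruit
density estimates."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colony import EffectEstimate
from .config import BENTHIC_CATEGORIES

__all__ = [
    "BenthicComposition",
    "proportional_cover",
    "compositions_table",
    "bray_curtis",
    "dissimilarity_to_baseline",
    "recruit_density",
]


@dataclass
class BenthicComposition:
    """Category proportions for one island-year, pooled across transects."""

    island_id: str
    year: int
    proportions: pd.Series  # indexed by category, sums to 1
    per_transect: pd.DataFrame | None = None  # transect x category proportions

    def __post_init__(self):
        p = self.proportions.to_numpy(dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")


def proportional_cover(
    point_records: pd.DataFrame, island: str, year: int
) -> BenthicComposition:
    """Pooled category proportions for one island-year from point-intercept
    counts (``island_id``, ``year``, ``transect``, ``category``, ``count``)."""
    sub = point_records[
        (point_records["island_id"] == island) & (point_records["year"] == year)
    ]
    if sub.empty:
        raise ValueError(f"no benthic records for island {island!r} in {year}")
    pooled = sub.groupby("category")["count"].sum()
    pooled = pooled.reindex(
        [c for c in BENTHIC_CATEGORIES if c in pooled.index] +
        sorted(set(pooled.index) - set(BENTHIC_CATEGORIES))
    )
    per_transect = (
        sub.pivot_table(
            index="transect", columns="category", values="count",
            aggfunc="sum", fill_value=0,
        )
        .apply(lambda row: row / row.sum(), axis=1)
    )
    return BenthicComposition(
        island_id=island,
        year=int(year),
        proportions=pooled / pooled.sum(),
        per_transect=per_transect,
    )


def compositions_table(point_records: pd.DataFrame) -> list[BenthicComposition]:
    """One :class:`BenthicComposition` per observed island-year."""
    keys = point_records[["island_id", "year"]].drop_duplicates()
    return [
        proportional_cover(point_records, rec.island_id, rec.year)
        for rec in keys.itertuples(index=False)
    ]


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity ``1 - 2 sum(min(a, b)) / sum(a + b)``.

    Accepts aligned vectors or category-indexed Series; mismatched category
    sets raise.
    """
    if isinstance(a, BenthicComposition):
        a = a.proportions
    if isinstance(b, BenthicComposition):
        b = b.proportions
    if isinstance(a, pd.Series) or isinstance(b, pd.Series):
        a = pd.Series(a)
        b = pd.Series(b)
        if set(a.index) != set(b.index):
            raise ValueError("compositions have mismatched categories")
        b = b.reindex(a.index)
        a = a.to_numpy(dtype=float)
        b = b.to_numpy(dtype=float)
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("compositions have mismatched categories")
    total = (a + b).sum()
    if total == 0:
        return 0.0
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / total)


def dissimilarity_to_baseline(
    point_records: pd.DataFrame, baseline_year: int = 2015
) -> pd.DataFrame:
    """Bray-Curtis distance of each island-year to that island's pre-bleaching
    baseline, on island-pooled proportions."""
    rows = []
    for island, sub in point_records.groupby("island_id", sort=True):
        years = sorted(sub["year"].unique())
        if baseline_year not in years:
            raise ValueError(f"island {island!r} lacks the {baseline_year} baseline")
        base = proportional_cover(point_records, island, baseline_year)
        treatment = sub.iloc[0].get("treatment", "")
        for year in years:
            if year == baseline_year:
                continue
            comp = proportional_cover(point_records, island, year)
            rows.append(
                dict(
                    island_id=island,
                    treatment=treatment,
                    year=int(year),
                    distance=bray_curtis(base, comp),
                )
            )
    return pd.DataFrame(rows)


def recruit_density(
    quadrat_counts: pd.DataFrame,
    genus_filter: str = "Acropora",
    *,
    quadrat_area: float = 0.25,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    interval: float = 0.95,
) -> dict[str, EffectEstimate]:
    """Recruit density per treatment (recruits m^-2) by stratified bootstrap.

    Island density = total counts / (n_quadrats * quadrat_area).  The point
    estimate is the median of the stratified bootstrap distribution of the
    mean island density (islands resampled with replacement within
    treatment).  The interval is the percentile interval of a two-stage
    hierarchical bootstrap (islands, then quadrats within each resampled
    island): with a handful of islands per treatment, a single-stage
    percentile interval is far too narrow for sparse counts.
    """
    if quadrat_area <= 0:
        raise ValueError("quadrat_area must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(int(seed)))
    )
    sub = quadrat_counts[quadrat_counts["genus"] == genus_filter]
    if sub.empty:
        raise ValueError(f"no quadrat records for genus {genus_filter!r}")
    out: dict[str, EffectEstimate] = {}
    for treatment, grp in sub.groupby("treatment", sort=True):
        counts_by_island = [
            g["count"].to_numpy(dtype=float)
            for _, g in grp.groupby("island_id", sort=True)
        ]
        if any(c.size == 0 for c in counts_by_island):
            raise ValueError("island with zero quadrats")
        densities = np.array(
            [c.mean() / quadrat_area for c in counts_by_island]
        )
        k = densities.size
        ii = rng.integers(0, k, size=(n_boot, k))
        stats_islands = densities[ii].mean(axis=1)
        point = float(np.median(stats_islands))
        if k > 1 and np.ptp(densities) > 0:
            # two-stage resample: one fresh quadrat-level mean per
            # (replicate, slot) for every island
            pools = np.empty((k, n_boot, k))
            for j, cj in enumerate(counts_by_island):
                idx = rng.integers(0, cj.size, size=(n_boot, k, cj.size))
                pools[j] = cj[idx].mean(axis=2) / quadrat_area
            gather = pools[
                ii, np.arange(n_boot)[:, None], np.arange(k)[None, :]
            ]
            stats2 = gather.mean(axis=1)
            lo, hi = np.quantile(
                stats2, [(1 - interval) / 2, 1 - (1 - interval) / 2]
            )
        else:  # degenerate (single island or identical densities)
            lo = hi = point
        out[treatment] = EffectEstimate(
            point=point,
            interval_lo=min(float(lo), point),
            interval_hi=max(float(hi), point),
            scale="additive",
            draws=stats_islands,
        )
    return out
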