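"""Colony-scale growth and isotope analyses.

Planar-area growth rates, symbiont-d15N acclimation summaries, and
hierarchical Bayesian contrasts (treatment effects and the growth-on-d15N
slope) built on :mod:`reefres.bayes`.  Fold-change effects are estimated on
the log scale; d15N differences on the raw per-mil scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import fit_hierarchical_normal

__all__ = [
    "EffectEstimate",
    "planar_growth_rate",
    "interval_growth_rates",
    "isotope_cell_medians",
    "hierarchical_contrast",
    "growth_isotope_slope",
    "transplant_growth_contrast",
    "natural_growth_contrast",
    "isotope_treatment_contrast",
]

DAYS_PER_YEAR = 365.25


@dataclass
class EffectEstimate:
    """A contrast summarized as posterior median and central interval."""

    point: float
    interval_lo: float
    interval_hi: float
    scale: str  # "additive" or "multiplicative"
    n_excluded: int = 0
    draws: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.interval_lo <= self.point <= self.interval_hi:
            raise ValueError("interval must bracket the point estimate")

    def covers(self, value: float) -> bool:
        return self.interval_lo <= value <= self.interval_hi


def planar_growth_rate(area_start: float, area_end: float, days: float) -> float:
    """Annualized planar-area growth: ``(area_end - area_start) / days * 365.25``.

    Negative values (shrinkage or partial mortality) are legitimate output.
    """
    if days <= 0:
        raise ValueError("days must be positive")
    if area_start <= 0 or area_end <= 0:
        raise ValueError("planar areas must be positive")
    return (area_end - area_start) / days * DAYS_PER_YEAR


def interval_growth_rates(colonies: pd.DataFrame) -> pd.DataFrame:
    """Per-colony growth rates between consecutive survey dates.

    Expects the long colony table (one row per colony visit with
    ``planar_area_cm2`` and ISO ``date``); returns one row per measurement
    interval with the annualized rate and the planar area at the interval
    start (the size covariate of the growth models).
    """
    required = {"colony_id", "date", "planar_area_cm2"}
    missing = required - set(colonies.columns)
    if missing:
        raise ValueError(f"colony table missing columns {sorted(missing)}")
    frames = []
    label_cols = [
        c
        for c in ("island_id", "atoll_id", "treatment", "mode", "origin", "transplant")
        if c in colonies.columns
    ]
    for colony_id, grp in colonies.groupby("colony_id", sort=True):
        grp = grp.sort_values("date")
        dates = pd.to_datetime(grp["date"]).to_numpy()
        if np.any(np.diff(dates) <= np.timedelta64(0, "D")):
            raise ValueError(f"dates not strictly increasing for colony {colony_id}")
        areas = grp["planar_area_cm2"].to_numpy(dtype=float)
        if np.any(areas <= 0):
            raise ValueError(f"non-positive planar area for colony {colony_id}")
        labels = {c: grp.iloc[0][c] for c in label_cols}
        for k in range(len(grp) - 1):
            days = (dates[k + 1] - dates[k]) / np.timedelta64(1, "D")
            frames.append(
                dict(
                    colony_id=colony_id,
                    **labels,
                    year_end=pd.Timestamp(dates[k + 1]).year,
                    days=float(days),
                    prior_area_cm2=areas[k],
                    growth_cm2_yr=planar_growth_rate(areas[k], areas[k + 1], days),
                )
            )
    return pd.DataFrame(frames)


def isotope_cell_medians(
    samples: pd.DataFrame, colonies: pd.DataFrame
) -> pd.DataFrame:
    """Median symbiont d15N by origin x transplant x year.

    Every sample must join to a colony record; orphan samples raise.  The
    full factorial grid is returned, with empty cells flagged (``n = 0``,
    ``median = NaN``) rather than dropped.
    """
    meta = colonies.drop_duplicates("colony_id")[
        ["colony_id", "origin", "transplant"]
    ]
    orphans = set(samples["colony_id"]) - set(meta["colony_id"])
    if orphans:
        raise ValueError(
            f"isotope samples reference unknown colonies: {sorted(orphans)[:5]}"
        )
    joined = samples.merge(meta, on="colony_id", how="left")
    grouped = (
        joined.groupby(["origin", "transplant", "year"])["d15n"]
        .agg(["median", "count"])
        .rename(columns={"median": "median_d15n", "count": "n"})
    )
    grid = pd.MultiIndex.from_product(
        [
            sorted(joined["origin"].unique()),
            sorted(joined["transplant"].unique()),
            sorted(joined["year"].unique()),
        ],
        names=["origin", "transplant", "year"],
    )
    out = grouped.reindex(grid).reset_index()
    out["n"] = out["n"].fillna(0).astype(int)
    out["empty"] = out["n"] == 0
    return out


def _factor_design(
    df: pd.DataFrame,
    factor: str,
    average_over: str | None,
    covariates: tuple[str, ...],
):
    """Treatment-coded design matrix plus a prediction-row builder."""
    n = len(df)
    levels_f = sorted(df[factor].astype(str).unique())
    if len(levels_f) < 2:
        raise ValueError(f"factor {factor!r} needs at least two levels")
    cols = [np.ones(n)]
    names = ["intercept"]
    fvals = df[factor].astype(str).to_numpy()
    for lv in levels_f[1:]:
        cols.append((fvals == lv).astype(float))
        names.append(f"{factor}[{lv}]")
    levels_a: list[str] = []
    if average_over is not None:
        levels_a = sorted(df[average_over].astype(str).unique())
        avals = df[average_over].astype(str).to_numpy()
        for la in levels_a[1:]:
            cols.append((avals == la).astype(float))
            names.append(f"{average_over}[{la}]")
        for lv in levels_f[1:]:
            for la in levels_a[1:]:
                cols.append(((fvals == lv) & (avals == la)).astype(float))
                names.append(f"{factor}[{lv}]:{average_over}[{la}]")
    centers = {}
    for cov in covariates:
        vals = df[cov].to_numpy(dtype=float)
        centers[cov] = float(vals.mean())
        cols.append(vals - centers[cov])
        names.append(cov)
    X = np.column_stack(cols)

    def prediction_row(f_level: str, a_level: str | None = None) -> np.ndarray:
        row = np.zeros(len(names))
        row[0] = 1.0
        for j, name in enumerate(names):
            if name == f"{factor}[{f_level}]":
                row[j] = 1.0
            if a_level is not None and name == f"{average_over}[{a_level}]":
                row[j] = 1.0
            if (
                a_level is not None
                and name == f"{factor}[{f_level}]:{average_over}[{a_level}]"
            ):
                row[j] = 1.0
        return row

    return X, names, levels_f, levels_a, prediction_row


def hierarchical_contrast(
    df: pd.DataFrame,
    outcome: str,
    factor: str,
    *,
    between: tuple[str, str] = ("seabird", "rat"),
    average_over: str | None = None,
    covariates: tuple[str, ...] = (),
    groups: tuple[str, ...] = ("atoll_id", "island_id"),
    log_scale: bool = False,
    drop_nonpositive: bool = False,
    draws: int = 3000,
    burn: int = 1000,
    chains: int = 4,
    seed: int = 0,
    interval: float = 0.95,
) -> EffectEstimate:
    """Hierarchical factor contrast with island-within-atoll style grouping.

    Returns the ``between[0]`` minus ``between[1]`` contrast: a difference on
    the outcome scale, or a fold-change if ``log_scale``.  With
    ``average_over`` the contrast is marginalized with equal weight over the
    levels of a second factor (including its interaction with ``factor``).
    Non-positive outcomes under ``log_scale`` raise unless
    ``drop_nonpositive``, in which case they are excluded and counted.
    """
    df = df.copy()
    y = df[outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    n_excluded = 0
    if log_scale:
        mask = y > 0
        n_excluded = int((~mask).sum())
        if n_excluded and not drop_nonpositive:
            raise ValueError(
                f"{n_excluded} non-positive outcomes under log_scale; "
                "set drop_nonpositive to exclude them"
            )
        df = df.loc[mask]
        y = np.log(y[mask])
    present = set(df[factor].astype(str).unique())
    for level in between:
        if level not in present:
            raise ValueError(f"factor level {level!r} has no data")

    X, _, _, levels_a, prow = _factor_design(df, factor, average_over, tuple(covariates))
    group_codes = {
        g: pd.factorize(df[g], sort=True)[0] for g in groups if g in df.columns
    }
    fit = fit_hierarchical_normal(
        y, X, group_codes, draws=draws, burn=burn, chains=chains, seed=seed
    )
    if average_over is None:
        c = prow(between[0]) - prow(between[1])
    else:
        c = np.mean(
            [prow(between[0], la) - prow(between[1], la) for la in levels_a], axis=0
        )
    diff = fit.beta @ c
    if log_scale:
        diff = np.exp(diff)
    lo, hi = np.quantile(diff, [(1 - interval) / 2, 1 - (1 - interval) / 2])
    return EffectEstimate(
        point=float(np.median(diff)),
        interval_lo=float(lo),
        interval_hi=float(hi),
        scale="multiplicative" if log_scale else "additive",
        n_excluded=n_excluded,
        draws=diff,
    )


def growth_isotope_slope(
    growth: pd.DataFrame,
    isotopes: pd.DataFrame,
    *,
    size_covariate: str = "prior_area_cm2",
    isotope_year: int = 2021,
    draws: int = 3000,
    burn: int = 1000,
    chains: int = 4,
    seed: int = 0,
    interval: float = 0.95,
) -> EffectEstimate:
    """Multiplicative change in colony growth per one-unit increase in d15N.

    Joins each colony's final-interval growth rate to its ``isotope_year``
    symbiont d15N and fits a log-linear hierarchical model controlling for
    the planar area at the interval start, colony type (when both natural and
    experimental colonies are present) and island treatment.  Conditioning on
    treatment separates the colony-level nutrient effect from island-scale
    treatment effects, which are otherwise confounded with the between-island
    d15N gradient.
    """
    iso = isotopes.loc[isotopes["year"] == isotope_year, ["colony_id", "d15n"]]
    last = growth.loc[growth.groupby("colony_id")["year_end"].idxmax()]
    df = last.merge(iso, on="colony_id", how="inner")
    if df["d15n"].nunique() < 3:
        raise ValueError("need at least 3 distinct d15N values to identify the slope")
    mask = df["growth_cm2_yr"] > 0
    n_excluded = int((~mask).sum())
    df = df.loc[mask].copy()
    y = np.log(df["growth_cm2_yr"].to_numpy(dtype=float))
    n = len(df)
    cols = [np.ones(n), df["d15n"].to_numpy(float) - df["d15n"].mean()]
    names = ["intercept", "d15n"]
    # contextual (site-mean) d15N term: identifies the colony-level slope
    # from within-site variation, separating it from between-site gradients
    if "island_id" in df.columns:
        site_key = df["island_id"].astype(str)
        if "mode" in df.columns:
            site_key = site_key + "|" + df["mode"].astype(str)
        site_mean = df.groupby(site_key.to_numpy())["d15n"].transform("mean")
        cols.append(site_mean.to_numpy(float) - site_mean.mean())
        names.append("d15n_site_mean")
    cols.append(
        df[size_covariate].to_numpy(float) / 100.0
        - df[size_covariate].mean() / 100.0
    )
    names.append(size_covariate)
    has_mode = "mode" in df.columns and df["mode"].nunique() > 1
    has_treat = "treatment" in df.columns and df["treatment"].nunique() > 1
    if has_mode:
        natural = (df["mode"].astype(str) == "natural").to_numpy(float)
        cols.append(natural)
        names.append("mode[natural]")
    if has_treat:
        seabird = (df["treatment"].astype(str) == "seabird").to_numpy(float)
        cols.append(seabird)
        names.append("treatment[seabird]")
    if has_mode and has_treat:
        cols.append(natural * seabird)
        names.append("mode[natural]:treatment[seabird]")
    X = np.column_stack(cols)
    # grouping: atoll, and the island x colony-type sampling unit
    if "island_id" in df.columns:
        site = df["island_id"].astype(str)
        if "mode" in df.columns:
            site = site + "|" + df["mode"].astype(str)
    group_codes = {}
    if "atoll_id" in df.columns:
        group_codes["atoll_id"] = pd.factorize(df["atoll_id"], sort=True)[0]
    if "island_id" in df.columns:
        group_codes["site"] = pd.factorize(site, sort=True)[0]
    fit = fit_hierarchical_normal(
        y, X, group_codes, draws=draws, burn=burn, chains=chains, seed=seed
    )
    slope = np.exp(fit.beta[:, names.index("d15n")])
    lo, hi = np.quantile(slope, [(1 - interval) / 2, 1 - (1 - interval) / 2])
    return EffectEstimate(
        point=float(np.median(slope)),
        interval_lo=float(lo),
        interval_hi=float(hi),
        scale="multiplicative",
        n_excluded=n_excluded,
        draws=slope,
    )


# --- study-design wrappers -------------------------------------------------


def transplant_growth_contrast(colonies: pd.DataFrame, **kwargs) -> EffectEstimate:
    """Fold-change in experimental colony growth by transplant treatment,
    averaged with equal weight over origin treatment (colony-within-atoll and
    year grouping)."""
    growth = interval_growth_rates(colonies[colonies["mode"] == "experimental"])
    kwargs.setdefault("groups", ("atoll_id", "colony_id", "year_end"))
    return hierarchical_contrast(
        growth,
        "growth_cm2_yr",
        "transplant",
        average_over="origin",
        covariates=("prior_area_cm2",),
        log_scale=True,
        drop_nonpositive=True,
        **kwargs,
    )


def natural_growth_contrast(colonies: pd.DataFrame, **kwargs) -> EffectEstimate:
    """Fold-change in natural colony growth around seabird vs rat islands
    (year and colony within island within atoll grouping)."""
    growth = interval_growth_rates(colonies[colonies["mode"] == "natural"])
    kwargs.setdefault("groups", ("atoll_id", "island_id", "colony_id", "year_end"))
    return hierarchical_contrast(
        growth,
        "growth_cm2_yr",
        "treatment",
        covariates=("prior_area_cm2",),
        log_scale=True,
        drop_nonpositive=True,
        **kwargs,
    )


def isotope_treatment_contrast(
    isotopes: pd.DataFrame,
    colonies: pd.DataFrame,
    *,
    year: int = 2018,
    **kwargs,
) -> EffectEstimate:
    """Additive seabird-minus-rat difference in natural-colony symbiont d15N
    (one sample per colony, island within atoll grouping)."""
    meta = colonies.loc[
        colonies["mode"] == "natural",
        ["colony_id", "island_id", "atoll_id", "treatment"],
    ].drop_duplicates("colony_id")
    df = isotopes.loc[isotopes["year"] == year].merge(meta, on="colony_id", how="inner")
    return hierarchical_contrast(df, "d15n", "treatment", **kwargs)
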