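"""Synthetic field-survey generator.

Emulates the study design around the rat-free ("seabird") and rat-infested
("rat") islands: tagged *Acropora* colonies with annual planar areas and
symbiont d15N (natural colonies and a reciprocal transplant experiment),
recruit quadrat counts with excess zeros, point-intercept benthic surveys over
nine functional groups, and per-island *Acropora* cover endpoints for the
trajectory reconstruction.  Treatment effects are injected on the log scale
for growth (the study reports fold-changes) and on the raw per-mil scale for
d15N (the study reports additive differences).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    BENTHIC_CATEGORIES,
    EXPERIMENT_YEARS,
    SURVEY_DATES,
    TREATMENTS,
    CalibrationConfig,
    ConfigurationError,
    substream,
)

__all__ = [
    "IslandSpec",
    "generate_islands",
    "generate_colonies",
    "generate_recruit_quadrats",
    "generate_benthic_surveys",
    "generate_cover_endpoints",
    "write_tables",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class IslandSpec:
    """One island: its identifier, atoll, and rat/seabird treatment."""

    island_id: str
    atoll_id: str
    treatment: str


def generate_islands(config: CalibrationConfig) -> list[IslandSpec]:
    """Lay out the islands: ``n_islands_per_treatment`` per treatment assigned
    round-robin to the atolls, so every atoll holds both treatments."""
    config.validate()
    islands = []
    for treatment, prefix in (("seabird", "S"), ("rat", "R")):
        for i in range(config.n_islands_per_treatment):
            islands.append(
                IslandSpec(
                    island_id=f"{prefix}{i + 1}",
                    atoll_id=f"A{i % config.n_atolls + 1}",
                    treatment=treatment,
                )
            )
    return islands


def _by_treatment(islands: list[IslandSpec], treatment: str) -> list[IslandSpec]:
    return [isl for isl in islands if isl.treatment == treatment]


def _interval_days() -> list[float]:
    dates = pd.to_datetime(list(SURVEY_DATES))
    return [(b - a).days for a, b in zip(dates[:-1], dates[1:])]


def generate_colonies(
    islands: list[IslandSpec],
    config: CalibrationConfig,
    mode: str,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate tagged-colony planar areas and symbiont d15N samples.

    ``mode="natural"`` tags 5-7 unmanipulated colonies at each of the
    monitored islands; ``mode="experimental"`` builds the reciprocal
    transplant between island pairs, each colony carrying both an origin and
    a transplant treatment label.

    Yearly planar areas follow ``A[t+1] = A[t] + rate * days / 365.25`` with a
    lognormal rate whose expected log encodes the configured treatment
    multiplier and the d15N slope; a colony's growth responds to its
    contemporaneous symbiont d15N deviation from the island-year mean.

    Returns ``(colonies, isotopes)``: a long measurement table (one row per
    colony visit) and a d15N table (one row per colony-year).
    """
    if mode not in ("natural", "experimental"):
        raise ValueError(f"unknown colony mode {mode!r}")
    if not islands:
        raise ValueError("islands list is empty")
    config.validate()
    seed = config.rng_seed if seed is None else seed
    rng = substream(seed, f"colonies-{mode}")

    log_slope = math.log(config.growth_per_unit_d15n)
    atoll_ids = sorted({isl.atoll_id for isl in islands})
    atoll_eff = dict(
        zip(atoll_ids, rng.normal(0.0, config.sd_log_growth_atoll, len(atoll_ids)))
    )
    year_eff = dict(
        zip(
            EXPERIMENT_YEARS[1:],
            rng.normal(0.0, config.sd_log_growth_year, len(EXPERIMENT_YEARS) - 1),
        )
    )
    days = _interval_days()

    colony_rows: list[dict] = []
    iso_rows: list[dict] = []

    def emit(colony_id, island, origin, transplant, d15n_targets, base_log,
             island_eff, dev_reference=None):
        # growth responds to the colony's d15N deviation from its island's
        # mean nutrient status (dev_reference, defaults to the cell targets)
        dev_reference = dev_reference or d15n_targets
        colony_eff = rng.normal(0.0, config.sd_log_growth_colony)
        d15n_dev = rng.normal(0.0, config.sd_d15n_colony)
        d15n_by_year = {}
        for yi, year in enumerate(EXPERIMENT_YEARS):
            wobble = rng.normal(0.0, config.sd_d15n_year)
            d15n_by_year[year] = d15n_targets[yi] + d15n_dev + wobble
            iso_rows.append(
                dict(colony_id=colony_id, year=year, d15n=d15n_by_year[year])
            )
        base_area = (
            config.initial_area_experimental
            if transplant is not None
            else config.initial_area_natural
        )
        area = float(
            base_area * np.exp(rng.normal(0.0, config.sd_log_initial_area))
        )
        areas = [area]
        for k, year_end in enumerate(EXPERIMENT_YEARS[1:]):
            dev = d15n_by_year[year_end] - dev_reference[k + 1]
            log_rate = (
                base_log
                + log_slope * dev
                + atoll_eff[island.atoll_id]
                + island_eff
                + colony_eff
                + year_eff[year_end]
                + rng.normal(0.0, config.sd_log_growth)
            )
            rate = math.exp(log_rate)  # cm^2 per year, strictly positive
            areas.append(areas[-1] + rate * days[k] / DAYS_PER_YEAR)
        for date, area_t in zip(SURVEY_DATES, areas):
            colony_rows.append(
                dict(
                    colony_id=colony_id,
                    island_id=island.island_id,
                    atoll_id=island.atoll_id,
                    treatment=island.treatment,
                    mode=mode,
                    origin=origin or "n/a",
                    transplant=transplant or "n/a",
                    date=date,
                    planar_area_cm2=area_t,
                )
            )

    if mode == "natural":
        chosen = (
            _by_treatment(islands, "seabird")[: config.natural_islands_per_treatment[0]]
            + _by_treatment(islands, "rat")[: config.natural_islands_per_treatment[1]]
        )
        if not chosen:
            raise ValueError("no islands available for natural colonies")
        base = math.log(config.growth_base_natural)
        mult = math.log(config.growth_multiplier_natural)
        for island in chosen:
            island_eff = rng.normal(0.0, config.sd_log_growth_island)
            iso_mean_jitter = rng.normal(0.0, config.sd_d15n_island)
            n_col = int(
                rng.integers(
                    config.colonies_per_island[0], config.colonies_per_island[1] + 1
                )
            )
            d15n_mean = config.delta15n_island_means[island.treatment] + iso_mean_jitter
            targets = (d15n_mean,) * len(EXPERIMENT_YEARS)
            base_log = base + (mult if island.treatment == "seabird" else 0.0)
            for k in range(n_col):
                emit(
                    f"{island.island_id}-N{k + 1}",
                    island,
                    None,
                    None,
                    targets,
                    base_log,
                    island_eff,
                )
    else:
        seabird = _by_treatment(islands, "seabird")
        rat = _by_treatment(islands, "rat")
        pairs = []
        for s in seabird:
            partner = next(
                (r for r in rat if r.atoll_id == s.atoll_id and r not in
                 [p[1] for p in pairs]),
                None,
            )
            if partner is not None:
                pairs.append((s, partner))
            if len(pairs) == config.experimental_island_pairs:
                break
        if len(pairs) < config.experimental_island_pairs:
            raise ValueError("not enough seabird/rat island pairs within atolls")
        base = math.log(config.growth_base_experimental)
        mult = math.log(config.growth_multiplier_transplant)
        for s_isl, r_isl in pairs:
            for dest_isl, origin_isl in ((s_isl, s_isl), (s_isl, r_isl),
                                         (r_isl, r_isl), (r_isl, s_isl)):
                    cell = (origin_isl.treatment, dest_isl.treatment)
                    targets = config.delta15n_transplant_trajectory[cell]
                    # island-mean nutrient status: both origin cells present
                    # in equal numbers at each destination island
                    island_mean = tuple(
                        0.5
                        * (
                            config.delta15n_transplant_trajectory[
                                ("seabird", dest_isl.treatment)
                            ][yi]
                            + config.delta15n_transplant_trajectory[
                                ("rat", dest_isl.treatment)
                            ][yi]
                        )
                        for yi in range(len(EXPERIMENT_YEARS))
                    )
                    base_log = base + (
                        mult if dest_isl.treatment == "seabird" else 0.0
                    )
                    for k in range(config.colonies_per_cell):
                        emit(
                            f"{origin_isl.island_id}>{dest_isl.island_id}-{k + 1}",
                            dest_isl,
                            origin_isl.treatment,
                            dest_isl.treatment,
                            targets,
                            base_log,
                            0.0,  # no island effect beyond the transplant treatment
                            dev_reference=island_mean,
                        )

    colonies = pd.DataFrame(colony_rows)
    isotopes = pd.DataFrame(iso_rows)
    return colonies, isotopes


def generate_recruit_quadrats(
    islands: list[IslandSpec],
    config: CalibrationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Zero-inflated recruit counts in 0.25 m^2 quadrats.

    Counts are zero-inflated Poisson: with probability ``zero_inflation`` a
    quadrat is structurally empty, otherwise Poisson with mean inflated by
    ``1 / (1 - zero_inflation)`` so the marginal mean stays at
    ``density * quadrat_area``.
    """
    config.validate()
    seed = config.rng_seed if seed is None else seed
    rng = substream(seed, "recruits")
    pi = config.zero_inflation
    chosen = (
        _by_treatment(islands, "seabird")[: config.recruit_islands_per_treatment]
        + _by_treatment(islands, "rat")[: config.recruit_islands_per_treatment]
    )
    quadrats_per_transect = max(
        1, config.quadrats_per_island // config.transects_per_island
    )
    rows = []
    for island in chosen:
        genus_density = {
            "Acropora": config.recruit_density[island.treatment],
            "other": max(
                0.0,
                config.total_recruit_density[island.treatment]
                - config.recruit_density[island.treatment],
            ),
        }
        for q in range(config.quadrats_per_island):
            transect = q // quadrats_per_transect + 1
            for genus, density in genus_density.items():
                mean = density * config.quadrat_area
                if pi >= 1.0 or mean == 0.0:
                    count = 0
                else:
                    occupied = rng.random() >= pi
                    count = int(rng.poisson(mean / (1.0 - pi))) if occupied else 0
                rows.append(
                    dict(
                        island_id=island.island_id,
                        atoll_id=island.atoll_id,
                        treatment=island.treatment,
                        transect=min(transect, config.transects_per_island),
                        quadrat=q + 1,
                        genus=genus,
                        count=count,
                    )
                )
    return pd.DataFrame(rows)


def generate_benthic_surveys(
    islands: list[IslandSpec],
    config: CalibrationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Point-intercept category counts along four transects per island.

    Each island-year draws its own composition from a Dirichlet centred on the
    treatment-by-year profile (concentration ``benthic_concentration``); each
    transect then records ``points_per_transect`` multinomial points.
    """
    config.validate()
    seed = config.rng_seed if seed is None else seed
    rng = substream(seed, "benthic")
    rows = []
    for island in islands:
        profiles = config.benthic_year_profiles[island.treatment]
        for year in sorted(profiles):
            profile = np.asarray(profiles[year], dtype=float)
            island_profile = np.zeros_like(profile)
            pos = profile > 0
            if pos.sum() == 1:
                island_profile[pos] = 1.0
            else:
                island_profile[pos] = rng.dirichlet(
                    profile[pos] * config.benthic_concentration
                )
            for transect in range(1, config.transects_per_island + 1):
                counts = rng.multinomial(config.points_per_transect, island_profile)
                for cat, count in zip(BENTHIC_CATEGORIES, counts):
                    rows.append(
                        dict(
                            island_id=island.island_id,
                            atoll_id=island.atoll_id,
                            treatment=island.treatment,
                            year=year,
                            transect=transect,
                            category=cat,
                            count=int(count),
                        )
                    )
    return pd.DataFrame(rows)


def generate_cover_endpoints(
    islands: list[IslandSpec], config: CalibrationConfig
) -> pd.DataFrame:
    """Per-island *Acropora* cover at the 2018 and 2021 surveys.

    Deterministic given the config: the treatment-level endpoints are spread
    across islands by ratio-preserving multiplicative factors, so every island
    in a treatment shares the same M/C1 ratio and the median island carries
    the treatment-level value.
    """
    config.validate()
    rows = []
    for treatment in TREATMENTS:
        members = _by_treatment(islands, treatment)
        spread = config.endpoint_island_spread
        for i, island in enumerate(members):
            f = spread[i % len(spread)]
            rows.append(
                dict(
                    island_id=island.island_id,
                    treatment=treatment,
                    c1=config.acropora_cover_2018[treatment] * f,
                    m_mu=config.acropora_cover_2021[treatment] * f,
                )
            )
    return pd.DataFrame(rows)


def write_tables(
    outdir: str | Path, config: CalibrationConfig, seed: int | None = None
) -> dict[str, Path]:
    """Generate every synthetic table and write the CSV files.

    Writes ``colonies.csv``, ``isotopes.csv``, ``recruits.csv``,
    ``benthic.csv`` and ``endpoints.csv``; returns the path of each.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    islands = generate_islands(config)
    nat_col, nat_iso = generate_colonies(islands, config, "natural", seed=seed)
    exp_col, exp_iso = generate_colonies(islands, config, "experimental", seed=seed)
    colonies = pd.concat([nat_col, exp_col], ignore_index=True)
    isotopes = pd.concat([nat_iso, exp_iso], ignore_index=True)
    tables = {
        "colonies": colonies,
        "isotopes": isotopes,
        "recruits": generate_recruit_quadrats(islands, config, seed=seed),
        "benthic": generate_benthic_surveys(islands, config, seed=seed),
        "endpoints": generate_cover_endpoints(islands, config),
    }
    paths = {}
    for name, table in tables.items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path
    return paths
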