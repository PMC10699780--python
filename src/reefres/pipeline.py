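"""End-to-end pipeline: simulate -> metrics -> rates -> reconstruct -> community.

Every stage reads and writes plain CSV/JSON under a run directory; a manifest
records the configuration hash and seed so a rerun with the same config is
byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colony import (
    growth_isotope_slope,
    interval_growth_rates,
    isotope_cell_medians,
    isotope_treatment_contrast,
    natural_growth_contrast,
    transplant_growth_contrast,
)
from .community import compositions_table, dissimilarity_to_baseline, recruit_density
from .config import CalibrationConfig, ConfigurationError, GompertzPriors
from .gompertz import pooled_recovery, months_to_fraction, simulate_posterior, trajectory_bands
from .rates import rate_params
from .synthetic import write_tables

logger = logging.getLogger("reefres")

ALL_STAGES = ("simulate", "metrics", "rates", "reconstruct", "community")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "runs/run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    priors: GompertzPriors = field(default_factory=GompertzPriors)
    colony_density: float = 3.6  # Acropora colonies per m^2, all islands
    recruit_area: float = 4.0  # cm^2 per recruit
    fraction: float = 0.9
    offset_months: float = 36.0
    contrast_draws: int = 3000
    contrast_burn: int = 1000
    contrast_chains: int = 4
    bootstrap_reps: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "calibration" in data and not isinstance(data["calibration"], CalibrationConfig):
            data["calibration"] = CalibrationConfig.from_dict(data["calibration"])
        if "priors" in data and not isinstance(data["priors"], GompertzPriors):
            data["priors"] = GompertzPriors(**data["priors"]).validate()
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calibration"] = self.calibration.to_dict()
        d["stages"] = list(self.stages)
        return d

    def validate(self) -> "RunConfig":
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        self.calibration.validate()
        self.priors.validate()
        outdir = Path(self.outdir)
        if "simulate" not in self.stages:
            needed = {
                "metrics": ("colonies.csv", "isotopes.csv"),
                "rates": ("colonies.csv", "recruits.csv"),
                "reconstruct": ("endpoints.csv",),
                "community": ("benthic.csv", "recruits.csv"),
            }
            for stage in self.stages:
                for fname in needed.get(stage, ()):
                    if not (outdir / fname).exists():
                        raise ConfigurationError(
                            f"stage {stage!r} requires {fname} but the simulate "
                            "stage is disabled and the file is missing"
                        )
        return self


def _effect_to_dict(effect) -> dict:
    return dict(
        point=effect.point,
        interval_lo=effect.interval_lo,
        interval_hi=effect.interval_hi,
        scale=effect.scale,
        n_excluded=effect.n_excluded,
    )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order and return the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cal = config.calibration
    seed = config.seed
    written: list[str] = []

    def record(*names: str):
        written.extend(names)

    try:
        if "simulate" in config.stages:
            paths = write_tables(outdir, cal, seed=seed)
            record(*[p.name for p in paths.values()])
            logger.info("simulate: wrote %d tables", len(paths))

        if "metrics" in config.stages:
            colonies = pd.read_csv(outdir / "colonies.csv")
            isotopes = pd.read_csv(outdir / "isotopes.csv")
            growth = interval_growth_rates(colonies)
            growth.to_csv(outdir / "growth.csv", index=False, float_format="%.10g")
            medians = isotope_cell_medians(
                isotopes.merge(
                    colonies.drop_duplicates("colony_id")[["colony_id", "mode"]]
                ).query("mode == 'experimental'").drop(columns="mode"),
                colonies,
            )
            medians.to_csv(
                outdir / "isotope_cell_medians.csv", index=False, float_format="%.10g"
            )
            kw = dict(
                draws=config.contrast_draws,
                burn=config.contrast_burn,
                chains=config.contrast_chains,
                seed=seed,
            )
            effects = {
                "transplant_growth_fold": transplant_growth_contrast(colonies, **kw),
                "natural_growth_fold": natural_growth_contrast(colonies, **kw),
                "isotope_difference": isotope_treatment_contrast(
                    isotopes, colonies, **kw
                ),
                "growth_per_unit_d15n": growth_isotope_slope(
                    growth, isotopes, **kw
                ),
            }
            for name, eff in effects.items():
                if eff.n_excluded:
                    logger.info(
                        "metrics: %s excluded %d non-positive growth records",
                        name,
                        eff.n_excluded,
                    )
            _write_json(
                outdir / "effects.json",
                {k: _effect_to_dict(v) for k, v in effects.items()},
            )
            record("growth.csv", "isotope_cell_medians.csv", "effects.json")

        if "rates" in config.stages:
            colonies = pd.read_csv(outdir / "colonies.csv")
            recruits = pd.read_csv(outdir / "recruits.csv")
            growth = interval_growth_rates(colonies[colonies["mode"] == "natural"])
            rates_out = {}
            for treatment, grp in growth.groupby("treatment"):
                mean_monthly = float(grp["growth_cm2_yr"].mean()) / 12.0
                acro = recruits[
                    (recruits["genus"] == "Acropora")
                    & (recruits["treatment"] == treatment)
                ]
                per_island = acro.groupby("island_id")["count"].agg(["sum", "size"])
                annual_density = float(
                    (per_island["sum"] / (per_island["size"] * cal.quadrat_area)).mean()
                )
                rp = rate_params(
                    treatment,
                    mean_monthly,
                    config.colony_density,
                    annual_density,
                    config.recruit_area,
                )
                rates_out[treatment] = dict(
                    mean_colony_growth_cm2_month=mean_monthly,
                    colony_density_m2=config.colony_density,
                    annual_recruit_density_m2=annual_density,
                    recruit_area_cm2=config.recruit_area,
                    G_raw=rp.G.raw,
                    G_per_month=rp.G.per_month,
                    R_per_month=rp.R,
                )
            _write_json(outdir / "rates.json", rates_out)
            record("rates.json")

        if "reconstruct" in config.stages:
            endpoints = pd.read_csv(outdir / "endpoints.csv")
            with open(outdir / "rates.json") as fh:
                rates_in = json.load(fh)
            rates = {
                tr: rate_params(
                    tr,
                    v["mean_colony_growth_cm2_month"],
                    v["colony_density_m2"],
                    v["annual_recruit_density_m2"],
                    v["recruit_area_cm2"],
                )
                for tr, v in rates_in.items()
            }
            posteriors = simulate_posterior(
                endpoints, rates, config.priors, seed=seed
            )
            rows = []
            for island, post in posteriors.items():
                est = months_to_fraction(post, config.fraction)
                est.with_offset(config.offset_months)
                if est.n_censored:
                    logger.info(
                        "reconstruct: %s censored %d/%d draws",
                        island,
                        est.n_censored,
                        est.n_draws,
                    )
                rows.append(
                    dict(
                        island_id=island,
                        treatment=post.treatment,
                        median_months=est.months_to_threshold,
                        ci_lo=est.ci_lo,
                        ci_hi=est.ci_hi,
                        n_censored=est.n_censored,
                        total_years=est.total_years,
                    )
                )
            summary = pd.DataFrame(rows)
            treatment_rows = [
                dict(
                    island_id=f"pooled-{tr}",
                    treatment=tr,
                    median_months=est.months_to_threshold,
                    ci_lo=est.ci_lo,
                    ci_hi=est.ci_hi,
                    n_censored=est.n_censored,
                    total_years=est.total_years,
                )
                for tr, est in pooled_recovery(
                    posteriors, config.fraction,
                    offset_months=config.offset_months,
                ).items()
            ]
            summary = pd.concat(
                [summary, pd.DataFrame(treatment_rows)], ignore_index=True
            )
            summary.to_csv(
                outdir / "recovery_summary.csv", index=False, float_format="%.10g"
            )
            bands = pd.concat(
                [trajectory_bands(p) for p in posteriors.values()],
                ignore_index=True,
            )
            bands.to_csv(
                outdir / "trajectory_bands.csv", index=False, float_format="%.6g"
            )
            record("recovery_summary.csv", "trajectory_bands.csv")

        if "community" in config.stages:
            benthic = pd.read_csv(outdir / "benthic.csv")
            recruits = pd.read_csv(outdir / "recruits.csv")
            dissim = dissimilarity_to_baseline(benthic)
            dissim.to_csv(
                outdir / "dissimilarity.csv", index=False, float_format="%.10g"
            )
            comps = compositions_table(benthic)
            cover = pd.DataFrame(
                [
                    dict(island_id=c.island_id, year=c.year, **c.proportions.to_dict())
                    for c in comps
                ]
            )
            cover.to_csv(
                outdir / "cover_summary.csv", index=False, float_format="%.10g"
            )
            dens = recruit_density(
                recruits,
                quadrat_area=cal.quadrat_area,
                n_boot=config.bootstrap_reps,
                seed=seed,
            )
            _write_json(
                outdir / "recruit_density.json",
                {k: _effect_to_dict(v) for k, v in dens.items()},
            )
            record("dissimilarity.csv", "cover_summary.csv", "recruit_density.json")
    except Exception as exc:  # pragma: no cover - error path formatting
        logger.error("pipeline aborted: %s", exc)
        raise

    config_dict = config.to_dict()
    config_dict.pop("outdir", None)  # location metadata, not run identity
    config_json = json.dumps(config_dict, sort_keys=True)
    manifest = dict(
        version=__version__,
        seed=seed,
        config=config_dict,
        config_sha256=hashlib.sha256(config_json.encode()).hexdigest(),
        outputs=sorted(set(written)),
    )
    _write_json(outdir / "manifest.json", manifest)
    return outdir
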