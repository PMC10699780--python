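"""Generator behaviour: layout, injected effects, marginal means, determinism."""
import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import reefres as rr
from reefres.config import BENTHIC_CATEGORIES, ConfigurationError
from reefres.synthetic import write_tables


def noise_free(config, **overrides):
    return dataclasses.replace(
        config,
        sd_d15n_island=0.0,
        sd_d15n_colony=0.0,
        sd_d15n_year=0.0,
        sd_log_initial_area=0.0,
        sd_log_growth=0.0,
        sd_log_growth_colony=0.0,
        sd_log_growth_island=0.0,
        sd_log_growth_atoll=0.0,
        sd_log_growth_year=0.0,
        **overrides,
    )


class TestIslandLayout:
    def test_default_layout(self, islands):
        assert len(islands) == 12
        assert sum(i.treatment == "seabird" for i in islands) == 6
        assert len({i.atoll_id for i in islands}) == 3
        assert len({i.island_id for i in islands}) == 12

    def test_single_island_per_treatment(self):
        cfg = rr.CalibrationConfig(n_islands_per_treatment=1, n_atolls=1)
        assert len(rr.generate_islands(cfg)) == 2

    def test_counts_validated(self):
        with pytest.raises(ConfigurationError):
            rr.generate_islands(rr.CalibrationConfig(n_islands_per_treatment=0))

    def test_deterministic(self, config):
        assert rr.generate_islands(config) == rr.generate_islands(config)


class TestColonies:
    def test_unknown_mode(self, islands, config):
        with pytest.raises(ValueError, match="mode"):
            rr.generate_colonies(islands, config, "wild")

    def test_empty_islands(self, config):
        with pytest.raises(ValueError):
            rr.generate_colonies([], config, "natural")

    def test_experimental_design(self, experimental_tables, config):
        colonies, isotopes = experimental_tables
        meta = colonies.drop_duplicates("colony_id")
        # reciprocal pairing: every origin x transplant cell populated equally
        cells = meta.groupby(["origin", "transplant"]).size()
        assert len(cells) == 4
        assert cells.nunique() == 1
        assert (meta[["origin", "transplant"]] != "n/a").all().all()
        # one isotope sample per colony-year
        assert not isotopes.duplicated(["colony_id", "year"]).any()

    def test_transplant_acclimation_medians(self, experimental_tables):
        """Rat-origin corals moved to seabird islands drift 6 -> 7 -> 8 per mil."""
        colonies, isotopes = experimental_tables
        med = rr.isotope_cell_medians(isotopes, colonies)
        cell = med[(med.origin == "rat") & (med.transplant == "seabird")]
        assert np.allclose(cell["median_d15n"], [6.0, 7.0, 8.0], atol=0.45)

    def test_areas_positive_and_growing(self, experimental_tables):
        colonies, _ = experimental_tables
        assert (colonies["planar_area_cm2"] > 0).all()

    def test_noise_free_multiplier_is_exact(self, islands, config):
        """With all noise off and no d15N slope, the ratio of transplant-arm
        mean growth equals the configured multiplier exactly."""
        cfg = noise_free(config, growth_per_unit_d15n=1.0)
        colonies, _ = rr.generate_colonies(islands, cfg, "experimental", seed=3)
        growth = rr.interval_growth_rates(colonies)
        means = growth.groupby("transplant")["growth_cm2_yr"].mean()
        assert means["seabird"] / means["rat"] == pytest.approx(2.0, abs=1e-9)

    def test_noise_free_geometric_ratio_with_slope(self, islands, config):
        """With the d15N slope active the *geometric* arm means keep the
        exact configured fold-change (deviations are symmetric per island)."""
        cfg = noise_free(config)
        colonies, _ = rr.generate_colonies(islands, cfg, "experimental", seed=3)
        growth = rr.interval_growth_rates(colonies)
        gm = growth.groupby("transplant")["growth_cm2_yr"].apply(
            lambda s: math.exp(np.log(s).mean())
        )
        assert gm["seabird"] / gm["rat"] == pytest.approx(2.0, rel=1e-9)

    def test_null_multiplier(self, islands, config):
        cfg = noise_free(config, growth_multiplier_transplant=1.0,
                         growth_per_unit_d15n=1.0)
        colonies, _ = rr.generate_colonies(islands, cfg, "experimental", seed=3)
        growth = rr.interval_growth_rates(colonies)
        means = growth.groupby("transplant")["growth_cm2_yr"].mean()
        assert means["seabird"] == pytest.approx(means["rat"], rel=1e-9)

    def test_known_rate_roundtrip(self, islands, config):
        """Recomputing rates from the emitted areas returns the generator's
        per-interval rate to numerical precision (noise-free: the base rate)."""
        cfg = noise_free(config, growth_per_unit_d15n=1.0)
        colonies, _ = rr.generate_colonies(islands, cfg, "natural", seed=3)
        growth = rr.interval_growth_rates(colonies)
        rat = growth[growth.treatment == "rat"]["growth_cm2_yr"]
        assert np.allclose(rat, cfg.growth_base_natural, atol=1e-9)


class TestRecruits:
    def test_marginal_mean_matches_density(self, config):
        cfg = dataclasses.replace(config, quadrats_per_island=20_000)
        islands = rr.generate_islands(cfg)
        quads = rr.generate_recruit_quadrats(islands, cfg, seed=5)
        acro = quads[(quads.genus == "Acropora") & (quads.treatment == "seabird")]
        density = acro["count"].mean() / cfg.quadrat_area
        assert density == pytest.approx(0.52, rel=0.03)

    def test_zero_density_all_zero(self, islands, config):
        cfg = dataclasses.replace(
            config,
            recruit_density={"seabird": 0.0, "rat": 0.0},
            total_recruit_density={"seabird": 0.0, "rat": 0.0},
        )
        quads = rr.generate_recruit_quadrats(islands, cfg, seed=5)
        assert (quads["count"] == 0).all()

    def test_zero_inflation_lower_bound(self, config):
        cfg = dataclasses.replace(config, quadrats_per_island=5000)
        islands = rr.generate_islands(cfg)
        quads = rr.generate_recruit_quadrats(islands, cfg, seed=5)
        acro = quads[quads.genus == "Acropora"]
        assert (acro["count"] == 0).mean() >= cfg.zero_inflation

    def test_negative_density_rejected(self, islands, config):
        cfg = dataclasses.replace(config, recruit_density={"seabird": -1, "rat": 1})
        with pytest.raises(ConfigurationError):
            rr.generate_recruit_quadrats(islands, cfg)


class TestBenthic:
    def test_counts_conserved_per_transect(self, islands, config):
        ben = rr.generate_benthic_surveys(islands, config, seed=5)
        totals = ben.groupby(["island_id", "year", "transect"])["count"].sum()
        assert (totals == config.points_per_transect).all()

    def test_degenerate_profile_single_category(self, islands, config):
        one_hot = tuple(1.0 if c == "pavement" else 0.0 for c in BENTHIC_CATEGORIES)
        cfg = dataclasses.replace(
            config,
            benthic_year_profiles={
                "seabird": {2015: one_hot},
                "rat": {2015: one_hot},
            },
        )
        ben = rr.generate_benthic_surveys(islands, cfg, seed=5)
        nonzero = ben[ben["count"] > 0]
        assert set(nonzero["category"]) == {"pavement"}

    def test_invalid_profile_rejected(self, islands, config):
        bad = dict(config.benthic_year_profiles)
        bad["seabird"] = {2015: (0.5,) * 9}
        cfg = dataclasses.replace(config, benthic_year_profiles=bad)
        with pytest.raises(ConfigurationError):
            rr.generate_benthic_surveys(islands, cfg)

    def test_seabird_prebleach_hard_coral(self, islands, config):
        """Pre-bleaching hard coral is ~31% of the benthos at seabird islands."""
        ben = rr.generate_benthic_surveys(islands, config, seed=5)
        sub = ben[
            (ben.treatment == "seabird") & (ben.year == 2015)
        ]
        prop = (
            sub[sub.category == "hard_coral"]["count"].sum() / sub["count"].sum()
        )
        assert prop == pytest.approx(0.31, abs=0.03)


class TestDeterminism:
    def test_tables_byte_identical(self, tmp_path, config):
        p1 = write_tables(tmp_path / "a", config, seed=9)
        p2 = write_tables(tmp_path / "b", config, seed=9)
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_seed_changes_output(self, tmp_path, config):
        p1 = write_tables(tmp_path / "a", config, seed=9)
        p2 = write_tables(tmp_path / "b", config, seed=10)
        assert p1["colonies"].read_bytes() != p2["colonies"].read_bytes()

    def test_endpoints_ratio_preserved(self, islands, config):
        eps = rr.generate_cover_endpoints(islands, config)
        for _, grp in eps.groupby("treatment"):
            ratios = (grp["m_mu"] / grp["c1"]).to_numpy()
            assert np.allclose(ratios, ratios[0])
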