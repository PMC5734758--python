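"""Survey filters, biomass conversion and covariate derivation."""

import numpy as np
import pandas as pd
import pytest

import trawldiv as td
from trawldiv.survey import CommunityMatrix, derive_covariates, interpolate_surface


def haul_table(rows):
    return pd.DataFrame(
        rows, columns=["haul_id", "site_id", "year", "depth_m", "duration_min", "species", "length_cm", "cpue_per_h"]
    )


class TestFilterHauls:
    def test_inclusive_duration_and_depth_bounds(self):
        rows = [
            ["h1", "a", 2000, 50.0, 30.0, "sp", 10, 1.0],   # kept
            ["h2", "a", 2000, 50.0, 26.9, "sp", 10, 1.0],   # duration low
            ["h3", "a", 2000, 50.0, 27.0, "sp", 10, 1.0],   # kept (boundary)
            ["h4", "a", 2000, 50.0, 33.0, "sp", 10, 1.0],   # kept (boundary)
            ["h5", "a", 2000, 50.0, 33.1, "sp", 10, 1.0],   # duration high
            ["h6", "a", 2000, 19.0, 30.0, "sp", 10, 1.0],   # too shallow
            ["h7", "a", 2000, 20.0, 30.0, "sp", 10, 1.0],   # kept (boundary)
        ]
        out = td.filter_hauls(haul_table(rows))
        assert sorted(out["haul_id"]) == ["h1", "h3", "h4", "h7"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rows = [
            [f"h{i}", "a", 2000, rng.uniform(10, 100), rng.uniform(20, 40), "sp", 10, 1.0]
            for i in range(50)
        ]
        once = td.filter_hauls(haul_table(rows))
        twice = td.filter_hauls(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_warns(self):
        rows = [["h1", "a", 2000, 5.0, 10.0, "sp", 10, 1.0]]
        with pytest.warns(UserWarning):
            out = td.filter_hauls(haul_table(rows))
        assert out.empty


class TestSiteCoverage:
    def make(self, years_by_site):
        rows = []
        for site, years in years_by_site.items():
            for y in years:
                rows.append([f"{site}-{y}", site, y, 50.0, 30.0, "sp", 10, 1.0])
        return haul_table(rows)

    def test_26_of_32_threshold(self):
        hauls = self.make({"keep": range(26), "drop": range(25)})
        kept = td.filter_sites_by_coverage(hauls, 26 / 32, n_years=32)
        assert kept == ["keep"]

    def test_identity_when_all_sites_complete(self):
        hauls = self.make({"a": range(10), "b": range(10)})
        assert td.filter_sites_by_coverage(hauls, 0.8, n_years=10) == ["a", "b"]

    def test_ceiling_rule_for_ten_years(self):
        hauls = self.make({"eight": range(8), "seven": range(7)})
        assert td.filter_sites_by_coverage(hauls, 0.8, n_years=10) == ["eight"]


class TestSpeciesOccurrence:
    def make_matrix(self, presence_years, n_years=32):
        # presence_years: species -> set of years where biomass > 0
        years = list(range(n_years))
        species = list(presence_years)
        rows = {}
        for y in years:
            rows[("s1", y)] = [1.0 if y in presence_years[sp] else 0.0 for sp in species]
        biomass = pd.DataFrame.from_dict(rows, orient="index", columns=species)
        biomass.index = pd.MultiIndex.from_tuples(biomass.index, names=["site_id", "year"])
        return CommunityMatrix(biomass=biomass, n_hauls=pd.Series(1, index=biomass.index))

    def test_seven_of_32_boundary(self):
        cm = self.make_matrix({"keep": set(range(7)), "drop": set(range(6)), "all": set(range(32))})
        out = td.filter_species_by_occurrence(cm, 7 / 32)
        assert sorted(out.species) == ["all", "keep"]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        presence = {f"sp{i}": set(rng.choice(32, rng.integers(1, 32), replace=False).tolist()) for i in range(20)}
        cm = self.make_matrix(presence)
        out = td.filter_species_by_occurrence(cm, 7 / 32)
        expected = sorted(sp for sp, ys in presence.items() if len(ys) >= 7)
        assert sorted(out.species) == expected

    def test_all_dropped_is_error(self):
        cm = self.make_matrix({"rare": {0}})
        with pytest.raises(ValueError):
            td.filter_species_by_occurrence(cm, 7 / 32)


class TestAggregateSpecies:
    def base(self):
        return haul_table(
            [
                ["h1", "a", 2000, 50, 30, "sp1", 10, 2.0],
                ["h1", "a", 2000, 50, 30, "sp2", 10, 3.0],
                ["h1", "a", 2000, 50, 30, "sp3", 20, 1.0],
            ]
        )

    def test_identity_mapping_unchanged(self):
        out = td.aggregate_species(self.base(), {})
        pd.testing.assert_frame_equal(
            out.sort_index(axis=1), self.base().sort_index(axis=1), check_like=True
        )

    def test_two_species_sum_into_group(self):
        out = td.aggregate_species(self.base(), {"sp1": "grp", "sp2": "grp"})
        grp = out[out["species"] == "grp"]
        assert len(grp) == 1
        assert grp["cpue_per_h"].iloc[0] == pytest.approx(5.0)

    def test_group_count_drops_by_merged_species(self):
        hauls = haul_table(
            [["h1", "a", 2000, 50, 30, f"sp{i}", 10, 1.0] for i in range(5)]
        )
        mapping = {"sp0": "g1", "sp1": "g1", "sp2": "g2", "sp3": "g2", "sp4": "g3"}
        out = td.aggregate_species(hauls, mapping)
        assert out["species"].nunique() == hauls["species"].nunique() - 2


class TestCpueToBiomass:
    def test_single_class_arithmetic(self):
        hauls = haul_table([["h1", "a", 2000, 50, 30, "sp", 10.0, 5.0]])
        lw = pd.DataFrame({"species": ["sp"], "a": [0.01], "b": [3.0]})
        out = td.cpue_to_biomass(hauls, lw)
        assert out["biomass_per_h"].iloc[0] == pytest.approx(50.0)

    def test_two_length_classes_sum(self):
        hauls = haul_table(
            [
                ["h1", "a", 2000, 50, 30, "sp", 10.0, 2.0],
                ["h1", "a", 2000, 50, 30, "sp", 20.0, 1.0],
            ]
        )
        lw = pd.DataFrame({"species": ["sp"], "a": [0.01], "b": [3.0]})
        out = td.cpue_to_biomass(hauls, lw)
        assert len(out) == 1
        assert out["biomass_per_h"].iloc[0] == pytest.approx(100.0)

    def test_zero_cpue_gives_zero_biomass(self):
        hauls = haul_table([["h1", "a", 2000, 50, 30, "sp", 10.0, 0.0]])
        lw = pd.DataFrame({"species": ["sp"], "a": [0.01], "b": [3.0]})
        assert td.cpue_to_biomass(hauls, lw)["biomass_per_h"].iloc[0] == 0.0

    def test_missing_parameters_error_names_species(self):
        hauls = haul_table([["h1", "a", 2000, 50, 30, "mystery", 10.0, 1.0]])
        lw = pd.DataFrame({"species": ["sp"], "a": [0.01], "b": [3.0]})
        with pytest.raises(KeyError, match="mystery"):
            td.cpue_to_biomass(hauls, lw)

    def test_linear_in_cpue(self):
        rng = np.random.default_rng(2)
        rows = [
            ["h1", "a", 2000, 50, 30, "sp", float(L), float(c)]
            for L, c in zip(rng.uniform(5, 50, 10), rng.uniform(0, 5, 10))
        ]
        lw = pd.DataFrame({"species": ["sp"], "a": [0.01], "b": [3.0]})
        single = td.cpue_to_biomass(haul_table(rows), lw)["biomass_per_h"].iloc[0]
        doubled = haul_table(rows)
        doubled["cpue_per_h"] *= 2
        assert td.cpue_to_biomass(doubled, lw)["biomass_per_h"].iloc[0] == pytest.approx(2 * single)


class TestBuildCommunityMatrix:
    def records(self, rows):
        return pd.DataFrame(rows, columns=["haul_id", "site_id", "year", "species", "biomass_per_h"])

    def test_single_haul_passthrough(self):
        cm = td.build_community_matrix(self.records([["h1", "a", 2000, "sp", 12.5]]))
        assert cm.biomass.loc[("a", 2000), "sp"] == pytest.approx(12.5)
        assert cm.n_hauls.loc[("a", 2000)] == 1

    def test_mean_across_hauls_counts_absences_as_zero(self):
        cm = td.build_community_matrix(
            self.records([["h1", "a", 2000, "sp", 10.0], ["h2", "a", 2000, "sp", 30.0]])
        )
        assert cm.biomass.loc[("a", 2000), "sp"] == pytest.approx(20.0)
        # species caught in one haul of two: mean over both hauls
        cm2 = td.build_community_matrix(
            self.records([["h1", "a", 2000, "sp", 10.0], ["h2", "a", 2000, "other", 1.0]])
        )
        assert cm2.biomass.loc[("a", 2000), "sp"] == pytest.approx(5.0)

    def test_matches_brute_force_group_mean(self):
        rng = np.random.default_rng(9)
        rows = []
        for site in "ab":
            for year in (2000, 2001):
                for h in range(rng.integers(1, 4)):
                    for sp in rng.choice(["x", "y", "z"], rng.integers(1, 3), replace=False):
                        rows.append([f"{site}{year}h{h}", site, year, sp, float(rng.gamma(2, 5))])
        rec = self.records(rows)
        cm = td.build_community_matrix(rec)
        for (site, year), grp in rec.groupby(["site_id", "year"]):
            n_h = grp["haul_id"].nunique()
            for sp in "xyz":
                expected = grp.loc[grp["species"] == sp, "biomass_per_h"].sum() / n_h
                assert cm.biomass.loc[(site, year), sp] == pytest.approx(expected)


class TestDeriveCovariates:
    def monthly(self, winter_t=6.0, summer_t=16.0, sal_min=30.0, sal_max=35.0):
        rows = []
        for year in (2000, 2001):
            for month in (12, 1, 2):
                rows.append(["s1", year, month, winter_t, sal_min])
            for month in (6, 7, 8):
                rows.append(["s1", year, month, summer_t, sal_max])
        return pd.DataFrame(rows, columns=["site_id", "year", "month", "sbt", "salinity"])

    def substrate(self, fractions):
        return pd.DataFrame(
            [["s1", f"cat{i}", f] for i, f in enumerate(fractions)],
            columns=["site_id", "category", "fraction"],
        )

    def test_winter_mean_and_seasonality(self):
        cov = derive_covariates(self.monthly(), self.substrate([1.0]))
        assert cov.loc["s1", "sbt_winter"] == pytest.approx(6.0)
        assert cov.loc["s1", "sbt_seasonality"] == pytest.approx(10.0)

    def test_salinity_variability_max_minus_min(self):
        cov = derive_covariates(self.monthly(), self.substrate([1.0]))
        assert cov.loc["s1", "salinity_variability"] == pytest.approx(5.0)

    def test_equal_substrate_coverage(self):
        cov = derive_covariates(self.monthly(), self.substrate([1 / 3, 1 / 3, 1 / 3]))
        assert cov.loc["s1", "substrate_richness"] == 3
        assert cov.loc["s1", "substrate_evenness"] == pytest.approx(1.0)

    def test_missing_months_listed(self):
        monthly = self.monthly()
        monthly = monthly[monthly["month"] != 7]
        with pytest.raises(ValueError, match="7"):
            derive_covariates(monthly, self.substrate([1.0]))


class TestInterpolateSurface:
    def grid_obs(self, f, n=20, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        lat, lon = np.meshgrid(np.linspace(50, 60, n), np.linspace(-3, 8, n))
        lat, lon = lat.ravel(), lon.ravel()
        return pd.DataFrame({"lat": lat, "lon": lon, "value": f(lat, lon) + rng.normal(0, noise, lat.size)})

    def sites(self):
        return pd.DataFrame(
            {"lat": [52.0, 55.0, 58.0], "lon": [0.0, 2.5, 5.0]},
            index=pd.Index(["a", "b", "c"], name="site_id"),
        )

    def test_constant_field_reproduced(self):
        obs = self.grid_obs(lambda la, lo: np.full_like(la, 7.25))
        pred = interpolate_surface(obs, self.sites())
        np.testing.assert_allclose(pred, 7.25, atol=1e-6)

    def test_planar_field_reproduced(self):
        obs = self.grid_obs(lambda la, lo: la)
        pred = interpolate_surface(obs, self.sites())
        np.testing.assert_allclose(pred, self.sites()["lat"], atol=1e-6)

    def test_smooth_field_rmse_below_noise(self):
        f = lambda la, lo: np.sin(la / 2.0) + np.cos(lo / 3.0)
        obs = self.grid_obs(f, n=40, noise=0.1, seed=1)
        sites = self.sites()
        pred = interpolate_surface(obs, sites)
        truth = f(sites["lat"].to_numpy(), sites["lon"].to_numpy())
        rmse = np.sqrt(np.mean((pred.to_numpy() - truth) ** 2))
        assert rmse < 0.1

    def test_too_few_observations_rejected(self):
        obs = self.grid_obs(lambda la, lo: la).iloc[:5]
        with pytest.raises(ValueError):
            interpolate_surface(obs, self.sites())

    def test_degenerate_coordinates_rejected(self):
        obs = self.grid_obs(lambda la, lo: la)
        obs["lon"] = 1.0
        with pytest.raises(np.linalg.LinAlgError):
            interpolate_surface(obs, self.sites())
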