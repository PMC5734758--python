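"""Biodiversity indicators: richness, evenness, hull and MST indices."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay

import trawldiv as td
from trawldiv.traitspace import TraitSpace


def hull_volume_oracle(points):
    """Brute force: sum of simplex volumes of the Delaunay triangulation."""
    tri = Delaunay(points)
    total = 0.0
    for simplex in tri.simplices:
        verts = points[simplex]
        mat = verts[1:] - verts[0]
        total += abs(np.linalg.det(mat)) / math.factorial(points.shape[1])
    return total


def make_space(coords, m):
    idx = pd.Index([f"s{i}" for i in range(len(coords))], name="species")
    cols = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return TraitSpace(
        coordinates=pd.DataFrame(coords, index=idx, columns=cols),
        eigenvalues=np.ones(coords.shape[1]),
        correction="none",
        m=m,
    )


class TestSpeciesRichness:
    def test_counts_positive_biomasses(self):
        assert td.species_richness(np.zeros(5)) == 0
        assert td.species_richness([5.0, 0.0, 2.0]) == 2

    def test_matches_brute_force_on_random_rows(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            row = rng.choice([0.0, 0.0, 1.5, 7.0], size=30)
            assert td.species_richness(row) == sum(1 for v in row if v > 0)


class TestPielou:
    def test_equal_biomasses_give_one(self):
        assert td.pielou_evenness([1, 1, 1, 1]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # p = (0.8, 0.1, 0.1): -sum p ln p / ln 3 = 0.5817
        assert td.pielou_evenness([8, 1, 1]) == pytest.approx(0.5817, abs=1e-4)

    def test_single_species_undefined(self):
        assert np.isnan(td.pielou_evenness([5.0]))
        assert np.isnan(td.pielou_evenness([0.0, 0.0]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        b = rng.gamma(1.0, 10.0, 12)
        assert td.pielou_evenness(b) == pytest.approx(td.pielou_evenness(123.4 * b), abs=1e-12)


class TestConvexHullVolume:
    def test_unit_square_and_triangle(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert td.convex_hull_volume(square) == pytest.approx(1.0)
        tri = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        assert td.convex_hull_volume(tri) == pytest.approx(0.5)

    @pytest.mark.parametrize("dim,n", [(2, 8), (3, 7), (3, 8)])
    def test_matches_delaunay_simplex_sum(self, dim, n):
        rng = np.random.default_rng(dim * 10 + n)
        pts = rng.standard_normal((n, dim))
        assert td.convex_hull_volume(pts) == pytest.approx(hull_volume_oracle(pts), abs=1e-9)

    def test_degenerate_points_flagged(self):
        line = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        assert np.isnan(td.convex_hull_volume(line))


class TestTraitRichness:
    def test_full_pool_equals_one(self, community, space):
        full = pd.Series(1.0, index=space.species)
        assert td.trait_richness(full, space) == pytest.approx(1.0)

    def test_too_few_species_undefined(self, space):
        b = pd.Series(0.0, index=space.species)
        b.iloc[: space.m] = 1.0
        assert np.isnan(td.trait_richness(b, space))

    def test_nested_communities_are_monotone(self, space):
        rng = np.random.default_rng(11)
        species = list(space.species)
        for _ in range(10):
            big = rng.choice(species, size=14, replace=False)
            small = rng.choice(big, size=9, replace=False)
            b_big = pd.Series(0.0, index=space.species)
            b_big[big] = 1.0
            b_small = pd.Series(0.0, index=space.species)
            b_small[small] = 1.0
            t_small = td.trait_richness(b_small, space)
            t_big = td.trait_richness(b_big, space)
            if not (np.isnan(t_small) or np.isnan(t_big)):
                assert t_small <= t_big + 1e-12

    def test_presence_only_ignores_biomass_values(self, space):
        rng = np.random.default_rng(13)
        b = pd.Series(0.0, index=space.species)
        b.iloc[:10] = 1.0
        base = td.trait_richness(b, space)
        for _ in range(5):
            b2 = b.copy()
            b2.iloc[:10] = rng.gamma(1.0, 5.0, 10) + 1e-6
            assert td.trait_richness(b2, space) == pytest.approx(base, abs=1e-12)

    def test_interior_species_leaves_hull_unchanged(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        space = make_space(square, m=2)
        corners = pd.Series([1, 1, 1, 1, 0.0], index=space.species)
        with_center = pd.Series(1.0, index=space.species)
        assert td.trait_richness(with_center, space) == pytest.approx(
            td.trait_richness(corners, space), abs=1e-12
        )

    def test_unknown_species_is_an_error(self, space):
        b = pd.Series(1.0, index=list(space.species[:5]) + ["ghost"])
        with pytest.raises(KeyError, match="ghost"):
            td.trait_richness(b, space)


class TestTraitEvenness:
    def setup_method(self):
        # 3 species on a line at 0, 1, 2 (plus an off-line species to give
        # the pool a positive hull), MST branches of length 1 and 1
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [1.0, 1.0]])
        self.space = make_space(coords, m=2)

    def test_regular_tree_equal_biomass_gives_one(self):
        b = pd.Series([1.0, 1.0, 1.0, 0.0], index=self.space.species)
        assert td.trait_evenness(b, self.space) == pytest.approx(1.0)

    def test_hand_computed_unequal_biomass(self):
        # w = (0.5, 0.25, 0.25): EW = (1/0.75, 1/0.5), PEW = (0.4, 0.6)
        # TEve = (0.4 + 0.5 - 0.5) / 0.5 = 0.8
        b = pd.Series([0.5, 0.25, 0.25, 0.0], index=self.space.species)
        assert td.trait_evenness(b, self.space) == pytest.approx(0.8, abs=1e-9)

    def test_fewer_than_three_species_undefined(self):
        b = pd.Series([1.0, 1.0, 0.0, 0.0], index=self.space.species)
        assert np.isnan(td.trait_evenness(b, self.space))

    def test_bounded_and_scale_invariant(self, community, space):
        for _, row in community.biomass.iloc[:10].iterrows():
            v = td.trait_evenness(row, space)
            assert 0.0 <= v <= 1.0
            assert td.trait_evenness(row * 42.0, space) == pytest.approx(v, abs=1e-12)


class TestIndicatorTable:
    def test_one_record_per_site_year(self, community, space):
        table = td.compute_indicator_table(community, space)
        assert len(table) == len(community.biomass)
        assert set(table.columns) >= {"site_id", "year", "n_hauls", "SRic", "SEve", "TRic", "TEve"}

    def test_matches_per_cell_recomputation(self, community, space):
        table = td.compute_indicator_table(community, space).set_index(["site_id", "year"])
        for key, row in community.biomass.iloc[:8].iterrows():
            assert table.loc[key, "SRic"] == td.species_richness(row)
            assert table.loc[key, "SEve"] == pytest.approx(td.pielou_evenness(row))
            got, exp = table.loc[key, "TRic"], td.trait_richness(row, space)
            assert got == pytest.approx(exp) or (np.isnan(got) and np.isnan(exp))


class TestEffortStandardize:
    def make_table(self, n=80, slope=3.0, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        n_hauls = 1 + rng.poisson(2.0, n)
        value = 2.0 + slope * n_hauls + rng.normal(0, noise, n)
        return pd.DataFrame({"site_id": "s", "year": np.arange(n), "n_hauls": n_hauls, "SRic": value})

    def test_removes_linear_effort_effect(self):
        table = self.make_table()
        out = td.effort_standardize(table, columns=("SRic",))
        r = np.corrcoef(out["SRic_std"], out["n_hauls"])[0, 1]
        assert abs(r) < 0.05

    def test_grand_mean_preserved(self):
        table = self.make_table(seed=1)
        out = td.effort_standardize(table, columns=("SRic",))
        assert out["SRic_std"].mean() == pytest.approx(table["SRic"].mean(), abs=1e-9)

    def test_constant_haul_count_is_identity(self):
        table = self.make_table()
        table["n_hauls"] = 2
        out = td.effort_standardize(table, columns=("SRic",))
        np.testing.assert_allclose(out["SRic_std"], table["SRic"])

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            td.effort_standardize(self.make_table(n=10), columns=("SRic",))
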