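import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from reeftraits.traitspace import (
    TRAIT_NAMES,
    TraitSpace,
    bin_traits,
    build_trait_space,
    functional_dispersion,
    functional_redundancy_5nn,
    gower_distance,
    impute_traits,
    kde_occupancy,
    trait_volume_fraction,
)
from oracles import fdis_direct, gower_direct, redundancy_5nn_direct


def _space_from_points(points, labels=None):
    pts = np.asarray(points, float)
    labels = labels or [f"t{i}" for i in range(len(pts))]
    coords = pd.DataFrame(
        pts, index=labels, columns=[f"PCoA{i+1}" for i in range(pts.shape[1])]
    )
    eig = np.var(pts, axis=0) * len(pts)
    return TraitSpace(coords, np.sort(eig)[::-1], eig / eig.sum())


class TestImputation:
    def test_genus_geometric_mean(self, mini_trait_table):
        table = mini_trait_table.copy()
        table.loc["Acropora sp0", "growth_rate"] = np.nan
        table.loc["Acropora sp1", "growth_rate"] = 4.0
        table.loc["Acropora sp2", "growth_rate"] = 6.0
        out = impute_traits(table)
        assert out.loc["Acropora sp0", "growth_rate"] == pytest.approx(
            np.exp(np.mean([np.log(4), np.log(6)])), abs=1e-9
        )
        assert out.loc["Acropora sp0", "imputed_growth_rate"]

    def test_growth_form_fallback_recorded(self, mini_trait_table):
        table = mini_trait_table.copy()
        table.loc["Acropora sp0", "genus"] = "Isopora"  # no measured congener
        table.loc["Acropora sp0", "colony_size"] = np.nan
        out = impute_traits(table)
        level = out.attrs["imputation_level"][("Acropora sp0", "colony_size")]
        assert level == "growth_form"
        form_members = table.index[
            (table["growth_form"] == "corymbose") & table["colony_size"].notna()
        ]
        expected = np.exp(np.log(table.loc[form_members, "colony_size"]).mean())
        assert out.loc["Acropora sp0", "colony_size"] == pytest.approx(expected)

    def test_complete_table_unchanged(self, mini_trait_table):
        out = impute_traits(mini_trait_table)
        for t in TRAIT_NAMES:
            assert np.allclose(out[t], mini_trait_table[t])
            assert not out[f"imputed_{t}"].any()

    def test_fully_missing_trait_is_error(self, mini_trait_table):
        table = mini_trait_table.copy()
        table["sav_ratio"] = np.nan
        with pytest.raises(ValueError, match="sav_ratio"):
            impute_traits(table)


class TestBinning:
    BREAKS = {t: (2.0, 4.0, 6.0, 8.0) for t in TRAIT_NAMES}

    def _frame(self, value):
        return pd.DataFrame({t: [value] for t in TRAIT_NAMES}, index=["x"])

    def test_count_of_cuts_below(self):
        assert bin_traits(self._frame(5.0), self.BREAKS).iloc[0, 0] == 3

    def test_value_on_cut_takes_lower_category(self):
        assert bin_traits(self._frame(4.0), self.BREAKS).iloc[0, 0] == 2

    @given(st.floats(0.5, 9.5), st.floats(0.5, 9.5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_raw_value(self, a, b):
        lo, hi = sorted([a, b])
        ca = bin_traits(self._frame(lo), self.BREAKS).iloc[0, 0]
        cb = bin_traits(self._frame(hi), self.BREAKS).iloc[0, 0]
        assert ca <= cb

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            out = bin_traits(self._frame(1e6), self.BREAKS)
        assert out.iloc[0, 0] == 5

    def test_gaps_rejected(self):
        frame = self._frame(3.0)
        frame.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="gaps"):
            bin_traits(frame, self.BREAKS)


class TestGower:
    def test_identical_rows_zero(self):
        ordi = pd.DataFrame([[3] * 7, [3] * 7], columns=TRAIT_NAMES,
                            index=["a", "b"])
        ordi.iloc[0, 0] = 1  # give one trait range
        ordi2 = ordi.copy()
        d = gower_distance(pd.concat([ordi, ordi2]).reset_index(drop=True))
        assert d.data[0, 2] == 0.0

    def test_opposite_extremes_distance_one(self):
        ordi = pd.DataFrame([[1] * 7, [5] * 7], columns=TRAIT_NAMES,
                            index=["lo", "hi"])
        assert gower_distance(ordi)["lo", "hi"] == pytest.approx(1.0)

    def test_hand_value_single_trait_step(self):
        rows = [[3, 1, 1, 1, 1, 1, 1], [1, 1, 1, 1, 1, 1, 1],
                [5, 5, 5, 5, 5, 5, 5]]  # third row fixes all ranges to 4
        ordi = pd.DataFrame(rows, columns=TRAIT_NAMES, index=["a", "b", "c"])
        assert gower_distance(ordi)["a", "b"] == pytest.approx((2 / 4) / 7)

    def test_matches_direct_formula_on_random(self):
        rng = np.random.default_rng(2)
        ordi = pd.DataFrame(rng.integers(1, 6, size=(8, 7)), columns=TRAIT_NAMES)
        d = gower_distance(ordi)
        ranges = ordi.max() - ordi.min()
        for i in range(8):
            for j in range(i + 1, 8):
                expected = gower_direct(ordi.iloc[i], ordi.iloc[j], ranges)
                assert d.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_range_trait_dropped_with_warning(self):
        ordi = pd.DataFrame([[1, 3], [5, 3]], columns=["a_trait", "b_trait"],
                            index=["x", "y"])
        with pytest.warns(UserWarning, match="zero-range"):
            d = gower_distance(ordi)
        assert d["x", "y"] == pytest.approx(1.0)  # only the informative trait


class TestTraitSpace:
    def test_simplex_distances_preserved(self):
        # regular 4-simplex: five points, all pairwise distances equal
        pts = np.vstack([np.eye(5)[i] for i in range(5)])
        ids = [f"t{i}" for i in range(5)]
        extra = np.full((1, 5), 0.2)  # centroid point to reach >= 6 taxa
        d = squareform(pdist(np.vstack([pts, extra])))
        space = build_trait_space(
            DistanceMatrix(d, ids=ids + ["centre"]), n_axes=4
        )
        got = squareform(pdist(space.coordinates.loc[ids].to_numpy()))
        want = squareform(pdist(pts))
        assert np.allclose(got, want, atol=1e-9)

    def test_axes_ordered_by_eigenvalue(self, default_scenario):
        from reeftraits.synthetic import default_trait_breaks

        table = impute_traits(default_scenario.trait_table)
        ordi = bin_traits(table, default_trait_breaks())
        space = build_trait_space(gower_distance(ordi))
        eig = space.eigenvalues
        assert np.all(np.diff(eig) <= 1e-12)

    def test_too_few_taxa_rejected(self):
        d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        with pytest.raises(ValueError):
            build_trait_space(d)


class TestVolumeFraction:
    def _square_space(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5], [0.2, 0.2]]
        return _space_from_points(pts, ["c1", "c2", "c3", "c4", "mid", "in2"])

    def test_full_set_is_one(self):
        space = self._square_space()
        assert trait_volume_fraction(space, space.taxa).fraction == pytest.approx(1.0)

    def test_three_corners_give_half_square(self):
        space = self._square_space()
        out = trait_volume_fraction(space, ["c1", "c2", "c3"])
        assert out.fraction == pytest.approx(0.5, abs=1e-12)
        assert not out.degenerate

    def test_interior_taxa_do_not_matter(self):
        space = self._square_space()
        with_mid = trait_volume_fraction(space, ["c1", "c2", "c3", "mid"])
        without = trait_volume_fraction(space, ["c1", "c2", "c3"])
        assert with_mid.fraction == pytest.approx(without.fraction, abs=1e-12)

    def test_degenerate_subset_flagged_zero(self):
        space = self._square_space()
        out = trait_volume_fraction(space, ["c1", "c2"])
        assert out.fraction == 0.0 and out.degenerate

    def test_monotone_under_superset(self):
        rng = np.random.default_rng(0)
        space = _space_from_points(rng.normal(size=(20, 3)))
        taxa = space.taxa
        sub = taxa[:8]
        sup = taxa[:14]
        assert (
            trait_volume_fraction(space, sub).fraction
            <= trait_volume_fraction(space, sup).fraction + 1e-12
        )

    def test_unknown_taxon_rejected(self):
        space = self._square_space()
        with pytest.raises(KeyError):
            trait_volume_fraction(space, ["c1", "nope"])


class TestRedundancy:
    def test_coincident_taxa_zero(self):
        space = _space_from_points(np.zeros((6, 4)))
        assert functional_redundancy_5nn(space, space.taxa) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 4))
        space = _space_from_points(pts)
        got = functional_redundancy_5nn(space, space.taxa)
        assert got == pytest.approx(redundancy_5nn_direct(pts), abs=1e-9)

    def test_duplicates_decrease_mean(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 4))
        dup = np.vstack([pts, np.repeat(pts[:1], 5, axis=0)])
        before = redundancy_5nn_direct(pts)
        after_direct = redundancy_5nn_direct(dup)
        space = _space_from_points(dup)
        after = functional_redundancy_5nn(space, space.taxa)
        assert after == pytest.approx(after_direct, abs=1e-9)
        assert after < before

    def test_minimum_subset_size(self):
        space = _space_from_points(np.zeros((6, 2)))
        with pytest.raises(ValueError):
            functional_redundancy_5nn(space, space.taxa[:5])


class TestDispersion:
    def test_single_taxon_zero(self):
        space = _space_from_points([[1.0, 2.0], [3.0, 4.0], [0.0, 0.0]])
        w = pd.Series({space.taxa[0]: 2.0})
        assert functional_dispersion(space, w) == 0.0

    def test_two_equal_weights_half_distance(self):
        space = _space_from_points([[0.0, 0.0], [3.0, 4.0], [9.0, 9.0]])
        w = pd.Series({space.taxa[0]: 1.0, space.taxa[1]: 1.0})
        assert functional_dispersion(space, w) == pytest.approx(2.5)

    def test_weighted_bruteforce_oracle(self):
        pts = [[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]]
        space = _space_from_points(pts)
        w = pd.Series(dict(zip(space.taxa, [2.0, 1.0, 1.0])))
        assert functional_dispersion(space, w) == pytest.approx(
            fdis_direct(pts, [2, 1, 1]), abs=1e-12
        )

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 4))
        space = _space_from_points(pts)
        w = pd.Series(rng.gamma(2.0, 1.0, 12), index=space.taxa)
        a = functional_dispersion(space, w)
        b = functional_dispersion(space, w * 1234.5)
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_zero_weights_rejected(self):
        space = _space_from_points(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            functional_dispersion(space, pd.Series(0.0, index=space.taxa))


class TestKdeOccupancy:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(4)
        space = _space_from_points(rng.normal(size=(40, 2)))
        kmap = kde_occupancy(space, space.taxa, axis_pair=(1, 2))
        cell = (kmap.x[1] - kmap.x[0]) * (kmap.y[1] - kmap.y[0])
        assert kmap.density.sum() * cell == pytest.approx(1.0, abs=0.02)

    def test_symmetric_cross_symmetric_density(self):
        pts = [[1, 0], [-1, 0], [0, 1], [0, -1]]
        space = _space_from_points(pts)
        kmap = kde_occupancy(space, space.taxa, grid_size=81)
        assert np.allclose(kmap.density, np.rot90(kmap.density), atol=1e-10)

    def test_contour_mass_on_gaussian_sample(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(1500, 2))
        space = _space_from_points(pts)
        kmap = kde_occupancy(space, space.taxa, grid_size=121)
        # independent draw: fraction of fresh points inside the 0.95 contour
        fresh = rng.normal(size=(4000, 2))
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(np.asarray(pts, float).T)
        dens = kde(fresh.T)
        frac = np.mean(dens >= kmap.contour_levels[0.95])
        assert frac == pytest.approx(0.95, abs=0.02)

    def test_zero_variance_axis_rejected(self):
        pts = [[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]]
        space = _space_from_points(pts)
        with pytest.raises(ValueError, match="zero-variance"):
            kde_occupancy(space, space.taxa)
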