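import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from reeftraits.multivariate import (
    bray_curtis,
    dbrda,
    dbrda_forward_select,
    pcoa,
    permanova,
)
from oracles import bray_curtis_direct, pseudo_f_one_factor_direct


def _euclid_dm(points):
    d = squareform(pdist(points))
    return DistanceMatrix(d, ids=[str(i) for i in range(len(points))])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert bray_curtis(m)["a", "b"] == 0.0

    def test_disjoint_rows_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis(m)["a", "b"] == pytest.approx(1.0)

    def test_hand_value(self):
        m = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["a", "b"], dtype=float)
        assert bray_curtis(m)["a", "b"] == pytest.approx(0.5)

    def test_matches_direct_formula_on_random(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.gamma(1.0, 1.0, size=(6, 9)))
        d = bray_curtis(m)
        for i in range(6):
            for j in range(i + 1, 6):
                assert d[str(i), str(j)] == pytest.approx(
                    bray_curtis_direct(m.iloc[i], m.iloc[j]), abs=1e-12
                )

    def test_all_zero_row_names_unit(self):
        m = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(m)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        ordn = pcoa(d)
        positive = ordn.eigenvalues[ordn.eigenvalues > 1e-9]
        assert positive.size == 1
        axis = ordn.coordinates.iloc[:, 0].to_numpy()
        assert np.allclose(np.sort(axis), [-1, 0, 1], atol=1e-9)

    def test_unit_square_two_equal_eigenvalues(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        ordn = pcoa(_euclid_dm(pts))
        assert ordn.explained[0] == pytest.approx(0.5, abs=1e-9)
        assert ordn.explained[1] == pytest.approx(0.5, abs=1e-9)

    def test_duplicated_unit_coincident(self):
        pts = np.array([[0, 0], [0, 0], [3, 4], [1, 2]], float)
        ordn = pcoa(_euclid_dm(pts))
        c = ordn.coordinates.to_numpy()
        assert np.allclose(c[0], c[1], atol=1e-9)

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 4))
        d = _euclid_dm(pts)
        ordn = pcoa(d)
        again = squareform(pdist(ordn.coordinates.to_numpy()))
        assert np.allclose(again, d.data, atol=1e-9)

    def test_eigenvalue_sum_equals_total_inertia(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = _euclid_dm(pts)
        ordn = pcoa(d)
        total = (d.data**2).sum() / (2 * 8)
        assert ordn.eigenvalues[ordn.eigenvalues > 0].sum() == pytest.approx(
            total, abs=1e-9
        )

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 3))
        d = _euclid_dm(pts)
        ours = pcoa(d).coordinates.to_numpy()
        theirs = skbio_pcoa(d, number_of_dimensions=3).samples.to_numpy()
        k = min(ours.shape[1], 3)
        assert np.allclose(np.abs(ours[:, :k]), np.abs(theirs[:, :k]), atol=1e-8)

    def test_cailliez_makes_bray_curtis_embeddable(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.gamma(1.0, 1.0, size=(8, 5)))
        d = bray_curtis(m)
        ordn = pcoa(d, correction="cailliez")
        assert (ordn.eigenvalues > -1e-8).all()

    def test_too_few_units(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


class TestPermanova:
    def test_identical_units_all_residual(self):
        d = DistanceMatrix(np.zeros((8, 8)), ids=[str(i) for i in range(8)])
        design = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4})
        table = permanova(d, design, terms=("g",), n_perm=99, seed=0)
        assert table.loc["Residual", "R2"] == pytest.approx(1.0)
        assert table.loc["g", "R2"] == pytest.approx(0.0, abs=1e-12)

    def test_separated_clusters_hit_p_floor(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(50, 0.1, (5, 2))])
        d = _euclid_dm(pts)
        design = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5})
        table = permanova(d, design, terms=("g",), n_perm=999, seed=2)
        assert table.loc["g", "p"] <= 10 / 1000  # identity-class permutations only

    def test_r2_partition_sums_to_one(self, default_scenario):
        from reeftraits.survey import coral_abundance_matrix

        mat = coral_abundance_matrix(default_scenario.transects, "site-year")
        d = bray_curtis(mat)
        design = pd.DataFrame(
            {
                "year": mat.index.get_level_values("year").astype(str),
                "protected": [str(mat.attrs["protected"][k]) for k in mat.index],
            }
        )
        table = permanova(d, design, ("year", "protected", "year:protected"),
                          n_perm=99, seed=3)
        terms = table.drop(index="Total")
        assert terms["R2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (table["p"].dropna() >= 1 / 100).all()

    def test_one_factor_f_matches_classical_formula(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        d = _euclid_dm(pts)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        table = permanova(d, pd.DataFrame({"g": labels}), terms=("g",),
                          n_perm=9, seed=0)
        f_direct = pseudo_f_one_factor_direct(d.data, labels)
        assert table.loc["g", "pseudo_F"] == pytest.approx(f_direct, abs=1e-9)

    def test_one_factor_agrees_with_skbio(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3))
        d = _euclid_dm(pts)
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, pd.DataFrame({"g": labels}), terms=("g",),
                         n_perm=9, seed=0)
        theirs = skbio_permanova(d, grouping=labels, permutations=9)
        assert ours.loc["g", "pseudo_F"] == pytest.approx(
            theirs["test statistic"], abs=1e-9
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 2))
        d = _euclid_dm(pts)
        design = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5})
        t1 = permanova(d, design, terms=("g",), n_perm=199, seed=42)
        t2 = permanova(d, design, terms=("g",), n_perm=199, seed=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_seed_required(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValueError, match="seed"):
            permanova(d, pd.DataFrame({"g": list("aabb")}), terms=("g",))

    def test_aliased_term_rejected(self):
        rng = np.random.default_rng(10)
        d = _euclid_dm(rng.normal(size=(6, 2)))
        design = pd.DataFrame({"g": list("aaabbb"), "h": list("aaabbb")})
        with pytest.raises(ValueError, match="aliased"):
            permanova(d, design, terms=("g", "h"), n_perm=9, seed=0)


class TestDbRda:
    def _setup(self, seed, effect=3.0, n=24):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = np.outer(x, np.array([1.0, -0.5, 0.5])) * effect + rng.normal(
            size=(n, 3)
        )
        d = _euclid_dm(y)
        cands = pd.DataFrame(
            {"driver": x, **{f"noise{i}": rng.normal(size=n) for i in range(11)}}
        )
        return d, cands

    def test_true_driver_selected_first(self):
        d, cands = self._setup(0)
        model = dbrda_forward_select(d, cands)
        assert model.selected[0] == "driver"

    def test_constant_response_empty_selection(self):
        d = DistanceMatrix(np.zeros((6, 6)), ids=[str(i) for i in range(6)])
        cands = pd.DataFrame({"x": np.arange(6.0)})
        model = dbrda_forward_select(d, cands)
        assert model.selected == [] and model.constrained_inertia == 0.0

    def test_inertia_decomposition(self):
        d, cands = self._setup(1)
        model = dbrda(d, cands[["driver", "noise0"]])
        assert (
            model.constrained_inertia + model.unconstrained_inertia
            == pytest.approx(model.total_inertia, abs=1e-9)
        )
        assert model.constrained_inertia <= model.total_inertia + 1e-9

    def test_collinear_candidate_skipped(self):
        d, cands = self._setup(2)
        cands["copy"] = cands["driver"] * 2.0
        model = dbrda_forward_select(d, cands[["driver", "copy"]])
        assert "copy" not in model.selected
        skipped = model.steps[model.steps["aic"].isna()]
        assert "copy" in set(skipped["candidate"])
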