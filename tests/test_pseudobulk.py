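import numpy as np
import pandas as pd
import pytest

from sscryo.pseudobulk import (
    distance_matrix,
    pca,
    permanova,
    pooled_group_design,
    pseudobulk_mean,
)


def _toy_obs():
    return pd.DataFrame(
        {
            "cell_type": ["SSC", "SSC", "SSC", "SSC"],
            "replicate": ["r1", "r1", "r2", "r2"],
            "treatment": ["fresh", "fresh", "frozen", "frozen"],
        },
        index=pd.Index([f"c{i}" for i in range(4)], name="barcode"),
    )


class TestPseudobulkMean:
    def test_row_means_match_hand_computation(self):
        genes = pd.Index(["g1", "g2"])
        X = np.array([[1.0, 0.0], [3.0, 2.0], [5.0, 5.0], [7.0, 1.0]])
        pb = pseudobulk_mean(X, genes, _toy_obs(), "SSC")
        assert pb.loc["r1", "g1"] == pytest.approx(2.0)
        assert pb.loc["r1", "g2"] == pytest.approx(1.0)
        assert pb.loc["r2", "g1"] == pytest.approx(6.0)
        assert list(pb["n_cells"]) == [2, 2]

    def test_single_cell_group_equals_that_cell(self):
        genes = pd.Index(["g1"])
        obs = _toy_obs().iloc[:3]
        X = np.array([[1.0], [3.0], [9.0]])
        pb = pseudobulk_mean(X, genes, obs, "SSC")
        assert pb.loc["r2", "g1"] == pytest.approx(9.0)

    def test_replicate_without_the_cell_type_is_omitted(self, caplog):
        obs = _toy_obs()
        obs.loc[["c2", "c3"], "cell_type"] = "progenitor"
        pb = pseudobulk_mean(np.ones((4, 1)), pd.Index(["g1"]), obs, "SSC")
        assert list(pb.index) == ["r1"]


class TestPca:
    def test_coordinates_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(5, 10))
        coords, var_pct = pca(X)
        centered = X - X.mean(axis=0)
        cov = centered.T @ centered / (X.shape[0] - 1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1][: coords.shape[1]]
        assert var_pct == pytest.approx(100 * evals / evals.sum())
        # coordinate variances equal the eigenvalues (up to component sign)
        assert coords.var(axis=0, ddof=1) == pytest.approx(evals)

    def test_identical_rows_coincide(self):
        X = np.vstack([np.ones(4), np.ones(4), np.zeros(4)])
        coords, _ = pca(X)
        assert coords[0] == pytest.approx(coords[1])

    def test_variance_shares_are_nonincreasing(self, rng):
        _, var_pct = pca(rng.normal(size=(8, 12)))
        assert np.all(np.diff(var_pct) <= 1e-9)

    def test_constant_matrix_handled_without_failure(self):
        coords, var_pct = pca(np.ones((3, 5)))
        assert np.allclose(coords, 0)
        assert np.allclose(var_pct, 0)


class TestDistanceMatrix:
    def test_closed_form_3_4_5(self):
        D = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 0] == 0.0

    def test_matches_brute_force_pairwise_oracle(self, rng):
        X = rng.normal(size=(6, 8))
        D = distance_matrix(X)
        for i in range(6):
            for j in range(6):
                assert D[i, j] == pytest.approx(np.linalg.norm(X[i] - X[j]))
        assert D == pytest.approx(D.T)

    def test_nan_input_rejected(self):
        X = np.ones((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            distance_matrix(X)


class TestPermanova:
    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        from itertools import combinations

        from sscryo.pseudobulk import _pseudo_f

        X = rng.normal(size=(5, 4))
        labels = ["a", "a", "b", "b", "b"]
        D = distance_matrix(X)
        res = permanova(D, labels, method="exhaustive")
        d2 = D**2
        obs = _pseudo_f(d2, np.array([0, 0, 1, 1, 1]), 2)
        hits = sum(
            _pseudo_f(
                d2,
                np.array([0 if i in combo else 1 for i in range(5)]),
                2,
            )
            >= obs - 1e-12
            for combo in combinations(range(5), 2)
        )
        assert res.n_permutations == 10
        assert res.p_value == pytest.approx(hits / 10)

    def test_scaling_distances_leaves_f_and_p_unchanged(self, rng):
        X = rng.normal(size=(8, 5))
        D = distance_matrix(X)
        labels = ["a"] * 4 + ["b"] * 4
        r1 = permanova(D, labels, n_permutations=99, seed=5)
        r2 = permanova(3.0 * D, labels, n_permutations=99, seed=5)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)
        assert r1.p_value == r2.p_value

    def test_pseudo_f_agrees_with_independent_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        X = rng.normal(size=(9, 6))
        X[:3] += 0.5
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        D = distance_matrix(X)
        mine = permanova(D, labels, n_permutations=99, seed=0)
        theirs = sk_permanova(DistanceMatrix(D), grouping=labels, permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"])

    def test_row_and_label_permutation_invariance(self, rng):
        X = rng.normal(size=(6, 4))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        D = distance_matrix(X)
        perm = rng.permutation(6)
        r1 = permanova(D, labels, method="exhaustive")
        r2 = permanova(D[np.ix_(perm, perm)], labels[perm], method="exhaustive")
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_single_group_and_bad_permutation_count_rejected(self, rng):
        D = distance_matrix(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            permanova(D, ["a"] * 4)
        with pytest.raises(ValueError):
            permanova(D, ["a", "a", "b", "b"], n_permutations=0)

    def test_planted_shift_saturates_the_permutation_floor(self, rng):
        """2-pooled-SD shift over 20 genes with 3+3 replicates: the test hits
        the resolution floor of the design in (almost) every simulation.

        A 3+3 two-group permutation test cannot go below p = 2/20 = 0.1: of
        the 20 labelings, the observed one and its mirror always tie F_obs.
        A well-powered test therefore sits *at* that floor, not under it.
        """
        ps = []
        for _ in range(100):
            X = rng.normal(size=(6, 20))
            X[:3] += 2.0
            res = permanova(
                distance_matrix(X), ["a"] * 3 + ["b"] * 3, method="exhaustive"
            )
            ps.append(res.p_value)
        assert np.median(ps) <= 0.1


class TestPooledGroupDesign:
    def test_frozen_arms_pool_into_sizes_three_and_six(self):
        treatments = ["fresh"] * 3 + ["short_frozen"] * 3 + ["long_frozen"] * 3
        pooling = {
            "fresh": "fresh",
            "short_frozen": "frozen",
            "long_frozen": "frozen",
        }
        groups = pooled_group_design(treatments, pooling)
        assert groups.value_counts().to_dict() == {"frozen": 6, "fresh": 3}

    def test_identity_pooling_preserves_treatments(self):
        groups = pooled_group_design(["a", "b"], None)
        assert list(groups) == ["a", "b"]

    def test_unmapped_treatment_rejected(self):
        with pytest.raises(KeyError):
            pooled_group_design(["a", "b"], {"a": "x"})
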