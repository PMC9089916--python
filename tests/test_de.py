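from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import sscryo as s
from sscryo.de import apply_deg_cutoffs, bh_adjust, overlap_sets, wilcoxon_de


def bh_oracle(p):
    """Brute-force BH step-up: min over the tail of p * m / rank, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_idx, i in enumerate(order):
        tail = [
            p[j] * m / (np.flatnonzero(order == j)[0] + 1)
            for j in order[rank_idx:]
        ]
        out[i] = min(1.0, min(tail))
    return out


def rank_sum_p_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(a)].sum()
    sums = [
        ranks[list(c)].sum() for c in combinations(range(len(pooled)), len(a))
    ]
    mean = np.mean(sums)
    extreme = sum(abs(v - mean) >= abs(obs - mean) - 1e-12 for v in sums)
    return extreme / len(sums)


def _counts_for_values(values_a, values_b, total=1000):
    """Two-gene count matrix with constant library size so CPM tracks gene 1."""
    vals = np.array(list(values_a) + list(values_b), dtype=np.int64)
    X = np.column_stack([vals, total - vals])
    obs = pd.DataFrame(
        {"treatment": ["A"] * len(values_a) + ["B"] * len(values_b)},
        index=pd.Index([f"c{i}" for i in range(len(vals))]),
    )
    return X, pd.Index(["gene", "ballast"]), obs


class TestWilcoxonDe:
    def test_small_sample_p_matches_exact_enumeration_oracle(self):
        a, b = [1, 2, 3], [4, 5, 6]
        X, genes, obs = _counts_for_values(a, b)
        table = wilcoxon_de(X, genes, obs, "A", "B")
        assert table.loc["gene", "p_value"] == pytest.approx(
            rank_sum_p_oracle(np.array(a, float), np.array(b, float))
        )
        a, b = [1, 9, 4], [3, 2, 8]
        X, genes, obs = _counts_for_values(a, b)
        table = wilcoxon_de(X, genes, obs, "A", "B")
        assert table.loc["gene", "p_value"] == pytest.approx(
            rank_sum_p_oracle(np.array(a, float), np.array(b, float))
        )

    def test_identical_groups_produce_no_signal(self):
        X, genes, obs = _counts_for_values([5, 7, 9, 11], [5, 7, 9, 11])
        table = wilcoxon_de(X, genes, obs, "A", "B")
        assert table["log2_fold_change"].tolist() == pytest.approx([0.0, 0.0])
        assert not table["significant"].any()

    def test_swapping_groups_negates_fold_changes_and_keeps_p(self, rng):
        X = rng.poisson(5, size=(40, 15))
        obs = pd.DataFrame(
            {"treatment": ["A"] * 20 + ["B"] * 20},
            index=pd.Index([f"c{i}" for i in range(40)]),
        )
        genes = pd.Index([f"g{i}" for i in range(15)])
        t_ab = wilcoxon_de(X, genes, obs, "A", "B")
        t_ba = wilcoxon_de(X, genes, obs, "B", "A")
        assert t_ba["log2_fold_change"].to_numpy() == pytest.approx(
            -t_ab["log2_fold_change"].to_numpy()
        )
        assert t_ba["p_value"].to_numpy() == pytest.approx(
            t_ab["p_value"].to_numpy()
        )

    def test_planted_fold_change_recovered_and_flagged(self):
        """A 2.8-fold planted effect at 500 cells/group is estimated within
        +/- 0.3 of log2(2.8) and called significant."""
        props = {st: 0.0 for st in s.STAGES}
        props["round spermatid"] = 1.0
        cfg = s.GeneratorConfig(
            treatments=("ctrl", "treat"),
            replicates_per_arm=1,
            cells_per_replicate=500,
            stage_proportions=props,
            proportion_noise_sigma=0.0,
            effects={
                "treat": s.ArmEffects(
                    expression_folds={"round spermatid": {"Prm1": 1 / 2.8}}
                )
            },
            seed=5,
        )
        counts, truth = s.simulate_experiment(cfg)
        table = wilcoxon_de(counts.rat, counts.rat_genes, truth.cells, "ctrl", "treat")
        row = table.loc["Prm1"]
        assert row["log2_fold_change"] == pytest.approx(np.log2(2.8), abs=0.3)
        assert row["significant"]

    def test_empty_group_rejected(self):
        X, genes, obs = _counts_for_values([1, 2], [3, 4])
        with pytest.raises(ValueError, match="empty group"):
            wilcoxon_de(X, genes, obs, "A", "C")


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_matches_brute_force_oracle_on_known_vector(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 30))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_equal_ps_stay_equal(self):
        assert len(set(np.round(bh_adjust([0.2] * 5), 12))) == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_padding_with_null_genes_only_acts_through_the_denominator(self, rng):
        p = rng.uniform(size=20)
        padded = np.concatenate([p, np.ones(10)])
        assert bh_adjust(padded)[:20] == pytest.approx(bh_oracle(padded)[:20])


class TestDegCutoffs:
    def _frame(self, log2fc, padj):
        return pd.DataFrame(
            {"log2_fold_change": log2fc, "p_adjusted": padj},
            index=[f"g{i}" for i in range(len(log2fc))],
        )

    def test_threshold_semantics_at_the_printed_cutoffs(self):
        res = self._frame([0.60, 0.50, -0.70, np.log2(1.5)], [0.04, 0.001, 0.05, 0.05])
        sig = apply_deg_cutoffs(res)
        assert sig == {"g0", "g2", "g3"}

    def test_empty_results_give_empty_set(self):
        assert apply_deg_cutoffs(self._frame([], [])) == set()


class TestOverlapSets:
    def test_disjoint_and_identical_sets(self):
        assert overlap_sets({"A": {"a"}, "B": {"b"}}) == {"A": 1, "B": 1, "A&B": 0}
        assert overlap_sets({"A": {"x", "y"}, "B": {"x", "y"}}) == {
            "A": 0,
            "B": 0,
            "A&B": 2,
        }

    def test_three_sets_match_membership_enumeration(self, rng):
        universe = [f"g{i}" for i in range(30)]
        sets = {
            name: {g for g in universe if rng.random() < 0.4}
            for name in ("A", "B", "C")
        }
        regions = overlap_sets(sets)
        for g in set.union(*sets.values()):
            key = "&".join(n for n in ("A", "B", "C") if g in sets[n])
            assert key in regions
        assert sum(regions.values()) == len(set.union(*sets.values()))

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_sets({"A": {"a"}})
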