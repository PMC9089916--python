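import numpy as np
import pandas as pd
import pytest

import sscryo as s
from sscryo import qc
from sscryo.scoring import (
    GeneProgram,
    PROAPOPTOTIC_PROGRAM,
    anova_per_celltype,
    celltype_proportions,
    classify_apoptotic,
    module_score,
)


@pytest.fixture(scope="module")
def apoptotic_experiment():
    cfg = s.preset(
        "null",
        seed=2,
        cells_per_replicate=250,
        n_genes_per_species=450,
        apoptotic_fraction=0.3,
    )
    counts, truth = s.simulate_experiment(cfg)
    return qc.normalize_cpm_log(counts.rat), counts.rat_genes, truth


class TestModuleScore:
    def test_whole_universe_program_scores_exactly_zero(self, apoptotic_experiment):
        X_norm, genes, _ = apoptotic_experiment
        program = GeneProgram("everything", list(genes))
        scores = module_score(X_norm[:40], genes, program, seed=0)
        assert np.abs(scores).max() == 0.0

    def test_per_cell_constant_shift_cancels(self, apoptotic_experiment):
        X_norm, genes, _ = apoptotic_experiment
        dense = X_norm[:60].toarray()
        shifted = dense.copy()
        shifted[7] += 3.0
        s1 = module_score(dense, genes, PROAPOPTOTIC_PROGRAM, seed=1)
        s2 = module_score(shifted, genes, PROAPOPTOTIC_PROGRAM, seed=1)
        assert s2[7] == pytest.approx(s1[7])

    def test_planted_induction_scores_higher_than_background(
        self, apoptotic_experiment
    ):
        X_norm, genes, truth = apoptotic_experiment
        scores = module_score(X_norm, genes, PROAPOPTOTIC_PROGRAM, seed=0)
        apopt = truth.cells["apoptotic"].to_numpy()
        assert np.median(scores[apopt]) > np.median(scores[~apopt])

    def test_deterministic_under_seed(self, apoptotic_experiment):
        X_norm, genes, _ = apoptotic_experiment
        a = module_score(X_norm[:50], genes, PROAPOPTOTIC_PROGRAM, seed=9)
        b = module_score(X_norm[:50], genes, PROAPOPTOTIC_PROGRAM, seed=9)
        assert a == pytest.approx(b)

    def test_missing_program_gene_named_in_error(self):
        with pytest.raises(KeyError, match="Bax"):
            module_score(
                np.zeros((3, 2)), pd.Index(["a", "b"]), GeneProgram("p", ["Bax"])
            )

    def test_duplicate_or_empty_program_rejected(self):
        with pytest.raises(ValueError):
            GeneProgram("p", [])
        with pytest.raises(ValueError):
            GeneProgram("p", ["Bax", "Bax"])


class TestClassifyApoptotic:
    def test_cutoff_is_strictly_greater_than(self):
        flags = classify_apoptotic(np.array([0.2, 0.1, 0.0999, 0.100001]))
        assert flags.tolist() == [True, False, False, True]

    def test_fraction_per_replicate_and_type(self):
        obs = pd.DataFrame(
            {"replicate": ["r1"] * 10, "cell_type": ["SSC"] * 10},
            index=[f"c{i}" for i in range(10)],
        )
        scores = np.array([0.5] * 3 + [0.0] * 7)
        _, fractions = classify_apoptotic(scores, obs)
        assert fractions.loc[0, "apoptotic_fraction"] == pytest.approx(0.3)

    def test_flagged_fraction_is_monotone_in_cutoff(self, rng):
        scores = rng.normal(size=500)
        rates = [classify_apoptotic(scores, cutoff=c).mean() for c in (-1, 0, 0.1, 1)]
        assert all(b <= a for a, b in zip(rates, rates[1:]))


class TestCelltypeProportions:
    def _obs(self):
        rows = (
            [("t1", "r1", "SSC")] * 50
            + [("t1", "r1", "round spermatid")] * 50
            + [("t1", "r2", "SSC")] * 30
            + [("t1", "r2", "round spermatid")] * 70
            + [("t2", "r3", "SSC")] * 10
            + [("t2", "r3", "round spermatid")] * 90
        )
        return pd.DataFrame(
            rows,
            columns=["treatment", "replicate", "cell_type"],
            index=[f"c{i}" for i in range(len(rows))],
        )

    def test_hand_counted_three_replicate_table(self):
        props = celltype_proportions(self._obs())
        assert props.loc[("t1", "r1"), "SSC"] == pytest.approx(0.5)
        assert props.loc[("t1", "r2"), "SSC"] == pytest.approx(0.3)
        assert props.loc[("t2", "r3"), "round spermatid"] == pytest.approx(0.9)

    def test_rows_sum_to_one(self):
        props = celltype_proportions(self._obs())
        assert props.sum(axis=1).to_numpy() == pytest.approx(1.0, abs=1e-9)

    def test_untyped_cells_rejected(self):
        obs = self._obs()
        obs.loc[obs.index[0], "cell_type"] = None
        with pytest.raises(ValueError):
            celltype_proportions(obs)


class TestAnovaPerCelltype:
    def _props(self, values):
        idx = pd.MultiIndex.from_tuples(
            [("a", "r1"), ("a", "r2"), ("a", "r3"), ("b", "r4"), ("b", "r5"), ("b", "r6")],
            names=["treatment", "replicate"],
        )
        return pd.DataFrame({"SSC": values}, index=idx)

    def test_identical_proportions_give_f_zero_p_one(self):
        res = anova_per_celltype(self._props([0.2] * 6))
        assert res.loc["SSC", "F"] == 0.0
        assert res.loc["SSC", "p_value"] == 1.0

    def test_f_statistic_matches_closed_form_sums_of_squares(self):
        vals = np.array([0.10, 0.12, 0.14, 0.20, 0.22, 0.24])
        res = anova_per_celltype(self._props(vals))
        groups = [vals[:3], vals[3:]]
        grand = vals.mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_b / 1) / (ss_w / 4)
        assert res.loc["SSC", "F"] == pytest.approx(f_oracle)

    def test_single_replicate_treatment_rejected(self):
        idx = pd.MultiIndex.from_tuples(
            [("a", "r1"), ("a", "r2"), ("b", "r3")],
            names=["treatment", "replicate"],
        )
        with pytest.raises(ValueError):
            anova_per_celltype(pd.DataFrame({"SSC": [0.1, 0.2, 0.3]}, index=idx))

    def test_power_against_planted_proportion_shift(self, rng):
        """+0.10 SSC shift with 3 replicates/arm and 0.02 within-arm SD is
        detected at p < 0.05 in at least 90% of 100 simulations."""
        hits = 0
        for _ in range(100):
            vals = np.concatenate(
                [
                    rng.normal(0.10, 0.02, 3),
                    rng.normal(0.20, 0.02, 3),
                    rng.normal(0.10, 0.02, 3),
                ]
            )
            idx = pd.MultiIndex.from_tuples(
                [(arm, f"r{i}") for arm in ("a", "b", "c") for i in range(3)],
                names=["treatment", "replicate"],
            )
            res = anova_per_celltype(pd.DataFrame({"SSC": vals}, index=idx))
            hits += res.loc["SSC", "p_value"] < 0.05
        assert hits >= 90
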