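"""Rank-sum case/control comparisons and tail tests."""

import numpy as np
import pandas as pd
import pytest

from geneburden.scoring import GeneScoreMatrix
from geneburden.simulate import causal_gene_scores
from geneburden.stats import StatsError, compare_gene, compare_tail, run_validation


class TestCompareGene:
    def test_identical_samples_give_no_evidence(self):
        res = compare_gene([1, 2, 3], [1, 2, 3])
        assert res.p_value > 0.9

    def test_all_tied_values_give_p_one(self):
        res = compare_gene([0.0] * 10, [0.0] * 7)
        assert res.p_value == 1.0
        assert res.u_statistic == 35.0  # n1*n2/2

    def test_maximal_separation_exact_small_sample(self):
        """Complete separation of 3 vs 3: U = 9 and the smallest exact one-sided p."""
        res = compare_gene([10, 11, 12], [1, 2, 3], alternative="greater")
        assert res.u_statistic == 9.0
        assert res.p_value == pytest.approx(1 / 20)  # 1 of C(6,3) arrangements

    def test_group_summaries_reported(self):
        res = compare_gene([1.0, 3.0], [0.0, 2.0], gene="NOD2", metric="CADD")
        assert (res.gene, res.metric) == ("NOD2", "CADD")
        assert (res.case_max, res.case_mean) == (3.0, 2.0)
        assert (res.control_max, res.control_mean) == (2.0, 1.0)
        assert (res.n_case, res.n_control) == (2, 2)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            compare_gene([], [1.0])
        with pytest.raises(StatsError):
            compare_gene([1.0], [])

    def test_unknown_alternative_rejected(self):
        with pytest.raises(StatsError):
            compare_gene([1.0], [2.0], alternative="less")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_asymptotic_p_matches_permutation_oracle(self, seed):
        """Tie-corrected normal approximation vs. a direct permutation null."""
        rng = np.random.default_rng(seed)
        case = np.round(rng.exponential(1.0, 30) * rng.integers(0, 2, 30), 1)
        control = np.round(rng.exponential(1.0, 25) * rng.integers(0, 2, 25), 1)
        res = compare_gene(case, control, alternative="greater")

        pooled = np.concatenate([case, control])
        n1 = case.size
        from scipy.stats import rankdata

        def u_stat(values):
            ranks = rankdata(values)
            return ranks[:n1].sum() - n1 * (n1 + 1) / 2

        observed = u_stat(pooled)
        perms = 20_000
        count = 0
        for _ in range(perms):
            rng.shuffle(pooled)
            count += u_stat(pooled) >= observed
        p_perm = (count + 1) / (perms + 1)
        assert res.p_value == pytest.approx(p_perm, abs=0.02)


class TestCompareTail:
    def test_ceil_rule_on_group_of_610(self):
        rng = np.random.default_rng(0)
        case = rng.normal(size=610)
        control = rng.normal(size=500)
        res = compare_tail(case, control, 0.05)
        assert res.n_case == 31  # ceil(0.05 * 610)
        assert res.n_control == 25
        assert res.tail_fraction == 0.05
        assert res.alternative == "greater"

    def test_ties_at_the_cut_are_all_included(self):
        case = np.array([5.0, 5.0, 5.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        res = compare_tail(case, np.arange(10.0), 0.1)  # ceil(1) = 1, but 3 tied at 5
        assert res.n_case == 3

    def test_full_tail_equals_one_sided_full_test(self):
        rng = np.random.default_rng(3)
        case = np.where(rng.random(60) < 0.6, 0.0, rng.exponential(1, 60))
        control = np.where(rng.random(55) < 0.6, 0.0, rng.exponential(1, 55))
        tail = compare_tail(case, control, 1.0)
        full = compare_gene(case, control, alternative="greater")
        assert tail.p_value == full.p_value
        assert tail.u_statistic == full.u_statistic

    def test_invalid_fraction_rejected(self):
        with pytest.raises(StatsError):
            compare_tail([1.0], [1.0], 0.0)
        with pytest.raises(StatsError):
            compare_tail([1.0], [1.0], 1.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tail_outperforms_full_test_for_minority_carrier_gene(self, seed):
        """When few cases carry the risk variant on top of a continuous
        background score distribution, restricting to the extreme tail
        concentrates the signal that the full-distribution test dilutes."""
        rng = np.random.default_rng(seed)
        background_case = rng.lognormal(-1, 0.7, 400)
        background_control = rng.lognormal(-1, 0.7, 400)
        carrier_bonus = causal_gene_scores(400, 0.05, 1e-4, 0.9, rng=rng)
        control_bonus = causal_gene_scores(400, 0.005, 1e-4, 0.9, rng=rng)
        case = background_case + carrier_bonus
        control = background_control + control_bonus
        p_tail = compare_tail(case, control, 0.05).p_value
        p_full = compare_gene(case, control, alternative="greater").p_value
        assert p_tail < p_full


def _matrix(df):
    return GeneScoreMatrix(values=df, metric_name="CADD")


@pytest.fixture()
def labelled_matrix():
    rng = np.random.default_rng(5)
    samples = [f"P{i}" for i in range(30)] + [f"C{i}" for i in range(30)]
    df = pd.DataFrame(
        {
            "SIGNAL": np.concatenate([rng.exponential(2.0, 30), rng.exponential(0.5, 30)]),
            "FLAT": np.zeros(60),
        },
        index=samples,
    )
    phen = {s: ("case" if s.startswith("P") else "control") for s in samples}
    return _matrix(df), phen


class TestRunValidation:
    def test_single_gene_single_test_single_row(self, labelled_matrix):
        matrix, phen = labelled_matrix
        table = run_validation(matrix, phen, gene_list=["SIGNAL"])
        assert len(table) == 1
        row = table.iloc[0]
        assert row["gene"] == "SIGNAL" and row["test"] == "two_sided"
        assert row["n_case"] == 30 and row["n_control"] == 30
        assert row["p"] < 0.01

    def test_degenerate_all_zero_gene(self, labelled_matrix):
        matrix, phen = labelled_matrix
        table = run_validation(matrix, phen, gene_list=["FLAT"])
        row = table.iloc[0]
        assert row["p"] == 1.0
        assert row["case_mean"] == 0.0 and row["control_mean"] == 0.0

    def test_multiple_tests_per_gene(self, labelled_matrix):
        matrix, phen = labelled_matrix
        table = run_validation(
            matrix, phen,
            tests=[("two_sided", None), ("greater", None), ("tail", 0.1)],
        )
        assert len(table) == 2 * 3
        assert set(table["test"]) == {"two_sided", "greater", "tail"}
        assert table.loc[table["test"] == "tail", "tail_fraction"].unique().tolist() == [0.1]

    def test_bonferroni_scales_with_genes_tested(self, labelled_matrix):
        matrix, phen = labelled_matrix
        table = run_validation(matrix, phen)
        flat = table[table["gene"] == "FLAT"].iloc[0]
        assert flat["p_bonferroni"] == 1.0
        signal = table[table["gene"] == "SIGNAL"].iloc[0]
        assert signal["p_bonferroni"] == pytest.approx(min(1.0, signal["p"] * 2))

    def test_unknown_phenotype_sample_is_an_error(self, labelled_matrix):
        matrix, phen = labelled_matrix
        with pytest.raises(StatsError, match="unknown sample"):
            run_validation(matrix, {**phen, "GHOST": "case"})

    def test_uncovered_matrix_sample_is_an_error(self, labelled_matrix):
        matrix, phen = labelled_matrix
        phen = dict(phen)
        del phen["P0"]
        with pytest.raises(StatsError, match="without phenotype"):
            run_validation(matrix, phen)

    def test_unknown_gene_is_an_error(self, labelled_matrix):
        matrix, phen = labelled_matrix
        with pytest.raises(StatsError, match="not in matrix"):
            run_validation(matrix, phen, gene_list=["NOPE"])
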