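import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panquant.core_io import AbundanceMatrix, CohortLabel
from panquant.evaluate import (
    enumerate_subsets,
    indication_ranks,
    protein_rna_correlation,
    rank_concordance,
    select_validation_proteins,
    subset_foldchange_consistency,
    subset_overlap_concordance,
    weighted_rank_correlation,
)
from panquant.synthetic import SyntheticConfig, generate_dataset, generate_rna_matrix


def _tumor_matrix(values, indication="A"):
    cohorts = {c: CohortLabel(indication, "tumor") for c in values.columns}
    return AbundanceMatrix(values, cohorts)


class TestProteinRnaCorrelation:
    def test_identical_matrices_give_r_one(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(20, 2, (10, 6)),
                             index=[f"P{j}" for j in range(10)],
                             columns=[f"S{c}" for c in range(6)])
        m = _tumor_matrix(frame)
        r = protein_rna_correlation(m, _tumor_matrix(frame.copy()), "A")
        assert np.allclose(r.to_numpy(), 1.0)

    def test_negated_matrix_gives_minus_one(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(20, 2, (5, 5)),
                             index=[f"P{j}" for j in range(5)],
                             columns=[f"S{c}" for c in range(5)])
        r = protein_rna_correlation(_tumor_matrix(frame), _tumor_matrix(-frame), "A")
        assert np.allclose(r.to_numpy(), -1.0)

    def test_constant_protein_gets_nan(self):
        frame = pd.DataFrame(
            {"S1": [1.0, 5.0], "S2": [1.0, 6.0], "S3": [1.0, 7.0]}, index=["P1", "P2"]
        )
        r = protein_rna_correlation(_tumor_matrix(frame), _tumor_matrix(frame * 2), "A")
        assert np.isnan(r["P1"]) and r["P2"] == pytest.approx(1.0)

    def test_attenuation_matches_analytic_target(self):
        # with rna = latent + noise, expected r = 1/sqrt(1 + rna_sd^2/noise_sd^2)
        cfg = SyntheticConfig(
            n_proteins=300, indications=("A",), samples_per_cohort=(100, 2),
            censor_slope=0.0, mar_rate=0.0, rna_noise_sd=1.0, noise_sd=1.0, seed=2,
        )
        m, _, truth = generate_dataset(cfg)
        rna = generate_rna_matrix(truth, cfg)
        r = protein_rna_correlation(m, rna, "A")
        target = 1.0 / math.sqrt(1.0 + cfg.rna_noise_sd**2 / cfg.noise_sd**2)
        assert abs(r.median() - target) < 0.1


class TestValidationSelection:
    def test_majority_rule_and_boundary(self):
        corr = pd.DataFrame(
            {f"I{i}": [0.9 if i < 6 else 0.1, 0.9 if i < 5 else 0.1] for i in range(10)},
            index=["keep", "drop"],
        )
        kept = select_validation_proteins(corr)
        assert list(kept) == ["keep"]  # 6/10 strict majority; 5/10 fails

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        corr = pd.DataFrame(rng.uniform(-1, 1, (40, 7)),
                            index=[f"P{j}" for j in range(40)])
        corr[corr.abs() < 0.05] = np.nan
        kept = set(select_validation_proteins(corr, 0.5, 0.5))
        expected = set()
        for pid, row in corr.iterrows():
            defined = row.dropna()
            if len(defined) and (defined > 0.5).sum() > 0.5 * len(defined):
                expected.add(pid)
        assert kept == expected


class TestIndicationRanks:
    def _multi_matrix(self):
        rng = np.random.default_rng(4)
        cols, cohorts = {}, {}
        for ind, shift in [("A", 0.0), ("B", 1.0), ("C", 2.0)]:
            for s in range(4):
                name = f"{ind}{s}"
                cols[name] = rng.normal(20 + shift, 0.01, 5)
                cohorts[name] = CohortLabel(ind, "tumor")
        frame = pd.DataFrame(cols, index=[f"P{j}" for j in range(5)])
        return AbundanceMatrix(frame, cohorts)

    def test_ordered_medians_give_ordered_ranks(self):
        m = self._multi_matrix()
        ranks = indication_ranks(m, m.protein_ids, ["A", "B", "C"])
        assert (ranks.to_numpy() == np.array([1.0, 2.0, 3.0])).all()

    def test_ties_averaged(self):
        frame = pd.DataFrame({"A1": [5.0], "B1": [5.0], "C1": [7.0]}, index=["P1"])
        m = AbundanceMatrix(
            frame,
            {c: CohortLabel(c[0], "tumor") for c in frame.columns},
        )
        ranks = indication_ranks(m, ["P1"], ["A", "B", "C"])
        assert list(ranks.loc["P1"]) == [1.5, 1.5, 3.0]


class TestWeightedRankCorrelation:
    def test_identical_and_reversed(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([0.5, 1.0, 2.0, 0.1])
        assert weighted_rank_correlation(a, a, w) == pytest.approx(1.0)
        assert weighted_rank_correlation(a, a[::-1], np.ones(4)) == pytest.approx(-1.0)

    def test_equal_weights_reduce_to_spearman(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        ra = stats.rankdata(x)
        rb = stats.rankdata(y)
        v = weighted_rank_correlation(ra, rb, np.ones(15))
        assert v == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            weighted_rank_correlation([1.0, 1.0], [1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="weights"):
            weighted_rank_correlation([1.0, 2.0], [1.0, 2.0], [0.0, 0.0])


class TestEnumerateSubsets:
    def test_paper_scale_counts(self):
        inds = [f"I{i}" for i in range(10)]
        subsets = enumerate_subsets(inds, 5)
        assert len(subsets) == 252
        assert sum(1 for s in subsets if "I0" in s) == 126

    def test_n_equals_k_single_subset(self):
        assert enumerate_subsets(["A", "B"], 2) == [("A", "B")]

    @pytest.mark.parametrize("n,k", [(6, 3), (8, 2), (12, 5), (5, 5)])
    def test_count_matches_binomial_coefficient(self, n, k):
        inds = [f"I{i}" for i in range(n)]
        assert len(enumerate_subsets(inds, k)) == math.comb(n, k)

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            enumerate_subsets(["A"], 2)


@pytest.fixture(scope="module")
def small_complete_dataset():
    """Complete (imputation-free) 4-indication dataset for subset tests."""
    cfg = SyntheticConfig(
        n_proteins=300, indications=("A", "B", "C", "D"), samples_per_cohort=(6, 6),
        censor_slope=0.0, mar_rate=0.0, seed=6, de_effect_size=2.0,
    )
    m, _, truth = generate_dataset(cfg)
    return m, truth


class TestSubsetStability:
    def test_anchor_vs_itself_skipped_others_high(self, small_complete_dataset):
        m, _ = small_complete_dataset
        subsets = enumerate_subsets(m.indications(), 3)
        table = subset_overlap_concordance(m, subsets, subsets[0])
        assert (table["r"] > 0.99).all()
        assert not (table["subset"] == "+".join(subsets[0])).any()

    def test_foldchange_consistency_across_subsets(self, small_complete_dataset):
        m, _ = small_complete_dataset
        subsets = enumerate_subsets(m.indications(), 3)
        report = subset_foldchange_consistency(m, "A", subsets)
        n_with_a = sum(1 for s in subsets if "A" in s)
        assert report.log2_fc.shape[1] == n_with_a
        iu = np.triu_indices(n_with_a, 1)
        assert np.median(report.pairwise_correlation.to_numpy()[iu]) > 0.95

    def test_null_indication_has_few_deps(self):
        cfg = SyntheticConfig(
            n_proteins=300, indications=("A", "B", "C", "D"), samples_per_cohort=(6, 6),
            censor_slope=0.0, mar_rate=0.0, seed=7, de_fraction=0.0,
        )
        m, _, _ = generate_dataset(cfg)
        subsets = enumerate_subsets(m.indications(), 3)
        report = subset_foldchange_consistency(m, "B", subsets)
        assert report.dep_counts.max() <= 0.01 * 300


class TestRankConcordance:
    def test_high_fidelity_rna_gives_high_v(self):
        cfg = SyntheticConfig(
            n_proteins=200, indications=("A", "B", "C", "D"), samples_per_cohort=(8, 2),
            censor_slope=0.0, mar_rate=0.0, rna_noise_sd=0.3, seed=8,
        )
        m, _, truth = generate_dataset(cfg)
        rna = generate_rna_matrix(truth, cfg)
        comparison = rank_concordance(m, rna)
        assert comparison.v.median() > 0.7
        assert comparison.v.between(-1, 1).all()
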