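import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panquant.core_io import AbundanceMatrix, CohortLabel, ProteinAnnotation
from panquant.selection import (
    percentile_rank,
    profile_cohort,
    profile_tumor_indications,
    select_robust_proteins,
    selection_mass_report,
)


def _matrix(values: dict, cohorts: dict) -> AbundanceMatrix:
    return AbundanceMatrix(pd.DataFrame(values), cohorts)


def _random_toy(rng, n_prot=50, n_ind=4, n_samp=4):
    """Random multi-indication tumor matrix with missingness."""
    values, cohorts = {}, {}
    for i in range(n_ind):
        for s in range(n_samp):
            name = f"I{i}_S{s}"
            col = rng.normal(20, 3, n_prot)
            col[rng.random(n_prot) < 0.35] = np.nan
            values[name] = col
            cohorts[name] = CohortLabel(f"I{i}", "tumor")
    frame = pd.DataFrame(values, index=[f"P{j}" for j in range(n_prot)])
    return AbundanceMatrix(frame, cohorts)


def brute_force_selection(matrix, rank_cutoff=0.5, missing_cutoff=0.25):
    """Literal re-evaluation of the rule, one protein at a time."""
    kept = []
    indications = sorted({c.indication for c in matrix.cohorts() if c.tissue == "tumor"})
    for pid in matrix.protein_ids:
        ok = False
        for ind in indications:
            cols = matrix.samples_of(CohortLabel(ind, "tumor"))
            vals = matrix.values.loc[pid, cols]
            m = vals.isna().mean()
            med = vals.median(skipna=True)
            if np.isnan(med):
                continue
            # rank among proteins with a defined median in this cohort
            medians = matrix.values.loc[:, cols].median(axis=1, skipna=True).dropna()
            rank = (medians < med).sum() + 0.5 * ((medians == med).sum() + 1)
            f = rank / len(medians)
            if f > rank_cutoff and m < missing_cutoff:
                ok = True
                break
        if ok:
            kept.append(pid)
    return pd.Index(kept)


class TestPercentileRank:
    def test_distinct_values_forced_by_definition(self):
        ranks = percentile_rank(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert np.allclose(ranks.to_numpy(), [0.25, 0.5, 0.75, 1.0])

    def test_all_ties_average(self):
        ranks = percentile_rank(pd.Series([5.0] * 4, index=list("abcd")))
        assert np.allclose(ranks.to_numpy(), 0.625)  # mean rank 2.5 / 4

    def test_single_protein_rank_one(self):
        assert percentile_rank(pd.Series({"a": 7.0})).loc["a"] == 1.0

    def test_nan_medians_excluded_from_denominator(self):
        ranks = percentile_rank(pd.Series({"a": 1.0, "b": np.nan, "c": 2.0}))
        assert set(ranks.index) == {"a", "c"}
        assert np.allclose(ranks.loc[["a", "c"]], [0.5, 1.0])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20, unique=True))
    def test_monotone_over_distinct_values(self, values):
        s = pd.Series(values, index=[f"p{i}" for i in range(len(values))])
        ranks = percentile_rank(s)
        order = s.sort_values().index
        assert ranks.loc[order].is_monotonic_increasing


class TestProfileCohort:
    def test_missing_rate_and_median(self):
        m = _matrix(
            {
                "S1": [2.0, np.nan],
                "S2": [4.0, np.nan],
                "S3": [6.0, np.nan],
                "S4": [np.nan, np.nan],
            },
            {s: CohortLabel("A", "tumor") for s in ["S1", "S2", "S3", "S4"]},
        )
        prof = profile_cohort(m, CohortLabel("A", "tumor"))
        p1 = prof.iloc[0]
        assert p1["missing_rate"] == 0.25
        assert p1["median_abundance"] == 4.0
        p2 = prof.iloc[1]
        assert p2["missing_rate"] == 1.0
        assert np.isnan(p2["median_abundance"]) and np.isnan(p2["percentile_rank"])

    def test_matches_brute_force_on_random_cohort(self):
        rng = np.random.default_rng(11)
        m = _random_toy(rng, n_prot=5, n_ind=1, n_samp=6)
        prof = profile_cohort(m, CohortLabel("I0", "tumor"))
        cols = m.samples_of(CohortLabel("I0", "tumor"))
        for pid in m.protein_ids:
            vals = m.values.loc[pid, cols]
            assert prof.loc[pid, "missing_rate"] == pytest.approx(vals.isna().mean())
            med = vals.median(skipna=True)
            if np.isnan(med):
                assert np.isnan(prof.loc[pid, "median_abundance"])
            else:
                assert prof.loc[pid, "median_abundance"] == pytest.approx(med)


class TestSelectionRule:
    def test_rule_satisfied_once_keeps_protein(self):
        profiles = {
            "A": pd.DataFrame({"missing_rate": [0.0], "median_abundance": [20.0],
                               "percentile_rank": [0.9]}, index=["P1"]),
            "B": pd.DataFrame({"missing_rate": [1.0], "median_abundance": [np.nan],
                               "percentile_rank": [np.nan]}, index=["P1"]),
        }
        assert list(select_robust_proteins(profiles)) == ["P1"]

    def test_boundary_strict_inequalities(self):
        # M = 0.25 exactly fails the < 0.25 cut even with a passing rank
        profiles = {
            "A": pd.DataFrame({"missing_rate": [0.25], "median_abundance": [20.0],
                               "percentile_rank": [0.51]}, index=["P1"]),
        }
        assert len(select_robust_proteins(profiles)) == 0
        # rank = 0.5 exactly fails the > 0.5 cut
        profiles["A"].loc["P1", ["missing_rate", "percentile_rank"]] = [0.0, 0.5]
        assert len(select_robust_proteins(profiles)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_rule_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_toy(rng)
        kept = select_robust_proteins(profile_tumor_indications(m))
        expected = brute_force_selection(m)
        assert sorted(kept) == sorted(expected)

    def test_monotone_in_cutoffs(self):
        rng = np.random.default_rng(99)
        m = _random_toy(rng)
        profiles = profile_tumor_indications(m)
        strict = set(select_robust_proteins(profiles, rank_cutoff=0.6, missing_cutoff=0.2))
        relaxed = set(select_robust_proteins(profiles, rank_cutoff=0.4, missing_cutoff=0.4))
        assert strict <= relaxed

    def test_selection_ignores_normal_tissue(self):
        rng = np.random.default_rng(5)
        m = _random_toy(rng, n_ind=2)
        # add normal cohorts with permuted data; the kept set must not change
        normals = {}
        for i, col in enumerate(m.values.columns[:4]):
            normals[f"N{i}"] = rng.permutation(m.values[col].to_numpy())
        values = pd.concat([m.values, pd.DataFrame(normals, index=m.protein_ids)], axis=1)
        cohorts = dict(m.sample_cohort)
        cohorts.update({f"N{i}": CohortLabel("I0", "normal") for i in range(4)})
        m2 = AbundanceMatrix(values, cohorts)
        kept1 = select_robust_proteins(profile_tumor_indications(m))
        kept2 = select_robust_proteins(profile_tumor_indications(m2))
        assert list(kept1) == list(kept2)

    def test_block_structure_recovered(self):
        # high-abundance fully observed block vs near-always-missing block
        rng = np.random.default_rng(3)
        n, n_low = 30, 90
        high = rng.normal(25, 1, (n, 8))
        low = rng.normal(15, 1, (n_low, 8))
        low[rng.random(low.shape) < 0.9] = np.nan
        frame = pd.DataFrame(
            np.vstack([high, low]),
            index=[f"H{j}" for j in range(n)] + [f"L{j}" for j in range(n_low)],
            columns=[f"S{c}" for c in range(8)],
        )
        m = AbundanceMatrix(frame, {f"S{c}": CohortLabel("A", "tumor") for c in range(8)})
        kept = select_robust_proteins(profile_tumor_indications(m))
        assert set(kept) == {f"H{j}" for j in range(n)}


class TestMassReport:
    def test_all_kept_gives_one_empty_gives_zero(self, toy_matrix, toy_annotation):
        frac_all = selection_mass_report(toy_matrix, toy_matrix.protein_ids, toy_annotation)
        assert np.allclose(frac_all.to_numpy(), 1.0)
        frac_none = selection_mass_report(toy_matrix, [], toy_annotation)
        assert np.allclose(frac_none.to_numpy(), 0.0)

    def test_matches_hand_summed_ibaq(self, toy_matrix, toy_annotation):
        frac = selection_mass_report(toy_matrix, ["P1"], toy_annotation)
        # sample T2: iBAQ = 2^21/4, 2^17.5/1, 2^15/10
        ibaq = np.array([2.0**21 / 4, 2.0**17.5 / 1, 2.0**15 / 10])
        assert frac["T2"] == pytest.approx(ibaq[0] / ibaq.sum())
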