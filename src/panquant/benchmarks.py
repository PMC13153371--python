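"""From-scratch benchmark computations that exercise the whole pipeline.

Each function regenerates its inputs with the synthetic generator,
runs the relevant part of the package, and measures the outcome:
combinatorial identities, classifier recovery, imputation contracts,
normalization properties, differential-expression operating
characteristics, and the end-to-end normalization/rank-concordance and
subset-stability mirrors. Problem sizes are chosen so the full battery
runs in a couple of minutes on one core.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from panquant.core_io import AbundanceMatrix, CohortLabel
from panquant.dep import (
    bh_adjust,
    call_deps,
    compare_foldchanges,
    fit_two_group,
    moderated_t,
    run_dep,
    squeeze_variances,
)
from panquant.evaluate import (
    enumerate_subsets,
    rank_concordance,
    subset_foldchange_consistency,
    subset_overlap_concordance,
)
from panquant.imputation import hybrid_impute, impute_knn, impute_qrilc
from panquant.missingness import (
    censoring_objective,
    classify_all_cohorts,
    classify_cohort,
    estimate_complete_distribution,
    find_censoring_threshold,
)
from panquant.normalize import (
    NormalizationSpec,
    apply_normalization,
    quantile_normalize_global,
    quantile_normalize_smooth,
)
from panquant.quantify import ibaq_from_log2, quantify, ribaq
from panquant.selection import profile_tumor_indications, select_robust_proteins
from panquant.synthetic import (
    SyntheticConfig,
    apply_technical_scaling,
    generate_dataset,
    generate_rna_matrix,
)
from panquant.core_io import ProteinAnnotation

#: hard left-censoring scenario: step-like intensity cut, between-protein
#: spread dominating within-cohort noise — the regime where the mechanism
#: is identifiable from observed protein means
HARD_CENSORING = dict(
    censor_slope=50.0, baseline_sd=3.0, noise_sd=0.05,
    samples_per_cohort=(10, 2), indications=("BRCA",),
)


def subset_counts() -> dict:
    """Five-of-ten subset enumeration and the fixed-indication count."""
    indications = [f"I{i:02d}" for i in range(10)]
    subsets = enumerate_subsets(indications, 5)
    containing = [s for s in subsets if indications[0] in s]
    return {"all": len(subsets), "containing_fixed": len(containing)}


def censoring_objective_agreement(seed: int, n_grid: int = 200) -> float:
    """Max |objective - independent symbolic evaluation| over a random grid."""
    from sympy import Rational

    rng = np.random.default_rng(seed)
    fe = rng.random(n_grid)
    fo = rng.random(n_grid)
    ours = censoring_objective(fe, fo)
    worst = 0.0
    for k in range(n_grid):
        e, o = Rational(fe[k]), Rational(fo[k])
        exact = float(((e - o + 1) / (o + 1) - 1) * 10)
        worst = max(worst, abs(ours[k] - exact))
    return worst


def selection_oracle_agreement(seed: int, n_trials: int = 1000) -> float:
    """Fraction of random toys where selection equals exhaustive evaluation."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        n_prot, n_ind, n_samp = 50, 4, 4
        values, cohorts = {}, {}
        for i in range(n_ind):
            for s in range(n_samp):
                name = f"I{i}_S{s}"
                col = rng.normal(20, 3, n_prot)
                col[rng.random(n_prot) < 0.35] = np.nan
                values[name] = col
                cohorts[name] = CohortLabel(f"I{i}", "tumor")
        matrix = AbundanceMatrix(
            pd.DataFrame(values, index=[f"P{j}" for j in range(n_prot)]), cohorts
        )
        kept = set(select_robust_proteins(profile_tumor_indications(matrix)))
        expected = _exhaustive_selection(matrix)
        agree += kept == expected
    return agree / n_trials


def _exhaustive_selection(matrix: AbundanceMatrix, rank_cutoff=0.5, missing_cutoff=0.25):
    """Literal protein-by-protein evaluation of the selection rule."""
    indications = sorted({c.indication for c in matrix.cohorts() if c.tissue == "tumor"})
    per_ind = {}
    for ind in indications:
        cols = matrix.samples_of(CohortLabel(ind, "tumor"))
        block = matrix.values[cols]
        medians = block.median(axis=1, skipna=True)
        defined = medians.dropna()
        per_ind[ind] = (block, medians, defined)
    kept = set()
    for pid in matrix.protein_ids:
        for ind in indications:
            block, medians, defined = per_ind[ind]
            vals = block.loc[pid]
            m = vals.isna().mean()
            med = medians.loc[pid]
            if np.isnan(med):
                continue
            rank = (defined < med).sum() + 0.5 * ((defined == med).sum() + 1)
            if rank / len(defined) > rank_cutoff and m < missing_cutoff:
                kept.add(pid)
                break
    return kept


def mnar_classification_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Min recall/precision of MNAR calls under hard censoring, across seeds.

    Protein-level truth: a protein-cohort is truly MNAR when the majority
    of its missing entries carry the generator's MNAR label.
    """
    recalls, precisions = [], []
    for k in range(n_seeds):
        cfg = SyntheticConfig(n_proteins=2000, seed=seed + k, **HARD_CENSORING)
        m, _, truth = generate_dataset(cfg)
        cohort = CohortLabel(cfg.indications[0], "tumor")
        call = classify_cohort(m, cohort)
        cols = m.samples_of(cohort)
        mech = truth.mechanism[cols]
        n_mnar = (mech == 1).sum(axis=1)
        n_mar = (mech == 2).sum(axis=1)
        has_missing = (n_mnar + n_mar) > 0
        true_mnar = (n_mnar > n_mar) & has_missing
        pred_mnar = (call.mechanism == "MNAR") & has_missing
        tp = int((true_mnar & pred_mnar).sum())
        recalls.append(tp / max(int(true_mnar.sum()), 1))
        precisions.append(tp / max(int(pred_mnar.sum()), 1))
    return {"recall_min": min(recalls), "precision_min": min(precisions), "n_seeds": n_seeds}


def imputation_contracts(seed: int) -> dict:
    """Observed preservation, QRILC left-tail contract, hybrid-vs-KNN RMSE.

    The QRILC tail fraction is pooled over 5 hard-censored replicates:
    the estimated truncation bound carries sampling error, so the
    population fraction is what the contract constrains.
    """
    fractions = []
    for k in range(5):
        rng = np.random.default_rng(seed + k)
        full = rng.normal(20, 2, 5000)
        cut = np.quantile(full, 0.3)
        col = full.copy()
        col[col < cut] = np.nan
        qr = impute_qrilc(pd.DataFrame({"S1": col}), seed=seed + 100 + k)
        fractions.append(float((qr.loc[np.isnan(col), "S1"] < cut).mean()))
    below = float(np.mean(fractions))

    cfg = SyntheticConfig(
        n_proteins=2000, seed=seed, censor_slope=50.0, indications=("BRCA", "LUAD")
    )
    m, _, truth = generate_dataset(cfg)
    calls = classify_all_cohorts(m)
    res = hybrid_impute(m, calls, seed=seed + 2)
    obs = ~m.values.isna().to_numpy()
    preserved = bool(
        np.array_equal(res.matrix.values.to_numpy()[obs], m.values.to_numpy()[obs])
    )
    err_h, err_k = [], []
    for cohort in m.cohorts():
        cols = m.samples_of(cohort)
        block = m.values[cols]
        knn = impute_knn(block.loc[block.notna().any(axis=1)], k=10).reindex(block.index)
        mech = truth.mechanism[cols].to_numpy()
        latent = truth.latent[cols].to_numpy()
        ok = (mech == 1) & ~np.isnan(knn.to_numpy())
        err_h.append((res.matrix.values[cols].to_numpy()[ok] - latent[ok]) ** 2)
        err_k.append((knn.to_numpy()[ok] - latent[ok]) ** 2)
    return {
        "qrilc_below_censor_fraction": below,
        "observed_preserved": 1.0 if preserved else 0.0,
        "hybrid_rmse_mnar": float(np.sqrt(np.concatenate(err_h).mean())),
        "knn_rmse_mnar": float(np.sqrt(np.concatenate(err_k).mean())),
    }


def quantification_identities(seed: int) -> dict:
    """riBAQ column-sum deviation and the iBAQ hand example 2^10/4."""
    rng = np.random.default_rng(seed)
    log2 = pd.DataFrame(
        rng.normal(20, 2, (200, 8)),
        index=[f"P{j}" for j in range(200)],
        columns=[f"S{c}" for c in range(8)],
    )
    ann = ProteinAnnotation(pd.Series(rng.integers(1, 60, 200), index=log2.index))
    rb = ribaq(ibaq_from_log2(log2, ann))
    hand = ibaq_from_log2(
        pd.DataFrame({"S": [10.0]}, index=["P"]), ProteinAnnotation(pd.Series({"P": 4}))
    ).iloc[0, 0]
    return {
        "ribaq_colsum_max_abs_dev": float(np.max(np.abs(rb.sum(axis=0) - 1.0))),
        "ibaq_hand_example": float(hand),
    }


def normalization_checks(seed: int) -> dict:
    """Definitional checks on global and smooth quantile normalization."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.normal(20, 2, (300, 10)),
        index=[f"P{j}" for j in range(300)],
        columns=[f"S{c}" for c in range(10)],
    )
    out = quantile_normalize_global(frame)
    sorted_cols = np.sort(out.to_numpy(), axis=0)
    col_diff = float(np.max(np.abs(sorted_cols - sorted_cols[:, [0]])))
    idem = float(np.max(np.abs(quantile_normalize_global(out).to_numpy() - out.to_numpy())))

    single = quantile_normalize_smooth(frame, {c: "g" for c in frame.columns})
    single_diff = float(np.max(np.abs(single.to_numpy() - out.to_numpy())))

    half = rng.normal(20, 2, (300, 200))
    twin = pd.DataFrame(
        np.hstack([half, half]),
        columns=[f"A{i}" for i in range(200)] + [f"B{i}" for i in range(200)],
    )
    smooth = quantile_normalize_smooth(twin, {c: c[0] for c in twin.columns})
    glob = quantile_normalize_global(twin)
    twin_diff = float(np.max(np.abs(smooth.to_numpy() - glob.to_numpy())))
    return {
        "global_qn_sorted_col_max_diff": col_diff,
        "global_qn_idempotence_max_diff": idem,
        "smooth_single_group_max_diff": single_diff,
        "smooth_identical_groups_max_diff": twin_diff,
    }


def dep_engine_checks(seed: int) -> dict:
    """Prior recovery, pooled-t limit, BH agreement, null calibration, power."""
    rng = np.random.default_rng(seed)
    d0_true, s0_true, df = 8.0, 4.0, 18
    sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 5000)
    s2 = sigma2 * rng.chisquare(df, 5000) / df
    d0_hat, s0_hat, _ = squeeze_variances(s2, df)

    cols = [f"s{i}" for i in range(20)]
    mat = pd.DataFrame(rng.normal(20, 1, (5000, 20)), columns=cols)
    fc, s2v, dfv = fit_two_group(mat.iloc[:200], cols[:10], cols[10:])
    _, p_mod = moderated_t(fc.to_numpy(), s2v.to_numpy(), 0.0, dfv, 10, 10)
    p_ref = np.array(
        [stats.ttest_ind(mat.iloc[j, :10], mat.iloc[j, 10:20]).pvalue for j in range(200)]
    )
    pooled_diff = float(np.max(np.abs(p_mod - p_ref)))

    p_rand = rng.random(2000)
    m = len(p_rand)
    order = np.argsort(p_rand, kind="mergesort")
    brute = np.empty(m)
    running = math.inf
    for pos in range(m - 1, -1, -1):
        running = min(running, m * p_rand[order[pos]] / (pos + 1))
        brute[order[pos]] = min(running, 1.0)
    bh_diff = float(np.max(np.abs(bh_adjust(p_rand) - brute)))

    null_res = run_dep(mat, cols[:10], cols[10:])
    ks = float(stats.kstest(null_res.table["p_value"], "uniform").statistic)

    n = 3000
    planted_mat = pd.DataFrame(rng.normal(20, 1, (n, 20)), columns=cols)
    idx = rng.choice(n, 300, replace=False)
    effect = np.zeros(n)
    effect[idx] = 2.0 * rng.choice([-1.0, 1.0], 300)
    planted_mat.iloc[:, :10] = planted_mat.iloc[:, :10].to_numpy() + effect[:, None]
    res = run_dep(planted_mat, cols[:10], cols[10:])
    deps = set(call_deps(res, 1.0, 0.01))
    planted = set(planted_mat.index[idx])
    return {
        "d0_rel_error": float(abs(d0_hat - d0_true) / d0_true),
        "s0sq_rel_error": float(abs(s0_hat - s0_true) / s0_true),
        "pooled_t_limit_max_p_diff": pooled_diff,
        "bh_vs_bruteforce_max_diff": bh_diff,
        "null_pvalue_ks": ks,
        "dep_recall_planted": len(deps & planted) / len(planted),
        "dep_false_positive_rate": len(deps - planted) / (n - 300),
    }


def _run_core_pipeline(cfg: SyntheticConfig, impute_seed: int, technical_sd: float = 0.0):
    m, ann, truth = generate_dataset(cfg)
    if technical_sd > 0:
        m = apply_technical_scaling(m, technical_sd, seed=cfg.seed)
    kept = select_robust_proteins(profile_tumor_indications(m))
    selected = AbundanceMatrix(m.values.loc[kept], dict(m.sample_cohort))
    calls = classify_all_cohorts(selected)
    imputed = hybrid_impute(selected, calls, seed=impute_seed)
    tables = quantify(imputed.matrix.values, ann)
    return m, ann, truth, kept, tables


def end_to_end_mirror(seed: int) -> dict:
    """Planted-effect dataset with cohort-level technical scaling.

    Measures (a) the per-indication fold-change correlation between
    globally normalized and unnormalized analyses and (b) the weighted
    rank concordance v against the paired RNA matrix with and without
    normalization.
    """
    cfg = SyntheticConfig(n_proteins=1500, seed=seed, rna_noise_sd=0.5, de_effect_size=2.0)
    m, ann, truth, kept, tables = _run_core_pipeline(cfg, impute_seed=seed, technical_sd=2.0)
    rna = generate_rna_matrix(truth, cfg)
    meta = dict(m.sample_cohort)

    norm_g = apply_normalization(tables, NormalizationSpec(method="global_quantile"))
    norm_none = apply_normalization(tables, NormalizationSpec(method="none"))

    fc_corrs = []
    for ind in m.indications():
        tumor = [s for s, c in meta.items() if c.indication == ind and c.tissue == "tumor"]
        normal = [s for s, c in meta.items() if c.indication == ind and c.tissue == "normal"]
        r_g = run_dep(norm_g, tumor, normal)
        r_n = run_dep(norm_none, tumor, normal)
        fc_corrs.append(compare_foldchanges(r_g, r_n))

    rna_kept = AbundanceMatrix(rna.values.loc[kept], dict(rna.sample_cohort))
    mat_g = AbundanceMatrix(norm_g, meta)
    mat_none = AbundanceMatrix(norm_none, meta)
    v_g = rank_concordance(mat_g, rna_kept, correlation_matrix=mat_none).v.median()
    v_none = rank_concordance(mat_none, rna_kept, correlation_matrix=mat_none).v.median()
    return {
        "fc_corr_normalized_vs_raw_min": float(min(fc_corrs)),
        "v_global_qn": float(v_g),
        "v_unnormalized": float(v_none),
        "n_kept": int(len(kept)),
    }


def subset_stability(seed: int) -> dict:
    """Size-3 subset stability of global QN on a 6-indication dataset."""
    cfg = SyntheticConfig(n_proteins=1500, seed=seed, de_effect_size=2.0)
    m, ann, truth, kept, tables = _run_core_pipeline(cfg, impute_seed=seed)
    log2_ibaq = np.log2(tables.ibaq)
    mat = AbundanceMatrix(log2_ibaq, dict(m.sample_cohort))
    subsets = enumerate_subsets(mat.indications(), 3)
    overlap = subset_overlap_concordance(mat, subsets, subsets[0])
    report = subset_foldchange_consistency(mat, mat.indications()[0], subsets)
    iu = np.triu_indices(len(report.pairwise_correlation), 1)
    return {
        "n_subsets": len(subsets),
        "min_overlap_sample_r": float(overlap["r"].min()),
        "median_pairwise_fc_corr": float(
            np.median(report.pairwise_correlation.to_numpy()[iu])
        ),
        "dep_count_iqr": float(report.dep_count_iqr),
    }
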