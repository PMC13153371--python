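"""Rank-concordance validation and subset-stability analysis.

Rank concordance: proteins whose protein and RNA expression correlate
strongly within tumor tissue of most indications serve as validation
proteins; for each, the indications are ranked by median protein signal
and by median RNA signal, and agreement is summarized by a weighted rank
correlation v — a weighted Pearson correlation of the two rank vectors
whose per-indication weights are the protein-RNA correlations. With
equal weights v reduces exactly to Spearman's rho.

Subset stability: global quantile normalization is re-run independently
inside every k-indication subset; samples shared between two subsets
should receive near-identical normalized profiles, and tumor-vs-normal
fold changes for an indication should agree across every subset that
contains it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from panquant.core_io import AbundanceMatrix, CohortLabel
from panquant.dep import DepResult, call_deps, run_dep
from panquant.normalize import quantile_normalize_global

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.5
DEFAULT_MAJORITY_FRACTION = 0.5
#: indications contributing fewer validation proteins than this are excluded
DEFAULT_MIN_VALIDATION_PROTEINS = 3


def _tumor_columns(matrix: AbundanceMatrix, indication: str) -> list[str]:
    return matrix.samples_of(CohortLabel(indication, "tumor"))


def protein_rna_correlation(
    protein_matrix: AbundanceMatrix, rna_matrix: AbundanceMatrix, indication: str
) -> pd.Series:
    """Per-protein Pearson r between protein and RNA over tumor samples.

    Computed over the indication's tumor samples shared by both matrices
    (>= 3 required); proteins with zero variance in either vector, or
    fewer than 3 jointly observed samples, get NaN.
    """
    prot_cols = _tumor_columns(protein_matrix, indication)
    rna_cols = _tumor_columns(rna_matrix, indication)
    shared_samples = [s for s in prot_cols if s in set(rna_cols)]
    if len(shared_samples) < 3:
        raise ValueError(f"fewer than 3 shared tumor samples for {indication}")
    shared_proteins = protein_matrix.protein_ids.intersection(rna_matrix.protein_ids)
    p = protein_matrix.values.loc[shared_proteins, shared_samples].to_numpy(dtype=float)
    r = rna_matrix.values.loc[shared_proteins, shared_samples].to_numpy(dtype=float)

    out = np.full(len(shared_proteins), np.nan)
    for j in range(len(shared_proteins)):
        ok = ~np.isnan(p[j]) & ~np.isnan(r[j])
        if ok.sum() < 3:
            continue
        pj, rj = p[j, ok], r[j, ok]
        if pj.std() == 0 or rj.std() == 0:
            continue
        out[j] = np.corrcoef(pj, rj)[0, 1]
    return pd.Series(out, index=shared_proteins)


def select_validation_proteins(
    correlations: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    majority_fraction: float = DEFAULT_MAJORITY_FRACTION,
) -> pd.Index:
    """Proteins with r > threshold in a strict majority of indications.

    ``correlations`` is proteins x indications (NaN where undefined);
    the majority is taken over indications where r is defined.
    """
    defined = correlations.notna().sum(axis=1)
    high = (correlations > r_threshold).sum(axis=1)
    keep = (defined > 0) & (high > majority_fraction * defined)
    return correlations.index[keep]


def indication_ranks(
    matrix: AbundanceMatrix, proteins, indications: list[str]
) -> pd.DataFrame:
    """Per-protein ranks of indications by median tumor signal.

    For each protein: the median over tumor samples per indication, then
    average ranks (1 = lowest) across the indications. Input may be any
    log2-scale quantification (iBAQ, riBAQ, normalized variants).
    """
    proteins = pd.Index(proteins)
    medians = pd.DataFrame(index=proteins, columns=indications, dtype=float)
    for ind in indications:
        cols = _tumor_columns(matrix, ind)
        if not cols:
            raise ValueError(f"no tumor samples for indication {ind}")
        medians[ind] = matrix.values.loc[proteins, cols].median(axis=1, skipna=True)
    ranks = medians.apply(lambda row: rankdata(row.to_numpy(), method="average"), axis=1, result_type="expand")
    ranks.columns = indications
    return ranks


def weighted_rank_correlation(ranks_a, ranks_b, weights) -> float:
    """Weighted Pearson correlation of two rank vectors.

    Weighted means, covariance and variances with per-item weights;
    equal weights reduce to Spearman's rho of the underlying values.
    Nonnegative weights, not all zero; degenerate (zero weighted
    variance) rank vectors raise.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be >= 0 and not all zero")
    w = w / w.sum()
    ma, mb = (w * a).sum(), (w * b).sum()
    cov = (w * (a - ma) * (b - mb)).sum()
    va = (w * (a - ma) ** 2).sum()
    vb = (w * (b - mb) ** 2).sum()
    if va == 0 or vb == 0:
        raise ValueError("degenerate ranks: zero weighted variance")
    # guard against |v| exceeding 1 by floating-point rounding
    return float(np.clip(cov / np.sqrt(va * vb), -1.0, 1.0))


@dataclass
class RankComparison:
    """Weighted rank concordance of protein vs RNA indication ranks."""

    protein_ranks: pd.DataFrame
    rna_ranks: pd.DataFrame
    weights: pd.DataFrame  # per protein x indication (protein-RNA r)
    v: pd.Series  # per validation protein


def rank_concordance(
    protein_matrix: AbundanceMatrix,
    rna_matrix: AbundanceMatrix,
    indications: list[str] | None = None,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    majority_fraction: float = DEFAULT_MAJORITY_FRACTION,
    min_validation_proteins: int = DEFAULT_MIN_VALIDATION_PROTEINS,
    correlation_matrix: AbundanceMatrix | None = None,
) -> RankComparison:
    """End-to-end weighted rank-concordance evaluation.

    Validation proteins are selected from protein-RNA correlations
    computed on ``correlation_matrix`` — pass the pre-normalization
    matrix there when ranking a normalized one; it defaults to
    ``protein_matrix``. Indications contributing fewer than
    ``min_validation_proteins`` qualifying proteins are excluded
    (rule-based, not hard-coded). The per-protein concordance v uses the
    protein-RNA correlations (clipped at 0) as indication weights.
    """
    if indications is None:
        indications = protein_matrix.indications()
    corr_source = correlation_matrix if correlation_matrix is not None else protein_matrix
    corr = pd.DataFrame(
        {ind: protein_rna_correlation(corr_source, rna_matrix, ind) for ind in indications}
    )
    validation = select_validation_proteins(corr, r_threshold, majority_fraction)
    qualifying = (corr.loc[validation] > r_threshold).sum(axis=0)
    kept_inds = [ind for ind in indications if qualifying[ind] >= min_validation_proteins]
    if len(kept_inds) < 3:
        raise ValueError("fewer than 3 indications qualify for rank comparison")
    dropped = sorted(set(indications) - set(kept_inds))
    if dropped:
        logger.info("indications excluded from rank comparison: %s", dropped)

    prot_ranks = indication_ranks(protein_matrix, validation, kept_inds)
    rna_ranks = indication_ranks(rna_matrix, validation, kept_inds)
    weights = corr.loc[validation, kept_inds].clip(lower=0.0).fillna(0.0)
    v = pd.Series(
        {
            pid: weighted_rank_correlation(
                prot_ranks.loc[pid], rna_ranks.loc[pid], weights.loc[pid]
            )
            for pid in validation
        }
    )
    return RankComparison(prot_ranks, rna_ranks, weights, v)


# ---------------------------------------------------------------- subsets


def enumerate_subsets(cohort_list: list[str], subset_size: int = 5) -> list[tuple[str, ...]]:
    """All distinct subsets of the given size, lexicographic order."""
    if subset_size > len(cohort_list):
        raise ValueError("subset_size exceeds the number of cohorts")
    return list(itertools.combinations(sorted(cohort_list), subset_size))


def _subset_samples(matrix: AbundanceMatrix, subset: tuple[str, ...]) -> list[str]:
    assert matrix.sample_cohort is not None
    members = set(subset)
    return [s for s in matrix.sample_ids if matrix.sample_cohort[s].indication in members]


def _normalize_within_subset(matrix: AbundanceMatrix, subset: tuple[str, ...]) -> pd.DataFrame:
    cols = _subset_samples(matrix, subset)
    return quantile_normalize_global(matrix.values[cols])


def subset_overlap_concordance(
    matrix: AbundanceMatrix,
    subsets: list[tuple[str, ...]],
    anchor_subset: tuple[str, ...],
) -> pd.DataFrame:
    """Per-sample correlation of anchor-subset vs other-subset normalization.

    Global quantile normalization is applied independently within each
    subset's samples; for every subset paired with the anchor, each
    overlapping sample's two normalized profiles are compared by Pearson
    r. Pairs with no overlapping samples are skipped (logged). Returns a
    long table (subset, sample, r).
    """
    anchor_norm = _normalize_within_subset(matrix, anchor_subset)
    rows = []
    for subset in subsets:
        if tuple(subset) == tuple(anchor_subset):
            continue
        overlap = [s for s in anchor_norm.columns if s in set(_subset_samples(matrix, subset))]
        if not overlap:
            logger.info("no overlapping samples between %s and anchor", subset)
            continue
        other_norm = _normalize_within_subset(matrix, subset)
        for s in overlap:
            a = anchor_norm[s].to_numpy()
            b = other_norm[s].to_numpy()
            rows.append({"subset": "+".join(subset), "sample": s, "r": float(np.corrcoef(a, b)[0, 1])})
    return pd.DataFrame(rows)


@dataclass
class SubsetReport:
    """Fold-change stability of one indication across cohort subsets."""

    indication: str
    log2_fc: pd.DataFrame  # proteins x subsets
    pairwise_correlation: pd.DataFrame
    dep_counts: pd.Series

    @property
    def dep_count_iqr(self) -> float:
        q1, q3 = self.dep_counts.quantile([0.25, 0.75])
        return float(q3 - q1)


def subset_foldchange_consistency(
    matrix: AbundanceMatrix,
    indication: str,
    subsets: list[tuple[str, ...]],
    abs_log2fc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
) -> SubsetReport:
    """Fold-change vectors and DEP counts for one indication across subsets.

    For every subset containing the indication: normalize within the
    subset, run the tumor-vs-normal moderated-t analysis, record the
    log2 fold-change vector and the DEP count. Reports the pairwise
    Pearson correlation matrix of the fold-change vectors and the DEP
    count distribution.
    """
    relevant = [s for s in subsets if indication in s]
    if not relevant:
        raise ValueError(f"no subset contains indication {indication}")
    fc_columns: dict[str, pd.Series] = {}
    counts: dict[str, int] = {}
    for subset in relevant:
        name = "+".join(subset)
        normalized = _normalize_within_subset(matrix, subset)
        tumor = matrix.samples_of(CohortLabel(indication, "tumor"))
        normal = matrix.samples_of(CohortLabel(indication, "normal"))
        result = run_dep(normalized, tumor, normal)
        fc_columns[name] = result.log2_fc
        counts[name] = len(call_deps(result, abs_log2fc_threshold, fdr_threshold))
    fc = pd.DataFrame(fc_columns)
    corr = fc.corr(method="pearson")
    return SubsetReport(
        indication=indication,
        log2_fc=fc,
        pairwise_correlation=corr,
        dep_counts=pd.Series(counts),
    )
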