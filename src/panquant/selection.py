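"""Selection of robustly expressed proteins across tumor indications.

For protein j in the tumor cohort of indication i, three statistics are
profiled: the missing rate M_ij (fraction of cohort samples with a
missing value), the median A_ij of the non-missing log2 abundances, and
the percentile rank F_i(A_ij) of that median within the indication. A
protein is kept — in all cohorts — if some indication has
F_i(A_ij) > rank_cutoff and M_ij < missing_cutoff (strict inequalities).

Percentile ranks use average ranks for ties divided by the number of
proteins with a defined median in the cohort; proteins entirely missing
in a cohort have no median and are excluded from that cohort's rank
denominator.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from panquant.core_io import AbundanceMatrix, CohortLabel, ProteinAnnotation

DEFAULT_RANK_CUTOFF = 0.5
DEFAULT_MISSING_CUTOFF = 0.25


def percentile_rank(medians: pd.Series) -> pd.Series:
    """Percentile ranks in (0, 1] of defined medians (ties averaged).

    NaN entries are dropped; the returned series covers only proteins
    with a defined median. Ranks are average ranks divided by the count,
    hence strictly monotone over distinct values and 1.0 at the maximum.
    """
    defined = medians.dropna()
    if defined.empty:
        return pd.Series(dtype=float)
    ranks = rankdata(defined.to_numpy(), method="average") / len(defined)
    return pd.Series(ranks, index=defined.index)


def profile_cohort(matrix: AbundanceMatrix, cohort: CohortLabel) -> pd.DataFrame:
    """Per-protein (missing_rate, median_abundance, percentile_rank) for one cohort.

    Proteins with all values missing get missing_rate 1 and undefined
    (NaN) median and rank.
    """
    block = matrix.cohort_values(cohort)
    n = block.shape[1]
    missing_rate = block.isna().sum(axis=1) / n
    median = block.median(axis=1, skipna=True)
    rank = percentile_rank(median).reindex(block.index)
    return pd.DataFrame(
        {"missing_rate": missing_rate, "median_abundance": median, "percentile_rank": rank}
    )


def profile_tumor_indications(matrix: AbundanceMatrix) -> dict[str, pd.DataFrame]:
    """Profiles for every tumor cohort, keyed by indication."""
    out: dict[str, pd.DataFrame] = {}
    for cohort in matrix.cohorts():
        if cohort.tissue == "tumor":
            out[cohort.indication] = profile_cohort(matrix, cohort)
    if not out:
        raise ValueError("no tumor cohorts present")
    return out


def select_robust_proteins(
    profiles: Mapping[str, pd.DataFrame],
    rank_cutoff: float = DEFAULT_RANK_CUTOFF,
    missing_cutoff: float = DEFAULT_MISSING_CUTOFF,
) -> pd.Index:
    """Kept protein set: rule satisfied in at least one tumor indication.

    Kept iff exists indication i with percentile_rank > rank_cutoff AND
    missing_rate < missing_cutoff (both strict). Kept proteins are
    retained in all cohorts downstream.
    """
    if not profiles:
        raise ValueError("profiles cover no indication")
    keep: pd.Series | None = None
    for prof in profiles.values():
        ok = (prof["percentile_rank"] > rank_cutoff) & (prof["missing_rate"] < missing_cutoff)
        ok = ok.fillna(False)
        keep = ok if keep is None else (keep | ok)
    assert keep is not None
    return keep.index[keep]


def observed_ibaq(values: pd.DataFrame, annotation: ProteinAnnotation) -> pd.DataFrame:
    """Linear-scale iBAQ of the observed entries only (NaN preserved)."""
    n_pep = annotation.require(values.index).to_numpy()
    return pd.DataFrame(
        np.power(2.0, values.to_numpy()) / n_pep[:, None],
        index=values.index,
        columns=values.columns,
    )


def selection_mass_report(
    matrix: AbundanceMatrix, kept: Iterable[str], annotation: ProteinAnnotation
) -> pd.Series:
    """Per-sample fraction of total observed iBAQ mass carried by kept proteins.

    Quantifies how much of each sample's summed protein signal survives
    selection; values lie in [0, 1] and equal 1.0 when everything is kept.
    """
    ibaq = observed_ibaq(matrix.values, annotation)
    total = ibaq.sum(axis=0, skipna=True)
    kept_idx = pd.Index(kept)
    kept_sum = ibaq.loc[ibaq.index.intersection(kept_idx)].sum(axis=0, skipna=True)
    frac = kept_sum / total
    return frac.fillna(0.0)
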