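"""Per-cohort classification of the missingness mechanism (MNAR vs MAR).

The model assumes that per-protein mean abundances within a cohort would
be normal if fully observed. The complete-distribution parameters
(mu, sigma) are estimated by a least-squares fit of the upper portion of
the normal Q-Q line of observed protein means — the upper quantile range
avoids the left-censored tail. A censoring threshold is then located by
scanning the observed means and scoring, at each candidate x, the
divergence between the theoretical CDF F_e = Phi((x - mu)/sigma) and the
empirical CDF F_o of the observed means with the objective

    ((F_e - F_o + 1) / (F_o + 1) - 1) * 10,

which up-weights divergence in the low-intensity range. The maximizing x
is the censoring threshold, reported only when the maximum is strictly
positive. Proteins whose mean observed value lies at or below the
threshold are called MNAR; all others (and every protein when no
threshold exists) are MAR. MAR and MCAR are deliberately not
distinguished — both route to the same imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from panquant.core_io import AbundanceMatrix, CohortLabel

DEFAULT_FIT_QUANTILE_RANGE = (0.5, 1.0)


@dataclass
class CohortMissingnessCall:
    """Classification result for one cohort.

    ``mechanism`` maps protein -> "MNAR" | "MAR"; ``mean_observed`` is
    NaN for proteins with no observed value in the cohort (those are
    MNAR by convention and listed in ``all_missing``). Proteins with no
    missing values keep their call but are exempt from imputation.
    """

    cohort: CohortLabel
    mechanism: pd.Series
    mean_observed: pd.Series
    censoring_threshold: float | None
    mu_hat: float
    sigma_hat: float
    objective_curve: pd.DataFrame
    all_missing: list[str]


def estimate_complete_distribution(
    observed_means: np.ndarray,
    fit_quantile_range: tuple[float, float] = DEFAULT_FIT_QUANTILE_RANGE,
    n_censored_low: int = 0,
) -> tuple[float, float]:
    """Estimate (mu, sigma) of the uncensored normal from observed values.

    Sorts the observations, pairs them with standard-normal quantiles of
    the plotting positions (n_censored_low + k - 0.5) / (n +
    n_censored_low), restricts to ``fit_quantile_range`` (the upper,
    presumed-uncensored portion by default), and fits the Q-Q line by
    least squares: slope -> sigma, intercept -> mu.

    ``n_censored_low`` is the number of values known to be censored
    below the smallest observation (missing cells of a sample column;
    fully missing proteins of a cohort). Without it the plotting
    positions of a censored sample are compressed and the fit is biased
    even in the uncensored upper range.
    """
    x = np.sort(np.asarray(observed_means, dtype=float))
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 observed means, got {n}")
    total = n + int(n_censored_low)
    pp = (n_censored_low + np.arange(1, n + 1) - 0.5) / total
    lo, hi = fit_quantile_range
    in_range = (pp >= lo) & (pp <= hi)
    if in_range.sum() < 3:
        raise ValueError("fewer than 3 points in the fit quantile range")
    q = norm.ppf(pp[in_range])
    y = x[in_range]
    slope, intercept = np.polyfit(q, y, 1)
    if slope <= 0:
        raise ValueError("degenerate distribution: non-positive Q-Q slope")
    return float(intercept), float(slope)


def censoring_objective(F_e, F_o):
    """Relative CDF-divergence score: ((F_e - F_o + 1)/(F_o + 1) - 1) * 10.

    Zero when the CDFs agree; positive when the theoretical CDF exceeds
    the empirical one (mass expected below that is not observed, the
    left-censoring signature); the (F_o + 1) denominator emphasises the
    low-intensity range. Increasing in F_e, decreasing in F_o on [0,1]^2.
    """
    F_e = np.asarray(F_e, dtype=float)
    F_o = np.asarray(F_o, dtype=float)
    out = ((F_e - F_o + 1.0) / (F_o + 1.0) - 1.0) * 10.0
    return float(out) if out.ndim == 0 else out


def find_censoring_threshold(
    observed_means: np.ndarray, mu_hat: float, sigma_hat: float
) -> tuple[float | None, pd.DataFrame]:
    """Locate the censoring threshold on the grid of sorted observed means.

    Returns (threshold, curve) where curve tabulates (x, F_e, F_o,
    objective) at every grid point. The threshold is the objective's
    maximizer when that maximum is strictly positive, ties broken toward
    the smaller x; otherwise None (no detectable censoring).
    """
    x = np.sort(np.asarray(observed_means, dtype=float))
    x = x[~np.isnan(x)]
    n = len(x)
    F_e = norm.cdf((x - mu_hat) / sigma_hat)
    F_o = np.searchsorted(x, x, side="right") / n  # empirical CDF at each data point
    obj = censoring_objective(F_e, F_o)
    curve = pd.DataFrame({"x": x, "F_e": F_e, "F_o": F_o, "objective": obj})
    best = int(np.argmax(obj))  # argmax returns the first (smallest-x) maximizer
    if obj[best] > 0:
        return float(x[best]), curve
    return None, curve


def classify_cohort(
    matrix: AbundanceMatrix,
    cohort: CohortLabel,
    fit_quantile_range: tuple[float, float] = DEFAULT_FIT_QUANTILE_RANGE,
) -> CohortMissingnessCall:
    """Classify every protein's missingness mechanism within one cohort.

    MNAR iff the protein's mean observed value is <= the cohort's
    censoring threshold; every protein is MAR when no threshold exists.
    Proteins with zero observed values in the cohort are MNAR by
    convention (left-censoring is the conservative mechanism when
    nothing was observed) and flagged in ``all_missing`` so downstream
    consumers can interpret them with caution.
    """
    block = matrix.cohort_values(cohort)
    mean_obs = block.mean(axis=1, skipna=True)
    defined = mean_obs.dropna()
    n_all_missing = int(mean_obs.isna().sum())  # left-censored below everything
    mu_hat, sigma_hat = estimate_complete_distribution(
        defined.to_numpy(), fit_quantile_range, n_censored_low=n_all_missing
    )
    threshold, curve = find_censoring_threshold(defined.to_numpy(), mu_hat, sigma_hat)

    mech = pd.Series("MAR", index=block.index, dtype=object)
    if threshold is not None:
        mech[mean_obs <= threshold] = "MNAR"
    all_missing = mean_obs.index[mean_obs.isna()].tolist()
    mech[all_missing] = "MNAR"
    return CohortMissingnessCall(
        cohort=cohort,
        mechanism=mech,
        mean_observed=mean_obs,
        censoring_threshold=threshold,
        mu_hat=mu_hat,
        sigma_hat=sigma_hat,
        objective_curve=curve,
        all_missing=all_missing,
    )


def classify_all_cohorts(
    matrix: AbundanceMatrix,
    fit_quantile_range: tuple[float, float] = DEFAULT_FIT_QUANTILE_RANGE,
) -> dict[CohortLabel, CohortMissingnessCall]:
    """Independent per-cohort classification for every cohort in the matrix."""
    return {
        cohort: classify_cohort(matrix, cohort, fit_quantile_range)
        for cohort in matrix.cohorts()
    }


def calls_from_frame(frame: pd.DataFrame) -> dict[CohortLabel, CohortMissingnessCall]:
    """Rebuild per-cohort mechanism calls from a ``calls_to_frame`` table.

    Only the fields imputation needs (mechanism, mean_observed) are
    restored; estimator diagnostics are left empty.
    """
    out: dict[CohortLabel, CohortMissingnessCall] = {}
    for (ind, tissue), sub in frame.groupby(["indication", "tissue"], sort=False):
        cohort = CohortLabel(str(ind), str(tissue))
        mech = pd.Series(sub["mechanism"].to_numpy(), index=sub["protein"].to_numpy())
        mean_obs = pd.Series(sub["mean_observed"].to_numpy(), index=sub["protein"].to_numpy())
        out[cohort] = CohortMissingnessCall(
            cohort=cohort,
            mechanism=mech,
            mean_observed=mean_obs,
            censoring_threshold=None,
            mu_hat=float("nan"),
            sigma_hat=float("nan"),
            objective_curve=pd.DataFrame(),
            all_missing=mean_obs.index[mean_obs.isna()].tolist(),
        )
    return out


def calls_to_frame(calls: dict[CohortLabel, CohortMissingnessCall]) -> pd.DataFrame:
    """Long-format (protein, indication, tissue, mechanism, mean_observed) table."""
    rows = []
    for cohort, call in calls.items():
        frame = pd.DataFrame(
            {
                "protein": call.mechanism.index,
                "indication": cohort.indication,
                "tissue": cohort.tissue,
                "mechanism": call.mechanism.to_numpy(),
                "mean_observed": call.mean_observed.to_numpy(),
            }
        )
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
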