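"""Tumor-vs-normal differential expression with empirical-Bayes moderation.

Per protein, a two-group comparison (tumor vs normal-adjacent tissue
within one indication) yields the log2 fold change, the pooled residual
variance s2 and its degrees of freedom. The per-protein variances are
then shrunk toward a prior: the hierarchical model takes s2 | sigma2 ~
sigma2 * chi2_df / df with 1/sigma2 ~ chi2_d0 / (d0 * s0^2); the prior
parameters (d0, s0^2) are estimated by moment matching of log s2 via the
digamma/trigamma identities, and the posterior variance

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)

feeds a moderated t-statistic on df + d0 degrees of freedom. P-values
are Benjamini-Hochberg adjusted (step-up, re-implemented here). The test
is unpaired: no tumor/normal sample blocking is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist

DEFAULT_LOG2FC_THRESHOLD = 1.0
DEFAULT_FDR_THRESHOLD = 0.01


@dataclass
class DepResult:
    """Per-protein differential expression for one tumor-vs-normal contrast."""

    table: pd.DataFrame  # columns: log2_fc, s2, t, p_value, fdr
    df_residual: float
    d0: float
    s0_squared: float

    @property
    def log2_fc(self) -> pd.Series:
        return self.table["log2_fc"]


def fit_two_group(
    matrix: pd.DataFrame, tumor_samples: list[str], normal_samples: list[str]
) -> tuple[pd.Series, pd.Series, float]:
    """Per-protein group-mean difference and pooled residual variance.

    Returns (log2_fc = tumor mean - normal mean, s2, df) with
    df = n1 + n2 - 2. Both groups need at least 2 samples.
    """
    n1, n2 = len(tumor_samples), len(normal_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    g1 = matrix[tumor_samples].to_numpy(dtype=float)
    g2 = matrix[normal_samples].to_numpy(dtype=float)
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    ss1 = ((g1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((g2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    idx = matrix.index
    return pd.Series(m1 - m2, index=idx), pd.Series(s2, index=idx), float(df)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 200) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection (trigamma is decreasing)."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # geometric bisection: x spans many decades
        if polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            break
    return math.sqrt(lo * hi)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Estimate the variance prior (d0, s0^2) and posterior variances.

    Moment matching on z = log s2: under the hierarchical model,
    E[z] = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2) and
    Var[z] = psi'(df/2) + psi'(d0/2), so d0 solves psi'(d0/2) =
    Var(z) - psi'(df/2) (bisection, tolerance 1e-8). Homogeneous
    variances give d0 = infinity and s2_post identically s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) < 10:
        raise ValueError("need >= 10 proteins with positive s2")
    z = np.log(positive)
    if np.ptp(z) == 0:  # exactly homogeneous: no excess dispersion at all
        s0_sq = float(positive[0])
        return math.inf, s0_sq, np.full_like(s2, s0_sq)
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - math.log(d0 / 2.0)))
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = math.inf
        s0_sq = float(np.exp(e.mean()))
        s2_post = np.full_like(s2, s0_sq)
    return d0, s0_sq, s2_post


def moderated_t(
    log2_fc: np.ndarray,
    s2_posterior: np.ndarray,
    d0: float,
    df: float,
    n1: int,
    n2: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p on df + d0 degrees of freedom.

    With d0 = 0 this is exactly the ordinary pooled two-sample t-test;
    with d0 = infinity the reference distribution is normal.
    """
    se = np.sqrt(s2_posterior * (1.0 / n1 + 1.0 / n2))
    t = np.asarray(log2_fc, dtype=float) / se
    total_df = df + d0
    if math.isinf(total_df):
        p = 2.0 * norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), total_df)
    return t, p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, clipped at 1.

    fdr_(i) = min_{k >= i} m * p_(k) / k over the sorted p-values,
    mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def run_dep(
    matrix: pd.DataFrame, tumor_samples: list[str], normal_samples: list[str]
) -> DepResult:
    """Full moderated-t analysis for one tumor-vs-normal contrast."""
    log2_fc, s2, df = fit_two_group(matrix, tumor_samples, normal_samples)
    d0, s0_sq, s2_post = squeeze_variances(s2.to_numpy(), df)
    t, p = moderated_t(
        log2_fc.to_numpy(), s2_post, d0, df, len(tumor_samples), len(normal_samples)
    )
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {"log2_fc": log2_fc, "s2": s2, "s2_posterior": s2_post, "t": t, "p_value": p, "fdr": fdr},
        index=matrix.index,
    )
    return DepResult(table=table, df_residual=df, d0=d0, s0_squared=s0_sq)


def call_deps(
    result: DepResult,
    abs_log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.Index:
    """Differentially expressed proteins: |log2 FC| and FDR both strict.

    The default thresholds (|log2 FC| > 1, FDR < 0.01) correspond to an
    absolute fold change > 2 at 1% FDR.
    """
    tab = result.table
    keep = (tab["log2_fc"].abs() > abs_log2fc_threshold) & (tab["fdr"] < fdr_threshold)
    return tab.index[keep]


def compare_foldchanges(result_a: DepResult, result_b: DepResult) -> float:
    """Pearson correlation of the two analyses' log2 fold-change vectors."""
    shared = result_a.table.index.intersection(result_b.table.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared proteins")
    a = result_a.table.loc[shared, "log2_fc"].to_numpy()
    b = result_b.table.loc[shared, "log2_fc"].to_numpy()
    return float(np.corrcoef(a, b)[0, 1])
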