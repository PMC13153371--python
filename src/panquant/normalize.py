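"""Global and smooth (group-aware) quantile normalization of log2(iBAQ).

Global quantile normalization forces every sample onto one reference
distribution: the across-sample mean of order statistics. Smooth
quantile normalization blends that overall reference with group-level
references using a data-driven weight per quantile: where the groups'
quantile functions agree the weight approaches 1 (global behaviour),
where they differ — genuine between-group distributional signal — the
weight drops toward 0 and the group reference is retained.

All normalization operates on the log2 scale; quantile normalization is
monotone per column, so sample-internal rank order is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from panquant.quantify import QuantTables

Method = Literal["none", "global_quantile", "smooth_quantile", "ribaq"]

#: rolling-median window for the smooth-quantile weights, fraction of ranks
DEFAULT_WINDOW_FRACTION = 0.05


@dataclass
class NormalizationSpec:
    """Which normalization to run and how to group samples for the smooth one."""

    method: Method = "global_quantile"
    groups: Mapping[str, str] | None = None  # sample id -> group label
    window_fraction: float = DEFAULT_WINDOW_FRACTION


def _tie_averaged_assign(column: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Assign reference order statistics by rank; ties get the mean of spanned values."""
    order = np.argsort(column, kind="mergesort")
    out = np.empty_like(reference)
    out[order] = reference
    sorted_vals = column[order]
    # average the reference over runs of equal input values
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(column)]))
    for a, b in zip(starts, ends):
        if b - a > 1:
            out[order[a:b]] = reference[a:b].mean()
    return out


def quantile_normalize_global(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean-of-order-statistics reference.

    A single-sample matrix is its own reference and returns unchanged.
    """
    if log2_matrix.isna().to_numpy().any():
        raise ValueError("quantile normalization requires a complete matrix")
    if log2_matrix.shape[1] < 2:
        return log2_matrix.copy()
    values = log2_matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.column_stack(
        [_tie_averaged_assign(values[:, c], reference) for c in range(values.shape[1])]
    )
    return pd.DataFrame(out, index=log2_matrix.index, columns=log2_matrix.columns)


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def smooth_quantile_weights(
    sorted_values: np.ndarray, group_codes: np.ndarray, window_fraction: float
) -> np.ndarray:
    """Per-rank blending weight w in [0, 1] between overall and group references.

    At each rank: the total sum of squares of the samples' order
    statistics around the overall reference is split into between-group
    and residual parts; the raw weight is 1 - SSB/SST (1 when groups are
    indistinguishable at that quantile), then rolling-median smoothed
    over ranks and floored at 0.
    """
    n_rank, n_samp = sorted_values.shape
    overall = sorted_values.mean(axis=1)
    sst = ((sorted_values - overall[:, None]) ** 2).sum(axis=1)
    ssb = np.zeros(n_rank)
    for g in np.unique(group_codes):
        cols = group_codes == g
        group_mean = sorted_values[:, cols].mean(axis=1)
        ssb += cols.sum() * (group_mean - overall) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = 1.0 - ssb / sst
    raw[sst == 0] = 1.0  # no variability at this quantile: references coincide
    window = max(1, int(round(window_fraction * n_rank)))
    w = _rolling_median(raw, window)
    return np.clip(w, 0.0, 1.0)


def quantile_normalize_smooth(
    log2_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
) -> pd.DataFrame:
    """Group-aware quantile normalization.

    Every sample's rank-q value becomes w(q) * Fbar(q) + (1 - w(q)) *
    Fbar_g(q), where Fbar is the overall mean order statistic, Fbar_g the
    sample's group mean order statistic, and w the smoothed blending
    weight. With a single group this is exactly global normalization. A
    group of size 1 uses the sample itself as its group reference.
    """
    if log2_matrix.isna().to_numpy().any():
        raise ValueError("quantile normalization requires a complete matrix")
    missing = [s for s in log2_matrix.columns if s not in groups]
    if missing:
        raise KeyError(f"samples without a group: {missing[:10]}")
    values = log2_matrix.to_numpy(dtype=float)
    labels = np.array([groups[s] for s in log2_matrix.columns])
    _, group_codes = np.unique(labels, return_inverse=True)

    sorted_values = np.sort(values, axis=0)
    overall = sorted_values.mean(axis=1)
    w = smooth_quantile_weights(sorted_values, group_codes, window_fraction)

    out = np.empty_like(values)
    for g in np.unique(group_codes):
        cols = np.flatnonzero(group_codes == g)
        group_ref = sorted_values[:, cols].mean(axis=1)
        target = w * overall + (1.0 - w) * group_ref
        for c in cols:
            out[:, c] = _tie_averaged_assign(values[:, c], target)
    return pd.DataFrame(out, index=log2_matrix.index, columns=log2_matrix.columns)


def apply_normalization(tables: QuantTables, spec: NormalizationSpec) -> pd.DataFrame:
    """Dispatch: produce the normalized log2-scale analysis matrix.

    "none" returns log2(iBAQ) untouched; "ribaq" returns log2(riBAQ)
    (no quantile step); the quantile methods operate on log2(iBAQ).
    """
    log2_ibaq = np.log2(tables.ibaq)
    if spec.method == "none":
        return log2_ibaq
    if spec.method == "ribaq":
        return np.log2(tables.ribaq)
    if spec.method == "global_quantile":
        return quantile_normalize_global(log2_ibaq)
    if spec.method == "smooth_quantile":
        if spec.groups is None:
            raise ValueError("smooth_quantile requires sample groups")
        return quantile_normalize_smooth(log2_ibaq, spec.groups, spec.window_fraction)
    raise ValueError(f"unknown normalization method {spec.method!r}")
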