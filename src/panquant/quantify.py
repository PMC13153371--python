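"""iBAQ, riBAQ, and copy-number quantification from imputed log2 abundance.

iBAQ divides the linear-scale (2^log2) imputed abundance by the
protein's number of theoretically observable peptides; riBAQ rescales
each sample's iBAQ values to sum to one; copy number scales riBAQ by a
configured total molecules-per-cell. riBAQ and copy number are derived
from the UN-normalized iBAQ table — quantile normalization applies only
to the log2(iBAQ) analysis track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from panquant.core_io import ProteinAnnotation


@dataclass
class QuantTables:
    """Parallel iBAQ / riBAQ (/ copy-number) tables, all proteins x samples."""

    ibaq: pd.DataFrame
    ribaq: pd.DataFrame
    copy_number: pd.DataFrame | None = None


def ibaq_from_log2(imputed_log2: pd.DataFrame, annotation: ProteinAnnotation) -> pd.DataFrame:
    """ibaq[j, s] = 2^log2_abundance[j, s] / n_theoretical_peptides[j]."""
    if imputed_log2.isna().to_numpy().any():
        raise ValueError("iBAQ requires a complete (imputed) matrix")
    n_pep = annotation.require(imputed_log2.index).to_numpy()
    return pd.DataFrame(
        np.power(2.0, imputed_log2.to_numpy()) / n_pep[:, None],
        index=imputed_log2.index,
        columns=imputed_log2.columns,
    )


def ribaq(ibaq: pd.DataFrame) -> pd.DataFrame:
    """Column-normalized iBAQ: every sample's values sum to one."""
    if (ibaq.to_numpy() <= 0).any():
        raise ValueError("iBAQ must be strictly positive")
    return ibaq / ibaq.sum(axis=0)


def copy_number(ribaq_table: pd.DataFrame, total_molecules_per_cell: float) -> pd.DataFrame:
    """Per-cell molecule estimates: riBAQ scaled by the configured total.

    The total is a required configuration parameter (typically ~1e9-1e10
    molecules per mammalian cell, from proteomic-ruler style estimates);
    there is no silent default.
    """
    if total_molecules_per_cell <= 0:
        raise ValueError("total_molecules_per_cell must be > 0")
    return ribaq_table * total_molecules_per_cell


def quantify(
    imputed_log2: pd.DataFrame,
    annotation: ProteinAnnotation,
    total_molecules_per_cell: float | None = None,
) -> QuantTables:
    """Derive all quantification tables from the imputed log2 matrix."""
    ibaq_table = ibaq_from_log2(imputed_log2, annotation)
    ribaq_table = ribaq(ibaq_table)
    cn = copy_number(ribaq_table, total_molecules_per_cell) if total_molecules_per_cell else None
    return QuantTables(ibaq=ibaq_table, ribaq=ribaq_table, copy_number=cn)
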