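"""Data model and TSV readers/writers for abundance matrices and metadata.

Matrices are stored proteins x samples throughout the package; every
per-cohort operation slices columns. Missing entries are represented as
NaN in the values frame; the boolean mask is derived from it, so a
masked cell never carries numeric meaning.

Identifiers are opaque strings: no gene/protein remapping is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

#: Missing-value tokens accepted on input (matched case-insensitively).
DEFAULT_NA_TOKENS = ("", "NA", "NaN")

#: Tissue aliases accepted by the metadata reader when enabled.
TISSUE_ALIASES = {
    "nat": "normal",
    "normal_adjacent": "normal",
    "normal-adjacent": "normal",
    "adjacent_normal": "normal",
    "tumour": "tumor",
    "primary tumor": "tumor",
}

VALID_TISSUES = ("tumor", "normal")


class CohortLabel(NamedTuple):
    """A cohort: the unique combination of indication and tissue type."""

    indication: str
    tissue: str  # "tumor" or "normal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.indication}:{self.tissue}"


@dataclass
class ProteinAnnotation:
    """Per-protein annotation required for iBAQ conversion.

    Parameters
    ----------
    n_peptides
        Series indexed by protein id holding the number of theoretically
        observable peptides (positive integers).
    gene_symbol
        Optional series of gene symbols, same index.
    """

    n_peptides: pd.Series
    gene_symbol: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.n_peptides.index.has_duplicates:
            raise ValueError("duplicate protein ids in annotation")
        vals = self.n_peptides.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or np.any(vals < 1):
            raise ValueError("n_theoretical_peptides must be >= 1 for every protein")
        self.n_peptides = self.n_peptides.astype(int)

    def require(self, protein_ids: Iterable[str]) -> pd.Series:
        """Return peptide counts for ``protein_ids``; error on any absent id."""
        ids = pd.Index(protein_ids)
        missing = ids.difference(self.n_peptides.index)
        if len(missing):
            raise KeyError(f"proteins missing from annotation: {sorted(missing)[:10]}")
        return self.n_peptides.loc[ids]


@dataclass
class AbundanceMatrix:
    """Proteins x samples log2 abundance with missing entries as NaN.

    ``sample_cohort`` maps each sample id to its :class:`CohortLabel`;
    it may be None until metadata is attached, but every cohort-aware
    operation validates that the join is total first.
    """

    values: pd.DataFrame
    sample_cohort: dict[str, CohortLabel] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values = self.values.astype(float)
        if self.sample_cohort is not None:
            self._validate_cohorts()

    def _validate_cohorts(self) -> None:
        assert self.sample_cohort is not None
        missing = [s for s in self.values.columns if s not in self.sample_cohort]
        if missing:
            raise KeyError(f"samples without cohort metadata: {missing[:10]}")
        bad = [s for s, c in self.sample_cohort.items() if c.tissue not in VALID_TISSUES]
        if bad:
            raise ValueError(f"invalid tissue label for samples: {bad[:10]}")

    # -- basic views -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the entry is missing."""
        return self.values.isna()

    def attach_metadata(self, sample_cohort: Mapping[str, CohortLabel]) -> "AbundanceMatrix":
        """Return a copy with cohort metadata joined (total join enforced)."""
        return AbundanceMatrix(self.values.copy(), dict(sample_cohort))

    # -- cohort slicing ----------------------------------------------
    def cohorts(self) -> list[CohortLabel]:
        """Distinct cohorts present, in first-appearance column order."""
        self._validate_cohorts()
        assert self.sample_cohort is not None
        seen: dict[CohortLabel, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_cohort[s], None)
        return list(seen)

    def samples_of(self, cohort: CohortLabel) -> list[str]:
        self._validate_cohorts()
        assert self.sample_cohort is not None
        return [s for s in self.values.columns if self.sample_cohort[s] == cohort]

    def cohort_values(self, cohort: CohortLabel) -> pd.DataFrame:
        """Column slice for one cohort (proteins x cohort samples)."""
        cols = self.samples_of(cohort)
        if not cols:
            raise ValueError(f"empty cohort {cohort}")
        return self.values[cols]

    def indications(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cohorts():
            seen.setdefault(c.indication, None)
        return list(seen)


def _parse_cell(raw: str, na_lower: frozenset[str], row: str, col: str) -> float:
    if raw.strip().lower() in na_lower:
        return math.nan
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"non-numeric cell at protein {row!r}, sample {col!r}: {raw!r}") from None


def read_abundance_table(
    path,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
    sample_cohort: Mapping[str, CohortLabel] | None = None,
) -> AbundanceMatrix:
    """Read a tab-separated protein x sample abundance table.

    First column holds protein ids, the header row sample ids. Cells equal
    to one of ``na_tokens`` (case-insensitive) become missing entries.
    Duplicate ids or non-numeric non-NA cells raise with coordinates.
    """
    na_lower = frozenset(t.lower() for t in na_tokens)
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError("empty file: no header row")
        columns = header.split("\t")[1:]
        rows: list[str] = []
        data: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(columns) + 1:
                raise ValueError(f"line {lineno}: expected {len(columns) + 1} fields, got {len(cells)}")
            pid = cells[0]
            rows.append(pid)
            data.append([_parse_cell(c, na_lower, pid, columns[k]) for k, c in enumerate(cells[1:])])
    if not rows:
        raise ValueError("no proteins: data section is empty")
    frame = pd.DataFrame(np.asarray(data, dtype=float), index=pd.Index(rows, name="protein"), columns=columns)
    cohorts = dict(sample_cohort) if sample_cohort is not None else None
    return AbundanceMatrix(frame, cohorts)


def read_sample_metadata(path, allow_aliases: bool = True) -> dict[str, CohortLabel]:
    """Read a (sample, indication, tissue) TSV into a cohort map.

    Tissue must resolve to ``tumor`` or ``normal``; with ``allow_aliases``
    common synonyms such as ``NAT`` are accepted. Duplicated sample rows
    with conflicting cohorts raise.
    """
    out: dict[str, CohortLabel] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ValueError("metadata must have at least 3 columns: sample, indication, tissue")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 fields")
            sample, indication, tissue = cells[0], cells[1], cells[2].strip().lower()
            if tissue not in VALID_TISSUES:
                if allow_aliases and tissue in TISSUE_ALIASES:
                    tissue = TISSUE_ALIASES[tissue]
                else:
                    raise ValueError(f"line {lineno}: unknown tissue token {cells[2]!r}")
            label = CohortLabel(indication, tissue)
            if sample in out and out[sample] != label:
                raise ValueError(f"line {lineno}: sample {sample!r} has conflicting cohorts")
            out[sample] = label
    return out


def write_matrix(matrix, path, na_token: str = "NA") -> None:
    """Write a matrix as TSV, masked cells as ``na_token``, full precision.

    Accepts an :class:`AbundanceMatrix` or a plain DataFrame. Values are
    formatted with ``repr`` so a read/write round trip is bit-exact.
    """
    frame = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("protein\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        arr = frame.to_numpy(dtype=float)
        for pid, row in zip(frame.index, arr):
            cells = [na_token if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")


def write_metadata(sample_cohort: Mapping[str, CohortLabel], path) -> None:
    """Write a cohort map as a (sample, indication, tissue) TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample\tindication\ttissue\n")
        for sample, label in sample_cohort.items():
            fh.write(f"{sample}\t{label.indication}\t{label.tissue}\n")


def read_annotation(path) -> ProteinAnnotation:
    """Read a (protein, n_theoretical_peptides[, gene]) TSV."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] < 1:
        raise ValueError("annotation needs at least a peptide-count column")
    n_pep = frame.iloc[:, 0]
    gene = frame.iloc[:, 1] if frame.shape[1] > 1 else None
    return ProteinAnnotation(n_pep, gene)


def write_annotation(annotation: ProteinAnnotation, path) -> None:
    frame = pd.DataFrame({"n_theoretical_peptides": annotation.n_peptides})
    if annotation.gene_symbol is not None:
        frame["gene"] = annotation.gene_symbol
    frame.index.name = "protein"
    frame.to_csv(path, sep="\t")
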