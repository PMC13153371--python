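"""Pipeline configuration and end-to-end orchestration.

Stages run in a fixed order — select, classify, impute, quantify,
normalize, dep, evaluate — each persisting its outputs under the output
directory; a JSON manifest records the package version, seeds, and
row/column counts per stage so that a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from panquant import __version__
from panquant.core_io import (
    AbundanceMatrix,
    CohortLabel,
    read_abundance_table,
    read_annotation,
    read_sample_metadata,
    write_matrix,
)
from panquant.dep import call_deps, run_dep
from panquant.evaluate import rank_concordance
from panquant.imputation import hybrid_impute
from panquant.missingness import calls_to_frame, classify_all_cohorts
from panquant.normalize import NormalizationSpec, apply_normalization
from panquant.quantify import quantify
from panquant.selection import (
    profile_tumor_indications,
    select_robust_proteins,
    selection_mass_report,
)

logger = logging.getLogger(__name__)

STAGES = ("select", "classify", "impute", "quantify", "normalize", "dep", "evaluate")


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML."""

    abundance_path: str
    metadata_path: str
    annotation_path: str
    rna_path: str | None = None
    output_dir: str = "panquant_out"
    # selection
    rank_cutoff: float = 0.5
    missing_cutoff: float = 0.25
    # classification
    fit_quantile_range: tuple[float, float] = (0.5, 1.0)
    # imputation
    seed: int = 0
    knn_k: int = 10
    tune_sigma: float = 1.0
    # quantification
    total_molecules_per_cell: float | None = None
    # normalization
    normalization_method: str = "global_quantile"
    group_by: str = "cohort"  # or "indication"
    # differential expression
    abs_log2fc_threshold: float = 1.0
    fdr_threshold: float = 0.01
    # evaluation
    rna_r_threshold: float = 0.5
    majority_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("abundance_path", "metadata_path", "annotation_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.rna_path is not None and not Path(self.rna_path).exists():
            raise FileNotFoundError(f"rna_path: {self.rna_path}")
        if not 0 <= self.rank_cutoff <= 1 or not 0 <= self.missing_cutoff <= 1:
            raise ValueError("selection cutoffs must lie in [0, 1]")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if self.normalization_method not in ("none", "global_quantile", "smooth_quantile", "ribaq"):
            raise ValueError(f"unknown normalization method {self.normalization_method!r}")
        if self.group_by not in ("cohort", "indication"):
            raise ValueError("group_by must be 'cohort' or 'indication'")


def _grouping(matrix: AbundanceMatrix, group_by: str) -> dict[str, str]:
    assert matrix.sample_cohort is not None
    if group_by == "cohort":
        return {s: f"{c.indication}:{c.tissue}" for s, c in matrix.sample_cohort.items()}
    return {s: c.indication for s, c in matrix.sample_cohort.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    A stage failure raises with the stage name; outputs of completed
    stages are retained in the output directory.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    metadata = read_sample_metadata(config.metadata_path)
    matrix = read_abundance_table(config.abundance_path, sample_cohort=metadata)
    annotation = read_annotation(config.annotation_path)

    stage = "select"
    try:
        profiles = profile_tumor_indications(matrix)
        kept = select_robust_proteins(profiles, config.rank_cutoff, config.missing_cutoff)
        mass = selection_mass_report(matrix, kept, annotation)
        pd.Series(kept).to_csv(out / "kept_proteins.txt", index=False, header=False)
        mass.rename("retained_ibaq_fraction").to_csv(out / "selection_mass_report.tsv", sep="\t")
        selected = AbundanceMatrix(matrix.values.loc[kept], dict(metadata))
        manifest["stages"][stage] = {
            "proteins_in": int(matrix.values.shape[0]),
            "proteins_kept": int(len(kept)),
        }

        stage = "classify"
        calls = classify_all_cohorts(selected, config.fit_quantile_range)
        calls_frame = calls_to_frame(calls)
        calls_frame.to_csv(out / "missingness_calls.tsv", sep="\t", index=False)
        summary = pd.DataFrame(
            [
                {
                    "indication": c.indication,
                    "tissue": c.tissue,
                    "censoring_threshold": call.censoring_threshold,
                    "mu_hat": call.mu_hat,
                    "sigma_hat": call.sigma_hat,
                }
                for c, call in calls.items()
            ]
        )
        summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "cohorts": len(calls),
            "mnar_calls": int((calls_frame["mechanism"] == "MNAR").sum()),
        }

        stage = "impute"
        imputed = hybrid_impute(selected, calls, config.seed, config.knn_k, config.tune_sigma)
        write_matrix(imputed.matrix, out / "imputed.tsv")
        imputed.provenance.to_csv(out / "imputation_provenance.tsv", sep="\t")
        prov = imputed.provenance.to_numpy()
        manifest["stages"][stage] = {
            "entries_qrilc": int((prov == "imputed_qrilc").sum()),
            "entries_knn": int((prov == "imputed_knn").sum()),
        }

        stage = "quantify"
        tables = quantify(imputed.matrix.values, annotation, config.total_molecules_per_cell)
        write_matrix(tables.ibaq, out / "ibaq.tsv")
        write_matrix(tables.ribaq, out / "ribaq.tsv")
        if tables.copy_number is not None:
            write_matrix(tables.copy_number, out / "copy_number.tsv")
        manifest["stages"][stage] = {"shape": list(tables.ibaq.shape)}

        stage = "normalize"
        spec = NormalizationSpec(
            method=config.normalization_method,
            groups=_grouping(selected, config.group_by),
        )
        normalized = apply_normalization(tables, spec)
        write_matrix(normalized, out / "normalized_log2_ibaq.tsv")
        manifest["stages"][stage] = {"method": config.normalization_method}

        stage = "dep"
        norm_matrix = AbundanceMatrix(normalized, dict(metadata))
        dep_counts = {}
        for ind in norm_matrix.indications():
            tumor = norm_matrix.samples_of(CohortLabel(ind, "tumor"))
            normal = norm_matrix.samples_of(CohortLabel(ind, "normal"))
            if len(tumor) < 2 or len(normal) < 2:
                logger.info("skipping DEP for %s: fewer than 2 samples per group", ind)
                continue
            result = run_dep(normalized, tumor, normal)
            deps = call_deps(result, config.abs_log2fc_threshold, config.fdr_threshold)
            result.table.assign(is_dep=result.table.index.isin(deps)).to_csv(
                out / f"dep_{ind}.tsv", sep="\t"
            )
            dep_counts[ind] = int(len(deps))
        manifest["stages"][stage] = {"dep_counts": dep_counts}

        stage = "evaluate"
        if config.rna_path is not None:
            rna = read_abundance_table(config.rna_path, sample_cohort=metadata)
            comparison = rank_concordance(
                norm_matrix, rna,
                r_threshold=config.rna_r_threshold,
                majority_fraction=config.majority_fraction,
            )
            comparison.v.rename("v").to_csv(out / "rank_concordance.tsv", sep="\t")
            manifest["stages"][stage] = {
                "validation_proteins": int(len(comparison.v)),
                "median_v": float(comparison.v.median()),
            }
        else:
            manifest["stages"][stage] = {"skipped": "no RNA matrix provided"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
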