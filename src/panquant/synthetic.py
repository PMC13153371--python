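"""Synthetic multi-cohort proteomics data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-protein log2-normal baseline abundance, per-indication
additive offsets shared by the tumor and normal cohorts of that
indication, tumor effects on a controlled fraction of proteins,
intensity-dependent left-censoring (MNAR, logistic in the latent value)
plus uniform random dropout (MAR), integer theoretical-peptide counts,
and an RNA matrix whose per-indication protein-RNA correlation is
controlled by an additive noise scale.

Censoring is probabilistic (logistic) rather than a hard cut so that the
missingness classifier faces a realistic soft boundary; a large
``censor_slope`` recovers hard censoring in the limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from panquant.core_io import AbundanceMatrix, CohortLabel, ProteinAnnotation

#: entry mechanism codes in SyntheticTruth.mechanism
OBSERVED, MNAR, MAR = 0, 1, 2

DEFAULT_INDICATIONS = ("BRCA", "COAD", "LUAD", "LSCC", "ccRCC", "UCEC")


@dataclass
class SyntheticConfig:
    """Generator parameters; all log2-scale units unless noted.

    ``samples_per_cohort`` is a (tumor, normal) pair of per-indication
    sample counts. ``de_effect_size``, when set, plants effects of fixed
    magnitude with random sign instead of drawing them Normal(0,
    ``de_effect_sd``). ``censor_slope=0`` disables MNAR censoring.
    """

    n_proteins: int = 2000
    indications: Sequence[str] = DEFAULT_INDICATIONS
    samples_per_cohort: tuple[int, int] = (10, 10)
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    cohort_shift_sd: float = 0.5
    indication_effect_sd: float = 1.0
    noise_sd: float = 1.0
    de_fraction: float = 0.1
    de_effect_sd: float = 1.5
    de_effect_size: float | None = None
    censor_threshold: float = 17.0
    censor_slope: float = 2.0
    mar_rate: float = 0.05
    peptide_count_range: tuple[int, int] = (1, 60)
    rna_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.mar_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        for name in (
            "baseline_sd",
            "cohort_shift_sd",
            "indication_effect_sd",
            "noise_sd",
            "de_effect_sd",
            "rna_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.samples_per_cohort) < 2:
            raise ValueError("samples_per_cohort must be >= 2")
        if self.censor_slope < 0:
            raise ValueError("censor_slope must be >= 0")
        lo, hi = self.peptide_count_range
        if lo < 1 or hi < lo:
            raise ValueError("peptide_count_range must satisfy 1 <= lo <= hi")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated dataset.

    ``mechanism`` holds one code per entry (0 observed, 1 MNAR, 2 MAR);
    the codes partition missing entries. ``latent`` is the complete
    noise-free-missingness matrix the observed data were censored from.
    Non-DE proteins have ``true_log2fc`` exactly 0.
    """

    baselines: pd.Series
    indication_offsets: pd.Series
    indication_effects: pd.DataFrame  # proteins x indications, biological
    true_log2fc: pd.Series
    censor_threshold: float
    mechanism: pd.DataFrame
    latent: pd.DataFrame
    all_missing_proteins: list[str]
    config: SyntheticConfig


def _sample_frame(config: SyntheticConfig) -> dict[str, CohortLabel]:
    n_tumor, n_normal = config.samples_per_cohort
    cohorts: dict[str, CohortLabel] = {}
    for ind in config.indications:
        for r in range(n_tumor):
            cohorts[f"{ind}_T{r + 1:02d}"] = CohortLabel(ind, "tumor")
        for r in range(n_normal):
            cohorts[f"{ind}_N{r + 1:02d}"] = CohortLabel(ind, "normal")
    return cohorts


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[AbundanceMatrix, ProteinAnnotation, SyntheticTruth]:
    """Generate an abundance matrix, annotation, and ground truth.

    The complete latent matrix is generated first; the MNAR mask is drawn
    per entry with probability sigmoid(censor_slope * (censor_threshold -
    value)), the MAR mask independently with ``mar_rate``, and an entry is
    observed where neither mask fires. Fully reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed)
    proteins = pd.Index([f"P{j + 1:05d}" for j in range(config.n_proteins)], name="protein")
    sample_cohort = _sample_frame(config)
    samples = pd.Index(list(sample_cohort), name="sample")

    baselines = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins), index=proteins
    )
    offsets = pd.Series(
        rng.normal(0.0, config.cohort_shift_sd, len(config.indications)),
        index=pd.Index(config.indications, name="indication"),
    )
    # protein-specific biological variation across indications: the signal
    # that makes cross-indication protein ranks informative and that
    # rank-preserving normalization is expected to retain
    interactions = pd.DataFrame(
        rng.normal(0.0, config.indication_effect_sd, (config.n_proteins, len(config.indications))),
        index=proteins,
        columns=pd.Index(config.indications, name="indication"),
    )

    n_de = int(round(config.de_fraction * config.n_proteins))
    de_idx = rng.choice(config.n_proteins, size=n_de, replace=False)
    effects = np.zeros(config.n_proteins)
    if n_de:
        if config.de_effect_size is not None:
            effects[de_idx] = config.de_effect_size * rng.choice([-1.0, 1.0], size=n_de)
        else:
            effects[de_idx] = rng.normal(0.0, config.de_effect_sd, n_de)
    true_fc = pd.Series(effects, index=proteins)

    ind_of = np.array([sample_cohort[s].indication for s in samples])
    is_tumor = np.array([sample_cohort[s].tissue == "tumor" for s in samples])
    col_offset = offsets.loc[ind_of].to_numpy()

    latent = (
        baselines.to_numpy()[:, None]
        + col_offset[None, :]
        + interactions.loc[:, ind_of].to_numpy()
        + effects[:, None] * is_tumor[None, :]
        + rng.normal(0.0, config.noise_sd, (config.n_proteins, len(samples)))
    )

    if config.censor_slope > 0:
        from scipy.special import expit

        p_mnar = expit(config.censor_slope * (config.censor_threshold - latent))
    else:
        p_mnar = np.zeros_like(latent)
    mnar_mask = rng.random(latent.shape) < p_mnar
    mar_mask = rng.random(latent.shape) < config.mar_rate

    mechanism = np.where(mnar_mask, MNAR, np.where(mar_mask, MAR, OBSERVED)).astype(np.int8)
    observed = np.where(mechanism == OBSERVED, latent, np.nan)

    values = pd.DataFrame(observed, index=proteins, columns=samples)
    latent_frame = pd.DataFrame(latent, index=proteins, columns=samples)
    mech_frame = pd.DataFrame(mechanism, index=proteins, columns=samples)
    all_missing = values.index[values.isna().all(axis=1)].tolist()

    lo, hi = config.peptide_count_range
    n_pep = pd.Series(rng.integers(lo, hi + 1, config.n_proteins), index=proteins)
    annotation = ProteinAnnotation(n_pep)

    truth = SyntheticTruth(
        baselines=baselines,
        indication_offsets=offsets,
        indication_effects=interactions,
        true_log2fc=true_fc,
        censor_threshold=config.censor_threshold,
        mechanism=mech_frame,
        latent=latent_frame,
        all_missing_proteins=all_missing,
        config=config,
    )
    matrix = AbundanceMatrix(values, dict(sample_cohort))
    return matrix, annotation, truth


def generate_rna_matrix(truth: SyntheticTruth, config: SyntheticConfig) -> AbundanceMatrix:
    """Generate a complete RNA (log2 TPM-like) matrix paired with the truth.

    RNA value = latent protein value + Normal(0, rna_noise_sd), so the
    achieved per-indication protein-RNA correlation decreases monotonically
    in ``rna_noise_sd``. A distinct stream off the master seed keeps the
    RNA noise independent of the proteomic noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_001]))
    noise = rng.normal(0.0, config.rna_noise_sd, truth.latent.shape)
    values = truth.latent + noise
    sample_cohort = _sample_frame(config)
    return AbundanceMatrix(pd.DataFrame(values, index=truth.latent.index, columns=truth.latent.columns), sample_cohort)


def apply_technical_scaling(
    matrix: AbundanceMatrix, scale_sd: float, seed: int
) -> AbundanceMatrix:
    """Add a per-cohort technical location shift (log2 units) to a matrix.

    Models cohort-level technical variation (platform/lab differences)
    that normalization is supposed to remove; shifts are drawn once per
    cohort, Normal(0, scale_sd), and added to every entry of the cohort.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_002]))
    assert matrix.sample_cohort is not None
    shifts = {c: rng.normal(0.0, scale_sd) for c in matrix.cohorts()}
    shifted = matrix.values.copy()
    for cohort, shift in shifts.items():
        cols = matrix.samples_of(cohort)
        shifted[cols] = shifted[cols] + shift
    return AbundanceMatrix(shifted, dict(matrix.sample_cohort))


def truth_to_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Flatten per-protein truth to a frame for TSV export."""
    return pd.DataFrame(
        {
            "baseline": truth.baselines,
            "true_log2fc": truth.true_log2fc,
            "all_missing": truth.baselines.index.isin(truth.all_missing_proteins),
        }
    )
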