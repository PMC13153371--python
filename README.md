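# panquant

Cross-indication harmonization of pan-cancer protein expression data.

Large proteome programs quantify tumors and normal-adjacent tissue (NAT)
across many cancer types ("indications") in separate TMT cohorts. Before
protein abundance can be compared *across* indications, three problems
must be solved: proteins quantified too unreliably must be removed,
missing values must be imputed according to their mechanism, and
sample-level abundance distributions must be normalized without erasing
biology. `panquant` implements that workflow as a tested, reusable
Python library and CLI, together with a synthetic-data generator that
provides ground truth for every step. It is aimed at computational
proteomics researchers harmonizing multi-cohort protein quantification.

## The method

All operations work on a proteins × samples log2 abundance matrix; a
**cohort** is the unique combination of indication and tissue type
(tumor / normal).

1. **Robust-protein selection.** For protein *j* in the tumor cohort of
   indication *i*, let *M<sub>ij</sub>* be the missing rate,
   *A<sub>ij</sub>* the median of non-missing log2 abundance, and
   *F<sub>i</sub>(A<sub>ij</sub>)* its percentile rank within the
   cohort. Protein *j* is kept in **all** cohorts if some indication has
   *F<sub>i</sub>(A<sub>ij</sub>)* > 50% and *M<sub>ij</sub>* < 25%
   (both strict).
2. **Missingness-mechanism classification.** Per cohort, protein means
   are assumed normal if fully observed; (μ, σ) are estimated from the
   upper half of the normal Q-Q line of observed means. A censoring
   threshold is the observed mean *x* maximizing the objective
   ((F<sub>e</sub> − F<sub>o</sub> + 1)/(F<sub>o</sub> + 1) − 1)·10,
   where F<sub>e</sub> = Φ((x−μ)/σ) and F<sub>o</sub> is the empirical
   CDF; it exists only if the maximum is positive. Proteins with mean
   observed value at or below the threshold are MNAR (left-censored);
   the rest are MAR/MCAR.
3. **Cohort-hybrid imputation.** MNAR proteins' holes are filled by
   QRILC — draws from a per-sample-column normal truncated above at the
   estimated quantile of the column's missing fraction. MAR proteins'
   holes are filled by protein-wise k-nearest-neighbor imputation
   (k = 10). Cohorts are processed independently and observed values are
   never modified.
4. **Quantification.** iBAQ = 2^(log2 abundance) / (number of
   theoretically observable peptides); riBAQ rescales each sample to
   total 1; copy number scales riBAQ by a configured molecules-per-cell
   total.
5. **Normalization.** Global quantile normalization maps every sample
   onto the mean-of-order-statistics reference; smooth (group-aware)
   quantile normalization blends global and per-cohort references with a
   per-quantile weight so genuine between-group differences survive.
6. **Differential expression.** Per indication, tumor vs NAT moderated
   t-statistics: protein-wise variances are shrunk toward an
   empirical-Bayes prior (d₀, s₀²) fitted by digamma/trigamma moment
   matching, with Benjamini-Hochberg FDR control. DEPs require
   |log2 FC| > 1 and FDR < 0.01.
7. **Evaluation.** Weighted rank concordance *v*: indications ranked by
   median protein signal vs median RNA signal per validation protein,
   compared by weighted Pearson correlation with protein-RNA
   correlations as weights. Subset stability: global normalization is
   re-run inside every k-indication subset and checked for per-sample
   concordance and fold-change consistency.

## Worked example

Generate a synthetic 6-indication dataset (1000 proteins, 10 tumor and
10 NAT samples per indication, left-censoring plus random dropout) and
run the full pipeline:

```bash
panquant simulate --outdir demo --seed 7 --n-proteins 1000
cat > demo/pipeline.yaml <<EOF
abundance_path: demo/abundance.tsv
metadata_path: demo/metadata.tsv
annotation_path: demo/annotation.tsv
rna_path: demo/rna.tsv
output_dir: demo/out
seed: 7
normalization_method: global_quantile
EOF
panquant run-all --config demo/pipeline.yaml
```

The run prints its manifest (abridged):

```json
{
  "stages": {
    "select":   {"proteins_in": 1000, "proteins_kept": 735},
    "classify": {"cohorts": 12, "mnar_calls": 139},
    "impute":   {"entries_qrilc": 638, "entries_knn": 6406},
    "dep":      {"dep_counts": {"BRCA": 21, "COAD": 22, "LUAD": 20,
                                "LSCC": 17, "ccRCC": 19, "UCEC": 16}},
    "evaluate": {"validation_proteins": 610, "median_v": 0.8156}
  }
}
```

Reading: 735 of 1000 proteins pass the robustness rule; across the 12
cohorts, 139 protein-cohort pairs are called MNAR, so 638 missing
entries are imputed from the censored left tail and 6406 by KNN; each
indication yields ~16-22 tumor-vs-NAT DEPs (the generator plants effects
on 10% of proteins); and the median weighted rank concordance between
protein and RNA indication ranks over 610 validation proteins is 0.82.
Per-stage tables (kept proteins, mechanism calls, imputed matrix, iBAQ /
riBAQ, normalized matrix, DEP tables, rank concordance) land in
`demo/out/`. Each stage is also available as its own subcommand
(`select`, `classify`, `impute`, `quantify`, `normalize`, `dep`,
`evaluate`, `subset-analysis`).

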