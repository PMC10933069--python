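# mrxome

Two-sample Mendelian randomization combined with transcriptomic risk
scoring: a tested, reusable pipeline from GWAS/QTL summary statistics to
gene-level causal screens, single-sample enrichment risk scores, regulon
activity analysis, and immune-cell scoring with sparse selection. A
synthetic-data module generates every input the pipeline consumes, so the
full analysis runs and is verifiable without any downloads.

## Components

| module        | what it does |
|---------------|--------------|
| `summary_io`  | readers/writers for summary-stats TSV, GMT gene sets, expression matrices, LD and spillover matrices, with strict validation |
| `synthetic`   | seeded generators: GWAS exposure/outcome pairs under a causal model with pleiotropy/heterogeneity, per-gene QTL catalogs, expression studies with planted risk genes, TF regulons and cell signatures (plus truth objects) |
| `instruments` | harmonization onto a common effect allele, LD clumping, instrument selection (p-threshold with fallback tier, outcome-association removal, F >= 10 filter, confounder exclusion list) with a full audit trail |
| `mr`          | Wald ratio, fixed-effect IVW (primary), Egger regression, Cochran's Q, simulation-based pleiotropy outlier test (global/outlier/distortion), leave-one-out |
| `gene_screen` | moderated two-group differential expression (empirical-Bayes variance shrinkage, BH), per-gene QTL MR with OR>1 risk / OR<1 protective classification, protein-level verification, DE cross-tabulation |
| `enrichment`  | single-sample ECDF-walk enrichment scores, Wilcoxon group comparison, two-group permutation GSEA |
| `regulon`     | mutual-information regulon inference (permutation + bootstrap + DPI pruning), signed two-arm activity scores, one/two-tailed phenotype tests |
| `cell_scores` | signature-averaged cell-type scores, spillover compensation by least squares, univariate logistic screen, L1-penalized logistic selection (CV, 1-SE rule), gene-cell correlation |
| `pipeline`    | config-driven orchestration of the three analysis arcs with derived per-stage seeds and JSON/TSV reports |

## CLI

```bash
# generate a full synthetic input bundle (3 exposures, 2 outcomes, per-gene
# QTL catalog, expression study with planted structure)
mrxome simulate --preset paper-shape --seed 7 --out data/

# instrument selection + full MR report for one pair
mrxome instruments --exposure data/exposure_1.tsv --outcome data/outcome_1.tsv --out h.tsv
mrxome mr --harmonized h.tsv --seed 7 --out report.json

# per-gene QTL screen
mrxome gene-screen --catalog-dir data/eqtls --outcome data/eqtls/outcome.tsv --out genes.tsv

# enrichment scores / two-group GSEA
mrxome enrich --expr data/expression.tsv --pheno data/phenotype.tsv \
    --sets data/pathways.gmt --mode ssgsea --out scores.tsv

# regulons and activity
mrxome regulon --expr data/expression.tsv --pheno data/phenotype.tsv \
    --tfs data/tfs.txt --seed 7 --out regulons.json --activity-out activity.tsv

# cell-type scores + selection
mrxome cells --expr data/expression.tsv --pheno data/phenotype.tsv \
    --signatures data/signatures.gmt --cellmap data/cellmap.tsv \
    --seed 7 --out cells.tsv --selection-out selection.json

# whole pipeline from a YAML config
mrxome run --config config.yaml
```

Every threshold of the instrument-selection pipeline is exposed as a flag
with the published defaults (P < 5e-8 with r^2 = 0.001, fallback P < 5e-6
with r^2 = 0.01 below 20 instruments, outcome P < 5e-6 removal first,
F >= 10).

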