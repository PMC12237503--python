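# dapcy

Population structure analysis via **discriminant analysis of principal
components (DAPC)**: truncated-SVD dimensionality reduction on sparse
allele-dosage matrices, followed by Fisher discriminant classification
into populations, with cross-validated model selection, de novo K-means
cluster inference, reporting/plotting, and a built-in structured-population
simulator so every stage is testable without external data.

## Library overview

| module | contents |
|---|---|
| `dapcy.genotype_io` | chunked VCF/PLINK-BED ingestion into a CSR dosage matrix, missing-call mask, mean/zero imputation, MAF filtering |
| `dapcy.dapc_core` | `fit_truncated_svd` (implicit column centering, no densification), `fit_lda`, `fit_dapc`, `predict`, `predict_proba` |
| `dapcy.model_selection` | k-fold / stratified / LOOCV split plans, `cross_validate`, `grid_search_pcs`, the `k_minus_one_pcs` retention rule |
| `dapcy.clustering` | K-means on PC scores, silhouette/SSE sweeps over candidate k |
| `dapcy.reporting` | classification reports, confusion matrices, scatter plots, versioned portable model archives |
| `dapcy.popsim` | Balding–Nichols cohort simulator, VCF/PLINK writers, Hudson-style FST estimator |

```python
from dapcy import (SimulationSpec, simulate_cohort, fit_dapc, predict,
                   make_split_plan, cross_validate)

cohort = simulate_cohort(SimulationSpec(n_populations=4, fst=0.1, seed=7))
G, labels = cohort.genotypes, cohort.true_labels
plan = make_split_plan(G.n_samples, labels, scheme="stratified_kfold",
                       kcv=10, seed=7, sample_ids=G.sample_ids)
print(cross_validate(G, labels, n_pcs=10, plan=plan).mean_accuracy)
```

## CLI

```bash
# simulate a fixture cohort and labels
dapcy simulate --pops 4 --per-pop 50 --snps 1000 --fst 0.1 --seed 7 \
    --out fixture.vcf.gz --labels-out labels.tsv

# ingest a VCF into a sparse matrix archive (with MAF filtering)
dapcy convert --vcf fixture.vcf.gz --out matrix.npz --min-maf 0.1

# fit, cross-validate, and tune the number of retained PCs
dapcy fit --matrix matrix.npz --labels labels.tsv --n-pcs 40 --seed 7 --out model.npz
dapcy cv --matrix matrix.npz --labels labels.tsv --n-pcs 40 --scheme stratified --kcv 10 --seed 7
dapcy gridsearch --matrix matrix.npz --labels labels.tsv --grid 10:120:10 --seed 7

# de novo cluster inference and reporting
dapcy kmeans --matrix matrix.npz --k-range 2:10 --seed 7 --out clusters.tsv
dapcy report --matrix matrix.npz --model model.npz --labels labels.tsv --out report_dir/
dapcy predict --model model.npz --vcf new.vcf.gz --out calls.tsv
```

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: PCA-oracle
equivalence of the truncated SVD, parameter recovery on simulated
4-population cohorts, a permutation-null leakage guard, exact format
round-trips (VCF, BED, model archive), split-plan invariants, clustering
invariants, and the sparse-storage contract.

## Notes

- Dosages count alternate alleles (0..ploidy); haploid inputs are
  supported (`ploidy=1`).
- Multiallelic VCF records are dropped by default (logged) or split into
  per-ALT pseudo-variants with `multiallelic="split"`.
- Half-calls (`./1`) are treated as missing; mean imputation runs after
  MAF filtering so frequencies reflect observed calls.
- Model archives are versioned bundles of plain numeric arrays plus JSON
  metadata — portable across environments, unlike a native pickle.
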