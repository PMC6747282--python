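# tmbsubtype

Molecular subtyping of tumor cohorts by tumor mutation burden (TMB), with
mutational-signature extraction and margin-controlled gene enrichment.

The package implements a complete analysis pipeline for somatic-mutation
cohorts:

- **`io_cohort`** — MAF-like mutation tables (configurable column mapping),
  clinical tables, trinucleotide-context annotation from a FASTA, and the
  binary gene × sample mutation matrix.
- **`subtyping`** — per-sample TMB, exact 1-D k-means by dynamic programming
  (globally optimal within-cluster sum of squares), cluster-number selection
  by Gaussian-mixture BIC over k = 1..9, and TMB-H / TMB-L labels by a
  mean (default), median, or k-means-boundary threshold.
- **`signatures`** — 96-trinucleotide-context classification (pyrimidine
  strand convention), signature extraction by Poisson/KL NMF with automatic
  relevance determination (the number of signatures is inferred, not fixed),
  cosine matching against a reference catalog, and per-sample attributed
  mutation counts.
- **`enrichment`** — a permutation test associating per-gene mutation status
  with signature activity while holding every gene's and every sample's
  mutation count fixed via Curveball trade randomization; empirical p-values
  use the add-one correction and are BH-adjusted.
- **`stats_survival`** — Fisher exact tests with Benjamini–Hochberg
  adjustment, Wilcoxon rank-sum comparisons, Kaplan–Meier curves, and the
  two-group log-rank test.
- **`synthetic`** — a cohort generator that reproduces the statistical
  structure the pipeline assumes (bimodal TMB, a smoking-like C>A signature
  rising with TMB, a TMB-coupled gene, correlated clinical covariates, and
  exponential DFS with a subtype hazard effect), with every latent draw
  recorded for parameter-recovery tests.

The packaged reference catalog
(`src/tmbsubtype/data/cosmic_v2_style_catalog.tsv`) uses the COSMIC v2
96-category dialect but contains parametric emulations of well-known
signature shapes, not the numeric COSMIC matrix (see the file header and
`scripts/build_catalog.py`); pass `--catalog` to substitute the real file.

## CLI

```sh
tmb-subtype simulate --seed 1 --out data/                 # synthetic cohort
tmb-subtype cluster  --maf data/mutations.maf.tsv \
                     --samples data/samples.txt --rule mean --out out/cluster
tmb-subtype signatures --maf data/mutations.maf.tsv \
                     --samples data/samples.txt --seed 1 --out out/sig
tmb-subtype enrich   --pattern out/sig/attribution.tsv \
                     --maf data/mutations.maf.tsv --samples data/samples.txt \
                     --signature W1 -R 2000 --seed 1 --out out/enrich.tsv
tmb-subtype associate --maf data/mutations.maf.tsv --clinical data/clinical.tsv \
                     --samples data/samples.txt --out out/assoc
tmb-subtype survival --maf data/mutations.maf.tsv --clinical data/clinical.tsv \
                     --samples data/samples.txt --out out/surv
```

All outputs are TSVs with stable column order; every stochastic step takes a
`--seed` and is fully reproducible.

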