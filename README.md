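# geno2lnc

Three-stage pipeline for identifying circulating transcripts (lncRNAs)
associated with disease risk when expression can only be measured in some
cohorts:

1. **Preselection** — in a staged tissue dataset (gallstones → dysplasia →
   cancer, `GS < Dys < GBC`), find transcripts with monotone expression
   trends using permutation Jonckheere–Terpstra tests (BH-FDR corrected)
   combined with a gradient-boosted three-class importance screen, after
   log2-TPM transformation, MAD filtering, two-pass quantile normalization
   and Mahalanobis-depth outlier exclusion.
2. **cis-eQTL validation** — in an independent cohort with both genotypes
   and serum expression, validate candidate SNP–transcript pairs by robust
   (Huber IRLS) linear regression under four penetrance encodings
   (additive / three-genotype / dominant / recessive), adjusted for age,
   gender and 10 genetic PCs, after full genotype QC (MAF/call-rate
   filters, method-of-moments IBD kinship pruning, LD pruning, eigenstrat
   PCA, depth-based exclusion). The multi-SNP prediction model is chosen by
   exhaustive robust-AIC (RAIC) subset search.
3. **Imputation + association** — in a genotype-only case-control cohort,
   predict serum expression as Σ βᵢ·Aᵢ from the validated eQTL model and
   estimate the disease odds ratio per log2 expression unit by robust
   quasi-likelihood logistic regression (Huberized Pearson residuals with
   consistency correction, tuning constant 1.2).

A fully deterministic synthetic-data module (`geno2lnc.synthdata`)
generates every input the pipeline consumes — negative-binomial staged
counts with planted trends, Balding–Nichols structured genotypes with
planted cis-eQTLs, serum expression at a controlled variance-explained
fraction, and logistic case-control status — together with a ground-truth
record, so every stage is verifiable end to end without restricted data.

## CLI

Every stage reads/writes plain-text formats (TSV, VCF v4.2, JSON) under a
single output directory and records a manifest (input hashes, parameters,
funnel counts). Cached stages are skipped when inputs and parameters are
unchanged.

```bash
geno2lnc simulate  --config cfg.yaml --out run/ --seed 1
geno2lnc prep      --config cfg.yaml --out run/
geno2lnc preselect --config cfg.yaml --out run/
geno2lnc genoqc    --config cfg.yaml --out run/
geno2lnc eqtl      --config cfg.yaml --out run/
geno2lnc associate --config cfg.yaml --out run/
# or everything at once:
geno2lnc pipeline  --config cfg.yaml --out run/ --seed 1
```

`cfg.yaml` overrides any defaults in `geno2lnc.pipeline.DEFAULTS`, e.g.

```yaml
seed: 1
sim:
  n_transcripts: 200
  n_trend: 10
  trend_effect: 1.0
preselect:
  n_perm: 5000
```

Exit codes: 0 ok, 1 user error (bad config/data), 2 internal error.

## Layout

```
src/geno2lnc/
  synthdata.py        synthetic inputs + ground truth
  expression_prep.py  log2-TPM, MAD filter, quantile normalization, depth exclusion
  preselect.py        J–T permutation test, BH-FDR, boosted-tree screen, funnel
  genotype_qc.py      SNP/sample filters, IBD, LD pruning, genetic PCA
  eqtl_validation.py  penetrance encodings, robust fits, RAIC model selection
  impute_associate.py expression imputation, robust logistic association, reports
  pipeline.py / cli.py  orchestration, manifests, caching, CLI
  _robust.py / _depth.py / _vcf.py  shared numerics and I/O
```
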