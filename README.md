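# gxeherit

Tools for estimating the heritability of gene–environment (G×E)
interactions for a quantitative trait from individual-level data, with a
fully synthetic validation path:

1. **synthetic_cohort** — LD-structured genotype / exposure / phenotype
   simulation with exactly-rescaled variance components and a recorded
   truth object, so every downstream stage can be validated by parameter
   recovery without any external data.
2. **preprocess** — variant QC (missingness → MAF → Hardy–Weinberg exact
   test) and phenotype/exposure transforms (log, rank-based inverse
   normal, within-sex quartiles, exposure–outcome association).
3. **gwis** — the per-variant interaction scan
   `phenotype ~ 1 + G + G×E + E + covariates`, reporting the interaction
   coefficient, SE, t, two-sided p and χ² = t² per variant, with a
   Frisch–Waugh–Lovell fast path that is exactly equal to full-design OLS.
4. **inflation** — genomic-control λ (median χ² / 0.45656), χ² correction,
   the intercept-above-1.1 decision rule, and Q–Q plot data.
5. **ldscores** — windowed LD scores with the (1−r²)/(n−2) finite-sample
   adjustment, plus the equal-per-SNP (GCTA-model) tagging view.
6. **heritability** — two summary-statistic estimators of h²_G×E:
   weighted LD-score regression and a scaled-χ² tagging likelihood, both
   with delete-one-block jackknife SEs; heritability summation across
   exposures and Bonferroni thresholds.
7. **pipeline_cli** — greedy LD clumping, the full orchestrated pipeline
   (scan → preliminary regression → GC decision → final fits → clump →
   report), and a `click` CLI.

## Test

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, whose replicate studies
(null calibration and parameter recovery at n=4000, M=5000) take several
minutes on one CPU.

## CLI

```bash
gxeherit simulate --n-samples 2000 --n-variants 1000 --block-size 25 \
    --rho 0.5 --h2-additive 0.2 --h2-gxe 0.05 --n-causal-additive 100 \
    --n-causal-gxe 50 --seed 1 --out cohort --format tsv
gxeherit qc      --genotypes cohort.dosage.tsv --out cohort
gxeherit gwis    --genotypes cohort.qc.dosage.tsv --pheno cohort.pheno.tsv --out cohort
gxeherit ldscore --genotypes cohort.qc.dosage.tsv --out cohort.l2.tsv
gxeherit h2      --sumstats cohort.sumstats.tsv --ldscores cohort.l2.tsv --out cohort.h2.tsv
gxeherit gc      --sumstats cohort.sumstats.tsv --out cohort.gc.sumstats.tsv
gxeherit clump   --sumstats cohort.sumstats.tsv --genotypes cohort.qc.dosage.tsv --out cohort.clumps.tsv
gxeherit run-all --config config.yaml --seed 1 --out run1
```

`run-all` reads a YAML config (see `tests/test_cli.py` for a worked
example) and writes a provenance-stamped report plus Manhattan/QQ/bar
plot data tables.

Genotypes are accepted as PLINK 1 `bed/bim/fam` (a path prefix) or as a
TSV dosage matrix (`*.tsv`); phenotype/exposure/covariates travel in a
TSV with header `IID PHENO EXPOSURE [COV1 ...]`.

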