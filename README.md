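# rlfvpredict

Genomic prediction with rare and low-frequency sequence variants (RLFV) in
structured populations: a simulation and analysis pipeline for dairy-cattle
style data.

## The problem

Routine genomic prediction in dairy cattle uses GBLUP on a common SNP
panel ("50k" chips). Imputed whole-genome sequence data add millions of
rare and low-frequency variants (minor allele frequency in [0.001, 0.05)),
many of them inside genes and potentially closer to causal mutations for
fitness traits such as fertility. Whether *adding a selected subset of
RLFV* as a second genomic relationship component actually improves the
reliability of genomic estimated breeding values (GEBV) — and how much the
answer depends on how the subset is selected — is the question this
package quantifies, on synthetic data that reproduce the relevant
structure of a progeny-tested sire population: half-sib families,
de-regressed proofs (DRP) with high reliabilities, and causal rare
variants confined to genes.

It is aimed at quantitative geneticists who want a fully reproducible,
desk-scale test bed for rare-variant selection strategies in genomic
prediction.

## Core models

* **GBLUP** with one or two genomic relationship matrices:
  `y = 1μ + Z₁g₁ + Z₂g₂ + e`, `gᵢ ~ N(0, Gᵢ σ²ᵢ)`, with each `G` computed
  by VanRaden's method 1, `G = (X − 2p1')(X − 2p1')' / 2Σpⱼ(1 − pⱼ)`.
* **REML** variance-component estimation (average-information updates with
  a robust fixed-point fallback; spectral path for single-kernel models)
  and mixed-model-equation prediction of validation GEBV from
  training-only records.
* **Gene-level rare-variant association** (famSKAT-style): a
  variance-component score test `Q = r'MM'r` with a pedigree polygenic
  background, p-values from the exact mixture-of-chi-squares null
  distribution (Imhof's integral), genes mapped at p < 0.01.
* **Selection strategies** for the second kernel: all genic RLFV,
  annotation-impact classes (high / medium-to-high), mapped genes,
  size-matched random controls, known causal variants (simulations only),
  and causal-plus-random noise controls.
* **Validation statistics**: reliability `cor(GEBV, y)² / mean(r²_DRP)`
  (0–100 scale), accuracy standard errors, the bias slope
  `cov(y, GEBV)/var(GEBV)`, and replicate means ± `sd/√k`.

## Worked example

```python
from rlfvpredict import workflow as wf

cfg = wf.ExperimentConfig(
    n_chr=5, genes_per_chr=12, rlfv_per_gene=8, n_common_per_chr=60,
    n_sires=30, daughters_per_sire=9, n_validation=60,
    scenarios=("LQTN",), strategies=("k50_only", "true_qtn"),
    replicates=3, seed=42)
report = wf.run_experiment(cfg)
print(report.summary.round(2).to_string(index=False))
```

prints

```
scenario strategy  n_replicates  reliability_pct_mean  reliability_pct_se  bias_slope_mean  bias_slope_se
    LQTN k50_only             3                 60.87                6.98             1.18           0.07
    LQTN true_qtn             3                 62.97                4.89             1.16           0.04
```

Each row is a selection strategy under the LQTN scenario (nine causal
genes genome-wide, jointly explaining 10% of the 50k genetic variance).
`k50_only` is the reference model with the common panel alone;
`true_qtn` adds a second relationship matrix built from the causal rare
variants themselves. Reliability is the squared GEBV–phenotype correlation
in the validation cohort divided by the mean DRP reliability, in percent,
averaged over replicates ± its standard error; even at this toy scale the
causal-variant kernel raises reliability. The bias slope near 1 indicates
GEBV on approximately the right scale. At the default desk scale
(n = 2000, 10 replicates) the contrast is sharper and the ordering
50k-only < 50k+mapped < 50k+true-QTN emerges, with random noise variants
eroding most of the causal gain.

A command-line interface mirrors the library:

```bash
rlfv-predict simulate --out data/            # VCF + BED + TSV dataset
rlfv-predict run --config config.yaml --out results/
rlfv-predict scan --vcf data/genotypes.vcf --variants data/variants.tsv \
    --pheno data/phenotypes.tsv --kinship data/grm_50k.tsv --out scan.tsv
```

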