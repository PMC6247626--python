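# Methods

## Scientific setting

`rlfvpredict` studies a question from dairy-cattle genomic prediction: when
imputed sequence data make rare and low-frequency variants (RLFV, minor
allele frequency in [0.001, 0.05)) available, does adding a selected subset
of them as a second genomic relationship component to a standard
GBLUP model based on a common ("50k"-style) SNP panel improve the
reliability of genomic estimated breeding values (GEBV)? Because suitable
sire datasets are proprietary, the package answers this on simulated data
whose structure mimics a progeny-tested sire population: half-sib families,
de-regressed proofs (DRP) as pseudo-phenotypes, and causal rare variants
("QTN") confined to genes.

## Models

### GBLUP

One- and two-kernel linear mixed models:

    y = 1 mu + g + e,                      g  ~ N(0, G  sigma2_g),
    y = 1 mu + g1 + g2 + e,                g1 ~ N(0, G1 sigma2_1),
                                           g2 ~ N(0, G2 sigma2_2),

with e ~ N(0, I sigma2_e). G is VanRaden's method-1 genomic relationship
matrix, G = (X − 2p1')(X − 2p1')' / (2 Σ p_j (1 − p_j)), computed from
observed allele frequencies of the analysed sample (each kernel uses the
frequencies of its own variant subset). The denominator scales G to the
pedigree-relationship scale. G is symmetric positive semidefinite by
construction; a 1e-6 diagonal jitter is added only if a Cholesky probe of
G + 1e-8 I fails (round-off protection).

### REML

Variance components are estimated by restricted maximum likelihood on the
training cohort. The default algorithm is average-information (AI) REML
warm-started with three fixed-point steps; the fixed-point update is the
multiplicative EM-type iteration sigma2 <- sigma2 * (y'PKPy)/tr(PK), which
approaches a zero boundary geometrically (the additive EM form, with its
sigma2^2-scaled step, stalls there). An AI step is rejected in favour of the
fixed point whenever the AI system is ill-conditioned (step larger than
1e3 * var(y)), a component would leave the parameter space, or the previous
iteration decreased the restricted likelihood. Components whose score is
negative at the lower bound (1e-8 * var(y)) are pinned there. Convergence is
declared when the maximum relative parameter change falls below 1e-6
(default), within at most 200 iterations; non-convergence is flagged on the
result, not fatal. A pure fixed-point path with Aitken extrapolation is
available via `method="em"` and is tested to agree with AI.

Single-kernel fits use a spectral decomposition of K so each iteration is
O(n) after one O(n^3) eigendecomposition; multi-kernel fits use dense
Cholesky solves (O(n^3) per iteration, ~10 AI iterations in practice).

### Prediction

Variance components are estimated on training data only and then fixed.
GEBV for validation individuals solve the mixed-model equations with
training records but relationship matrices over all individuals:

    g_hat_i = sigma2_i K_i[val, train] V_train^{-1} (y_train − mu_hat),

reported per kernel and summed. This mirrors standard forward-validation
practice for sire evaluations.

### Gene-level rare-variant association

The mapping strategy scans genes with a kernel variance-component score
test in a family-adjusted model (famSKAT-style): under the null,
y = X gamma + u + e with u ~ N(0, A sigma2_a), A the pedigree relationship
matrix (a GRM may be substituted via configuration). For a gene with RLFV
dosage matrix M the statistic is Q = r'MM'r with r = V0^{-1}(y − X gamma),
variant effects carrying equal weights (no assumption on effect direction;
a MAF-based weighting hook exists but is off by default, matching the
equal-variance model). Under the null Q ~ Σ lambda_i chi2_1 with lambda_i
the eigenvalues of M'P0M. Tail probabilities are computed by numerical
inversion of the characteristic function (Imhof's integral, via adaptive
quadrature) with a Satterthwaite two-moment fallback recorded on the
result. The null model is fitted once per trait and reused across genes.
Genes with p strictly below alpha = 0.01 are "mapped". The pure kernel
test is used (no burden/SKAT-O blending).

A note on finite-sample behaviour: the analytic p-value is normal-theory.
At very small n it differs from a permutation p-value by O(1/n) because the
permutation distribution conditions on the empirical moments of the sample;
at n = 30 this difference (typically 0.005–0.02 in absolute p) exceeds the
Monte-Carlo error of 1e5 permutations. Calibration at scan scale (hundreds
of individuals) is accurate, as the type-I-error tests show.

## Validation statistics

* Reliability: r2_GEBV = cor(GEBV, y_val)^2 / mean(r2_DRP), on 0–100 in
  tables. It can exceed 1 when the correlation is near 1 and DRP
  reliability is below 1.
* Accuracy SE: ((1 − r2_GEBV)/sqrt(N − 2)) / rbar_DRP, N = training size,
  rbar_DRP = sqrt(mean r2_DRP).
* Scale bias: slope of the regression of validation phenotype on GEBV,
  cov(y, GEBV)/var(GEBV); 1 means no over/under-dispersion.
* Replicate summaries: mean and sd/sqrt(k) with the k−1 sd (k = 10 by
  default).
* Pearson correlations and ddof = 1 sample variances throughout.

## Synthetic data

### What is emulated

* **Genome**: 29 autosomes, each a row of 100-kb blocks; one gene per
  block with its RLFV at 100-bp spacing, common SNPs and optional
  intergenic RLFV in the intergenic remainder. RLFV target MAFs are
  log-uniform on [0.001, 0.05) (rarer variants more numerous, as in
  sequence data); common-panel MAFs uniform on [0.05, 0.5). Annotation
  impact classes are i.i.d. per genic RLFV with defaults high 1%,
  medium 2%, low 97%, giving <1% high-impact and <3% medium-to-high
  RLFV as observed in annotated cattle sequence.
* **Population**: founder sires and dams in linkage equilibrium
  (per-locus Bernoulli haplotypes at target MAF); daughters by
  gene-dropping with Haldane recombination at 1 cM/Mb, one unique founder
  dam per daughter, so paternal half-sib families are the only close
  relationships. Dams enter the pedigree (for A) but not the genotype
  matrix, as in real sire datasets. Within-chromosome LD therefore arises
  only from family co-segregation, which is the mechanism by which a
  common panel captures rare-variant variance through relationships.
* **Phenotypes**: a polygenic true breeding value built from the common
  panel with i.i.d. normal SNP effects, rescaled to an exact genetic
  variance sigma2_g (default 145, fertility-like). DRP = TBV + noise with
  per-individual noise variance sigma2_g (1 − r2)/r2, where r2 is
  Beta-distributed with mean 0.85 (concentration 200) — the mean DRP
  reliability is what sire datasets report; the spread is a modelling
  stand-in since individual reliabilities vary with progeny-group size in
  an unreported way. The trait's phenotypic variance (default 328.8)
  enters as known bookkeeping: heritability = sigma2_g / total, 0.441 at
  the defaults, and REML recovery is assessed on that scale.
* **Causal RLFV (QTN) scenarios**: SQTN draws 7–10 genes per chromosome
  (uniformly per replicate), MQTN one gene per chromosome, LQTN nine
  genes genome-wide; every RLFV of a selected gene becomes causal.
  Effects are standard normal and TBV_Q = M_Q alpha is rescaled so its
  sample variance is *exactly* fraction × sigma2_g (default 10%, i.e.
  14.5), giving a composed-phenotype heritability of
  (14.5 + 145)/328.8 = 0.485. The composed phenotype is y = DRP + TBV_Q.

### What is not emulated

Population-level LD beyond family co-segregation, imputation error and its
MAF dependence, real VEP/SIFT annotation (classes are labels with no
functional consequence for effect sizes), selection/inbreeding, multi-trait
index construction. Passing tests therefore demonstrate the statistical
machinery and the relatedness-driven mechanisms, not the magnitude of
LD-driven effects in real cattle data.

## Experiment grid and problem sizes

The default experiment (the "desk-scale" profile) uses 29 chromosomes × 20
genes × 15 RLFV (8700 genic RLFV, 4350 common SNPs, 290 intergenic RLFV),
100 sires × 19 daughters (n = 2000 genotyped individuals; youngest 400 are
validation), 10 replicates per scenario, and the strategy set {50k-only,
50k + true QTN, 50k + QTN + random RLFV, 50k + mapped RLFV}. Twenty genes
per chromosome (rather than fewer, larger gene sets) leave room for the
SQTN scenario and for the 10 random non-causal genes per chromosome that
the noise-control strategy adds. Genome, population and DRP are shared
across all cells of one experiment; only the QTN draw varies by
(scenario, replicate), with per-replicate seeds a pure function of
(master seed, scenario, replicate) so any cell can be recomputed alone.
The mapping scan runs once per replicate on the composed phenotype using
training individuals only.

Mapping power at this scale is modest by design honesty, not accident: for
LQTN the nine causal genes each explain ~0.9% of the phenotypic variance,
and the scan detects roughly a third to a half of them at alpha = 0.01
with n_train = 1600, so the mapped strategy sits between the 50k-only
reference and the known-QTN ceiling but much closer to the former. Under
SQTN (variance spread over ~250 genes) per-gene power is essentially nil
and mapped selection degenerates to a random-noise control — consistent
with real-data experience where mapped RLFV change reliability by at most
a point or two in either direction.

## Numerical choices

* Variance floors: 1e-8 × var(y) in REML; eigenvalues below
  1e-10 × lambda_max dropped in the score test (all-monomorphic genes are
  "degenerate" with p = 1).
* Imhof quadrature: adaptive with 500 subdivisions; the result is
  rejected (fallback to Satterthwaite) if the integral error exceeds 1e-5
  or the probability leaves [0, 1].
* MAF filter: floor-inclusive, ceiling-exclusive; MAF computed on the full
  genotyped sample before the training/validation split. At the floor
  0.001 with 6337 diploids this retains variants with ≥ 13 minor-allele
  copies.
* The second-kernel strategies compute GRM frequencies from their own
  variant subset; the 50k and RLFV variant sets are disjoint by the MAF
  threshold.
* An empty second-kernel set (e.g. no genes mapped) degrades the cell to
  the one-kernel model with an explanatory note rather than failing.
* Ties and degenerate inputs raise typed errors (`SimulationError`,
  `KinshipError`, `RemlError`, `GeneTestError`, `SelectionError`,
  `WorkflowError`) at the offending stage; the experiment runner isolates
  cell failures so one bad cell cannot abort a grid.

## Known limitations

* Founder linkage equilibrium understates LD-tagging of rare variants by
  the common panel relative to real cattle, so absolute reliabilities are
  not comparable with field results; strategy *contrasts* are.
* DRP records are unweighted in REML; weighting residuals by DRP
  reliability is a configuration extension, not implemented.
* The pedigree A assumes non-inbred, unrelated founders (no metafounders,
  no inbreeding accumulation beyond the recorded two generations).
* The kernel test uses equal variant weights and no burden component;
  rho-blending (SKAT-O-style) is out of scope.
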