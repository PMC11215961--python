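# Methods

## Problem

A gene's expression level is often driven by a small number of regulatory
variants inside its cis-window, yet single-variant association testing is
confounded by linkage disequilibrium (LD): a non-causal SNP correlated with
the true regulatory variant can carry the strongest marginal signal, and
joint effects of several causal SNPs are invisible to one-at-a-time tests.
`cisfine` treats causal cis-eQTL detection as a best-subset regression
problem over the gene's cis genotype matrix and benchmarks that selector
against the standard penalized-regression and single-variant alternatives
under simulated genetic architectures with controlled heritability.

## The selection model

For one gene with expression vector `y` (n samples) and cis dosage matrix
`X` (n × p, ALT-allele counts), the selector minimizes

    J(β) = ½‖y − Xβ‖² + λ₀‖β‖₀ + λ₁‖β‖₁

The L0 term charges a fixed price per active SNP, which is what actually
enforces a small causal set in high LD (the L1 term alone shrinks but
spreads weight over correlated SNPs); the L1 term keeps the fit stable and
the fitted expression close to the observed transcriptome. Columns of `X`
are centered and scaled to unit sum of squares and `y` is centered before
optimization, making the coordinate update closed-form exact and the
penalties comparable across SNPs; coefficients are reported on both scales
and the support is scale-invariant.

### Optimization

* **Cyclic coordinate descent.** For coordinate j with partial-residual
  correlation ρ_j, the exact scalar minimizer is soft-thresholding at λ₁
  followed by a hard L0 gate: keep t = sign(ρ)·max(|ρ|−λ₁, 0) iff
  |t| ≥ √(2λ₀). Sweeps run on the Gram matrix with an incrementally
  maintained correlation vector (O(p) per coordinate) and are compiled with
  numba.
* **Local swap search.** Coordinate descent can park in a poor local
  minimum when columns are highly correlated (pick the decoy, never see the
  truth). After CD converges, every (remove active j, admit inactive k)
  exchange is scored in closed form; the best strictly-improving swap is
  applied and CD resumes. The loop ends when no improving single swap
  exists, so solutions are coordinate-wise and swap-optimal, and the
  objective is non-increasing across every accepted step (asserted per
  iteration in the tests).
* **Convergence.** Relative objective change below `tol` (default 1e-7) per
  sweep, capped at 1000 sweeps and 100 swap rounds; `tol = 0` switches to an
  exact floating-point fixed-point criterion, used by the tests that compare
  against closed-form optima. Non-convergence is reported in the result,
  never raised.

### Penalty selection

A warm-started two-dimensional path (λ₁ outer, λ₀ inner, both descending)
feeds K-fold cross-validation (default 5 folds, seeded). Grids default to 50
log-spaced λ₁ values spanning four decades down from λ₁max = max_j |x_jᵀy|
(the smallest L1 penalty with an empty model) and 20 log-spaced λ₀ values
down from ½λ₁max², plus λ₀ = 0. The grid point with minimal CV mean squared
prediction error is refit on the full data; exact CV ties break toward the
sparser model (larger λ₀, then larger λ₁). The benchmark harness uses a
20 × (10+1) grid — selections are indistinguishable in practice and the
sweep over hundreds of genes stays cheap; `select_by_cv` keeps the fuller
default for single-gene use.

Minimum-CV selection occasionally admits one or two spurious variants under
weak signal; the optional stability ensemble (subsample without replacement,
re-select, keep variants chosen in ≥ `freq_threshold` of draws) tightens
this at extra cost. It is off by default (`n_boot = 1`, reducing exactly to
a single CV selection).

## Simulation framework

Each simulated gene gets an independent cis panel: per-variant target MAFs
drawn uniform(0.05, 0.5); haplotypes generated from a latent first-order
autoregressive Gaussian along the variant axis (parameter `ld_rho`, default
0.3 in the benchmarks) thresholded at the MAF quantile; dosage = sum of two
haplotypes. This is the simplest generator with a single interpretable LD
knob; it produces monotone-decaying local LD but none of the block
structure, allele-frequency/LD coupling, or population stratification of
real panels — conclusions about those features require substituting a real
panel through `genotype_io`.

Four architectures map the causal genotypes to a genetic value g:

| architecture | g_i | effect size |
|---|---|---|
| additive | Σ_j β_j x_ij | β_j iid N(0, 1) |
| heterogeneous | θ·1[carrier at SNP1 **or** SNP2] | θ = 1 |
| recessive | θ·1[carrier at SNP1 **and** SNP2] | θ = 1 |
| compensatory | θ·1[carrier at exactly one SNP] | θ = 1 |

"Carrier" means dosage ≥ 1 by default; a homozygote-only reading
(dosage ≥ 2) is available via `carrier_threshold=2` since the verbal
definitions of such logic models are genuinely ambiguous. The three logic
architectures require exactly two causal SNPs; a causal pattern with zero
variance (e.g. no joint carriers under the recessive rule) is redrawn, up
to 100 times, before the gene is abandoned.

Noise is calibrated exactly in-sample: σe² = Var(g)·(1−h²)/h² with Var the
population (1/n) variance, then y = g + e, e ~ N(0, σe²). Using the 1/n
variance makes Var(g)/(Var(g)+σe²) equal h² identically per gene rather
than only in expectation; the realized Var(g)/Var(y) still fluctuates
through the noise draw, and its mean over genes recovers h² to ±0.02 at
1000 genes (checked for every architecture and h² ∈ {0.02, 0.05, 0.1,
0.5}). A gene with zero causal SNPs is a pure-noise null with σe² = 1 by
convention, since the calibration ratio is undefined at Var(g) = 0.

All randomness flows through per-gene `SeedSequence` streams keyed by
(seed, gene index), so enlarging a dataset never perturbs earlier genes.

## Baseline selectors

All selectors consume the same per-gene inputs and emit one schema.

* **LASSO / Elastic Net** (scikit-learn `LassoCV` / `ElasticNetCV`,
  mixing 0.5): nonzero coefficients at the CV-minimizing penalty, on
  z-scored genotypes.
* **Thresholded Ridge**: ridge keeps every weight nonzero, so selection
  uses |coef| ≥ 0.6 on z-scored genotypes with expression on its original
  scale. The threshold scale matters: the simulations draw additive effects
  from N(0,1) on the expression scale, so a 0.6 cut bites exactly when
  signal is strong enough to resist ridge shrinkage, giving the
  characteristic near-zero selection at h² = 0.02 that grows with h².
  Fully standardizing y would pin all ridge coefficients below ~√h² and
  make the selector permanently empty. The L2 penalty is chosen by
  efficient leave-one-out CV.
* **Marginal association with Bonferroni control**: per-SNP simple linear
  regression, two-sided t-test, selected iff p < 0.05/m (strict), m = cis
  SNP count. Zero-variance SNPs get p = 1. Per-gene family-wise error under
  the global null is ≤ 0.05 (Bonferroni is conservative under LD).

External selectors (fine-mapping tools, single-variant pipelines) join the
benchmark through a generic selections TSV (gene_id, variant_id).

## Evaluation

Per gene: tp/fp/fn of the selected set against the true causal set, then
precision, recall and F1 = 2PR/(P+R). Empty selection or empty truth scores
0 for the undefined ratio — an all-zero model is penalized, not skipped.
Per benchmark cell the per-gene F1 is macro-averaged across genes (a pooled
micro-F1 column is also emitted), together with the total selected-SNP
count per method, which exposes the parsimony difference between the L0+L1
selector and the convex baselines. Pairwise similarity of two eQTL sets
(e.g. two tissues) is the Dice coefficient 2|A∩B|/(|A|+|B|), identical to
F1 with either set as truth; both-empty pairs score 0.

## Allele-effect ANOVA

For a selected (variant, gene) pair, samples are grouped by rounded dosage
(round-half-even; classes with fewer than 3 samples dropped, configurable)
and a classical one-way F-test compares mean expression across surviving
classes (scipy under the hood; degenerate inputs follow fixed conventions —
identical group means give F = 0, p = 1; zero within-group variance with
distinct means gives p = 0). No multiple-testing correction is applied in
this module. Fewer than two surviving classes marks the pair untestable
rather than producing a p-value.

## Genotype and expression I/O

PLINK 1.9 bed/bim/fam is read and written directly (the 2-bit SNP-major
packing, A1 = ALT so dosages count ALT alleles); VCF goes through cyvcf2
with DS preferred over GT and multiallelic records skipped with a count.
Missing calls are imputed to the per-variant mean dosage, the standard
choice for dense penalized-regression pipelines. Monomorphic variants are
always removed; the default MAF filter of 0.01 can be set to 0 to disable
frequency filtering. Cis-windows are closed intervals of ±1 Mb (default)
around the TSS on the same chromosome, 1-based coordinates throughout.

## Problem sizes used in the shipped checks

The automated checks run at desk scale, chosen to exercise each claim with
tight Monte-Carlo error: solver-vs-oracle on 200 instances (n = 30, p ≤ 8;
exhaustive support enumeration bounds p), LASSO-limit on 50 instances,
calibration on 1000 genes per architecture × h², parameter recovery on 100
genes (n = 500, p = 50, h² = 0.5), heritability trend on 300 genes
(n = 670, p = 50, h² ∈ {0.02, 0.1}), marginal type-I control on 10,000 null
genes (m = 20), ANOVA on 100 random groupings and 10,000 null pairs.

## Known limitations

* No covariates, PEER/expression factors, population structure,
  relatedness or trans effects anywhere in the simulation or the models.
* Min-CV penalty selection is not a formal error-control procedure; under
  pure noise it keeps the empty model in roughly three quarters of genes
  rather than always.
* The genotype generator's AR(1) LD is a caricature of real haplotype
  structure; benchmark rankings transfer to real panels only insofar as
  local LD decay is the dominant confounder.
* The logic (non-additive) architectures are fit by linear selectors, as
  intended by the benchmark design: F1 there measures robustness to model
  misspecification, not correctness of the linear model.
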