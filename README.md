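# cisfine

Sparse **L0+L1 penalized regression for cis-eQTL causal-variant
selection**, with a simulation benchmark that compares it against the
standard alternatives (LASSO, Elastic Net, thresholded Ridge,
single-variant association with Bonferroni control).

## Why

Most expression quantitative trait loci (eQTL) are mapped one SNP at a
time. In a cis-window dense with linkage disequilibrium (LD) that approach
(i) lets a non-causal SNP in LD with the true regulatory variant carry the
strongest signal, (ii) misses joint effects of several causal SNPs, and
(iii) favors common variants. `cisfine` instead selects the causal set
jointly per gene by minimizing

```
J(β) = ½ ‖y − Xβ‖² + λ₀‖β‖₀ + λ₁‖β‖₁
```

where `X` is the gene's cis dosage matrix (ALT-allele counts, columns
standardized), `y` the expression vector, `‖β‖₀` the number of active SNPs
and `‖β‖₁` the usual shrinkage term. The non-convex objective is solved by
cyclic coordinate descent with an exact combined thresholding update,
refined by a local swap search (exchange one active SNP for one inactive
one whenever that strictly lowers `J`), with penalties chosen by
cross-validation over a warm-started two-dimensional path. The L0 term is
what produces genuinely small causal sets in high LD; the L1 term keeps
predicted expression aligned with the transcriptome. See
`docs/methods.md` for the full model, the four simulated genetic
architectures (additive, heterogeneous, recessive, compensatory) with
exact heritability calibration, and the design choices.

Audience: statistical geneticists and method developers who want a
reproducible causal-eQTL benchmark, or a per-gene best-subset selector for
real PLINK/VCF panels.

## Worked example

Simulate one gene (670 samples, 50 cis SNPs with AR(1)-style LD, two
causal variants, heritability 0.1) and compare the L0+L1 selection with
LASSO:

```python
import numpy as np
from cisfine import (SimConfig, simulate_genotype_panel, simulate_expression,
                     CisRegion, select_by_cv, fit_lasso_select,
                     confusion_counts, f1_score)

panel = simulate_genotype_panel(n_samples=670, n_variants=50, ld_rho=0.3, seed=7)
region = CisRegion("GENE1", "1", tss=1_025_000, window_bp=1_000_000,
                   variant_indices=np.arange(50))
gene = simulate_expression(panel, region,
                           SimConfig(architecture="additive", n_causal=2, h2=0.1),
                           seed=7)
print("true causal SNPs:", sorted(gene.causal_set),
      "effects:", np.round(gene.coefficients, 3))

fit = select_by_cv(panel.dosages, gene.expression, seed=0)
print("L0+L1 selected:  ", fit.support.tolist(),
      "penalty: (%.3g, %.3g)" % (fit.penalty.lambda0, fit.penalty.lambda1))

lasso = fit_lasso_select(panel.dosages, gene.expression, seed=0)
print("LASSO selected:  ", sorted(lasso.selected))

ev = f1_score(*confusion_counts(fit.support, gene.causal_set))
print(f"L0+L1  precision={ev.precision:.2f} recall={ev.recall:.2f} F1={ev.f1:.2f}")
ev = f1_score(*confusion_counts(lasso.selected, gene.causal_set))
print(f"LASSO  precision={ev.precision:.2f} recall={ev.recall:.2f} F1={ev.f1:.2f}")
```

Output:

```
true causal SNPs: [31, 46] effects: [-0.274 -0.891]
L0+L1 selected:   [31, 46] penalty: (3.54, 0.442)
LASSO selected:   [2, 15, 28, 31, 35, 41, 44, 46, 48, 49]
L0+L1  precision=1.00 recall=1.00 F1=1.00
LASSO  precision=0.20 recall=1.00 F1=0.33
```

Both methods recover the causal pair, but CV-tuned LASSO drags in eight LD
partners; the per-SNP L0 price removes them. Benchmarked over hundreds of
genes (`cisfine.benchmark_grid` or the `cisfine benchmark` command), that
difference is systematic: at h² = 0.1 the L0+L1 selector's mean F1 is
roughly 0.77 against 0.51 for LASSO and 0.41 for Elastic Net, while
selecting about a third fewer SNPs in total.

## Command line

```bash
cisfine simulate  --n-genes 50 --n-samples 300 --h2 0.1 --seed 1 --out-prefix sim/run1
cisfine fit       --genotypes sim/run1 --expression sim/run1.expression.tsv \
                  --gene-map sim/run1.genes.tsv --out selections.tsv
cisfine benchmark --methods l0l1,lasso,ridge --h2 0.02,0.1 --n-genes 100 --out bench.tsv
cisfine anova     --genotypes sim/run1 --expression sim/run1.expression.tsv \
                  --selections selections.tsv --out anova.tsv
cisfine compare-sets --selections tissueA.tsv --selections tissueB.tsv --out dice.tsv
```

Genotypes may be a PLINK 1.9 prefix or a VCF. All commands are
deterministic given `--seed`, accept a flat TOML `--config`, and write TSVs
with a version/config-hash header.

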