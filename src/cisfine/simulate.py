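"""Simulation of LD-structured genotype panels and gene expression.

Expression is generated under four genetic architectures:

* ``additive`` — y is a weighted sum of causal dosages, weights drawn from a
  standard normal.
* ``heterogeneous`` — a shift of size theta for carriers of the alternative
  allele at either of two causal SNPs (logical OR).
* ``recessive`` — a shift only when both causal SNPs carry the alternative
  allele (logical AND).
* ``compensatory`` — a shift when exactly one of the two causal SNPs carries
  the alternative allele (logical XOR).

For every architecture the environmental noise variance is calibrated so the
in-sample heritability Var(g) / (Var(g) + sigma_e^2) equals a preset h^2:
sigma_e^2 = Var(g) * (1 - h2) / h2, with Var the population (1/n) variance.

Genotypes come from a latent AR(1) Gaussian copula over haplotypes: each
haplotype is a thresholded first-order autoregressive Gaussian along the
variant axis, so a single parameter ``ld_rho`` tunes local allelic
correlation; a sample's dosage is the sum of its two haplotypes. Real panels
can be substituted through :mod:`cisfine.genotype_io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import CisRegion, GenotypePanel

logger = logging.getLogger(__name__)

ARCHITECTURES = ("additive", "heterogeneous", "recessive", "compensatory")
LOGIC_ARCHITECTURES = ("heterogeneous", "recessive", "compensatory")


class DegenerateGeneError(ValueError):
    """The genetic component has zero variance (no informative carriers)."""


class GeneSkipped(ValueError):
    """A gene cannot be simulated under the requested configuration."""


@dataclass
class SimConfig:
    """Configuration for simulating one gene's expression.

    carrier_threshold: dosage at which a SNP counts as "carrying" the
    alternative allele in the logic architectures (1 = any alt allele,
    2 = homozygous-only reading).
    on_degenerate: what to do when the drawn causal pattern has zero
    variance — "redraw" a new causal set, or "error".
    """

    architecture: str = "additive"
    n_causal: int = 2
    h2: float = 0.1
    effect_mode: str = "gaussian"
    theta: float = 1.0
    carrier_threshold: int = 1
    on_degenerate: str = "redraw"
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture in LOGIC_ARCHITECTURES and self.n_causal != 2:
            raise ValueError(f"{self.architecture} architecture requires n_causal=2")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if self.effect_mode not in ("gaussian", "fixed"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if self.carrier_threshold not in (1, 2):
            raise ValueError("carrier_threshold must be 1 or 2")
        if self.on_degenerate not in ("redraw", "error"):
            raise ValueError("on_degenerate must be 'redraw' or 'error'")
        if self.n_causal < 0:
            raise ValueError("n_causal must be nonnegative")


@dataclass
class SimulatedGene:
    """One simulated gene with its full ground truth."""

    gene_id: str
    region: CisRegion
    architecture: str
    h2: float
    causal_indices: np.ndarray
    coefficients: np.ndarray
    genetic_values: np.ndarray
    sigma_g2: float
    sigma_e2: float
    expression: np.ndarray

    @property
    def causal_set(self) -> frozenset[int]:
        return frozenset(int(j) for j in self.causal_indices)


def simulate_genotype_panel(
    n_samples: int,
    n_variants: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_rho: float = 0.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing_bp: int = 1_000,
    id_prefix: str = "var",
) -> GenotypePanel:
    """Simulate a dosage panel with AR(1)-style local LD.

    Per-variant target MAFs are drawn uniform(maf_low, maf_high). Each of a
    sample's two haplotypes is a latent AR(1) Gaussian (parameter ``ld_rho``)
    thresholded at the MAF quantile, so adjacent-variant allelic correlation
    rises monotonically with ``ld_rho``.
    """
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    if n_samples < 1 or n_variants < 1:
        raise ValueError("n_samples and n_variants must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, size=n_variants)
    n_hap = 2 * n_samples
    z = np.empty((n_hap, n_variants))
    z[:, 0] = rng.standard_normal(n_hap)
    if n_variants > 1:
        innov = rng.standard_normal((n_hap, n_variants - 1))
        scale = np.sqrt(1.0 - ld_rho**2)
        for m in range(1, n_variants):
            z[:, m] = ld_rho * z[:, m - 1] + scale * innov[:, m - 1]
    alleles = (z < stats.norm.ppf(mafs)).astype(np.float64)
    dosages = alleles.reshape(n_samples, 2, n_variants).sum(axis=1)
    variants = pd.DataFrame(
        {
            "variant_id": [f"{id_prefix}{i}" for i in range(n_variants)],
            "chrom": str(chrom),
            "pos": start_pos + spacing_bp * np.arange(n_variants),
            "ref": "A",
            "alt": "G",
        }
    )
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    return GenotypePanel(dosages, sample_ids, variants)


def draw_causal_set(
    region: CisRegion | int,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``k`` distinct causal variant indices uniformly without replacement.

    ``region`` may be a :class:`CisRegion` (indices drawn from its variant
    list) or an integer variant count (indices drawn from range(p)).
    """
    if isinstance(region, CisRegion):
        pool = np.asarray(region.variant_indices, dtype=int)
    else:
        pool = np.arange(int(region))
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k > pool.size:
        raise GeneSkipped(f"requested {k} causal SNPs from {pool.size} variants")
    if k == 0:
        return np.empty(0, dtype=int)
    return np.sort(rng.choice(pool, size=k, replace=False))


def genetic_values(
    dosages: np.ndarray,
    causal_indices: np.ndarray,
    architecture: str,
    coefficients: np.ndarray | None = None,
    theta: float = 1.0,
    carrier_threshold: int = 1,
) -> np.ndarray:
    """Per-sample genetic component g under a given architecture.

    additive: g = X_causal @ coefficients. Logic architectures use carrier
    indicators (dosage >= carrier_threshold) at two causal SNPs combined by
    OR (heterogeneous), AND (recessive) or XOR (compensatory), scaled by
    ``theta``.
    """
    causal_indices = np.asarray(causal_indices, dtype=int)
    if architecture == "additive":
        if coefficients is None:
            raise ValueError("additive architecture requires coefficients")
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.shape != (causal_indices.size,):
            raise ValueError("one coefficient per causal SNP required")
        if causal_indices.size == 0:
            return np.zeros(dosages.shape[0])
        return dosages[:, causal_indices] @ coefficients
    if architecture not in LOGIC_ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if causal_indices.size != 2:
        raise ValueError(f"{architecture} architecture requires exactly 2 causal SNPs")
    a, b = (dosages[:, j] >= carrier_threshold for j in causal_indices)
    if architecture == "heterogeneous":
        pattern = a | b
    elif architecture == "recessive":
        pattern = a & b
    else:  # compensatory
        pattern = a ^ b
    return theta * pattern.astype(np.float64)


def calibrate_environmental_variance(g: np.ndarray, h2: float) -> float:
    """Noise variance making the in-sample heritability exactly ``h2``.

    Uses the population (1/n) variance of g, so sigma_e2 = Var(g)*(1-h2)/h2.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    var_g = float(np.var(np.asarray(g, dtype=float)))
    if var_g == 0.0:
        raise DegenerateGeneError("genetic component has zero variance")
    return var_g * (1.0 - h2) / h2


def simulate_expression(
    panel: GenotypePanel,
    region: CisRegion,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    gene_id: str | None = None,
) -> SimulatedGene:
    """Simulate one gene's expression: y = g + e with e ~ N(0, sigma_e2).

    A causal set whose genetic pattern has zero variance (e.g. no recessive
    carriers) is redrawn up to ``config.max_redraws`` times when
    ``config.on_degenerate == "redraw"``; a k=0 configuration produces a
    pure-noise null gene with unit noise variance.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gene_id = gene_id if gene_id is not None else region.gene_id
    k = config.n_causal
    n = panel.n_samples
    attempts = config.max_redraws if config.on_degenerate == "redraw" else 1
    last_err: Exception | None = None
    for _ in range(max(1, attempts)):
        causal = draw_causal_set(region, k, rng)
        if config.architecture == "additive":
            if config.effect_mode == "gaussian":
                coefficients = rng.standard_normal(k)
            else:
                coefficients = np.full(k, config.theta)
        else:
            coefficients = np.full(k, config.theta)
        g = genetic_values(
            panel.dosages,
            causal,
            config.architecture,
            coefficients=coefficients if config.architecture == "additive" else None,
            theta=config.theta,
            carrier_threshold=config.carrier_threshold,
        )
        if k == 0:
            sigma_g2, sigma_e2 = 0.0, 1.0
        else:
            try:
                sigma_e2 = calibrate_environmental_variance(g, config.h2)
            except DegenerateGeneError as err:
                last_err = err
                continue
            sigma_g2 = float(np.var(g))
        e = rng.normal(0.0, np.sqrt(sigma_e2), size=n) if sigma_e2 > 0 else np.zeros(n)
        return SimulatedGene(
            gene_id=gene_id,
            region=region,
            architecture=config.architecture,
            h2=config.h2,
            causal_indices=causal,
            coefficients=coefficients,
            genetic_values=g,
            sigma_g2=sigma_g2,
            sigma_e2=float(sigma_e2),
            expression=g + e,
        )
    raise DegenerateGeneError(
        f"gene {gene_id}: no non-degenerate causal set in {attempts} draws"
    ) from last_err


def gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    """Independent per-gene stream: adding genes never perturbs earlier genes."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gene_index,)))


def simulate_gene_dataset(
    n_genes: int,
    config: SimConfig,
    n_samples: int = 670,
    n_variants: int = 50,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_rho: float = 0.3,
    seed: int = 0,
):
    """Yield (panel, SimulatedGene) pairs, one independent cis panel per gene."""
    for i in range(n_genes):
        rng = gene_rng(seed, i)
        panel = simulate_genotype_panel(
            n_samples,
            n_variants,
            maf_low=maf_low,
            maf_high=maf_high,
            ld_rho=ld_rho,
            rng=rng,
            chrom=str(i + 1),
            id_prefix=f"g{i}v",
        )
        region = CisRegion(
            gene_id=f"gene{i}",
            chrom=str(i + 1),
            tss=int(panel.variants["pos"].iloc[n_variants // 2]),
            window_bp=1_000_000,
            variant_indices=np.arange(n_variants),
        )
        yield panel, simulate_expression(panel, region, config, rng=rng)
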