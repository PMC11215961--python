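"""Scoring of variant selections against simulation truth.

Per-gene selections are scored by precision, recall and F1 over the true
causal set; the benchmark harness sweeps genetic architectures, causal-set
sizes and heritabilities, averaging per-gene F1 (macro) across simulated
genes for each selector. Pairwise similarity of two eQTL sets uses the Dice
coefficient, which is exactly the F1 obtained when either set is treated as
the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from . import comparators
from .simulate import (
    DegenerateGeneError,
    SimConfig,
    simulate_expression,
    simulate_genotype_panel,
    gene_rng,
)
from .genotype_io import CisRegion

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Confusion counts and derived scores for one selection vs truth."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def confusion_counts(selected: Iterable, truth: Iterable) -> tuple[int, int, int]:
    """(tp, fp, fn) between a selected set and the true causal set."""
    selected, truth = set(selected), set(truth)
    return (
        len(selected & truth),
        len(selected - truth),
        len(truth - selected),
    )


def f1_score(tp: int, fp: int, fn: int) -> EvalResult:
    """Precision, recall and their harmonic mean; degenerate cases score 0.

    An empty selection (tp+fp = 0) or empty truth (tp+fn = 0) yields 0 for
    the undefined ratio, so a model that selects nothing is penalized rather
    than skipped.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


def set_similarity_f1(set_a: Iterable, set_b: Iterable) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def pairwise_similarity(sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Symmetric Dice similarity matrix across named eQTL sets."""
    names = list(sets)
    mat = np.ones((len(names), len(names)))
    frozen = {k: set(v) for k, v in sets.items()}
    for i, a in enumerate(names):
        for j, b in enumerate(names[: i + 1]):
            mat[i, j] = mat[j, i] = set_similarity_f1(frozen[a], frozen[b])
    return pd.DataFrame(mat, index=names, columns=names)


# --------------------------------------------------------------------------
# benchmark harness
# --------------------------------------------------------------------------

Selector = Callable[..., comparators.SelectionResult]


def _oracle_method(X, y, *, seed, gene_id, truth):
    return comparators.SelectionResult(
        gene_id=gene_id,
        method="oracle",
        selected=frozenset(truth),
        scores=np.zeros(X.shape[1]),
        threshold_used=0.0,
    )


def _none_method(X, y, *, seed, gene_id, truth):
    return comparators.SelectionResult(
        gene_id=gene_id,
        method="none",
        selected=frozenset(),
        scores=np.zeros(X.shape[1]),
        threshold_used=0.0,
    )


def _make_registry(l0l1_options: dict | None = None) -> dict[str, Selector]:
    """Method name -> callable(X, y, *, seed, gene_id, truth) -> SelectionResult.

    The harness fits the L0+L1 CV on a 20 x (10+1) penalty grid by default —
    a problem size that keeps multi-hundred-gene sweeps cheap without moving
    selections appreciably versus the solver's fuller default grid.
    """
    opts = {"n_lambda1": 20, "n_lambda0": 10}
    opts.update(l0l1_options or {})
    return {
        "l0l1": lambda X, y, *, seed, gene_id, truth: comparators.fit_l0l1_select(
            X, y, seed=seed, gene_id=gene_id, **opts
        ),
        "lasso": lambda X, y, *, seed, gene_id, truth: comparators.fit_lasso_select(
            X, y, seed=seed, gene_id=gene_id
        ),
        "elasticnet": lambda X, y, *, seed, gene_id, truth: comparators.fit_elastic_net_select(
            X, y, seed=seed, gene_id=gene_id
        ),
        "ridge": lambda X, y, *, seed, gene_id, truth: comparators.fit_ridge_select(
            X, y, seed=seed, gene_id=gene_id
        ),
        "marginal": lambda X, y, *, seed, gene_id, truth: comparators.marginal_association_select(
            X, y, gene_id=gene_id
        ),
        "oracle": _oracle_method,
        "none": _none_method,
    }


def benchmark_grid(
    architectures: Iterable[str],
    n_causal_list: Iterable[int],
    h2_list: Iterable[float],
    methods: Iterable[str] | Mapping[str, Selector],
    n_genes: int,
    seed: int = 0,
    n_samples: int = 670,
    n_variants: int = 50,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_rho: float = 0.3,
    panel_source: Callable[[np.random.Generator], object] | None = None,
    l0l1_options: dict | None = None,
    effect_mode: str = "gaussian",
) -> pd.DataFrame:
    """Mean per-gene F1 per (architecture, n_causal, h2, method) cell.

    Every gene gets an independent simulated cis panel (or one produced by
    ``panel_source(rng)``), a fresh causal draw and expression; each selector
    then runs on identical inputs. Output is a tidy frame with macro-averaged
    precision/recall/F1, pooled (micro) F1, and the total selected-SNP count
    per method. Deterministic given ``seed``.
    """
    registry = _make_registry(l0l1_options)
    if isinstance(methods, Mapping):
        selectors = dict(methods)
    else:
        unknown = set(methods) - set(registry)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        selectors = {m: registry[m] for m in methods}
    rows = []
    cell_index = 0
    for arch in architectures:
        for k in n_causal_list:
            for h2 in h2_list:
                config = SimConfig(
                    architecture=arch, n_causal=k, h2=h2, effect_mode=effect_mode
                )
                per_method: dict[str, dict] = {
                    m: {"f1": [], "prec": [], "rec": [], "sel": 0, "tp": 0, "fp": 0, "fn": 0, "failed": 0}
                    for m in selectors
                }
                for i in range(n_genes):
                    rng = gene_rng(seed, cell_index * n_genes + i)
                    if panel_source is not None:
                        panel = panel_source(rng)
                    else:
                        panel = simulate_genotype_panel(
                            n_samples,
                            n_variants,
                            maf_low=maf_low,
                            maf_high=maf_high,
                            ld_rho=ld_rho,
                            rng=rng,
                        )
                    region = CisRegion(
                        gene_id=f"{arch}_{k}_{h2}_g{i}",
                        chrom="1",
                        tss=int(panel.variants["pos"].iloc[panel.n_variants // 2]),
                        window_bp=1_000_000,
                        variant_indices=np.arange(panel.n_variants),
                    )
                    try:
                        gene = simulate_expression(panel, region, config, rng=rng)
                    except DegenerateGeneError as err:
                        logger.warning("skipping gene %s: %s", region.gene_id, err)
                        continue
                    truth = gene.causal_set
                    method_seed = int(rng.integers(0, 2**31 - 1))
                    for name, selector in selectors.items():
                        try:
                            sel = selector(
                                panel.dosages,
                                gene.expression,
                                seed=method_seed,
                                gene_id=gene.gene_id,
                                truth=truth,
                            )
                        except Exception as err:  # a method failing one gene
                            logger.warning(
                                "method %s failed on gene %s: %s", name, gene.gene_id, err
                            )
                            per_method[name]["failed"] += 1
                            continue
                        tp, fp, fn = confusion_counts(sel.selected, truth)
                        ev = f1_score(tp, fp, fn)
                        acc = per_method[name]
                        acc["f1"].append(ev.f1)
                        acc["prec"].append(ev.precision)
                        acc["rec"].append(ev.recall)
                        acc["sel"] += len(sel.selected)
                        acc["tp"] += tp
                        acc["fp"] += fp
                        acc["fn"] += fn
                for name, acc in per_method.items():
                    pooled = f1_score(acc["tp"], acc["fp"], acc["fn"])
                    rows.append(
                        {
                            "architecture": arch,
                            "n_causal": k,
                            "h2": h2,
                            "method": name,
                            "mean_f1": float(np.mean(acc["f1"])) if acc["f1"] else 0.0,
                            "mean_precision": float(np.mean(acc["prec"])) if acc["prec"] else 0.0,
                            "mean_recall": float(np.mean(acc["rec"])) if acc["rec"] else 0.0,
                            "pooled_f1": pooled.f1,
                            "total_selected": acc["sel"],
                            "n_genes": len(acc["f1"]),
                            "n_failed": acc["failed"],
                        }
                    )
                cell_index += 1
    return pd.DataFrame(rows)
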