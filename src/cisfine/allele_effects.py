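"""Genotype-class effects on expression via one-way ANOVA.

For each (variant, gene) pair, samples are grouped by rounded dosage
(0/1/2 = hom-ref / het / hom-alt) and the classical F-test compares mean
expression across the surviving classes. No multiple-testing correction is
applied here; downstream filtering is the caller's choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class UntestableVariant(ValueError):
    """Fewer than two genotype classes with enough samples."""


@dataclass
class AnovaResult:
    gene_id: str
    variant_id: str
    group_sizes: dict[int, int]
    group_means: dict[int, float]
    f_stat: float
    p_value: float


def genotype_classes(dosages: np.ndarray, min_n: int = 3) -> dict[int, np.ndarray]:
    """Partition samples by rounded dosage into classes {0, 1, 2}.

    Rounding is round-half-even (numpy's rint), so a dosage of 1.5 joins
    class 2 and 0.5 joins class 0. Classes with fewer than ``min_n`` samples
    are dropped with a log message; fewer than two surviving classes raises
    :class:`UntestableVariant`.
    """
    cls = np.clip(np.rint(np.asarray(dosages, dtype=float)), 0, 2).astype(int)
    groups: dict[int, np.ndarray] = {}
    for g in (0, 1, 2):
        idx = np.flatnonzero(cls == g)
        if idx.size == 0:
            continue
        if idx.size < min_n:
            logger.info("dropping genotype class %d with %d < %d samples", g, idx.size, min_n)
            continue
        groups[g] = idx
    if len(groups) < 2:
        raise UntestableVariant(f"only {len(groups)} genotype class(es) with >= {min_n} samples")
    return groups


def one_way_anova(
    expression: np.ndarray,
    grouping: dict[int, np.ndarray],
    gene_id: str = "",
    variant_id: str = "",
) -> AnovaResult:
    """Classical one-way ANOVA of expression across genotype classes.

    F = (between-group SS / (k-1)) / (within-group SS / (n-k)) with the p
    from an F(k-1, n-k) distribution. Degenerate cases follow fixed
    conventions: all values identical -> F = 0, p = 1; zero within-group
    variance with distinct group means -> F = inf, p = 0.
    """
    expression = np.asarray(expression, dtype=float)
    samples = [expression[idx] for idx in grouping.values()]
    if len(samples) < 2:
        raise UntestableVariant("need at least two genotype classes")
    if any(len(s) < 2 for s in samples):
        raise UntestableVariant("each genotype class needs at least two samples")
    sizes = {g: int(len(idx)) for g, idx in grouping.items()}
    means = {g: float(expression[idx].mean()) for g, idx in grouping.items()}
    n = sum(sizes.values())
    k = len(samples)
    if n <= k:
        raise UntestableVariant("need more samples than groups")
    pooled = np.concatenate(samples)
    within_ss = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    between_ss = sum(len(s) * (s.mean() - pooled.mean()) ** 2 for s in samples)
    if within_ss == 0.0:
        if between_ss == 0.0:
            f_stat, p_value = 0.0, 1.0
        else:
            f_stat, p_value = np.inf, 0.0
    elif between_ss == 0.0:
        f_stat, p_value = 0.0, 1.0
    else:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_value = stats.f_oneway(*samples)
        f_stat, p_value = float(f_stat), float(p_value)
    return AnovaResult(
        gene_id=gene_id,
        variant_id=variant_id,
        group_sizes=sizes,
        group_means=means,
        f_stat=float(f_stat),
        p_value=float(p_value),
    )


def anova_scan(
    panel,
    expression: pd.DataFrame,
    pairs: list[tuple[str, str]],
    min_n: int = 3,
) -> pd.DataFrame:
    """Run one-way ANOVA over (gene_id, variant_id) pairs.

    ``expression`` is a samples x genes frame aligned to ``panel.sample_ids``.
    Untestable pairs appear in the output with testable=False and NaN
    statistics.
    """
    vid_to_col = {v: i for i, v in enumerate(panel.variants["variant_id"])}
    expr = expression.loc[panel.sample_ids]
    rows = []
    for gene_id, variant_id in pairs:
        row = {
            "gene_id": gene_id,
            "variant_id": variant_id,
            "n0": 0,
            "n1": 0,
            "n2": 0,
            "mean0": np.nan,
            "mean1": np.nan,
            "mean2": np.nan,
            "F": np.nan,
            "p": np.nan,
            "testable": False,
        }
        if gene_id not in expr.columns or variant_id not in vid_to_col:
            logger.warning("skipping unknown pair (%s, %s)", gene_id, variant_id)
            rows.append(row)
            continue
        dos = panel.dosages[:, vid_to_col[variant_id]]
        try:
            grouping = genotype_classes(dos, min_n=min_n)
            res = one_way_anova(
                expr[gene_id].to_numpy(), grouping, gene_id=gene_id, variant_id=variant_id
            )
        except UntestableVariant as err:
            logger.info("untestable pair (%s, %s): %s", gene_id, variant_id, err)
            rows.append(row)
            continue
        for g in (0, 1, 2):
            row[f"n{g}"] = res.group_sizes.get(g, 0)
            row[f"mean{g}"] = res.group_means.get(g, np.nan)
        row["F"] = res.f_stat
        row["p"] = res.p_value
        row["testable"] = True
        rows.append(row)
    return pd.DataFrame(rows)
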