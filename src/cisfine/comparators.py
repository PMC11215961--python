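"""Baseline cis-eQTL selectors benchmarked against the L0+L1 model.

Four selectors share one output schema so the evaluation harness is
selector-agnostic: LASSO and Elastic Net (nonzero coefficients at the
CV-minimizing penalty), thresholded Ridge (|coefficient| >= tau on z-scored
genotypes, tau = 0.6 by default), and per-SNP marginal association with a
per-gene Bonferroni threshold (p < alpha / m, strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LassoCV, RidgeCV
from sklearn.model_selection import KFold

from .solver import select_by_cv

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Per-gene selected variant set for one method.

    ``scores`` holds one value per cis variant (|coefficient| for model-based
    selectors, the p-value for marginal association).
    """

    gene_id: str
    method: str
    selected: frozenset[int]
    scores: np.ndarray
    threshold_used: float

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _zscore(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    return (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def fit_lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    gene_id: str = "",
) -> SelectionResult:
    """LASSO at the K-fold CV-minimizing penalty; selected = nonzero coefficients."""
    Xs = _zscore(X)
    yc = np.asarray(y, dtype=float) - np.mean(y)
    model = LassoCV(
        cv=KFold(n_splits=n_folds, shuffle=True, random_state=seed),
        fit_intercept=False,
        alphas=100,
    )
    model.fit(Xs, yc)
    return SelectionResult(
        gene_id=gene_id,
        method="lasso",
        selected=frozenset(np.flatnonzero(model.coef_ != 0.0).tolist()),
        scores=np.abs(model.coef_),
        threshold_used=0.0,
    )


def fit_elastic_net_select(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
    gene_id: str = "",
) -> SelectionResult:
    """Elastic Net (default mixing 0.5) at the CV-minimizing penalty."""
    if not 0.0 < l1_ratio <= 1.0:
        raise ValueError("l1_ratio must lie in (0, 1]")
    Xs = _zscore(X)
    yc = np.asarray(y, dtype=float) - np.mean(y)
    model = ElasticNetCV(
        l1_ratio=l1_ratio,
        cv=KFold(n_splits=n_folds, shuffle=True, random_state=seed),
        fit_intercept=False,
        alphas=100,
    )
    model.fit(Xs, yc)
    return SelectionResult(
        gene_id=gene_id,
        method="elasticnet",
        selected=frozenset(np.flatnonzero(model.coef_ != 0.0).tolist()),
        scores=np.abs(model.coef_),
        threshold_used=0.0,
    )


def threshold_select(coefs: np.ndarray, tau: float) -> frozenset[int]:
    """Indices with |coefficient| >= tau (boundary inclusive)."""
    return frozenset(np.flatnonzero(np.abs(coefs) >= tau).tolist())


def fit_ridge_select(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    tau: float = 0.6,
    gene_id: str = "",
) -> SelectionResult:
    """Ridge with threshold selection: |coef| >= tau on z-scored genotypes.

    Ridge keeps every weight nonzero, so selection needs an explicit cut;
    the default tau of 0.6 applies to coefficients for unit-variance dosage
    columns with expression left on its original scale. The L2 penalty is
    chosen by sklearn's efficient leave-one-out CV (``n_folds`` and ``seed``
    are accepted for interface symmetry but unused).
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    del n_folds, seed
    Xs = _zscore(X)
    yc = np.asarray(y, dtype=float) - np.mean(y)
    model = RidgeCV(alphas=np.logspace(-3, 5, 41), fit_intercept=False)
    model.fit(Xs, yc)
    return SelectionResult(
        gene_id=gene_id,
        method="ridge",
        selected=threshold_select(model.coef_, tau),
        scores=np.abs(model.coef_),
        threshold_used=tau,
    )


def marginal_association_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    gene_id: str = "",
) -> SelectionResult:
    """Single-variant association with per-gene Bonferroni control.

    Each SNP is tested by simple linear regression of expression on its
    dosage (two-sided t-test); SNPs with p < alpha / m are selected, where m
    is the number of cis SNPs. Zero-variance SNPs get p = 1 by convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for a t-test")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    df = n - 2
    pvals = np.ones(m)
    ok = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = np.maximum(syy - sxy[ok] ** 2 / sxx[ok], 0.0)
        se2 = rss / df / sxx[ok]
        tstat = np.where(
            se2 > 0,
            sxy[ok] / sxx[ok] / np.sqrt(np.where(se2 > 0, se2, 1.0)),
            np.where(sxy[ok] != 0, np.inf, 0.0),
        )
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    threshold = alpha / m
    return SelectionResult(
        gene_id=gene_id,
        method="marginal",
        selected=frozenset(np.flatnonzero(pvals < threshold).tolist()),
        scores=pvals,
        threshold_used=threshold,
    )


def fit_l0l1_select(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    gene_id: str = "",
    **cv_kwargs,
) -> SelectionResult:
    """The package's own L0+L1 selector wrapped in the common schema."""
    fit = select_by_cv(X, y, n_folds=n_folds, seed=seed, **cv_kwargs)
    return SelectionResult(
        gene_id=gene_id,
        method="l0l1",
        selected=frozenset(fit.support.tolist()),
        scores=np.abs(fit.beta_std),
        threshold_used=0.0,
    )
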