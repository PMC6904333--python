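"""Expression preprocessing and differential-expression screening.

The DEG screen nominates candidate genes for pairing; it uses Welch's
two-sample t-test on log2 expression (a deliberate, documented
simplification of moderated array statistics — the screen's role here
is candidate nomination only) with plain, unadjusted p-values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import DomainError, ExpressionMatrix

__all__ = ["DEGCriteria", "DEGResult", "log2_transform", "quantile_normalize",
           "select_degs"]


@dataclass(frozen=True)
class DEGCriteria:
    """Selection thresholds: p <= p_threshold and |log2 FC| >= abs_logfc_threshold."""

    p_threshold: float = 0.05
    abs_logfc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise DomainError("p_threshold must be in (0, 1]")
        if self.abs_logfc_threshold < 0:
            raise DomainError("abs_logfc_threshold must be >= 0")


@dataclass
class DEGResult:
    """Per-gene differential-expression statistics plus the selected subset."""

    gene_ids: list[str]
    logfc: np.ndarray        # mean(group A) - mean(group B), log2 scale
    p_value: np.ndarray
    selected: np.ndarray     # boolean mask under the criteria used

    @property
    def direction(self) -> np.ndarray:
        return np.where(self.logfc > 0, "up", "down")

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.selected) if s]


def log2_transform(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Return log2(v + offset) per cell; refuses already-log data."""
    if expr.log_scale:
        raise DomainError("matrix is already on log scale")
    if not offset > 0:
        raise DomainError("offset must be > 0")
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids,
                            np.log2(expr.values + offset),
                            units=f"log2({expr.units}+{offset:g})", log_scale=True)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common reference distribution
    (the row-wise mean of the per-column sorted values), preserving the
    within-column ranks.  Ties within a column receive the mean of the
    reference values at their rank positions.
    """
    if expr.n_samples < 2:
        raise DomainError("quantile normalization needs >= 2 samples")
    v = expr.values
    order = np.argsort(v, axis=0, kind="stable")
    sorted_v = np.take_along_axis(v, order, axis=0)
    reference = sorted_v.mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = np.empty(v.shape[0])
        col[order[:, j]] = reference
        # average reference values over tied input positions
        uniq, inv = np.unique(v[:, j], return_inverse=True)
        if len(uniq) < v.shape[0]:
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[:, j] = col
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, out,
                            units=expr.units, log_scale=expr.log_scale)


def select_degs(expr: ExpressionMatrix, group_labels, criteria: DEGCriteria | None = None
                ) -> DEGResult:
    """Two-group differential-expression screen on log2 data.

    ``group_labels`` is a boolean/0-1 vector per sample; group A is label 1.
    logfc = mean(A) - mean(B); p from Welch's t-test.  Genes with zero
    variance in both groups get p = 1.
    """
    criteria = criteria or DEGCriteria()
    if not expr.log_scale:
        raise DomainError("DEG screen expects log-scale expression")
    labels = np.asarray(group_labels).astype(bool)
    if labels.shape != (expr.n_samples,):
        raise DomainError("group_labels length does not match samples")
    n_a, n_b = int(labels.sum()), int((~labels).sum())
    if n_a < 2 or n_b < 2:
        raise DomainError(f"each group needs >= 2 samples (got {n_a}, {n_b})")
    a, b = expr.values[:, labels], expr.values[:, ~labels]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    selected = (p <= criteria.p_threshold) & (np.abs(logfc) >= criteria.abs_logfc_threshold)
    return DEGResult(list(expr.gene_ids), logfc, p, selected)
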