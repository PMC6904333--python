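"""Time-dependent ROC curves for censored data (nearest-neighbour
estimator) and data-driven cutoff selection.

At a horizon t, case status ("event by t") is only partially observed
under censoring.  The estimator here smooths the conditional survival
S(t | marker) with a symmetric nearest-neighbour window in marker rank
(a 0/1 kernel covering a fraction 2*span of the sample) and derives

    sens(c) = sum_{m_i > c} (1 - S_i) / sum_i (1 - S_i)
    spec(c) = sum_{m_i <= c} S_i / sum_i S_i

so the curve uses only marker ranks and the censoring-adjusted
conditional survival — the AUC is therefore exactly invariant under any
strictly increasing transform of the marker.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import DomainError, SurvivalData

__all__ = ["ROCResult", "td_roc_nne", "optimal_cutoff", "default_span"]


@dataclass
class ROCResult:
    horizon_t: float
    thresholds: np.ndarray   # decreasing; +inf first
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    span: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr,
                             "tpr": self.tpr})


def default_span(n: int) -> float:
    """Conventional NNE smoothing span, 0.25 * n^(-1/5)."""
    return 0.25 * n ** -0.20


def _conditional_survival(marker: np.ndarray, time: np.ndarray, event: np.ndarray,
                          horizon: float, span: float) -> np.ndarray:
    """S(horizon | marker_i) by a nearest-neighbour-weighted Kaplan-Meier."""
    n = len(marker)
    pct = (stats.rankdata(marker) - 0.5) / n
    neighbour = np.abs(pct[:, None] - pct[None, :]) <= span   # n x n, row = centre
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    nb = neighbour[:, order].astype(float)
    # suffix counts: at-risk in each window at every sorted position
    at_risk = np.cumsum(nb[:, ::-1], axis=1)[:, ::-1]
    _, first = np.unique(t_s, return_index=True)
    d = np.add.reduceat(nb * e_s, first, axis=1)      # events per window per time
    n_at = at_risk[:, first]
    utimes = t_s[first]
    use = (utimes <= horizon)
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where((n_at[:, use] > 0),
                           1.0 - d[:, use] / np.maximum(n_at[:, use], 1.0), 1.0)
    s = np.prod(factors, axis=1)
    return np.clip(s, 0.0, 1.0)


def td_roc_nne(marker, surv: SurvivalData, horizon_t: float,
               span: float | None = None) -> ROCResult:
    """Time-dependent ROC at ``horizon_t`` months via the NNE estimator.

    ``span`` is the half-width of the rank window (window fraction is
    2*span); default ``0.25 * n**-0.2``.
    """
    marker = np.asarray(marker, float)
    if marker.shape != (len(surv),):
        raise DomainError("marker length does not match survival data")
    if not np.all(np.isfinite(marker)):
        raise DomainError("marker must be finite")
    n = len(marker)
    if span is None:
        span = default_span(n)
    if not (0 < span < 0.5):
        raise DomainError("span must lie in (0, 0.5)")
    if not (surv.time.min() <= horizon_t <= surv.time.max()):
        raise DomainError("horizon outside the observed time range")
    if not np.any((surv.time <= horizon_t) & (surv.event == 1)):
        raise DomainError(f"no events on or before the horizon {horizon_t}")
    s_i = _conditional_survival(marker, surv.time, surv.event, horizon_t, span)
    case_w = 1.0 - s_i
    ctrl_w = s_i
    if case_w.sum() <= 0 or ctrl_w.sum() <= 0:
        raise DomainError("degenerate conditional survival at the horizon")
    # thresholds: descending unique marker values; prepend +inf for (0, 0)
    uniq = np.unique(marker)[::-1]
    thresholds = np.concatenate(([np.inf], uniq, [-np.inf]))
    # sens uses strict >, so evaluate cumulative weights of markers above c
    order = np.argsort(marker, kind="stable")[::-1]   # descending markers
    m_desc = marker[order]
    cum_case = np.concatenate(([0.0], np.cumsum(case_w[order])))
    cum_ctrl = np.concatenate(([0.0], np.cumsum(ctrl_w[order])))
    counts_above = np.searchsorted(-m_desc, -thresholds, side="left")
    tpr = cum_case[counts_above] / case_w.sum()
    fpr = cum_ctrl[counts_above] / ctrl_w.sum()
    # defensive monotonization before integration
    tpr = np.maximum.accumulate(tpr)
    fpr = np.maximum.accumulate(fpr)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(float(horizon_t), thresholds, tpr, fpr, auc, float(span))


def optimal_cutoff(marker, surv: SurvivalData, horizon_t: float = 60.0,
                   span: float | None = None, criterion: str = "youden") -> float:
    """Marker threshold maximizing Youden's J (tpr - fpr) on the NNE
    curve; ties broken toward the smaller threshold (larger high-risk
    group)."""
    if criterion != "youden":
        raise DomainError(f"unknown cutoff criterion {criterion!r}")
    roc = td_roc_nne(marker, surv, horizon_t, span)
    j = roc.tpr - roc.fpr
    finite = np.isfinite(roc.thresholds)
    j_f, thr_f = j[finite], roc.thresholds[finite]
    if j_f.size == 0:
        raise DomainError("no finite thresholds available")
    best = j_f.max()
    if best <= 1e-12:
        warnings.warn("flat ROC curve: marker is uninformative at this horizon",
                      stacklevel=2)
    # smallest threshold among the maximizers
    candidates = thr_f[np.isclose(j_f, best)]
    return float(candidates.min())
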