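"""Pair screening, risk-score (RPI) computation, stratification and
survival evaluation of risk groups.

The RPI of a sample is sum_k beta_k * s_k over the signature's pairs,
where s_k is 1 iff the first gene's abundance is strictly below the
second's *within that sample*.  Scoring therefore needs nothing but the
sample's own profile: no reference distribution, no normalization, and
the score is identical whichever monotone abundance unit the platform
reports.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (ClinicalTable, DomainError, ExpressionMatrix, RiskScore,
                        SignatureModel, SurvivalData)
from .pairs import PairMatrix
from .survival import (CoxResult, KMCurve, LogRankResult, adjust_fwer, cox_fit,
                       km_estimate, logrank_chi2_many, logrank_test)
from .tdroc import td_roc_nne

__all__ = ["ScreenConfig", "ScreenedPairs", "GroupEvaluation",
           "screen_prognostic_pairs", "score_rpi", "stratify",
           "evaluate_groups", "subgroup_analysis"]


@dataclass(frozen=True)
class ScreenConfig:
    """Pair-screening settings: familywise error level and adjustment."""

    fwer_alpha: float = 0.05
    method: str = "holm"

    def __post_init__(self) -> None:
        if not (0 < self.fwer_alpha < 1):
            raise DomainError("fwer_alpha must be in (0, 1)")
        if self.method not in ("holm", "bonferroni"):
            raise DomainError("method must be holm or bonferroni")


@dataclass
class ScreenedPairs:
    """Screen output: selected pairs ordered by adjusted p ascending."""

    pair_ids: list[tuple[str, str]]
    chi2: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    selected: list[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene1": [a for a, _ in self.pair_ids],
            "gene2": [b for _, b in self.pair_ids],
            "chi2": self.chi2, "p": self.p_raw, "p_fwer": self.p_adjusted,
            "selected": [p in set(self.selected) for p in self.pair_ids]})


def screen_prognostic_pairs(pm: PairMatrix, surv: SurvivalData,
                            config: ScreenConfig | None = None) -> ScreenedPairs:
    """Log-rank screen of every pair indicator against survival.

    Each pair splits the cohort by its 0/1 value; pairs whose
    FWER-adjusted log-rank p falls below ``fwer_alpha`` are selected,
    ordered by adjusted p (ties by raw p, then pair id).
    """
    config = config or ScreenConfig()
    surv = surv.align(pm.sample_ids)
    if surv.n_events == 0:
        raise DomainError("no events: cannot screen pairs")
    constant = pm.values.min(axis=1) == pm.values.max(axis=1)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant pair(s) skipped by the "
                      "screen (run filter_constant_pairs first)", stacklevel=2)
    testable = ~constant
    chi2 = np.zeros(pm.n_pairs)
    p_raw = np.ones(pm.n_pairs)
    if testable.any():
        c, p = logrank_chi2_many(surv.time, surv.event, pm.values[testable])
        chi2[testable], p_raw[testable] = c, p
    p_adj = np.ones(pm.n_pairs)
    p_adj[testable] = adjust_fwer(p_raw[testable], config.method)
    sel_idx = [i for i in range(pm.n_pairs)
               if testable[i] and p_adj[i] < config.fwer_alpha]
    sel_idx.sort(key=lambda i: (p_adj[i], p_raw[i], pm.pair_ids[i]))
    return ScreenedPairs(list(pm.pair_ids), chi2, p_raw, p_adj,
                         [pm.pair_ids[i] for i in sel_idx])


def _indicators_from_profile(profile: Mapping[str, float], model: SignatureModel
                             ) -> np.ndarray:
    missing = sorted({g for p in model.pairs for g in p if g not in profile})
    if missing:
        raise DomainError(f"profile lacks signature genes: {missing}")
    vals = [(profile[a], profile[b]) for a, b in model.pairs]
    arr = np.asarray(vals, float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("non-finite expression for a signature gene")
    return (arr[:, 0] < arr[:, 1]).astype(float)


def score_rpi(data, model: SignatureModel, sample_id: str = "sample") -> RiskScore:
    """Compute the RPI under ``model``.

    ``data`` may be an :class:`ExpressionMatrix` (all samples scored), a
    :class:`PairMatrix` containing the model's pairs in the model's
    stored orientation, or a single-sample mapping ``gene -> value``.
    """
    coeffs = model.coefficients
    if isinstance(data, ExpressionMatrix):
        missing = sorted({g for p in model.pairs for g in p if g not in data})
        if missing:
            raise DomainError(f"expression matrix lacks signature genes: {missing}")
        ind = np.stack([(data.row(a) < data.row(b)).astype(float)
                        for a, b in model.pairs])
        # per-sample 1-d dots so cohort and single-sample scoring agree bitwise
        scores = np.array([np.dot(coeffs, ind[:, j])
                           for j in range(ind.shape[1])])
        return RiskScore(list(data.sample_ids), scores)
    if isinstance(data, PairMatrix):
        try:
            ind = np.stack([data.row(p).astype(float) for p in model.pairs])
        except KeyError as err:
            raise DomainError(
                f"pair matrix lacks signature pair (stored orientation): {err}"
            ) from None
        return RiskScore(list(data.sample_ids), coeffs @ ind)
    if isinstance(data, Mapping):
        ind = _indicators_from_profile(data, model)
        return RiskScore([sample_id], np.array([coeffs @ ind]))
    raise TypeError(f"cannot score object of type {type(data).__name__}")


def stratify(scores: RiskScore, cutoff: float) -> RiskScore:
    """High/low call: high iff score > cutoff (ties fall to low)."""
    if not np.isfinite(cutoff):
        raise DomainError("cutoff must be finite")
    group = np.where(scores.score > cutoff, "high", "low").astype(object)
    return RiskScore(scores.sample_ids, scores.score, group)


@dataclass
class GroupEvaluation:
    """Survival comparison of the high- vs low-risk groups."""

    km_curves: dict[str, KMCurve]
    median_survival: dict[str, float]
    logrank: LogRankResult
    cox_group: CoxResult            # covariate = 1{high}
    hr_high_vs_low: float
    hr_low_vs_high: float
    auc_by_horizon: dict[float, float]
    n_by_group: dict[str, int] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = {}
        for g, km in self.km_curves.items():
            med = self.median_survival[g]
            rows[g] = {"n": self.n_by_group.get(g, np.nan),
                       "median_survival": "not reached" if np.isnan(med) else f"{med:g}"}
        df = pd.DataFrame(rows).T
        df.attrs["logrank_p"] = self.logrank.p_value
        return df


def evaluate_groups(scores: RiskScore, surv: SurvivalData,
                    horizons: Sequence[float] = (12.0, 36.0, 60.0),
                    span: float | None = None) -> GroupEvaluation:
    """Per-group KM, log-rank, group-covariate Cox HR, and time-dependent
    AUC of the continuous score at each horizon."""
    if any(h <= 0 for h in horizons):
        raise DomainError("horizons must be positive")
    surv = surv.align(scores.sample_ids)
    groups = np.asarray(scores.group)
    present = set(groups)
    if "unassigned" in present:
        raise DomainError("scores not stratified yet (unassigned groups)")
    if len(present) < 2:
        raise DomainError("only one risk group present")
    km, med, n_by = {}, {}, {}
    for g in ("low", "high"):
        sub = surv.subset(groups == g)
        km[g] = km_estimate(sub)
        med[g] = km[g].median_time
        n_by[g] = len(sub)
    lr = logrank_test(surv, groups)
    high = (groups == "high").astype(float)
    cox = cox_fit(high[:, None], surv, names=["high_risk"])
    hr_hl = float(cox.hr[0])
    aucs = {}
    for h in horizons:
        try:
            aucs[float(h)] = td_roc_nne(scores.score, surv, float(h), span).auc
        except DomainError as err:
            warnings.warn(f"AUC at {h} months unavailable: {err}", stacklevel=2)
            aucs[float(h)] = float("nan")
    return GroupEvaluation(km, med, lr, cox, hr_hl, 1.0 / hr_hl, aucs, n_by)


def subgroup_analysis(scores: RiskScore, clinical: ClinicalTable,
                      surv: SurvivalData, factors: Sequence[str] = (
                          "sex", "age_ge_18m", "mycn_amplified", "stage4"),
                      horizons: Sequence[float] = (12.0, 36.0, 60.0),
                      min_samples: int = 10) -> dict[str, dict]:
    """Risk-group evaluation repeated within each level of each clinical
    factor.  Levels with fewer than ``min_samples`` samples or no events,
    and degenerate strata (single risk group), are skipped with a warning.
    Samples missing a factor are excluded from that factor only."""
    out: dict[str, dict] = {}
    clin = clinical.data.loc[[s for s in scores.sample_ids]]
    groups = pd.Series(scores.group, index=scores.sample_ids)
    for factor in factors:
        col = clin[factor]
        levels = sorted(col.dropna().unique())
        if len(levels) < 2:
            warnings.warn(f"factor {factor!r} has a single level; skipped",
                          stacklevel=2)
            continue
        out[factor] = {}
        for level in levels:
            ids = [s for s in scores.sample_ids if col.get(s) == level]
            mask = np.isin(scores.sample_ids, ids)
            if mask.sum() < min_samples:
                warnings.warn(f"{factor}={level}: fewer than {min_samples} "
                              "samples; skipped", stacklevel=2)
                continue
            sub_scores = RiskScore(list(np.array(scores.sample_ids)[mask]),
                                   scores.score[mask], scores.group[mask])
            try:
                sub_surv = surv.align(sub_scores.sample_ids)
                if sub_surv.n_events < 1:
                    warnings.warn(f"{factor}={level}: no events; skipped",
                                  stacklevel=2)
                    continue
                out[factor][level] = evaluate_groups(sub_scores, sub_surv, horizons)
            except DomainError as err:
                warnings.warn(f"{factor}={level}: {err}; skipped", stacklevel=2)
    return out
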