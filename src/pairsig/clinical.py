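"""Clinical covariate screening, stepwise Cox selection, and the
clinically adjusted composite score (RCPI).

The RCPI is a Cox-weighted linear combination of clinical terms and the
continuous RPI, e.g. ``RCPI = w_stage * stage4 + w_rpi * RPI``; unlike
the RPI's fixed transferable cutoff, the RCPI threshold is the *median
of the scores in the cohort it is applied to*, recomputed per cohort.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ClinicalTable, DomainError, RiskScore, SurvivalData
from .signature import stratify
from .survival import CoxResult, cox_fit, logrank_test

__all__ = ["RCPIModel", "ScreenTable", "univariate_screen", "multivariate_fit",
           "stepwise_select", "build_rcpi", "score_rcpi", "apply_rcpi"]

DEFAULT_VARIABLES = ("sex", "age_ge_18m", "mycn_amplified", "stage4", "rpi_group")


@dataclass
class RCPIModel:
    """Composite clinical + RPI risk model with a per-cohort median cutoff."""

    terms: list[str]
    weights: np.ndarray
    cutoff: float | None = None
    cutoff_method: str = "median"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if len(self.terms) != len(self.weights):
            raise DomainError("terms and weights differ in length")
        if not np.all(np.isfinite(self.weights)):
            raise DomainError("non-finite RCPI weight")


@dataclass
class ScreenTable:
    """Per-variable univariate (log-rank + single-covariate Cox) and
    multivariate Cox statistics."""

    table: pd.DataFrame
    n_multivariate: int = 0
    n_dropped_missing: int = 0

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.3g}")


def _design_frame(clinical: ClinicalTable, rpi: RiskScore | None,
                  variables) -> pd.DataFrame:
    """Assemble a per-sample covariate frame; ``rpi_group`` is the
    dichotomized risk group (high=1), ``rpi`` the continuous score."""
    df = clinical.data.copy()
    df.index = df.index.astype(str)
    if rpi is not None:
        s = pd.Series(rpi.score, index=rpi.sample_ids)
        df["rpi"] = s.reindex(df.index)
        g = pd.Series(rpi.group, index=rpi.sample_ids).reindex(df.index)
        df["rpi_group"] = g.map({"high": 1.0, "low": 0.0})
    unknown = [v for v in variables if v not in df.columns]
    if unknown:
        raise DomainError(f"unknown variables: {unknown}")
    return df[list(variables)]


def univariate_screen(clinical: ClinicalTable, rpi: RiskScore | None,
                      surv: SurvivalData,
                      variables=DEFAULT_VARIABLES) -> ScreenTable:
    """One-variable-at-a-time prognostic screen.

    Categorical (binary) variables get a log-rank p across their levels
    plus a single-covariate Cox HR with 95% CI; continuous variables get
    the Cox statistics only.  All-missing or constant variables are
    skipped with a warning.
    """
    design = _design_frame(clinical, rpi, variables)
    rows = {}
    for var in design.columns:
        col = design[var]
        obs = col.dropna()
        ids = [str(i) for i in obs.index if str(i) in surv.sample_ids]
        if len(ids) < 2 or obs.loc[ids].nunique() < 2:
            warnings.warn(f"variable {var!r} constant or all-missing; skipped",
                          stacklevel=2)
            continue
        sub = surv.align(ids)
        x = obs.loc[ids].to_numpy(float)
        row = {}
        if len(np.unique(x)) <= 4:  # treat as categorical
            try:
                row["logrank_p"] = logrank_test(sub, x).p_value
            except DomainError:
                row["logrank_p"] = np.nan
        else:
            row["logrank_p"] = np.nan
        try:
            cr = cox_fit(x[:, None], sub, names=[var])
            row.update({"HR": cr.hr[0], "CI_low": cr.ci_low[0],
                        "CI_high": cr.ci_high[0], "cox_p": cr.p_value[0],
                        "n": len(ids)})
        except (DomainError, RuntimeError) as err:
            warnings.warn(f"univariate Cox failed for {var!r}: {err}", stacklevel=2)
            row.update({"HR": np.nan, "CI_low": np.nan, "CI_high": np.nan,
                        "cox_p": np.nan, "n": len(ids)})
        rows[var] = row
    return ScreenTable(pd.DataFrame(rows).T)


def multivariate_fit(variables, clinical: ClinicalTable, rpi: RiskScore | None,
                     surv: SurvivalData, min_samples: int = 30,
                     min_events: int = 10) -> CoxResult:
    """Joint Cox fit of the selected variables with listwise deletion of
    missing values (the dropped count is reported via the result's n)."""
    design = _design_frame(clinical, rpi, variables)
    complete = design.dropna()
    ids = [str(i) for i in complete.index if str(i) in surv.sample_ids]
    n_dropped = len(design) - len(ids)
    if n_dropped:
        warnings.warn(f"listwise deletion removed {n_dropped} sample(s)",
                      stacklevel=2)
    sub = surv.align(ids)
    if len(ids) < min_samples or sub.n_events < min_events:
        raise DomainError(
            f"multivariate fit needs >= {min_samples} complete samples and "
            f">= {min_events} events (got {len(ids)}, {sub.n_events})")
    X = complete.loc[ids].to_numpy(float)
    return cox_fit(X, sub, names=list(variables))


def stepwise_select(candidates, clinical: ClinicalTable, rpi: RiskScore | None,
                    surv: SurvivalData, p_enter: float = 0.15,
                    p_remove: float = 0.05) -> list[str]:
    """Forward selection (smallest Wald p < ``p_enter``) with backward
    pruning, after each entry, of any term whose joint-model p exceeds
    ``p_remove``.  Pruned terms never re-enter, so the procedure is
    deterministic and cycle-free given the data."""
    selected: list[str] = []
    remaining = list(candidates)

    def joint_p(terms: list[str]) -> np.ndarray:
        fit = multivariate_fit(terms, clinical, rpi, surv,
                               min_samples=2, min_events=1)
        return fit.p_value

    while remaining:
        best_var, best_p = None, np.inf
        for var in remaining:
            try:
                p = joint_p(selected + [var])[-1]
            except (DomainError, RuntimeError):
                continue
            if p < best_p:
                best_var, best_p = var, p
        if best_var is None or best_p >= p_enter:
            break
        selected.append(best_var)
        remaining.remove(best_var)
        # backward pruning (may remove the term just entered)
        while selected:
            p = joint_p(selected)
            worst = int(np.argmax(p))
            if p[worst] > p_remove:
                selected.pop(worst)
            else:
                break
    if not selected:
        warnings.warn("stepwise selection retained no variables", stacklevel=2)
    return selected


def build_rcpi(variables, clinical: ClinicalTable, rpi: RiskScore,
               surv: SurvivalData) -> RCPIModel:
    """Fit the composite model: weights are the joint Cox coefficients of
    the listed terms, with the RPI entering as its continuous score.
    The cutoff is left unset — it is the median of the scores in
    whichever cohort the model is applied to (see :func:`apply_rcpi`)."""
    if not variables:
        raise DomainError("RCPI needs at least one term")
    variables = ["rpi" if v == "rpi_group" else v for v in variables]
    fit = multivariate_fit(variables, clinical, rpi, surv)
    return RCPIModel(list(variables), fit.beta.copy())


def score_rcpi(values, model: RCPIModel) -> float:
    """Composite score of one sample: dot product of term values and
    weights.  ``values`` maps term name -> value."""
    missing = [t for t in model.terms if t not in values or pd.isna(values[t])]
    if missing:
        raise DomainError(f"missing RCPI term value(s): {missing}")
    return float(sum(w * float(values[t]) for t, w in zip(model.terms, model.weights)))


def apply_rcpi(model: RCPIModel, clinical: ClinicalTable, rpi: RiskScore
               ) -> tuple[RiskScore, float]:
    """Score a cohort and stratify at the cohort's own median.

    Samples missing any model term are excluded.  Returns the stratified
    scores and the median cutoff used.
    """
    design = _design_frame(clinical, rpi, model.terms).dropna()
    if design.empty:
        raise DomainError("no sample has complete RCPI terms")
    scores = design.to_numpy(float) @ model.weights
    cutoff = float(np.median(scores))
    rs = RiskScore([str(i) for i in design.index], scores)
    return stratify(rs, cutoff), cutoff
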