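"""High-level modelling interface.

:class:`PairSignatureCox` is built from an expression matrix and
survival outcomes; :meth:`~PairSignatureCox.fit` runs the full signature
pipeline — pair construction, constant-pair removal, FWER-controlled
log-rank screening, cross-validated lasso-Cox, and cutoff selection —
and returns a :class:`PairSignatureResults` carrying the signature, the
per-sample risk scores, stage counts and diagnostics, with
``summary()``, ``predict()`` and ``evaluate()`` in the style of the
usual statistical-modelling packages.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (ClinicalTable, DomainError, ExpressionMatrix, RiskScore,
                        SignatureModel, SurvivalData)
from .lasso import PenalizedCoxConfig, PenalizedCoxFit, extract_signature, \
    fit_penalized_cox
from .pairs import PairMatrix, build_pair_matrix, filter_constant_pairs
from .signature import (GroupEvaluation, ScreenConfig, ScreenedPairs,
                        evaluate_groups, score_rpi, screen_prognostic_pairs,
                        stratify)
from .tdroc import optimal_cutoff

__all__ = ["PairSignatureCox", "PairSignatureResults"]


class PairSignatureCox:
    """Gene-pair prognostic signature model.

    Parameters
    ----------
    expression : training cohort abundances (any monotone unit).
    survival : right-censored outcomes; samples are matched by id and the
        intersection with the expression columns is used.
    candidate_genes : genes to pair (default: all genes in the matrix).
    screen_config, penalty_config : stage settings.
    cutoff_horizon : months; horizon of the ROC used for the cutoff.
    extra_matrices : additional expression matrices (e.g. the validation
        cohort) whose pair constancy should also veto pairs.
    """

    def __init__(self, expression: ExpressionMatrix, survival: SurvivalData,
                 candidate_genes: Sequence[str] | None = None,
                 screen_config: ScreenConfig | None = None,
                 penalty_config: PenalizedCoxConfig | None = None,
                 cutoff_horizon: float = 60.0, span: float | None = None,
                 extra_matrices: Sequence[ExpressionMatrix] = ()):
        self.expression = expression
        common = [s for s in expression.sample_ids if s in set(survival.sample_ids)]
        if not common:
            raise DomainError("no overlap between expression and survival samples")
        self.survival = survival.align(common)
        self.candidate_genes = sorted(candidate_genes or expression.gene_ids)
        self.screen_config = screen_config or ScreenConfig()
        self.penalty_config = penalty_config or PenalizedCoxConfig()
        self.cutoff_horizon = cutoff_horizon
        self.span = span
        self.extra_matrices = list(extra_matrices)

    @classmethod
    def from_dataframes(cls, expression: pd.DataFrame, clinical: ClinicalTable,
                        endpoint: str = "OS", **kwargs) -> "PairSignatureCox":
        expr = ExpressionMatrix.from_frame(expression)
        return cls(expr, clinical.survival(endpoint), **kwargs)

    def fit(self, cutoff_method: str = "roc", rule: str | None = None
            ) -> "PairSignatureResults":
        """Run the pipeline and return fitted results."""
        counts: dict[str, int] = {"genes_in": len(self.candidate_genes)}
        pm_full = build_pair_matrix(self.expression, self.candidate_genes)
        counts["pairs_built"] = pm_full.n_pairs
        matrices = [pm_full] + [build_pair_matrix(m, self.candidate_genes)
                                for m in self.extra_matrices]
        keep = filter_constant_pairs(matrices)
        counts["pairs_after_constant_filter"] = len(keep)
        if not keep:
            raise DomainError("no non-constant pairs to screen")
        pm = pm_full.subset(keep).subset_samples(self.survival.sample_ids)
        screen = screen_prognostic_pairs(pm, self.survival, self.screen_config)
        counts["pairs_after_screen"] = len(screen.selected)
        if not screen.selected:
            raise DomainError("no pair passed the FWER screen")
        pm_sel = pm.subset(screen.selected)
        X = pm_sel.values.T.astype(float)
        lasso_fit = fit_penalized_cox(X, self.survival, self.penalty_config,
                                      names=pm_sel.pair_ids)
        signature = extract_signature(lasso_fit, pm_sel.pair_ids,
                                      rule or self.penalty_config.rule)
        counts["pairs_in_model"] = len(signature)
        scores = score_rpi(self.expression, signature)
        train_scores = RiskScore(self.survival.sample_ids,
                                 scores.to_frame().loc[self.survival.sample_ids,
                                                       "score"].to_numpy())
        if cutoff_method == "roc":
            cutoff = optimal_cutoff(train_scores.score, self.survival,
                                    self.cutoff_horizon, self.span)
        elif cutoff_method == "median":
            cutoff = float(np.median(train_scores.score))
        else:
            raise DomainError("cutoff_method must be 'roc' or 'median'")
        signature = signature.with_cutoff(cutoff, cutoff_method)
        signature.metadata.setdefault("endpoint", self.survival.endpoint_label)
        stratified = stratify(train_scores, cutoff)
        return PairSignatureResults(self, signature, stratified, screen,
                                    lasso_fit, counts)


@dataclass
class PairSignatureResults:
    """Fitted signature plus training-cohort scores and diagnostics."""

    model: PairSignatureCox
    signature: SignatureModel
    risk_scores: RiskScore           # training cohort, stratified
    screen: ScreenedPairs
    lasso_fit: PenalizedCoxFit
    stage_counts: dict = field(default_factory=dict)

    def predict(self, expression: ExpressionMatrix) -> RiskScore:
        """Score a new cohort (or single-sample matrix) with the fixed
        signature and fixed cutoff — no re-estimation."""
        scores = score_rpi(expression, self.signature)
        return stratify(scores, self.signature.cutoff)

    def evaluate(self, survival: SurvivalData | None = None,
                 scores: RiskScore | None = None,
                 horizons: Sequence[float] = (12.0, 36.0, 60.0)
                 ) -> GroupEvaluation:
        """Survival separation of the risk groups (training cohort by
        default; pass a new cohort's scores and survival to validate)."""
        scores = scores if scores is not None else self.risk_scores
        survival = survival if survival is not None else self.model.survival
        common = [s for s in scores.sample_ids if s in set(survival.sample_ids)]
        mask = np.isin(scores.sample_ids, common)
        sub = RiskScore(list(np.asarray(scores.sample_ids)[mask]),
                        scores.score[mask], scores.group[mask])
        return evaluate_groups(sub, survival.align(sub.sample_ids), horizons,
                               span=self.model.span)

    def summary(self) -> str:
        c = self.stage_counts
        lines = [
            "Gene-pair prognostic signature (penalized Cox)",
            "=" * 54,
            f"endpoint: {self.model.survival.endpoint_label}   "
            f"n = {len(self.model.survival)}, events = {self.model.survival.n_events}",
            f"candidate genes: {c.get('genes_in')}  ->  pairs built: "
            f"{c.get('pairs_built')}",
            f"after constant filter: {c.get('pairs_after_constant_filter')}   "
            f"after FWER screen: {c.get('pairs_after_screen')}",
            f"pairs in model: {c.get('pairs_in_model')}   "
            f"(rule: {self.lasso_fit.rule}, lambda = "
            f"{float(self.signature.metadata.get('lambda', 'nan')):.6g})",
            f"cutoff: {self.signature.cutoff:.6g} ({self.signature.cutoff_method})",
            "-" * 54,
            f"{'gene1':<12}{'gene2':<12}{'coef':>14}",
        ]
        for (g1, g2), b in zip(self.signature.pairs, self.signature.coefficients):
            lines.append(f"{g1:<12}{g2:<12}{b:>14.6f}")
        n_high = int((self.risk_scores.group == "high").sum())
        n_low = int((self.risk_scores.group == "low").sum())
        lines += ["-" * 54,
                  f"training stratification: high = {n_high}, low = {n_low}"]
        return "\n".join(lines)
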