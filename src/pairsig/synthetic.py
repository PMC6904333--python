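"""Two-cohort synthetic data with the structure the pipeline assumes.

Each cohort is a gene x sample abundance matrix (log-normal per gene)
plus a clinical table with right-censored OS/EFS outcomes.  The
prognostic signal is planted directly on the *order relation* of
designated gene pairs: a latent Bernoulli state per sample decides
which member of the pair is larger, and the hazard is

    h_i = baseline * exp( sum_k beta_k * s_ik + clinical effects )

so the pair indicator is, by construction, the true hazard driver.
Event times are exponential by default (Weibull shape exposed);
censoring is independent uniform on (0, c_max) with c_max calibrated to
the target censoring fraction.  The two cohorts share gene identities
and the planted mechanism but differ in sample size, clinical mix and a
global abundance scale factor (emulating FPKM vs RPM platforms) — the
scale factor is strictly monotone, so pair indicators are unaffected.

Defaults mirror the two neuroblastoma cohorts the pipeline is designed
around: sizes 153 and 498, a 10-pair signature, stage-4 and age
log-hazard ratios at the magnitudes reported for those cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import ClinicalTable, DomainError, ExpressionMatrix

__all__ = ["SimConfig", "TwoCohorts", "generate_cohort", "generate_two_cohorts"]

_TABLE1_MIX = (
    {"sex": 0.58, "age_ge_18m": 0.81, "mycn_amplified": 0.22, "stage4": 0.82},
    {"sex": 0.58, "age_ge_18m": 0.39, "mycn_amplified": 0.18, "stage4": 0.37},
)


@dataclass(frozen=True)
class SimConfig:
    n_samples: tuple[int, int] = (153, 498)
    n_genes: int = 40
    n_planted_pairs: int = 3
    pair_effect_betas: tuple = (float(np.log(4.0)),) * 3
    pair_prevalence: float = 0.5
    baseline_hazard: float = float(np.log(2) / 36.0)   # median ~36 months
    weibull_shape: float = 1.0
    censoring_rate_target: float = 0.4
    clinical_effects: dict = field(default_factory=lambda: {
        "stage4": float(np.log(5.44)), "age_ge_18m": float(np.log(1.15))})
    clinical_mix: tuple = _TABLE1_MIX
    platform_scale_factors: tuple[float, float] = (1.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_samples) or self.n_genes <= 0:
            raise DomainError("counts must be positive")
        if len(self.pair_effect_betas) != self.n_planted_pairs:
            raise DomainError("pair_effect_betas length != n_planted_pairs")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise DomainError("not enough genes for disjoint planted pairs")
        if not (0 <= self.censoring_rate_target < 1):
            raise DomainError("censoring target must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise DomainError("baseline hazard and shape must be positive")
        if any(s <= 0 for s in self.platform_scale_factors):
            raise DomainError("scale factors must be positive")


@dataclass
class TwoCohorts:
    cohorts: list[tuple[ExpressionMatrix, ClinicalTable]]
    truth: dict


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _gene_means(config: SimConfig) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    return rng.normal(2.0, 1.5, size=config.n_genes)


def planted_pairs(config: SimConfig) -> list[tuple[str, str]]:
    """The planted pairs, in the canonical (lexicographic) orientation:
    latent state 1 means gene1 < gene2, which raises the hazard by
    exp(beta)."""
    ids = _gene_ids(config.n_genes)
    return [(ids[2 * k], ids[2 * k + 1]) for k in range(config.n_planted_pairs)]


def _calibrate_censoring(t_event: np.ndarray, target: float) -> float:
    """Upper bound of the uniform censoring law so that the expected
    censored fraction over the drawn event times equals the target."""
    if target == 0:
        return np.inf

    def frac(c):
        return float(np.minimum(t_event / c, 1.0).mean()) - target

    lo, hi = 1e-9, float(t_event.max()) * 1e4
    if frac(hi) > 0:
        raise DomainError("infeasible censoring target for these event times")
    return brentq(frac, lo, hi, xtol=1e-10)


def generate_cohort(config: SimConfig, cohort_index: int
                    ) -> tuple[ExpressionMatrix, ClinicalTable]:
    expr, clin, _ = _generate_cohort(config, cohort_index)
    return expr, clin


def _generate_cohort(config: SimConfig, cohort_index: int):
    if cohort_index not in (0, 1):
        raise DomainError("cohort_index must be 0 or 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, cohort_index]))
    n = config.n_samples[cohort_index]
    mu = _gene_means(config)
    ids = _gene_ids(config.n_genes)
    sample_ids = [f"c{cohort_index}s{i:04d}" for i in range(1, n + 1)]

    values = np.exp(rng.normal(mu[:, None], 0.8, size=(config.n_genes, n)))
    # plant the order relations: pair genes share a mean, so swapping the
    # two draws leaves marginals untouched while fixing the indicator
    latent = rng.random((config.n_planted_pairs, n)) < config.pair_prevalence
    for k in range(config.n_planted_pairs):
        a, b = 2 * k, 2 * k + 1
        v1 = np.exp(rng.normal(mu[a], 0.8, size=n))
        v2 = np.exp(rng.normal(mu[a], 0.8, size=n))
        lo, hi = np.minimum(v1, v2), np.maximum(v1, v2)
        values[a] = np.where(latent[k], lo, hi)
        values[b] = np.where(latent[k], hi, lo)

    mix = config.clinical_mix[cohort_index]
    clin = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for colname in ("sex", "age_ge_18m", "mycn_amplified", "stage4"):
        clin[colname] = (rng.random(n) < mix[colname]).astype(float)

    # centre the linear predictor at its expectation so baseline_hazard
    # describes the average patient and times stay on a month scale
    lp = np.zeros(n)
    expected = 0.0
    for k, beta in enumerate(config.pair_effect_betas):
        lp += beta * latent[k]
        expected += beta * config.pair_prevalence
    for term, beta in config.clinical_effects.items():
        lp += beta * clin[term].to_numpy()
        expected += beta * mix[term]
    hazard = config.baseline_hazard * np.exp(lp - expected)

    e_std = rng.exponential(1.0, size=n)
    t_os = (e_std / hazard) ** (1.0 / config.weibull_shape)
    # progression occurs at 1.4x the death hazard; EFS time = first of the two
    e2 = rng.exponential(1.0, size=n)
    t_prog = (e2 / (1.4 * hazard)) ** (1.0 / config.weibull_shape)
    t_efs = np.minimum(t_os, t_prog)

    c_max = _calibrate_censoring(t_os, config.censoring_rate_target)
    cens = rng.uniform(0, c_max, size=n) if np.isfinite(c_max) else np.full(n, np.inf)
    clin["os_time"] = np.minimum(t_os, cens)
    clin["os_event"] = (t_os <= cens).astype(float)
    clin["efs_time"] = np.minimum(t_efs, cens)
    clin["efs_event"] = (t_efs <= cens).astype(float)

    scale = config.platform_scale_factors[cohort_index]
    units = "FPKM" if cohort_index == 0 else "RPM"
    expr = ExpressionMatrix(ids, sample_ids, values * scale, units=units)
    return expr, ClinicalTable(clin), latent


def generate_two_cohorts(config: SimConfig | None = None) -> TwoCohorts:
    """Training + validation cohorts sharing the planted mechanism, plus a
    ground-truth record of the planted pairs, effects and latent states."""
    config = config or SimConfig()
    cohorts = []
    latents = {}
    for idx in (0, 1):
        expr, clin, latent = _generate_cohort(config, idx)
        cohorts.append((expr, clin))
        latents[idx] = latent
    truth = {
        "planted_pairs": planted_pairs(config),
        "betas": list(config.pair_effect_betas),
        "prevalence": config.pair_prevalence,
        "clinical_effects": dict(config.clinical_effects),
        "latent_states": latents,
        "seed": config.seed,
    }
    return TwoCohorts(cohorts, truth)
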