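"""Survival statistics: Kaplan-Meier, log-rank, Cox PH, FWER adjustment.

These are implemented directly on the Breslow partial likelihood because
downstream stages need its score and Hessian explicitly (KKT checks for
the penalized path, gradient-based working responses, grid-search
oracles in the tests).  Conventions: Breslow tie handling throughout;
at tied times events precede censorings (both are at risk at the tie).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import DomainError, SurvivalData

__all__ = [
    "KMCurve", "LogRankResult", "CoxResult",
    "km_estimate", "logrank_test", "logrank_chi2_many", "cox_fit",
    "adjust_fwer", "BreslowWorkspace", "ConvergenceError", "SeparationError",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge."""


class SeparationError(RuntimeError):
    """Monotone partial likelihood (complete separation); consider an
    L1/L2 penalized fit instead."""


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median_time: float  # NaN when the curve never reaches 0.5

    @property
    def median_reached(self) -> bool:
        return bool(np.isfinite(self.median_time))

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time": self.event_times, "survival": self.survival,
                             "n_at_risk": self.n_at_risk, "n_events": self.n_events})


@dataclass
class LogRankResult:
    chi2: float
    p_value: float
    df: int


@dataclass
class CoxResult:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"coef": self.beta, "se": self.se, "HR": self.hr,
                             "HR 95% low": self.ci_low, "HR 95% high": self.ci_high,
                             "p": self.p_value}, index=self.names)


def km_estimate(surv: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    The median is the smallest event time with S(t) <= 0.5, NaN ("not
    reached") if the curve never falls that far.
    """
    if len(surv) == 0:
        raise DomainError("empty survival data")
    order = np.argsort(surv.time, kind="stable")
    t, e = surv.time[order], surv.event[order]
    utimes, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    n_at = len(t) - first
    mask = d > 0
    times, d, n_at = utimes[mask], d[mask], n_at[mask]
    survival = np.cumprod(1.0 - d / n_at)
    below = np.nonzero(survival <= 0.5)[0]
    median = float(times[below[0]]) if below.size else float("nan")
    return KMCurve(times, survival, n_at, d, median)


def _risk_table(time: np.ndarray, event: np.ndarray):
    """Sorted times, per-unique-time first indices and event counts."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    _, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    n_at = len(t) - first
    return order, first, d, n_at


def logrank_test(surv: SurvivalData, groups) -> LogRankResult:
    """Multi-group log-rank test (observed minus expected, hypergeometric
    variance); df = number of groups - 1."""
    groups = np.asarray(groups)
    if groups.shape != (len(surv),):
        raise DomainError("groups length mismatch")
    levels, gidx = np.unique(groups, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise DomainError("log-rank test needs >= 2 groups")
    if surv.n_events == 0:
        raise DomainError("log-rank test needs >= 1 event")
    order, first, d, n_at = _risk_table(surv.time, surv.event)
    e_s, g_s = surv.event[order], gidx[order]
    n = len(surv)
    # per-group at-risk counts via suffix sums of one-hot labels
    onehot = np.zeros((k, n))
    onehot[g_s, np.arange(n)] = 1.0
    suffix = np.cumsum(onehot[:, ::-1], axis=1)[:, ::-1]
    n_g = suffix[:, first]                              # k x T
    d_g = np.add.reduceat(onehot * e_s, first, axis=1)  # k x T
    mask = d > 0
    d, n_at, n_g, d_g = d[mask], n_at[mask], n_g[:, mask], d_g[:, mask]
    O = d_g.sum(axis=1)
    E = (d * n_g / n_at).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(n_at > 1, d * (n_at - d) / (n_at - 1), 0.0)
    p_g = n_g / n_at
    # covariance: V_kl = sum_t c_t * (p_k delta_kl - p_k p_l)
    V = -np.einsum("t,kt,lt->kl", c, p_g, p_g)
    V[np.diag_indices(k)] += (c * p_g).sum(axis=1)
    u = (O - E)[:-1]
    Vr = V[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(Vr) @ u) if u.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(chi2, float(stats.chi2.sf(chi2, df)), df)


def logrank_chi2_many(time: np.ndarray, event: np.ndarray, indicators: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank statistics for many binary groupings at once.

    ``indicators`` is (m, n); each row splits the n samples into the
    0-group and 1-group.  Returns (chi2, p) arrays of length m.  Rows
    whose variance term is zero (e.g. a constant grouping) get chi2 = 0,
    p = 1.
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    G = np.asarray(indicators, float)
    order, first, d, n_at = _risk_table(time, event)
    e_s = event[order]
    Gs = G[:, order]
    suffix = np.cumsum(Gs[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, first]                       # m x T, at-risk in group 1
    d1 = np.add.reduceat(Gs * e_s, first, axis=1)
    mask = d > 0
    d, n_at, n1, d1 = d[mask], n_at[mask], n1[:, mask], d1[:, mask]
    p1 = n1 / n_at
    O1 = d1.sum(axis=1)
    E1 = (d * p1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(n_at > 1, d * (n_at - d) / (n_at - 1), 0.0)
    V = (c * p1 * (1 - p1)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, (O1 - E1) ** 2 / V, 0.0)
    return chi2, stats.chi2.sf(chi2, 1)


class BreslowWorkspace:
    """Precomputed risk-set structure for the Breslow partial likelihood.

    Provides the log partial likelihood, its gradient and Hessian with
    respect to beta, and the per-subject gradient / diagonal Hessian
    with respect to the linear predictor eta (used by the coordinate-
    descent lasso).
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        self.n = len(time)
        self.order = np.argsort(time, kind="stable")
        self.t = np.asarray(time, float)[self.order]
        self.e = np.asarray(event)[self.order].astype(float)
        _, self.first = np.unique(self.t, return_index=True)
        self.d = np.add.reduceat(self.e, self.first)          # events per unique time
        self.ev_mask = self.d > 0
        # block index of each sorted subject (which unique time it belongs to)
        self.block = np.searchsorted(self.first, np.arange(self.n), side="right") - 1

    def _s0(self, eta_s: np.ndarray) -> np.ndarray:
        """S0 at each unique time = sum of exp(eta) over the risk set."""
        w = np.exp(eta_s)
        suffix = np.cumsum(w[::-1])[::-1]
        return suffix[self.first]

    def loglik(self, eta: np.ndarray) -> float:
        eta_s = eta[self.order]
        s0 = self._s0(eta_s)
        ll = float((self.e * eta_s).sum())
        ll -= float((self.d[self.ev_mask] * np.log(s0[self.ev_mask])).sum())
        return ll

    def _cum_hazard_terms(self, eta_s: np.ndarray):
        """A_i = sum_{event times <= t_i} d/S0 and B_i likewise with d/S0^2."""
        s0 = self._s0(eta_s)
        inc_a = np.where(self.ev_mask, self.d / s0, 0.0)
        inc_b = np.where(self.ev_mask, self.d / s0 ** 2, 0.0)
        A_blocks = np.cumsum(inc_a)
        B_blocks = np.cumsum(inc_b)
        return A_blocks[self.block], B_blocks[self.block]

    def grad_eta(self, eta: np.ndarray) -> np.ndarray:
        """d loglik / d eta_i, in original sample order."""
        eta_s = eta[self.order]
        A, _ = self._cum_hazard_terms(eta_s)
        g_s = self.e - np.exp(eta_s) * A
        g = np.empty(self.n)
        g[self.order] = g_s
        return g

    def diag_hess_eta(self, eta: np.ndarray) -> np.ndarray:
        """-(d^2 loglik / d eta_i^2) >= 0, in original sample order."""
        eta_s = eta[self.order]
        A, B = self._cum_hazard_terms(eta_s)
        r = np.exp(eta_s)
        w_s = r * A - r ** 2 * B
        w = np.empty(self.n)
        w[self.order] = np.maximum(w_s, 0.0)
        return w

    def grad_beta(self, X: np.ndarray, eta: np.ndarray) -> np.ndarray:
        return X.T @ self.grad_eta(eta)

    def info_beta(self, X: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Observed information matrix (negative Hessian) w.r.t. beta."""
        eta_s = eta[self.order]
        Xs = X[self.order]
        w = np.exp(eta_s)
        wx = w[:, None] * Xs
        wxx = wx[:, :, None] * Xs[:, None, :]
        suf0 = np.cumsum(w[::-1])[::-1][self.first]
        suf1 = np.cumsum(wx[::-1], axis=0)[::-1][self.first]
        suf2 = np.cumsum(wxx[::-1], axis=0)[::-1][self.first]
        m = self.ev_mask
        d, s0 = self.d[m], suf0[m]
        s1, s2 = suf1[m], suf2[m]
        mu = s1 / s0[:, None]
        info = np.einsum("t,tij->ij", d, s2 / s0[:, None, None])
        info -= np.einsum("t,ti,tj->ij", d, mu, mu)
        return info


def cox_fit(X, surv: SurvivalData, names: list[str] | None = None,
            max_iter: int = 100, score_tol: float = 1e-8,
            ll_tol: float = 1e-10) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson on the Breslow
    partial likelihood, with Wald confidence intervals.

    Raises :class:`SeparationError` on monotone likelihood and
    :class:`ConvergenceError` after ``max_iter`` iterations.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != len(surv):
        raise DomainError("X rows do not match survival samples")
    if surv.n_events < 1:
        raise DomainError("no events")
    if surv.n_events < p:
        raise DomainError("fewer events than covariates")
    if np.any(X.std(axis=0) == 0):
        raise DomainError("constant covariate in design matrix")
    names = names or [f"x{j}" for j in range(p)]
    ws = BreslowWorkspace(surv.time, surv.event)
    beta = np.zeros(p)
    scale = np.abs(X).max(axis=0)
    ll = ws.loglik(X @ beta)
    for _ in range(max_iter):
        eta = X @ beta
        U = ws.grad_beta(X, eta)
        if np.max(np.abs(U)) < score_tol:
            break
        info = ws.info_beta(X, eta)
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, U, rcond=None)[0]
        # step-halving to keep the likelihood non-decreasing
        new_ll, shrink = -np.inf, 1.0
        for _ in range(30):
            cand = beta + shrink * step
            new_ll = ws.loglik(X @ cand)
            if new_ll >= ll - 1e-12:
                break
            shrink *= 0.5
        beta = beta + shrink * step
        if np.max(np.abs(beta) * scale) > 200:
            raise SeparationError(
                "diverging coefficient: monotone partial likelihood "
                "(complete separation); use a penalized fit")
        if abs(new_ll - ll) <= ll_tol * max(1.0, abs(ll)):
            ll = new_ll
            eta = X @ beta
            U = ws.grad_beta(X, eta)
            break
        ll = new_ll
    else:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")
    if np.max(np.abs(beta) * scale) > 15:
        raise SeparationError(
            "unbounded coefficient: monotone partial likelihood "
            "(complete separation); use a penalized fit")
    eta = X @ beta
    info = ws.info_beta(X, eta)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    hr = np.exp(beta)
    return CoxResult(names, beta, se, hr, np.exp(beta - z * se),
                     np.exp(beta + z * se),
                     2 * stats.norm.sf(np.abs(beta / se)),
                     float(ws.loglik(eta)), n, surv.n_events)


def adjust_fwer(p_values, method: str = "holm") -> np.ndarray:
    """Familywise-error-rate adjusted p-values (Holm step-down by
    default; Bonferroni available)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise DomainError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise DomainError(f"unknown FWER method {method!r}")
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method=method)[1]
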