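"""Survival-statistics engine.

Self-contained implementations of the two estimators the enrichment pipeline
hammers hardest — the Cox proportional-hazards partial-likelihood fitter
(Newton-Raphson, Efron or Breslow ties) and the two-group log-rank test —
plus thin wrappers around established libraries for the remaining standard
steps: Kaplan-Meier curves with Brookmeyer-Crowley style median CIs
(lifelines), Benjamini-Hochberg adjustment (statsmodels) and the
cohort-characteristics tests (scipy).

All Cox covariates are centred internally; reported coefficients are
invariant to that centring.  Hazard-ratio confidence intervals are Wald
95% intervals, ``exp(beta +/- 1.96*se)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit",
    "KMCurve",
    "ConvergenceError",
    "cox_fit",
    "logrank",
    "km_estimate",
    "bh_adjust",
    "ph_check",
    "chisq_independence",
    "wilcoxon_ranksum",
    "pearson",
]

Z95 = 1.959963984540054  # Phi^-1(0.975)


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (often monotone likelihood)."""


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model.

    ``beta`` are log hazard ratios, ``hr = exp(beta)`` with Wald 95% CI.
    ``vcov`` is the inverse observed information at the optimum.
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    n: int
    n_events: int
    vcov: np.ndarray
    ties: str
    x_center: np.ndarray = field(repr=False, default=None)

    def summary(self) -> "pd.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "hr": self.hr,
                "hr_ci_low": self.ci_low,
                "hr_ci_high": self.ci_high,
            },
            index=self.names,
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "p": self.p.tolist(),
            "hr": self.hr.tolist(),
            "hr_ci_low": self.ci_low.tolist(),
            "hr_ci_high": self.ci_high.tolist(),
            "loglik": float(self.loglik),
            "n": int(self.n),
            "n_events": int(self.n_events),
            "ties": self.ties,
        }


def _prepare(X, time, event):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if not (len(X) == len(time) == len(event)):
        raise ValueError("X, time and event must have equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate column(s): "
                         f"{list(np.where(sd == 0)[0])}")
    return X, time, event


def _efron_quantities(Xc, time, event, beta, ties):
    """Log partial likelihood, gradient and observed information.

    Vectorised over event times: risk-set sums are suffix cumulative sums
    over the time-sorted sample; the Efron correction subtracts the tied
    deaths' contribution with per-rank fractions l/d.
    """
    n, p = Xc.shape
    order = np.argsort(time, kind="mergesort")
    t_s, e_s, X_s = time[order], event[order], Xc[order]
    eta = X_s @ beta
    eta -= eta.max()  # rescale for overflow safety; cancels in all ratios
    w = np.exp(eta)

    # suffix sums over the risk set {j : t_j >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
    outer = w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :])
    S2 = np.cumsum(outer[::-1], axis=0)[::-1]

    ev_idx = np.where(e_s)[0]
    ev_times = t_s[ev_idx]
    # one group per distinct event time
    grp_start = np.searchsorted(t_s, np.unique(ev_times), side="left")
    uniq, counts = np.unique(ev_times, return_counts=True)

    # per-event arrays: group id and within-group rank
    gid = np.repeat(np.arange(len(uniq)), counts)
    rank = np.concatenate([np.arange(c) for c in counts])
    frac = rank / np.repeat(counts, counts) if ties == "efron" else np.zeros(len(gid))

    # tied-death sums per group
    D0 = np.zeros(len(uniq))
    np.add.at(D0, gid, w[ev_idx])
    D1 = np.zeros((len(uniq), p))
    np.add.at(D1, gid, w[ev_idx, None] * X_s[ev_idx])
    D2 = np.zeros((len(uniq), p, p))
    np.add.at(D2, gid, outer[ev_idx])

    pos = grp_start[gid]
    denom = S0[pos] - frac * D0[gid]
    num1 = S1[pos] - frac[:, None] * D1[gid]
    num2 = S2[pos] - frac[:, None, None] * D2[gid]

    loglik = float(eta[ev_idx].sum() - np.log(denom).sum())
    xbar = num1 / denom[:, None]
    grad = X_s[ev_idx].sum(axis=0) - xbar.sum(axis=0)
    info = (num2 / denom[:, None, None]).sum(axis=0) - np.einsum(
        "kp,kq->pq", xbar, xbar
    )
    return loglik, grad, info


def cox_fit(
    X,
    time,
    event,
    names: Sequence[str] | None = None,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) covariate matrix (or length-n vector)
    time, event : right-censored survival outcome; event=1 is death
    ties : 'efron' (default) or 'breslow'
    tol : convergence tolerance on the coefficient update (sup-norm)

    Raises
    ------
    ConvergenceError
        if Newton-Raphson does not converge within ``max_iter`` or the
        likelihood is monotone (e.g. perfect risk separation).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    X, time, event = _prepare(X, time, event)
    center = X.mean(axis=0)
    Xc = X - center
    p = Xc.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _efron_quantities(Xc, time, event, beta, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # step-halving line search on the partial likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _efron_quantities(Xc, time, event, cand, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.any(np.abs(beta) > 50):
            raise ConvergenceError(
                "diverging coefficients (monotone likelihood / separation?)"
            )
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")

    vcov = np.linalg.inv(info)
    if np.any(np.diag(vcov) <= 0):
        raise ConvergenceError("information matrix not positive definite")
    se = np.sqrt(np.diag(vcov))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    if names is None:
        names = [f"x{i}" for i in range(p)]
    return CoxFit(
        names=list(names),
        beta=beta,
        se=se,
        z=z,
        p=pvals,
        hr=np.exp(beta),
        ci_low=np.exp(np.clip(beta - Z95 * se, -700, 700)),
        ci_high=np.exp(np.clip(beta + Z95 * se, -700, 700)),
        loglik=ll,
        n=len(time),
        n_events=int(event.sum()),
        vcov=vcov,
        ties=ties,
        x_center=center,
    )


def cox_lrt_p(fit: CoxFit, X, time, event) -> float:
    """Likelihood-ratio p-value of a fitted Cox model against beta = 0
    (used as the global test for multi-level categorical covariates)."""
    X, time, event = _prepare(X, time, event)
    Xc = X - fit.x_center
    ll0, _, _ = _efron_quantities(Xc, time, event, np.zeros(len(fit.beta)), fit.ties)
    chi2 = 2.0 * (fit.loglik - ll0)
    return float(sps.chi2.sf(max(chi2, 0.0), len(fit.beta)))


def logrank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df.

    Uses the standard hypergeometric variance at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    g1 = group == labels[1]

    order = np.argsort(time, kind="mergesort")
    t_s, e_s, g_s = time[order], event[order], g1[order]
    n = len(t_s)
    uniq, first = np.unique(t_s, return_index=True)
    # numbers at risk just before each distinct time
    at_risk = n - first
    n1_cum = np.cumsum(g_s[::-1])[::-1]
    at_risk1 = n1_cum[first]
    d_tot = np.zeros(len(uniq))
    d1 = np.zeros(len(uniq))
    idx = np.searchsorted(uniq, t_s[e_s])
    np.add.at(d_tot, idx, 1.0)
    np.add.at(d1, idx, g_s[e_s].astype(float))

    keep = d_tot > 0
    nj, n1j, dj, d1j = at_risk[keep], at_risk1[keep], d_tot[keep], d1[keep]
    exp1 = dj * n1j / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    var = np.where(nj > 1, var, 0.0)
    o_minus_e = (d1j - exp1).sum()
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return float(chi2), float(sps.chi2.sf(chi2, 1))


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve with median survival and 95% CI.

    A non-estimable CI limit (curve never drops far enough) is ``inf`` and
    rendered as ``"N.E"``.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @staticmethod
    def _fmt(v: float) -> str:
        return "N.E" if not np.isfinite(v) else f"{v:.1f}"

    def median_str(self) -> str:
        lo, hi = self.median_ci
        return f"{self._fmt(self.median)} ({self._fmt(lo)}–{self._fmt(hi)})"

    def to_dict(self) -> dict:
        lo, hi = self.median_ci
        none_if_ne = lambda v: None if not np.isfinite(v) else float(v)
        return {
            "median": none_if_ne(self.median),
            "median_ci": [none_if_ne(lo), none_if_ne(hi)],
            "n": self.n,
            "n_events": self.n_events,
        }


def km_estimate(time, event) -> KMCurve:
    """Product-limit survival estimate.

    Median = first time with S(t) <= 0.5; its 95% CI comes from inverting
    the log(-log) confidence band of the curve (the convention of
    mainstream survival software).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if len(time) < 1:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMCurve(
        times=kmf.survival_function_.index.to_numpy(),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
        median=median,
        median_ci=(lo, hi),
        n=len(time),
        n_events=int(event.sum()),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _schoenfeld(Xc, time, event, beta, ties):
    """Schoenfeld residuals (one row per event, time-ordered) at beta."""
    order = np.argsort(time, kind="mergesort")
    t_s, e_s, X_s = time[order], event[order], Xc[order]
    eta = X_s @ beta
    eta -= eta.max()
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
    ev_idx = np.where(e_s)[0]
    ev_times = t_s[ev_idx]
    uniq, counts = np.unique(ev_times, return_counts=True)
    grp_start = np.searchsorted(t_s, uniq, side="left")
    gid = np.repeat(np.arange(len(uniq)), counts)
    rank = np.concatenate([np.arange(c) for c in counts])
    frac = rank / np.repeat(counts, counts) if ties == "efron" else np.zeros(len(gid))
    D0 = np.zeros(len(uniq))
    np.add.at(D0, gid, w[ev_idx])
    D1 = np.zeros((len(uniq), Xc.shape[1]))
    np.add.at(D1, gid, w[ev_idx, None] * X_s[ev_idx])
    pos = grp_start[gid]
    denom = S0[pos] - frac * D0[gid]
    xbar = (S1[pos] - frac[:, None] * D1[gid]) / denom[:, None]
    return ev_times, X_s[ev_idx] - xbar


def ph_check(fit: CoxFit, time, event, X) -> dict:
    """Proportional-hazards diagnostic via scaled Schoenfeld residuals.

    Correlates scaled Schoenfeld residuals against event time (identity
    time transform) and returns a per-covariate score test plus the
    Grambsch-Therneau global test.
    """
    X, time, event = _prepare(X, time, event)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for a PH check")
    Xc = X - fit.x_center
    ev_times, resid = _schoenfeld(Xc, time, event, fit.beta, fit.ties)
    d = len(ev_times)
    g = ev_times - ev_times.mean()
    gss = float((g**2).sum())
    if gss == 0:
        raise ValueError("all events at a single time; PH check undefined")
    u = resid.T @ g  # p-vector
    V = fit.vcov
    # per-covariate: corr of scaled residual d*V*s with g
    vu = V @ u
    chi_cov = d * vu**2 / (np.diag(V) * gss)
    p_cov = sps.chi2.sf(chi_cov, 1)
    chi_glob = float(d * u @ V @ u / gss)
    p_glob = float(sps.chi2.sf(chi_glob, fit.vcov.shape[0]))
    return {
        "names": list(fit.names),
        "chi2": chi_cov.tolist(),
        "p": p_cov.tolist(),
        "global_chi2": chi_glob,
        "global_p": p_glob,
        "n_events": d,
        "residual_sums": resid.sum(axis=0).tolist(),
    }


def chisq_independence(table, continuity_correction: str | bool = "auto") -> float:
    """Chi-square test of independence on a contingency table.

    2x2 tables get the Yates continuity correction (the convention needed
    to reproduce published cohort-table p-values); larger tables use the
    uncorrected Pearson statistic.  Returns the two-sided p-value.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    if continuity_correction == "auto":
        correction = table.shape == (2, 2)
    else:
        correction = bool(continuity_correction)
    res = sps.chi2_contingency(table, correction=correction)
    return float(res[1])


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs length >= 2")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
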