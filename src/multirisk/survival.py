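"""Self-contained survival-statistics kernel.

Cox proportional-hazards partial likelihood (Efron / Breslow ties),
Newton–Raphson fitting, Kaplan–Meier product-limit estimation, the
two-group log-rank test, Harrell's concordance index and the
Benjamini–Hochberg step-up adjustment.  All times are in months and must
be strictly positive; events are coded 0 = censored, 1 = progressed/died.

The implementations are exact (no subsampling); every routine is
deterministic.  Fits serialize to plain dictionaries suitable for JSON.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "NOT_REACHED",
    "SurvivalData",
    "CoxFit",
    "KMCurve",
    "cox_partial_loglik",
    "cox_gradient",
    "fit_coxph",
    "km_estimate",
    "logrank_test",
    "concordance_index",
    "bh_adjust",
]

#: Sentinel for a Kaplan–Meier median that is never crossed.
NOT_REACHED = float("inf")


@dataclass
class SurvivalData:
    """Right-censored survival outcomes with a covariate matrix.

    time
        Event/censoring times in months, strictly positive.
    event
        1 if the endpoint was observed, 0 if right-censored.
    covariates
        n x p design matrix (no missing values; missingness is resolved
        upstream by complete-case filtering).
    names
        Column names of the design matrix.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.shape[0]:
            self.covariates = self.covariates.T
        n = self.time.shape[0]
        if n < 2:
            raise ValueError("survival data needs at least 2 observations")
        if np.any(self.time <= 0):
            raise ValueError("all survival times must be > 0")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event indicators must be 0 or 1")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows must match number of observations")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing/non-finite values")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.covariates.shape[1])]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_p: np.ndarray
    loglik_at_solution: float
    converged: bool
    n_iterations: int
    ties_method: str
    names: list[str]

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        """95% confidence interval of the hazard ratios (Wald, log scale)."""
        z = stats.norm.ppf(0.975)
        lo = np.exp(self.coefficients - z * self.standard_errors)
        hi = np.exp(self.coefficients + z * self.standard_errors)
        return lo, hi

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("coefficients", "standard_errors", "wald_p"):
            d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit curve."""

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    median: float

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        """S(t) as a right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _sorted_view(data: SurvivalData):
    """Time-ascending view with tie bookkeeping.

    Returns (order, ts, ev, Xs, first, etimes, d, f) where ``first``
    maps each sorted position to the first index of its tied-time block
    (risk sets are suffixes starting there), ``etimes`` are distinct
    event times with multiplicities ``d`` and first indices ``f``.
    """
    order = np.argsort(data.time, kind="stable")
    ts = data.time[order]
    ev = data.event[order]
    Xs = data.covariates[order]
    first = np.searchsorted(ts, ts, side="left")
    etimes, d = np.unique(ts[ev == 1], return_counts=True)
    f = np.searchsorted(ts, etimes, side="left")
    return order, ts, ev, Xs, first, etimes, d, f


def cox_partial_loglik(
    beta: np.ndarray,
    data: SurvivalData,
    ties: str = "efron",
) -> float:
    """Exact Cox partial log-likelihood at ``beta``.

    Efron (default) or Breslow handling of tied event times.  The value
    is the full-sample partial log-likelihood, not normalized.
    Vectorized over risk sets via suffix sums; Efron corrections touch
    only the tied event-time blocks.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    if beta.shape[0] != data.covariates.shape[1]:
        raise ValueError("beta length must match number of covariates")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")

    _, ts, ev, Xs, _, etimes, d, f = _sorted_view(data)
    eta = Xs @ beta
    c = eta.max()  # subtracted for overflow safety; cancels in the ratio
    w = np.exp(eta - c)
    s0 = np.cumsum(w[::-1])[::-1]

    ll = float(eta[ev == 1].sum()) - float(ev.sum()) * 0.0
    if ties == "breslow":
        ll -= float((d * (np.log(s0[f]) + c)).sum())
    else:
        single = d == 1
        ll -= float((np.log(s0[f[single]]) + c).sum())
        for t, dd, ff in zip(etimes[~single], d[~single], f[~single]):
            tied = (ts == t) & (ev == 1)
            s_tied = w[tied].sum()
            ell = np.arange(dd)
            ll -= float(np.log(s0[ff] - (ell / dd) * s_tied).sum()) + dd * c
    return ll


def cox_gradient(
    beta: np.ndarray,
    data: SurvivalData,
    ties: str = "efron",
):
    """Gradient and observed information of the partial log-likelihood."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    _, ts, ev, Xs, _, etimes, d, f = _sorted_view(data)
    p = Xs.shape[1]
    eta = Xs @ beta
    c = eta.max()
    w = np.exp(eta - c)

    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    xxw = w[:, None, None] * Xs[:, :, None] * Xs[:, None, :]
    s2 = np.cumsum(xxw[::-1], axis=0)[::-1]

    grad = Xs[ev == 1].sum(axis=0)
    info = np.zeros((p, p))
    if ties == "breslow":
        mu = s1[f] / s0[f, None]
        grad = grad - (d[:, None] * mu).sum(axis=0)
        info = (
            d[:, None, None] * (s2[f] / s0[f, None, None]
                                - mu[:, :, None] * mu[:, None, :])
        ).sum(axis=0)
    else:
        single = d == 1
        fs = f[single]
        if fs.size:
            mu = s1[fs] / s0[fs, None]
            grad = grad - mu.sum(axis=0)
            info = (
                s2[fs] / s0[fs, None, None] - mu[:, :, None] * mu[:, None, :]
            ).sum(axis=0)
        for t, dd, ff in zip(etimes[~single], d[~single], f[~single]):
            tied = (ts == t) & (ev == 1)
            wd = w[tied]
            Xd = Xs[tied]
            s0d = wd.sum()
            s1d = wd @ Xd
            s2d = (Xd * wd[:, None]).T @ Xd
            for ell in range(dd):
                frac = ell / dd
                s0e = s0[ff] - frac * s0d
                s1e = s1[ff] - frac * s1d
                s2e = s2[ff] - frac * s2d
                mu = s1e / s0e
                grad = grad - mu
                info = info + s2e / s0e - np.outer(mu, mu)
    return grad, info


def fit_coxph(
    data: SurvivalData,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Newton–Raphson maximum partial likelihood with step-halving.

    Standard errors come from the inverse observed information at the
    solution; Wald p-values are two-sided normal.

    Raises on degenerate (constant) covariates and on a singular
    information matrix (e.g. duplicated columns); monotone likelihood
    (separation) yields ``converged=False`` with a warning rather than
    an exception.
    """
    X = data.covariates
    if data.n_events < 1:
        raise ValueError("need at least one event to fit a Cox model")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"degenerate covariate {data.names[j]!r} (constant)")

    p = X.shape[1]
    beta = np.zeros(p)
    ll = cox_partial_loglik(beta, data, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, info = cox_gradient(beta, data, ties)
        if np.linalg.norm(grad, ord=np.inf) <= tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular information matrix (collinear covariates?)"
            ) from e
        cond = np.linalg.cond(info)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "singular information matrix (collinear covariates?)"
            )
        # step-halving line search on the partial likelihood
        alpha = 1.0
        for _ in range(40):
            cand = beta + alpha * step
            ll_new = cox_partial_loglik(cand, data, ties)
            if ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        ll = cox_partial_loglik(beta, data, ties)
        if np.linalg.norm(beta, ord=np.inf) > 50:
            warnings.warn(
                "monotone partial likelihood (separation); "
                "coefficients diverging, fit flagged non-converged",
                RuntimeWarning,
                stacklevel=2,
            )
            break

    if not converged:
        grad, info = cox_gradient(beta, data, ties)
        converged = bool(np.linalg.norm(grad, ord=np.inf) <= tol)
        if not converged:
            warnings.warn("Cox fit did not converge", RuntimeWarning, stacklevel=2)
    if converged and np.linalg.norm(beta, ord=np.inf) > 15:
        # gradient can vanish along a monotone likelihood; |beta| this large
        # means hazard ratios beyond e^15 — treat as separation
        converged = False
        warnings.warn(
            "monotone partial likelihood (separation); coefficients diverging, "
            "fit flagged non-converged",
            RuntimeWarning,
            stacklevel=2,
        )

    _, info = cox_gradient(beta, data, ties)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(
        coefficients=beta,
        standard_errors=se,
        wald_p=pvals,
        loglik_at_solution=float(cox_partial_loglik(beta, data, ties)),
        converged=converged,
        n_iterations=it,
        ties_method=ties,
        names=list(data.names),
    )


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Events precede censorings at equal times (the standard convention),
    so a patient censored at an event time is still at risk for it.  The
    median is the smallest event time t with S(t) <= 0.5, or
    ``NOT_REACHED`` when the curve never drops that far.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size < 1:
        raise ValueError("need at least one observation")
    if np.any(time <= 0):
        raise ValueError("all survival times must be > 0")

    etimes = np.unique(time[event == 1])
    surv, at_risk = [], []
    s = 1.0
    for t in etimes:
        n_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    surv_arr = np.asarray(surv)
    below = np.flatnonzero(surv_arr <= 0.5 + 1e-12)
    median = float(etimes[below[0]]) if below.size else NOT_REACHED
    return KMCurve(
        event_times=etimes,
        survival=surv_arr,
        n_at_risk=np.asarray(at_risk, dtype=int),
        median=median,
    )


def logrank_test(time, event, group) -> dict:
    """Two-group log-rank test with hypergeometric variance.

    Returns ``{"chi2": ..., "p": ...}`` with a chi-square(1) reference.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("log-rank test requires exactly two non-empty groups")
    g1 = group == levels[0]

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return {"chi2": 0.0, "p": 1.0}
    chi2 = o_minus_e**2 / var
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, df=1))}


def concordance_index(risk, time, event) -> float:
    """Harrell's C.

    Comparable pairs (i, j): time_i < time_j and event_i = 1.  A pair is
    concordant when risk_i > risk_j; ties in risk credit 0.5.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = risk.shape[0]
    if n < 2:
        raise ValueError("need at least two patients")
    if event.sum() < 1:
        raise ValueError("need at least one event")

    # pairwise, vectorized: rows i with event, columns j with time_j > time_i
    lt = time[:, None] < time[None, :]
    comparable = lt & (event[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = comparable & (risk[:, None] > risk[None, :])
    tied = comparable & (risk[:, None] == risk[None, :])
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty(m)
    q[order] = q_sorted
    return q
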