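"""Survival statistics used to score copy-number classifications.

Kaplan-Meier product-limit estimation and the log-rank test are delegated to
lifelines.  Cox proportional-hazards regression is implemented directly as a
Newton-Raphson maximization of the Breslow partial likelihood, reporting
hazard ratios with Wald standard errors and confidence intervals; an
independence check compares univariate and bivariate log hazard ratios, the
criterion used to argue that a copy-number classification predicts survival
independently of standard clinical indicators such as tumor stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "kaplan_meier",
    "logrank",
    "cox",
    "independence_check",
    "KaplanMeierEstimate",
    "LogrankResult",
    "CoxResults",
    "CoxConvergenceError",
]


class CoxConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (non-convergence/separation)."""


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit survival curve with its median.

    ``median`` is the earliest time at which the curve is <= 0.5 and is NaN
    (with ``median_defined`` False) when the curve never reaches 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    median_defined: bool

    def at(self, t: float) -> float:
        """Survival probability at time ``t`` (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int


def _validate_te(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival data")
    if t.size != e.size:
        raise ValueError("time and event must be aligned")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    return t, e


def kaplan_meier(time, event) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimate with median survival time."""
    t, e = _validate_te(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    defined = np.isfinite(median)
    return KaplanMeierEstimate(
        times=times, survival=surv, median=median if defined else float("nan"),
        median_defined=bool(defined),
    )


def logrank(time, event, group) -> LogrankResult:
    """k-sample log-rank test (chi-square with k-1 degrees of freedom)."""
    t, e = _validate_te(time, event)
    g = np.asarray(group)
    if g.size != t.size:
        raise ValueError("group must be aligned with time/event")
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least two nonempty groups")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(levels) - 1,
    )


def _breslow_loglik(beta, X, order_t, order_e):
    """Breslow partial log-likelihood with gradient and Hessian.

    ``X`` is sorted by ascending time; risk-set sums are suffix sums over
    blocks of tied times.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    r = np.exp(eta)
    rX = r[:, None] * X
    rXX = np.einsum("i,ij,ik->ijk", r, X, X)
    # suffix sums
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rX[::-1], axis=0)[::-1]
    S2 = np.cumsum(rXX[::-1], axis=0)[::-1]
    # risk set at an event time includes everyone with the same (tied) time:
    # map each index to the first index of its tie block.
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if order_t[i] == order_t[i - 1] else i
    ev = np.flatnonzero(order_e)
    fb = first[ev]
    ll = float(np.sum(eta[ev] - np.log(S0[fb])))
    grad = X[ev].sum(axis=0) - (S1[fb] / S0[fb, None]).sum(axis=0)
    mean = S1[fb] / S0[fb, None]
    hess = -(
        (S2[fb] / S0[fb, None, None]).sum(axis=0)
        - np.einsum("ij,ik->jk", mean, mean)
    )
    return ll, grad, hess


@dataclass
class CoxResults:
    """Fitted Cox model: coefficients, hazard ratios, Wald errors and CIs."""

    params: pd.Series
    bse: pd.Series
    n: int
    n_events: int
    loglik: float

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "hr_lower": np.exp(self.params - z * self.bse),
                "hr_upper": np.exp(self.params + z * self.bse),
            }
        )

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "hazard_ratio": self.hazard_ratios,
                "se": self.bse,
                "hr_lower95": ci["hr_lower"],
                "hr_upper95": ci["hr_upper"],
            }
        )


def cox(time, event, covariates, max_iter: int = 100, tol: float = 1e-9) -> CoxResults:
    """Cox proportional-hazards fit (Newton-Raphson, Breslow tie handling).

    ``covariates`` may be a 1-D vector, a 2-D array, or a DataFrame (column
    names become covariate names).  Raises :class:`CoxConvergenceError` on
    non-convergence within ``max_iter`` iterations or on the diverging
    coefficients typical of complete separation.
    """
    t, e = _validate_te(time, event)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    if X.shape[0] != t.size:
        raise ValueError("covariates must be aligned with time/event")
    if not e.any():
        raise ValueError("no events observed; partial likelihood undefined")
    if np.any(np.ptp(X, axis=0) == 0):
        j = int(np.flatnonzero(np.ptp(X, axis=0) == 0)[0])
        raise ValueError(f"covariate '{names[j]}' is constant")

    # center for conditioning (does not change beta)
    Xc = X - X.mean(axis=0)
    order = np.argsort(t, kind="stable")
    Xs, ts, es = Xc[order], t[order], e[order]

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik(beta, Xs, ts, es)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise CoxConvergenceError(f"singular Hessian: {err}") from err
        beta_new = beta - step
        # step-halving if the likelihood does not improve
        for _h in range(30):
            ll_new = _breslow_loglik(beta_new, Xs, ts, es)[0]
            if ll_new >= ll - 1e-12:
                break
            beta_new = (beta + beta_new) / 2
        # monotone partial likelihood (complete separation) drives |beta| off
        # to infinity while the likelihood plateaus; exp(15) is far beyond any
        # interpretable hazard ratio
        if np.any(np.abs(beta_new) > 15):
            raise CoxConvergenceError(
                "coefficients diverging; likely complete separation"
            )
        converged = np.max(np.abs(beta_new - beta)) < tol or abs(ll_new - ll_old) < tol * (
            abs(ll_old) + 1.0
        )
        beta, ll_old = beta_new, ll_new
        if converged:
            break
    else:
        raise CoxConvergenceError(f"no convergence in {max_iter} iterations")

    _, _, hess = _breslow_loglik(beta, Xs, ts, es)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CoxResults(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        n=int(t.size),
        n_events=int(e.sum()),
        loglik=ll_old,
    )


def independence_check(
    uni: pd.Series, bi: pd.Series, tol: float = 0.25
) -> pd.Series:
    """Whether jointly fitted hazard ratios resemble the separately fitted ones.

    For each covariate: True iff
    ``|log HR_bi - log HR_uni| <= tol * |log HR_uni|``.  Two predictors whose
    hazard ratios barely move when fitted jointly carry independent prognostic
    information.  ``uni`` and ``bi`` are hazard-ratio series over the same
    covariates.
    """
    uni = pd.Series(uni, dtype=float)
    bi = pd.Series(bi, dtype=float)
    if set(uni.index) != set(bi.index):
        raise ValueError("univariate and bivariate fits cover different covariates")
    bi = bi.reindex(uni.index)
    lu, lb = np.log(uni), np.log(bi)
    return (np.abs(lb - lu) <= tol * np.abs(lu)).astype(bool)
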