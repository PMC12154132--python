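"""Survival primitives: right-continuous step functions, Kaplan-Meier with
Greenwood bands, and weighted Cox partial-likelihood fitting with a Breslow
baseline.

These are the building blocks for the mixture cure model: the EM algorithm
needs a Cox fit that accepts fractional case weights (posterior probabilities
of being uncured) in both the event terms and the risk sets, with a baseline
hazard estimator that uses the same weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepFunction",
    "KMResult",
    "CoxFit",
    "km_estimate",
    "cox_fit",
]


@dataclass
class StepFunction:
    """A right-continuous step function.

    The function takes ``initial_value`` on ``(-inf, knots[0])`` and
    ``values[i]`` on ``[knots[i], knots[i+1])``; evaluation *at* a knot
    returns the post-jump value.
    """

    knots: np.ndarray
    values: np.ndarray
    initial_value: float = 1.0

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.knots.ndim != 1 or self.values.shape != self.knots.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if self.knots.size > 1 and not np.all(np.diff(self.knots) > 0):
            raise ValueError("knots must be strictly increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        padded = np.concatenate([[self.initial_value], self.values])
        out = padded[idx + 1]
        return out if out.ndim else float(out)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.knots, "value": self.values})


@dataclass
class KMResult:
    """Kaplan-Meier product-limit estimate with linear Greenwood bands."""

    survival: StepFunction
    lower: StepFunction
    upper: StepFunction
    conf_level: float
    n_events: int
    n_subjects: int


def km_estimate(times, events, conf_level: float = 0.95) -> KMResult:
    """Product-limit survival estimate with Greenwood-variance confidence
    bands on the plain (linear) scale, clipped to [0, 1].

    Parameters
    ----------
    times, events
        Follow-up times (>= 0) and binary event indicators (1 = death).
    conf_level
        Two-sided confidence level for the Greenwood bands.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be binary")

    if events.sum() == 0:
        warnings.warn("all subjects censored: KM curve is identically 1", stacklevel=2)
        one = StepFunction(np.array([]), np.array([]), 1.0)
        return KMResult(one, one, one, conf_level, 0, times.size)

    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order].astype(int)
    event_times = np.unique(t[e == 1])
    # at risk just before each event time; deaths at each event time
    n_at_risk = t.size - np.searchsorted(t, event_times, side="left")
    d = np.array([int(e[t == et].sum()) for et in event_times])

    surv = np.cumprod(1.0 - d / n_at_risk)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(d / (n_at_risk * (n_at_risk - d)))
        var = surv**2 * gw
    var = np.where(np.isfinite(var), var, 0.0)
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf_level / 2.0)
    lo = np.clip(surv - z * np.sqrt(var), 0.0, 1.0)
    hi = np.clip(surv + z * np.sqrt(var), 0.0, 1.0)

    return KMResult(
        StepFunction(event_times, surv),
        StepFunction(event_times, lo),
        StepFunction(event_times, hi),
        conf_level,
        int(e.sum()),
        times.size,
    )


@dataclass
class CoxFit:
    """Weighted Cox proportional-hazards fit (Breslow ties and baseline)."""

    beta: np.ndarray
    covariate_names: list
    log_partial_likelihood: float
    baseline_survival: StepFunction
    baseline_cumhaz: StepFunction
    hazard_times: np.ndarray = field(repr=False)
    hazard_increments: np.ndarray = field(repr=False)
    n_iterations: int = 0
    converged: bool = False

    def linear_predictor(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta


def _breslow_quantities(t_sorted, e_sorted, w_sorted, eta_sorted, X_sorted):
    """Log partial likelihood, gradient and Hessian for weighted Breslow ties.

    Arrays must be sorted by ascending time.  Linear predictors are centred
    by the caller before exponentiation.
    """
    r = w_sorted * np.exp(eta_sorted)
    # reverse cumulative sums: S0[i] = sum_{j >= i} r_j (risk set of t_i)
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((r[:, None] * X_sorted)[::-1], axis=0)[::-1]
    s2 = np.cumsum(np.einsum("i,ij,ik->ijk", r, X_sorted, X_sorted)[::-1], axis=0)[::-1]
    # risk set for an event at time t starts at the first index with that time
    first = np.searchsorted(t_sorted, t_sorted, side="left")
    ev = e_sorted == 1
    fi = first[ev]
    we = w_sorted[ev]
    s0e = s0[fi]
    ll = float(np.sum(we * (eta_sorted[ev] - np.log(s0e))))
    mean1 = s1[fi] / s0e[:, None]
    grad = np.sum(we[:, None] * (X_sorted[ev] - mean1), axis=0)
    hess = -np.einsum("i,ijk->jk", we, s2[fi] / s0e[:, None, None]) + np.einsum(
        "i,ij,ik->jk", we, mean1, mean1
    )
    return ll, grad, hess, s0, first


def cox_fit(
    X,
    times,
    events,
    weights=None,
    beta0=None,
    max_iter: int = 100,
    tol_ll: float = 1e-9,
    tol_grad: float = 1e-6,
) -> CoxFit:
    """Newton-Raphson maximizer of the weighted Breslow-tie partial
    likelihood, with step-halving, followed by the weighted Breslow baseline.

    Subjects with zero weight drop out of both the event terms and the risk
    sets; the baseline cumulative hazard uses the same weights, so the fit is
    internally consistent with the EM posterior-weighting scheme.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.isnan(X)) or np.any(np.isnan(times)):
        raise ValueError("missing values in design or times")
    if float(w[events == 1].sum()) <= 0:
        raise ValueError("needs at least one event with positive weight")
    names = [f"x{j}" for j in range(p)]

    order = np.argsort(times, kind="stable")
    ts, es, ws, Xs = times[order], events[order], w[order], X[order]

    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)

    def evaluate(b):
        eta = Xs @ b
        eta_c = eta - np.average(eta, weights=ws) if ws.sum() > 0 else eta
        return _breslow_quantities(ts, es, ws, eta_c, Xs), eta - eta_c

    (ll, grad, hess, s0, first), shift = evaluate(beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol_grad:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving: accept only likelihood-non-decreasing updates
        accepted = False
        for _ in range(30):
            cand = beta + step
            (ll_new, grad_new, hess_new, s0_new, _), shift = evaluate(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * (1 + abs(ll)):
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        rel = abs(ll_new - ll) / (1.0 + abs(ll))
        beta, ll, grad, hess, s0 = cand, ll_new, grad_new, hess_new, s0_new
        if rel < tol_ll or np.max(np.abs(grad)) < tol_grad:
            converged = True
            break
    if np.max(np.abs(beta)) > 50:
        warnings.warn(
            "diverging coefficients: possible monotone likelihood (separation)",
            stacklevel=2,
        )
        converged = False
    if not converged:
        warnings.warn("cox_fit did not converge", stacklevel=2)

    # Breslow baseline at beta-hat
    eta = Xs @ beta
    c = np.average(eta, weights=ws)
    r = ws * np.exp(eta - c)
    s0 = np.cumsum(r[::-1])[::-1]
    first = np.searchsorted(ts, ts, side="left")
    ev_times = np.unique(ts[es == 1])
    fi = np.searchsorted(ts, ev_times, side="left")
    d_t = np.array([float(ws[(ts == et) & (es == 1)].sum()) for et in ev_times])
    dlam = d_t / s0[fi] * np.exp(-c)
    cumhaz = np.cumsum(dlam)
    base_surv = np.exp(-cumhaz)

    # uncentred partial likelihood value
    ll_true = ll  # centring constant cancels: ll computed with centred eta equals true value

    return CoxFit(
        beta=beta,
        covariate_names=names,
        log_partial_likelihood=ll_true,
        baseline_survival=StepFunction(ev_times, base_surv),
        baseline_cumhaz=StepFunction(ev_times, cumhaz, initial_value=0.0),
        hazard_times=ev_times,
        hazard_increments=dlam,
        n_iterations=n_iter,
        converged=converged,
    )
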