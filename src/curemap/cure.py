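"""Semiparametric mixture cure model (MCM) fitted by EM.

The population survival for covariates (x, z) is

    S(t; x, z) = pi(z) * S0(t)^exp(beta' x) + 1 - pi(z)

where pi(z) = expit(b'z) is the *incidence* (probability of being uncured)
and S0(t)^exp(beta'x) is the *latency* (proportional-hazards survival of the
uncured, Breslow baseline).  The E-step computes the posterior probability of
being uncured for each censored subject; the M-step is a weighted logistic
regression for b and a weighted Cox partial likelihood for beta.  A zero-tail
constraint (S0 = 0 beyond the largest event time) makes the cure fraction
identifiable.  Standard errors come from nonparametric subject-level
bootstrap resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .survival import CoxFit, StepFunction, cox_fit

__all__ = [
    "MCMFit",
    "MCMStdErrors",
    "incidence_probability",
    "mcm_survival",
    "mcm_fit",
    "bootstrap_se",
    "wald_z",
    "save_fit",
    "load_fit",
]


@dataclass
class MCMFit:
    b: np.ndarray
    b_names: list
    beta: np.ndarray
    beta_names: list
    baseline_survival: StepFunction  # zero-tail completed
    posterior_uncured: np.ndarray
    n_em_iterations: int
    converged: bool
    loglik_trace: np.ndarray
    monotone: bool = True

    def incidence(self, Z) -> np.ndarray:
        return incidence_probability(self.b, Z)

    def latency_survival(self, X, t):
        """S(t; x) = S0(t)^exp(beta'x) for each row of X at each t."""
        theta = np.exp(np.asarray(X, dtype=float) @ self.beta)
        s0 = np.atleast_1d(self.baseline_survival(t))
        return s0[None, :] ** theta[:, None]


@dataclass
class MCMStdErrors:
    se_b: np.ndarray
    se_beta: np.ndarray
    n_bootstrap: int
    n_failed: int
    seed: int


def incidence_probability(b, z):
    """pi(z) = exp(b'z) / (1 + exp(b'z)), the probability of being uncured."""
    b = np.asarray(b, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != b.shape[0]:
        raise ValueError("dimension mismatch between b and z")
    lp = z @ b
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-lp))


def mcm_survival(fit: MCMFit, x, z, t):
    """Population survival S(t; x, z) for one covariate profile.

    Bounded below by the cure fraction 1 - pi(z); equal to it beyond the
    largest event time because of the zero-tail constraint.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    pi = float(incidence_probability(fit.b, np.asarray(z, dtype=float)))
    theta = float(np.exp(np.asarray(x, dtype=float) @ fit.beta))
    s0 = fit.baseline_survival(t)
    return pi * s0**theta + 1.0 - pi


def _zero_tail(base: StepFunction) -> StepFunction:
    """Append a jump to 0 just beyond the last event-time knot."""
    if base.knots.size == 0:
        return base
    t_last = base.knots[-1]
    eps_knot = np.nextafter(t_last, np.inf)
    return StepFunction(
        np.concatenate([base.knots, [eps_knot]]),
        np.concatenate([base.values, [0.0]]),
        base.initial_value,
    )


def _weighted_logistic(Z, w, start=None):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(w, Z, family=sm.families.Binomial())
        res = model.fit(start_params=start, maxiter=200)
    return np.asarray(res.params)


def _observed_loglik(b, beta, cox: CoxFit, Z, X, times, events):
    """Nonparametric observed-data log-likelihood of the fitted MCM."""
    pi = incidence_probability(b, Z)
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    eta = X @ beta
    cumhaz = np.asarray(cox.baseline_cumhaz(times))
    ev = events == 1
    ll = 0.0
    if ev.any():
        # hazard increment at each event's own time
        idx = np.searchsorted(cox.hazard_times, times[ev])
        dlam = cox.hazard_increments[np.clip(idx, 0, len(cox.hazard_increments) - 1)]
        dlam = np.maximum(dlam, 1e-300)
        ll += float(
            np.sum(
                np.log(pi[ev]) + np.log(dlam) + eta[ev] - cumhaz[ev] * np.exp(eta[ev])
            )
        )
    cs = ~ev
    if cs.any():
        t_last = cox.hazard_times[-1]
        su = np.where(
            times[cs] > t_last, 0.0, np.exp(-cumhaz[cs] * np.exp(eta[cs]))
        )
        ll += float(np.sum(np.log(pi[cs] * su + 1.0 - pi[cs])))
    return ll


def mcm_fit(
    latency_design,
    incidence_design,
    times,
    events,
    max_em_iter: int = 500,
    coef_tol: float = 1e-6,
    force_uncured: bool = False,
    init_b=None,
    init_beta=None,
    cox_options: dict | None = None,
) -> MCMFit:
    """Fit the mixture cure model by EM.

    Parameters
    ----------
    latency_design
        Covariate matrix x for the proportional-hazards latency part
        (no intercept, no constant columns).
    incidence_design
        Covariate matrix z for the logistic incidence part; must contain an
        intercept column.
    force_uncured
        Pin pi == 1 (every posterior weight 1): the model degenerates to a
        plain Cox fit of the latency part, used for equivalence checks.

    Notes
    -----
    Initialization: b from a logistic regression of the event indicator on z,
    beta from a plain Cox fit on all subjects.  Convergence when the damped
    relative change |delta| / (1 + |old|) of every coefficient falls below
    ``coef_tol``.  The observed-data log-likelihood trace is recorded each
    iteration and checked for monotonicity.
    """
    X = np.asarray(latency_design, dtype=float)
    Z = np.asarray(incidence_design, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if X.ndim == 1:
        X = X[:, None]
    if events.sum() == 0:
        raise ValueError("mcm_fit requires at least one event")
    if X.shape[0] != Z.shape[0] or X.shape[0] != times.size:
        raise ValueError("designs and outcomes must be aligned")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("latency design contains a constant column")
    if not np.any(np.all(Z == 1.0, axis=0)):
        raise ValueError("incidence design must include an intercept column")
    copts = dict(cox_options or {})

    # init: logistic of event on z; Cox on everyone
    b = (
        np.asarray(init_b, dtype=float)
        if init_b is not None
        else _weighted_logistic(Z, events.astype(float))
    )
    cox = cox_fit(X, times, events, beta0=init_beta, **copts)
    beta = cox.beta

    w = np.ones(len(times), dtype=float)
    trace = []
    converged = False
    monotone = True
    n_iter = 0
    for n_iter in range(1, max_em_iter + 1):
        # E-step
        if force_uncured:
            w = np.ones(len(times), dtype=float)
        else:
            pi = np.clip(incidence_probability(b, Z), 1e-12, 1 - 1e-12)
            base0 = _zero_tail(cox.baseline_survival)
            su = np.asarray(base0(times)) ** np.exp(X @ beta)
            num = pi * su
            w = np.where(events == 1, 1.0, num / (num + 1.0 - pi))
        # M-step
        b_new = b if force_uncured else _weighted_logistic(Z, w, start=b)
        cox = cox_fit(X, times, events, weights=w, beta0=beta, **copts)
        beta_new = cox.beta

        ll = _observed_loglik(b_new, beta_new, cox, Z, X, times, events)
        if trace and ll < trace[-1] - 1e-8 * (1.0 + abs(trace[-1])):
            monotone = False
        trace.append(ll)

        delta = max(
            np.max(np.abs(b_new - b) / (1.0 + np.abs(b))),
            np.max(np.abs(beta_new - beta) / (1.0 + np.abs(beta))),
        )
        b, beta = b_new, beta_new
        if force_uncured or delta < coef_tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM did not converge within max_em_iter", stacklevel=2)
    if not monotone:
        warnings.warn("observed-data log-likelihood decreased during EM", stacklevel=2)

    return MCMFit(
        b=b,
        b_names=[f"z{j}" for j in range(Z.shape[1])],
        beta=beta,
        beta_names=[f"x{j}" for j in range(X.shape[1])],
        baseline_survival=_zero_tail(cox.baseline_survival),
        posterior_uncured=w,
        n_em_iterations=n_iter,
        converged=converged,
        loglik_trace=np.asarray(trace),
        monotone=monotone,
    )


def bootstrap_se(
    latency_design,
    incidence_design,
    times,
    events,
    n_bootstrap: int = 100,
    seed: int = 0,
    fit_options: dict | None = None,
) -> MCMStdErrors:
    """Nonparametric subject-level bootstrap standard errors for (b, beta).

    Resamples failing to converge are dropped and counted; more than 50%
    failures raises.  Same seed, same SEs.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be at least 2")
    X = np.asarray(latency_design, dtype=float)
    Z = np.asarray(incidence_design, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    opts = dict(fit_options or {})
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = times.size
    # warm start at the full-data estimates
    full = mcm_fit(X, Z, times, events, **opts)
    bs_b, bs_beta = [], []
    failed = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = mcm_fit(
                    X[idx],
                    Z[idx],
                    times[idx],
                    events[idx],
                    init_b=full.b,
                    init_beta=full.beta,
                    **opts,
                )
            if not fit.converged:
                failed += 1
                continue
            bs_b.append(fit.b)
            bs_beta.append(fit.beta)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
    if failed > n_bootstrap / 2:
        raise RuntimeError(f"{failed}/{n_bootstrap} bootstrap resamples failed")
    se_b = np.std(np.asarray(bs_b), axis=0, ddof=1)
    se_beta = np.std(np.asarray(bs_beta), axis=0, ddof=1)
    return MCMStdErrors(se_b, se_beta, n_bootstrap, failed, seed)


def wald_z(fit: MCMFit, ses: MCMStdErrors):
    """Per-coefficient Wald z = estimate / SE for both model parts.

    Zero SEs yield NaN with a warning (undefined z flagged, not fabricated).
    """
    if np.any(ses.se_b == 0) or np.any(ses.se_beta == 0):
        warnings.warn("zero bootstrap SE: z undefined for that coefficient", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_b = np.where(ses.se_b > 0, fit.b / ses.se_b, np.nan)
        z_beta = np.where(ses.se_beta > 0, fit.beta / ses.se_beta, np.nan)
    return z_b, z_beta


def save_fit(fit: MCMFit, path, b_names=None, beta_names=None) -> None:
    """Serialize a fit to a plain-text key=value file for scoring reuse."""
    bn = list(b_names or fit.b_names)
    xn = list(beta_names or fit.beta_names)
    lines = ["[incidence]"]
    lines += [f"{nm}={float(v)!r}" for nm, v in zip(bn, fit.b)]
    lines.append("[latency]")
    lines += [f"{nm}={float(v)!r}" for nm, v in zip(xn, fit.beta)]
    lines.append("[meta]")
    lines.append(f"n_em_iterations={fit.n_em_iterations}")
    lines.append(f"converged={int(fit.converged)}")
    lines.append("[baseline]")
    lines += [
        f"{float(t)!r},{float(s)!r}"
        for t, s in zip(fit.baseline_survival.knots, fit.baseline_survival.values)
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_fit(path) -> MCMFit:
    section = None
    b, bn, beta, xn, knots, vals = [], [], [], [], [], []
    meta = {"n_em_iterations": 0, "converged": 1}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]")
            elif section == "incidence":
                nm, v = line.split("=")
                bn.append(nm)
                b.append(float(v))
            elif section == "latency":
                nm, v = line.split("=")
                xn.append(nm)
                beta.append(float(v))
            elif section == "meta":
                nm, v = line.split("=")
                meta[nm] = int(v)
            elif section == "baseline":
                t, s = line.split(",")
                knots.append(float(t))
                vals.append(float(s))
    return MCMFit(
        b=np.asarray(b),
        b_names=bn,
        beta=np.asarray(beta),
        beta_names=xn,
        baseline_survival=StepFunction(np.asarray(knots), np.asarray(vals)),
        posterior_uncured=np.array([]),
        n_em_iterations=meta["n_em_iterations"],
        converged=bool(meta["converged"]),
        loglik_trace=np.array([]),
    )
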