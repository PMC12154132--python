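"""Censoring-aware concordance with tie splitting, ordinary-jackknife
standard errors, event-stratified Monte-Carlo cross-validation, and the
entire-vs-region model comparison on Cox surrogates.

Pair semantics: risks live on the linear-predictor scale (higher risk =
shorter expected survival).  A pair is comparable iff the two observed times
differ and the subject with the smaller time experienced the event — a
censored time only certifies survival beyond itself.  The concordance
estimate splits risk ties:

    C = (c + t_y/2) / (c + d + t_y)

with c, d, t_y the concordant, discordant and risk-tied comparable pairs.
Pairs with equal observed times (including two tied event times) are not
comparable under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import cox_fit

__all__ = [
    "ConcordanceResult",
    "MCCVResult",
    "concordance",
    "jackknife_se",
    "mccv",
    "compare_entire_vs_regions",
]


@dataclass
class ConcordanceResult:
    concordant: int
    discordant: int
    tied_risk: int
    comparable_pairs: int
    C: float
    se_jackknife: float | None = None


@dataclass
class MCCVResult:
    samples: np.ndarray
    mean: float
    se: float
    ci: tuple
    train_fraction: float
    n_splits: int
    seed: int
    n_resampled_splits: int = 0


def _pair_counts(times, events, risks, chunk: int = 512):
    """Totals and per-subject counts of concordant / discordant / risk-tied
    comparable pairs.  O(n^2) in chunks; exact."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    r = np.asarray(risks, dtype=float)
    n = t.size
    ci = np.zeros(n)
    di = np.zeros(n)
    ti = np.zeros(n)
    # orient every comparable pair by its earlier subject i: t_i < t_j, e_i = 1
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        sl = slice(lo, hi)
        early = (t[sl, None] < t[None, :]) & (e[sl, None] == 1)
        conc = early & (r[sl, None] > r[None, :])
        disc = early & (r[sl, None] < r[None, :])
        tied = early & (r[sl, None] == r[None, :])
        ci[sl] += conc.sum(axis=1)
        di[sl] += disc.sum(axis=1)
        ti[sl] += tied.sum(axis=1)
        ci += conc.sum(axis=0)
        di += disc.sum(axis=0)
        ti += tied.sum(axis=0)
    # each pair was added once to each endpoint; totals halve the sums
    c = int(round(ci.sum() / 2))
    d = int(round(di.sum() / 2))
    ty = int(round(ti.sum() / 2))
    return c, d, ty, ci, di, ti


def concordance(times, events, risks) -> ConcordanceResult:
    """Concordance statistic with risk-tie splitting.

    Raises if no pair is comparable (C undefined).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    risks = np.asarray(risks, dtype=float)
    if not (times.size == events.size == risks.size):
        raise ValueError("times, events and risks must have equal length")
    c, d, ty, *_ = _pair_counts(times, events, risks)
    total = c + d + ty
    if total == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    return ConcordanceResult(c, d, ty, total, (c + ty / 2.0) / total)


def jackknife_se(times, events, risks) -> float:
    """Ordinary-jackknife standard error of the concordance.

    Leave-one-out values are obtained by removing subject i's pair
    contributions from the counts — no model refit.  Variance is
    (n-1)/n * sum_i (theta_(i) - theta_bar)^2.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 3:
        raise ValueError("jackknife needs at least 3 subjects")
    c, d, ty, ci, di, ti = _pair_counts(times, np.asarray(events), np.asarray(risks))
    total = c + d + ty
    if total == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    denom = total - (ci + di + ti)
    if np.any(denom <= 0):
        raise ValueError("degenerate jackknife: C undefined after a removal")
    theta_i = (c - ci + (ty - ti) / 2.0) / denom
    n = times.size
    var = (n - 1) / n * np.sum((theta_i - theta_i.mean()) ** 2)
    return float(np.sqrt(var))


def _stratified_split(events, train_fraction, rng):
    """Event-stratified index split; train counts per stratum are fixed by
    rounding, so every split matches the full event proportion to +/-1."""
    events = np.asarray(events).astype(int)
    train_idx, test_idx = [], []
    for val in (0, 1):
        idx = np.flatnonzero(events == val)
        idx = rng.permutation(idx)
        k = int(round(train_fraction * idx.size))
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def mccv(
    data: pd.DataFrame,
    fit_procedure,
    n_splits: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    conf_level: float = 0.95,
    event_col: str = "event",
    time_col: str = "time",
    max_resample: int = 20,
) -> MCCVResult:
    """Monte-Carlo cross-validation of test-set concordance.

    ``fit_procedure(train, test)`` must return risks (higher = worse) for the
    rows of ``test``.  Splits are stratified by event status; a split whose
    test set has no events is redrawn and counted.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = []
    resampled = 0
    for _ in range(n_splits):
        for _attempt in range(max_resample):
            tr, te = _stratified_split(data[event_col].to_numpy(), train_fraction, rng)
            test = data.iloc[te]
            if test[event_col].sum() > 0:
                break
            resampled += 1
        else:
            raise RuntimeError("could not draw a test split with events")
        train = data.iloc[tr]
        risks = np.asarray(fit_procedure(train, test), dtype=float)
        res = concordance(test[time_col].to_numpy(), test[event_col].to_numpy(), risks)
        samples.append(res.C)
    samples = np.asarray(samples)
    mean = float(samples.mean())
    se = float(samples.std(ddof=1) / np.sqrt(samples.size))
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf_level / 2.0)
    return MCCVResult(
        samples, mean, se, (mean - z * se, mean + z * se), train_fraction, n_splits, seed, resampled
    )


def compare_entire_vs_regions(
    data: pd.DataFrame,
    covariate_design,
    region_design=None,
    region_col: str = "region_id",
    time_col: str = "time",
    event_col: str = "event",
    n_splits: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    min_region_events: int = 5,
) -> pd.DataFrame:
    """Entire-based vs region-based Cox surrogate comparison.

    ``covariate_design(df)`` -> (matrix, names) builds the shared covariates;
    ``region_design(df)`` (optional) -> (matrix, names) builds region dummy
    columns that are appended only for the entire-data model, mirroring the
    convention that the region covariate is dropped from region-based fits.

    Returns one row per (region, scheme) plus an 'entire' region whose two
    schemes coincide by construction.  Each row carries the full-data
    concordance, its jackknife SE, and MCCV mean/SE/CI.
    """
    data = data.reset_index(drop=True)
    regions = sorted(data[region_col].unique())

    def entire_design(df):
        X, _ = covariate_design(df)
        if region_design is not None:
            R, _ = region_design(df)
            X = np.column_stack([X, R])
        return X

    def region_only_design(df):
        X, _ = covariate_design(df)
        return X

    t_all = data[time_col].to_numpy()
    e_all = data[event_col].to_numpy()
    fit_entire = cox_fit(entire_design(data), t_all, e_all)
    risks_entire = fit_entire.linear_predictor(entire_design(data))

    rows = []

    def _mccv_risks_entire(train, test):
        f = cox_fit(entire_design(train), train[time_col].to_numpy(), train[event_col].to_numpy())
        return f.linear_predictor(entire_design(test))

    # 'entire' row: the same model under either scheme
    res = concordance(t_all, e_all, risks_entire)
    se_jk = jackknife_se(t_all, e_all, risks_entire)
    mc = mccv(
        data, _mccv_risks_entire, n_splits=n_splits, train_fraction=train_fraction, seed=seed,
        event_col=event_col, time_col=time_col,
    )
    for scheme in ("entire_model", "region_model"):
        rows.append(
            dict(
                region="entire", scheme=scheme, C=res.C, se_jackknife=se_jk,
                mccv_mean=mc.mean, mccv_se=mc.se, ci_low=mc.ci[0], ci_high=mc.ci[1],
                n=len(data), n_events=int(e_all.sum()), flagged="",
            )
        )

    for k, reg in enumerate(regions):
        sub = data[data[region_col] == reg].reset_index(drop=True)
        t_r = sub[time_col].to_numpy()
        e_r = sub[event_col].to_numpy()
        base = dict(region=reg, n=len(sub), n_events=int(e_r.sum()))
        if e_r.sum() < min_region_events:
            for scheme in ("entire_model", "region_model"):
                rows.append(
                    dict(
                        **base, scheme=scheme, C=np.nan, se_jackknife=np.nan,
                        mccv_mean=np.nan, mccv_se=np.nan, ci_low=np.nan, ci_high=np.nan,
                        flagged="too_few_events",
                    )
                )
            continue

        # scheme (a): entire-data model evaluated on this region's subjects
        mask = (data[region_col] == reg).to_numpy()
        r_ent = risks_entire[mask]
        res_a = concordance(t_r, e_r, r_ent)
        jk_a = jackknife_se(t_r, e_r, r_ent)

        def _mccv_entire_on_region(train, test, _reg=reg):
            f = cox_fit(
                entire_design(train), train[time_col].to_numpy(), train[event_col].to_numpy()
            )
            te = test[test[region_col] == _reg]
            if te[event_col].sum() == 0:
                return np.array([])
            return f.linear_predictor(entire_design(te))

        mc_a = _mccv_region_scheme(
            data, reg, region_col, _mccv_entire_on_region, n_splits, train_fraction,
            seed + 1000 + k, time_col, event_col,
        )

        # scheme (b): region-only model (region covariate excluded)
        fit_r = cox_fit(region_only_design(sub), t_r, e_r)
        r_reg = fit_r.linear_predictor(region_only_design(sub))
        res_b = concordance(t_r, e_r, r_reg)
        jk_b = jackknife_se(t_r, e_r, r_reg)

        def _mccv_region_only(train, test, _reg=reg):
            tr = train[train[region_col] == _reg]
            te = test[test[region_col] == _reg]
            if tr[event_col].sum() == 0 or te[event_col].sum() == 0:
                return np.array([])
            f = cox_fit(
                region_only_design(tr), tr[time_col].to_numpy(), tr[event_col].to_numpy()
            )
            return f.linear_predictor(region_only_design(te))

        mc_b = _mccv_region_scheme(
            data, reg, region_col, _mccv_region_only, n_splits, train_fraction,
            seed + 2000 + k, time_col, event_col,
        )

        for scheme, res_s, jk_s, mc_s in (
            ("entire_model", res_a, jk_a, mc_a),
            ("region_model", res_b, jk_b, mc_b),
        ):
            rows.append(
                dict(
                    **base, scheme=scheme, C=res_s.C, se_jackknife=jk_s,
                    mccv_mean=mc_s["mean"], mccv_se=mc_s["se"],
                    ci_low=mc_s["ci"][0], ci_high=mc_s["ci"][1], flagged="",
                )
            )
    cols = [
        "region", "scheme", "C", "se_jackknife", "mccv_mean", "mccv_se",
        "ci_low", "ci_high", "n", "n_events", "flagged",
    ]
    return pd.DataFrame(rows)[cols]


def _mccv_region_scheme(
    data, reg, region_col, risk_fn, n_splits, train_fraction, seed, time_col, event_col
):
    """MCCV where the test statistic is the concordance on one region's test
    subjects; splits are stratified on the full data."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = []
    attempts = 0
    while len(samples) < n_splits and attempts < n_splits * 20:
        attempts += 1
        tr, te = _stratified_split(data[event_col].to_numpy(), train_fraction, rng)
        train, test = data.iloc[tr], data.iloc[te]
        risks = np.asarray(risk_fn(train, test))
        if risks.size == 0:
            continue
        te_reg = test[test[region_col] == reg]
        try:
            res = concordance(te_reg[time_col].to_numpy(), te_reg[event_col].to_numpy(), risks)
        except ValueError:
            continue
        samples.append(res.C)
    samples = np.asarray(samples)
    if samples.size < 2:
        return {"mean": np.nan, "se": np.nan, "ci": (np.nan, np.nan)}
    mean = float(samples.mean())
    se = float(samples.std(ddof=1) / np.sqrt(samples.size))
    from scipy.stats import norm

    z = norm.ppf(0.975)
    return {"mean": mean, "se": se, "ci": (mean - z * se, mean + z * se)}
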