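"""County-level summarization of survival scores: the three mode-based
schemes (univariate mode, multivariate mode with fallback, KDE multiple
mode), variable-importance ranking by summed |z|, small-cell suppression
with nearest-neighbor imputation, representative-individual lookup, and the
clinical-variable correlation validation.

Reporting rule: any value computed from a county of 1-10 subjects is
suppressed and replaced by a summary of the county's non-suppressed
neighbors (mode for categorical fields, mean for numeric); counties with no
subjects are simply absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceTable",
    "rank_importance",
    "county_univariate_mode",
    "county_multivariate_mode",
    "silverman_bandwidth",
    "county_score_modes",
    "impute_suppressed",
    "representative_individual",
    "clinical_score_correlation",
    "SUPPRESS_MIN",
    "SUPPRESS_MAX",
]

log = logging.getLogger(__name__)

SUPPRESS_MIN, SUPPRESS_MAX = 1, 10


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # covariate_level, summed_abs_z, rank
    cutoff_rank: int

    def top_levels(self):
        return list(self.table.loc[self.table["rank"] <= self.cutoff_rank, "covariate_level"])


def rank_importance(z_values_by_level: dict, top_k: int | None = None) -> ImportanceTable:
    """Summed |z| importance across the two model parts.

    ``z_values_by_level`` maps a covariate level (design column) to its
    (incidence z, latency z) pair; both must be present.  Levels are ranked
    by |z_incidence| + |z_latency| descending, ties broken by name.  The
    cutoff is the largest gap between consecutive sorted importance values
    (the clearest break in the empirical CDF), unless a fixed ``top_k``
    overrides it.
    """
    rows = []
    for level, zs in z_values_by_level.items():
        if zs is None or len(zs) != 2 or any(v is None or np.isnan(v) for v in zs):
            raise ValueError(f"missing z-value for level {level!r}")
        rows.append({"covariate_level": level, "summed_abs_z": abs(zs[0]) + abs(zs[1])})
    tab = pd.DataFrame(rows).sort_values(
        ["summed_abs_z", "covariate_level"], ascending=[False, True], kind="stable"
    )
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab = tab.reset_index(drop=True)
    if top_k is not None:
        cutoff = min(top_k, len(tab))
    else:
        vals = tab["summed_abs_z"].to_numpy()
        gaps = vals[:-1] - vals[1:]
        cutoff = len(tab) if gaps.size == 0 or gaps.max() <= 0 else int(np.argmax(gaps)) + 1
    return ImportanceTable(tab, cutoff)


def _mode_with_tie(values, order=None):
    """Most frequent value; ties broken by the given level order (or sorted
    order).  Returns (mode, tied)."""
    counts = pd.Series(values).value_counts()
    top = counts.max()
    winners = set(counts[counts == top].index)
    if order:
        ranking = [v for v in order if v in winners] + sorted(
            w for w in winners if w not in order
        )
    else:
        ranking = sorted(winners)
    return ranking[0], len(winners) > 1


def county_univariate_mode(
    df: pd.DataFrame,
    covariates: list,
    county_col: str = "county_id",
    level_order: dict | None = None,
    continuous_decimals: dict | None = None,
) -> pd.DataFrame:
    """Per-county, per-covariate mode (first summarization scheme).

    Continuous covariates are rounded to their native resolution before
    taking the mode; ties break deterministically to the earliest level in
    schema order and are logged.
    """
    level_order = level_order or {}
    continuous_decimals = continuous_decimals or {}
    rows = []
    for county, grp in df.groupby(county_col, sort=True):
        row = {county_col: county, "n_subjects": len(grp)}
        for cov in covariates:
            vals = grp[cov]
            if cov in continuous_decimals:
                vals = vals.round(continuous_decimals[cov])
            mode, tied = _mode_with_tie(vals.tolist(), level_order.get(cov))
            row[cov] = mode
            if tied:
                log.info("tie for %s in county %s broken to %r", cov, county, mode)
        rows.append(row)
    return pd.DataFrame(rows)


def county_multivariate_mode(
    df: pd.DataFrame,
    top_vars: list,
    all_covariates: list,
    county_col: str = "county_id",
    level_order: dict | None = None,
    continuous_decimals: dict | None = None,
) -> pd.DataFrame:
    """Joint mode of the most important categorical covariates, with
    fallback (second summarization scheme).

    The joint mode is the strictly most frequent combination of ``top_vars``
    within the county; when no strict maximizer exists the least-important
    variable (last in ``top_vars``) is dropped and the search retried.  The
    remaining covariates are filled by their univariate modes.  The fallback
    depth (number of variables dropped) is recorded per county.
    """
    uni = county_univariate_mode(
        df, all_covariates, county_col, level_order, continuous_decimals
    )
    depths, joint_rows = {}, {}
    for county, grp in df.groupby(county_col, sort=True):
        vars_now = list(top_vars)
        depth = 0
        found = {}
        while vars_now:
            combos = grp.groupby(vars_now, sort=True).size()
            top = combos.max()
            winners = combos[combos == top]
            if len(winners) == 1:
                combo = winners.index[0]
                if len(vars_now) == 1:
                    combo = (combo,)
                found = dict(zip(vars_now, combo))
                break
            vars_now = vars_now[:-1]
            depth += 1
        depths[county] = depth
        joint_rows[county] = found
    out = uni.copy()
    for cov in top_vars:
        out[cov] = [
            joint_rows[c].get(cov, v) for c, v in zip(out[county_col], out[cov])
        ]
    out["fallback_depth"] = out[county_col].map(depths)
    return out


def silverman_bandwidth(values) -> float:
    """Silverman's rule-of-thumb bandwidth for a Gaussian kernel:

        h = 0.9 * min(sd, IQR / 1.34) * n^(-1/5)

    with the sample standard deviation (ddof=1) and type-7 quantiles, the
    dialect of R's default density estimator.  Falls back to the sd when the
    IQR is zero; a constant sample has no usable bandwidth and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        raise ValueError("constant sample: no density bandwidth")
    return float(0.9 * spread * x.size ** (-0.2))


def _kde_grid(x, h, grid_size):
    lo, hi = x.min() - 3 * h, x.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
    dens /= x.size * h * np.sqrt(2 * np.pi)
    return grid, dens


def county_score_modes(
    score_values,
    grid_size: int = 512,
    prominence_frac: float = 0.05,
):
    """First and second KDE mode of a set of continuous scores.

    A Gaussian-kernel density with Silverman bandwidth is evaluated on a
    ``grid_size``-point grid over [min - 3h, max + 3h]; local maxima are
    located by discrete sign change and ordered by density height.  The
    second mode must rise above the valley separating it from the first by
    ``prominence_frac`` of the peak density, else it is reported missing —
    this suppresses spurious wiggle-level peaks.

    Returns ``(mode1, mode2)`` with ``mode2 is None`` when no second mode
    exists.  A constant sample returns (value, None).
    """
    x = np.asarray(score_values, dtype=float)
    if x.size < 1:
        raise ValueError("empty score sample")
    if np.ptp(x) == 0:
        return float(x[0]), None
    h = silverman_bandwidth(x)
    grid, dens = _kde_grid(x, h, grid_size)
    d = np.diff(dens)
    peaks = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    order = peaks[np.argsort(-dens[peaks], kind="stable")]
    mode1_idx = order[0]
    mode1 = float(grid[mode1_idx])
    dmax = dens[mode1_idx]
    for cand in order[1:]:
        lo, hi = sorted((mode1_idx, cand))
        valley = dens[lo:hi + 1].min()
        if dens[cand] - valley >= prominence_frac * dmax:
            return mode1, float(grid[cand])
    return mode1, None


def impute_suppressed(
    county_table: pd.DataFrame,
    adjacency: list,
    categorical_cols: list,
    numeric_cols: list,
    county_col: str = "county_id",
    n_col: str = "n_subjects",
) -> pd.DataFrame:
    """Apply the 1-10-subject suppression rule and neighbor imputation.

    Counties with 1 <= n <= 10 have every reported field replaced: categorical
    fields by the mode over adjacent non-suppressed counties, numeric fields
    by their mean.  A suppressed county with no non-suppressed direct
    neighbor expands once to neighbors-of-neighbors; if that also fails the
    county is flagged unresolved and its fields set to NA.  Zero-subject
    counties are expected to be absent from ``county_table`` already.
    """
    out = county_table.copy().reset_index(drop=True)
    nb: dict = {}
    for a, b in adjacency:
        nb.setdefault(a, set()).add(b)
        nb.setdefault(b, set()).add(a)
    n_by_county = dict(zip(out[county_col], out[n_col]))
    suppressed = {
        c for c, n in n_by_county.items() if SUPPRESS_MIN <= n <= SUPPRESS_MAX
    }
    out["suppressed"] = out[county_col].isin(suppressed).astype(int)
    out["imputed"] = 0
    out["unresolved"] = 0
    by_county = out.set_index(county_col)

    for county in sorted(suppressed):
        # donor order is sorted so float reductions are reproducible across runs
        donors = sorted(
            c for c in nb.get(county, ())
            if c in n_by_county and c not in suppressed
        )
        if not donors:
            second = set()
            for c in nb.get(county, ()):
                second |= nb.get(c, set())
            second.discard(county)
            donors = sorted(c for c in second if c in n_by_county and c not in suppressed)
        i = out.index[out[county_col] == county][0]
        if not donors:
            out.loc[i, "unresolved"] = 1
            for col in categorical_cols + numeric_cols:
                out.loc[i, col] = np.nan
            continue
        donor_rows = by_county.loc[donors]
        for col in categorical_cols:
            vals = donor_rows[col].dropna().tolist()
            out.loc[i, col] = _mode_with_tie(vals)[0] if vals else np.nan
        for col in numeric_cols:
            out.loc[i, col] = donor_rows[col].astype(float).mean()
        out.loc[i, "imputed"] = 1
    return out


def representative_individual(
    records: pd.DataFrame,
    target_score: float,
    score_col: str,
    id_col: str = "id",
):
    """The individual whose named score is nearest the target; exact ties
    break to the lowest id (logged)."""
    if len(records) == 0:
        raise ValueError("empty county")
    diff = (records[score_col] - target_score).abs()
    best = diff.min()
    winners = records.loc[diff == best].sort_values(id_col, kind="stable")
    if len(winners) > 1:
        log.info("representative tie at |diff|=%g broken to %r", best, winners.iloc[0][id_col])
    row = winners.iloc[0]
    return row[id_col], row.to_dict()


def _iqr_fence(x: pd.Series) -> pd.Series:
    q25, q75 = x.quantile([0.25, 0.75])
    iqr = q75 - q25
    return (x >= q25 - 1.5 * iqr) & (x <= q75 + 1.5 * iqr)


def clinical_score_correlation(
    df: pd.DataFrame,
    clinical_cols: list,
    score_cols: list,
    county_col: str = "county_id",
) -> pd.DataFrame:
    """Validation of the scores against out-of-model clinical measurements.

    Outliers beyond the 1.5*IQR fence of each clinical variable are removed
    first; Pearson correlations are then computed at the individual level and
    at the county level (county means and county medians).
    """
    rows = []
    for cvar in clinical_cols:
        keep = _iqr_fence(df[cvar])
        sub = df.loc[keep]
        grp = sub.groupby(county_col)
        means = grp.mean(numeric_only=True)
        medians = grp.median(numeric_only=True)
        for svar in score_cols:
            rows.append(
                {
                    "clinical": cvar,
                    "score": svar,
                    "r_individual": sub[cvar].corr(sub[svar]),
                    "r_county_mean": means[cvar].corr(means[svar]),
                    "r_county_median": medians[cvar].corr(medians[svar]),
                    "n_individuals": len(sub),
                    "n_counties": len(means),
                }
            )
    return pd.DataFrame(rows)
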