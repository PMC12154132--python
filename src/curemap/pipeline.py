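"""End-to-end orchestration: generate/load a registry cohort, apply
inclusion rules, fit mixture cure models (entire-data and per-region),
compare them with Cox surrogates, extract the seven survival scores, build
the three county summaries with suppression and imputation, validate against
the clinical analog, and write a reproducible artifact bundle.

Every stochastic stage draws from a named sub-seed derived from the master
seed, so re-running with the same configuration reproduces every output file
byte-for-byte.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cure import bootstrap_se, mcm_fit, save_fit, wald_z
from .evaluate import compare_entire_vs_regions
from .scores import individual_scores, km_score_overlay
from .spatial import (
    clinical_score_correlation,
    county_multivariate_mode,
    county_score_modes,
    county_univariate_mode,
    impute_suppressed,
    rank_importance,
    representative_individual,
)
from .survival import km_estimate
from .synthetic import (
    CategoricalSpec,
    CohortConfig,
    ContinuousSpec,
    generate_cohort,
    make_design,
    write_cohort,
)

__all__ = [
    "InclusionRules",
    "PipelineConfig",
    "apply_inclusion_criteria",
    "run_pipeline",
    "default_pipeline_config",
    "load_pipeline_config",
]

SCORE_COLS = ["s2y", "s5y", "s10y", "s15y", "t25", "t50", "t75"]

# fixed stage indices for named sub-seed derivation
_STAGES = {"generate": 0, "fit": 1, "evaluate": 2, "score": 3, "summarize": 4, "validate": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class InclusionRules:
    max_age: float = 108.0
    age_col: str = "age"
    required_covariates: tuple = ()
    geography_col: str = "region_id"
    allowed_geography: tuple | None = None


@dataclass
class PipelineConfig:
    outdir: str = "curemap_out"
    seed: int = 0
    # exactly one of the two input modes
    cohort_path: str | None = None
    adjacency_path: str | None = None
    generator: dict = field(default_factory=dict)
    inclusion: InclusionRules = field(default_factory=InclusionRules)
    # model options
    region_based_scores: bool = True
    bootstrap_B: int = 30
    em_coef_tol: float = 1e-6
    max_em_iter: int = 500
    # evaluation options
    mccv_splits: int = 100
    train_fraction: float = 0.8
    conf_level: float = 0.95
    # scoring
    horizons: tuple = (2.0, 5.0, 10.0, 15.0)
    quantiles: tuple = (0.25, 0.50, 0.75)
    t_max: float = 21.5
    # summarization
    schemes: tuple = ("univariate", "multivariate", "multimode")
    top_k_importance: int = 5
    representative_score: str = "t50"

    def __post_init__(self):
        if (self.cohort_path is None) == (not self.generator):
            # exactly one of input-path / generator-config must be present
            if self.cohort_path is not None and self.generator:
                raise ValueError("give either cohort_path or generator config, not both")


def default_pipeline_config(outdir="curemap_out", seed=0, n_subjects=5000, **gen_kwargs):
    gen = dict(n_subjects=n_subjects, seed=stage_seed(seed, "generate"))
    gen.update(gen_kwargs)
    return PipelineConfig(outdir=outdir, seed=seed, generator=gen)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    incl = raw.pop("inclusion", {})
    cfg = PipelineConfig(**raw)
    if incl:
        cfg.inclusion = InclusionRules(**incl)
    return cfg


def apply_inclusion_criteria(df: pd.DataFrame, rules: InclusionRules):
    """Sequentially drop rows violating the inclusion rules.

    Order: missing model covariates, age above threshold, geography outside
    the allowed set.  Returns (filtered, tally of exclusions per rule).
    """
    tally = {"missing_covariate": 0, "age": 0, "geography": 0}
    keep = df.copy()
    if rules.required_covariates:
        bad = keep[list(rules.required_covariates)].isna().any(axis=1)
        tally["missing_covariate"] = int(bad.sum())
        keep = keep[~bad]
    if rules.age_col in keep.columns:
        bad = keep[rules.age_col] > rules.max_age
        tally["age"] = int(bad.sum())
        keep = keep[~bad]
    if rules.allowed_geography is not None:
        bad = ~keep[rules.geography_col].isin(rules.allowed_geography)
        tally["geography"] = int(bad.sum())
        keep = keep[~bad]
    if len(keep) == 0:
        raise ValueError("all rows excluded by inclusion criteria")
    return keep.reset_index(drop=True), tally


def _schema_from_config(gen_cfg: CohortConfig):
    return gen_cfg.covariate_schema


def _designs(df, schema):
    X, xnames = make_design(df, schema)
    Z, znames = make_design(df, schema, intercept=True)
    return X, xnames, Z, znames


def _region_dummies(df, regions):
    cols = [(df["region_id"].to_numpy() == r).astype(float) for r in regions[1:]]
    names = [f"region_{r}" for r in regions[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(df), 0))), names


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle into ``config.outdir``.

    Returns a dict of the in-memory artifacts.  Any stage failure raises with
    the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage = "generate"
    try:
        # ---- generate / load -------------------------------------------
        if config.generator:
            gen_cfg = CohortConfig(**config.generator)
            cohort, geo, truth = generate_cohort(gen_cfg)
            adjacency = geo.adjacency
            write_cohort(cohort, geo, out / "cohort.csv", out / "adjacency.csv")
        else:
            from .synthetic import read_cohort

            cohort, adjacency = read_cohort(config.cohort_path, config.adjacency_path)
            gen_cfg = CohortConfig(**(config.generator or {}))  # schema source
            truth = None
        schema = _schema_from_config(gen_cfg)
        covariates = [s.name for s in schema]
        cat_covs = [s.name for s in schema if isinstance(s, CategoricalSpec)]
        cont_decimals = {
            s.name: s.decimals for s in schema if isinstance(s, ContinuousSpec)
        }
        level_order = {
            s.name: list(s.levels) for s in schema if isinstance(s, CategoricalSpec)
        }

        # ---- filter -----------------------------------------------------
        stage = "filter"
        rules = config.inclusion
        if not rules.required_covariates:
            rules = InclusionRules(
                max_age=rules.max_age,
                age_col=rules.age_col,
                required_covariates=tuple(covariates),
                geography_col=rules.geography_col,
                allowed_geography=rules.allowed_geography,
            )
        cohort, tally = apply_inclusion_criteria(cohort, rules)
        pd.DataFrame([tally]).to_csv(out / "exclusions.csv", index=False)
        artifacts["exclusions"] = tally
        regions = sorted(cohort["region_id"].unique())

        summary = cohort.groupby("region_id").agg(
            n=("id", "size"), events=("event", "sum"), median_time=("time", "median")
        )
        summary.to_csv(out / "cohort_summary.csv")

        # ---- fit --------------------------------------------------------
        stage = "fit"
        X, xnames, Z, znames = _designs(cohort, schema)
        R, rnames = _region_dummies(cohort, regions)
        X_ent = np.column_stack([X, R])
        Z_ent = np.column_stack([Z, R])
        t = cohort["time"].to_numpy()
        e = cohort["event"].to_numpy()
        fit_opts = dict(max_em_iter=config.max_em_iter, coef_tol=config.em_coef_tol)
        fit_entire = mcm_fit(X_ent, Z_ent, t, e, **fit_opts)
        save_fit(
            fit_entire, out / "fit_entire.txt",
            b_names=znames + rnames, beta_names=xnames + rnames,
        )
        region_fits = {}
        for reg in regions:
            sub = cohort[cohort["region_id"] == reg]
            Xr, _, Zr, _ = _designs(sub, schema)
            region_fits[reg] = mcm_fit(
                Xr, Zr, sub["time"].to_numpy(), sub["event"].to_numpy(), **fit_opts
            )
            save_fit(region_fits[reg], out / f"fit_region_{reg}.txt",
                     b_names=znames, beta_names=xnames)
        artifacts["fit_entire"] = fit_entire
        artifacts["region_fits"] = region_fits

        # importance from bootstrap z-values of the entire-data fit
        ses = bootstrap_se(
            X_ent, Z_ent, t, e,
            n_bootstrap=config.bootstrap_B,
            seed=stage_seed(config.seed, "fit"),
            fit_options=fit_opts,
        )
        z_b, z_beta = wald_z(fit_entire, ses)
        lat_names = xnames + rnames
        inc_names = znames + rnames
        z_by_level = {}
        for j, nm in enumerate(lat_names):
            zi = z_b[inc_names.index(nm)] if nm in inc_names else 0.0
            z_by_level[nm] = (zi, z_beta[j])
        imp = rank_importance(z_by_level, top_k=config.top_k_importance)
        imp.table.assign(cutoff_rank=imp.cutoff_rank).to_csv(
            out / "importance.csv", index=False
        )
        artifacts["importance"] = imp

        # ---- evaluate ---------------------------------------------------
        stage = "evaluate"
        comparison = compare_entire_vs_regions(
            cohort,
            covariate_design=lambda d: make_design(d, schema),
            region_design=lambda d: _region_dummies(d, regions),
            n_splits=config.mccv_splits,
            train_fraction=config.train_fraction,
            seed=stage_seed(config.seed, "evaluate"),
        )
        comparison.to_csv(out / "model_comparison.csv", index=False)
        artifacts["comparison"] = comparison

        # ---- score ------------------------------------------------------
        stage = "score"
        if config.region_based_scores:
            parts = []
            for reg in regions:
                sub = cohort[cohort["region_id"] == reg]
                Xr, _, Zr, _ = _designs(sub, schema)
                parts.append(
                    individual_scores(
                        region_fits[reg], Xr, Zr, sub["id"].to_numpy(),
                        horizons=config.horizons, quantiles=config.quantiles,
                        t_max=config.t_max,
                    )
                )
            scores_df = pd.concat(parts, ignore_index=True)
        else:
            scores_df = individual_scores(
                fit_entire, X_ent, Z_ent, cohort["id"].to_numpy(),
                horizons=config.horizons, quantiles=config.quantiles,
                t_max=config.t_max,
            )
        scores_df = (
            scores_df.set_index("id").loc[cohort["id"]].reset_index()
        )
        scores_df.to_csv(out / "individual_scores.csv", index=False)
        artifacts["individual_scores"] = scores_df
        scored = cohort.merge(scores_df, on="id")

        # ---- summarize --------------------------------------------------
        stage = "summarize"
        # map design-column levels back to their covariate, keep categoricals
        top_covs = []
        for lv in imp.top_levels():
            for c in covariates:
                if lv == c or lv.startswith(c + "_"):
                    if c not in top_covs:
                        top_covs.append(c)
        top_covs_cat = [c for c in top_covs if c in cat_covs]

        county_region = cohort.groupby("county_id")["region_id"].first()

        def _profile_scores(profiles: pd.DataFrame) -> pd.DataFrame:
            prof = profiles.copy()
            prof["region_id"] = prof["county_id"].map(county_region)
            sc = []
            for reg, grp in prof.groupby("region_id", sort=True):
                use = region_fits[reg] if config.region_based_scores else fit_entire
                if config.region_based_scores:
                    Xp, _, Zp, _ = _designs(grp, schema)
                else:
                    Xg, _, Zg, _ = _designs(grp, schema)
                    Rg, _ = _region_dummies(grp, regions)
                    Xp, Zp = np.column_stack([Xg, Rg]), np.column_stack([Zg, Rg])
                sc.append(
                    individual_scores(
                        use, Xp, Zp, grp["county_id"].to_numpy(),
                        horizons=config.horizons, quantiles=config.quantiles,
                        t_max=config.t_max,
                    ).rename(columns={"id": "county_id"})
                )
            return prof.merge(pd.concat(sc, ignore_index=True), on="county_id")

        clamp_cols = [f"t{int(round(q * 100))}_clamped" for q in config.quantiles]
        county_tables = {}
        if "univariate" in config.schemes:
            uni = county_univariate_mode(
                cohort, covariates, level_order=level_order,
                continuous_decimals=cont_decimals,
            )
            uni = _profile_scores(uni)
            uni = impute_suppressed(
                uni, adjacency, categorical_cols=cat_covs,
                numeric_cols=[c for c in covariates if c not in cat_covs]
                + SCORE_COLS,
            )
            uni.drop(columns=clamp_cols, errors="ignore").to_csv(
                out / "county_univariate.csv", index=False
            )
            county_tables["univariate"] = uni
        if "multivariate" in config.schemes:
            multi = county_multivariate_mode(
                cohort, top_covs_cat, covariates,
                level_order=level_order, continuous_decimals=cont_decimals,
            )
            multi = _profile_scores(multi)
            multi = impute_suppressed(
                multi, adjacency, categorical_cols=cat_covs,
                numeric_cols=[c for c in covariates if c not in cat_covs]
                + SCORE_COLS + ["fallback_depth"],
            )
            multi.drop(columns=clamp_cols, errors="ignore").to_csv(
                out / "county_multivariate.csv", index=False
            )
            county_tables["multivariate"] = multi
        if "multimode" in config.schemes:
            rows = []
            for county, grp in scored.groupby("county_id", sort=True):
                row = {"county_id": county, "n_subjects": len(grp)}
                any_second = False
                for sc in SCORE_COLS:
                    vals = grp[sc].to_numpy()
                    if len(vals) >= 2 and np.ptp(vals) > 0:
                        m1, m2 = county_score_modes(vals)
                    else:
                        m1, m2 = float(vals[0]), None
                    row[f"mode1_{sc}"] = m1
                    row[f"mode2_{sc}"] = np.nan if m2 is None else m2
                    any_second = any_second or (m2 is not None)
                row["mode2_missing"] = int(not any_second)
                rows.append(row)
            mm = pd.DataFrame(rows)
            mode_cols = [c for c in mm.columns if c.startswith("mode")]
            mm = impute_suppressed(
                mm, adjacency, categorical_cols=[],
                numeric_cols=[c for c in mode_cols if c != "mode2_missing"],
            )
            mm.to_csv(out / "county_multimode.csv", index=False)
            county_tables["multimode"] = mm

            # representative individuals for the two modes of the chosen score
            rep_rows = []
            rep_score = config.representative_score
            for _, row in mm[(mm["suppressed"] == 0)].iterrows():
                grp = scored[scored["county_id"] == row["county_id"]]
                for mode in ("mode1", "mode2"):
                    target = row.get(f"{mode}_{rep_score}")
                    if pd.isna(target):
                        continue
                    rid, prof = representative_individual(grp, float(target), rep_score)
                    rep_rows.append(
                        {
                            "county_id": row["county_id"],
                            "mode": mode,
                            "target": float(target),
                            "rep_id": rid,
                            **{c: prof[c] for c in cat_covs},
                        }
                    )
            pd.DataFrame(rep_rows).to_csv(out / "representatives.csv", index=False)
            artifacts["representatives"] = pd.DataFrame(rep_rows)
        artifacts["county_tables"] = county_tables

        # ---- validate ---------------------------------------------------
        stage = "validate"
        clinical_cols = [c for c in cohort.columns if c == "creatinine_analog"]
        if clinical_cols:
            val = clinical_score_correlation(scored, clinical_cols, SCORE_COLS)
            val.to_csv(out / "clinical_validation.csv", index=False)
            artifacts["clinical_validation"] = val

        # ---- report -----------------------------------------------------
        stage = "report"
        _km_figure(cohort, config, out / "km_scores.png")
        log_lines = [
            f"curemap {__version__}",
            f"numpy {np.__version__}, pandas {pd.__version__}",
            f"master_seed {config.seed}",
        ]
        log_lines += [f"seed[{s}] {stage_seed(config.seed, s)}" for s in _STAGES]
        log_lines.append("config:")
        cfg_dict = _listify(asdict(config))
        log_lines.append(yaml.safe_dump(cfg_dict, sort_keys=True).strip())
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return artifacts


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def _km_figure(cohort, config, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    km = km_estimate(cohort["time"].to_numpy(), cohort["event"].to_numpy())
    overlay = km_score_overlay(
        cohort["time"].to_numpy(), cohort["event"].to_numpy(),
        horizons=config.horizons, quantiles=config.quantiles, t_max=config.t_max,
    )
    fig, ax = plt.subplots(figsize=(7, 5))
    ts = np.concatenate([[0], km.survival.knots])
    ax.step(ts, np.concatenate([[1.0], km.survival.values]), where="post", color="k")
    ax.step(ts, np.concatenate([[1.0], km.lower.values]), where="post", ls="--", lw=0.8, color="k")
    ax.step(ts, np.concatenate([[1.0], km.upper.values]), where="post", ls="--", lw=0.8, color="k")
    for h, p in zip(overlay.horizons, overlay.horizon_probs):
        ax.plot(h, p, "o", color="tab:red")
        ax.annotate(f"S({int(h)}y)={p:.2f}", (h, p), textcoords="offset points", xytext=(5, 5))
    for q, tq in zip(overlay.quantile_levels, overlay.quantile_times):
        ax.plot(tq, q, "s", color="tab:blue")
    ax.set_xlabel("years since incidence")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def main_run(config_path=None, **overrides) -> dict:
    cfg = load_pipeline_config(config_path) if config_path else default_pipeline_config()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    try:
        return run_pipeline(cfg)
    except RuntimeError as err:
        print(err, file=sys.stderr)
        raise
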