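"""County summarization: importance ranking, modes, Silverman bandwidth,
KDE peaks, suppression/imputation, representatives, clinical validation."""

import numpy as np
import pandas as pd
import pytest

from curemap.spatial import (
    _kde_grid,
    clinical_score_correlation,
    county_multivariate_mode,
    county_score_modes,
    county_univariate_mode,
    impute_suppressed,
    rank_importance,
    representative_individual,
    silverman_bandwidth,
)


class TestRankImportance:
    def test_summed_magnitudes(self):
        tab = rank_importance({"a": (3.0, -5.0), "b": (1.0, 1.0)})
        row = tab.table.set_index("covariate_level")
        assert row.loc["a", "summed_abs_z"] == 8.0
        assert row.loc["a", "rank"] == 1

    def test_all_equal_tiebreak_by_name_and_cutoff_all(self):
        tab = rank_importance({"b": (1.0, 1.0), "a": (1.0, 1.0), "c": (1.0, 1.0)})
        assert list(tab.table["covariate_level"]) == ["a", "b", "c"]
        assert tab.cutoff_rank == 3

    def test_largest_gap_cutoff(self):
        tab = rank_importance(
            {"big1": (10.0, 10.0), "big2": (9.0, 9.0), "small": (0.5, 0.5)}
        )
        assert tab.cutoff_rank == 2
        assert tab.top_levels() == ["big1", "big2"]

    def test_missing_z_rejected(self):
        with pytest.raises(ValueError):
            rank_importance({"a": (1.0, np.nan)})

    def test_dominant_effect_ranks_first(self):
        # one covariate with a 10x effect must occupy rank 1
        from curemap.cure import bootstrap_se, mcm_fit, wald_z
        from curemap.synthetic import CohortConfig, generate_cohort, make_design

        cfg = CohortConfig(
            n_subjects=2000,
            seed=31,
            latency_coefs={"transplant_transplant": -1.0, "race_Black": -0.1,
                           "comorbidity_index": 0.05},
            incidence_coefs={"intercept": 0.5, "transplant_transplant": -1.0,
                             "race_Black": 0.1, "comorbidity_index": 0.05},
        )
        df, _, _ = generate_cohort(cfg)
        X, xn = make_design(df, cfg.covariate_schema)
        Z, zn = make_design(df, cfg.covariate_schema, intercept=True)
        t, e = df["time"].to_numpy(), df["event"].to_numpy()
        fit = mcm_fit(X, Z, t, e)
        ses = bootstrap_se(X, Z, t, e, n_bootstrap=12, seed=5,
                           fit_options={"coef_tol": 1e-4})
        z_b, z_beta = wald_z(fit, ses)
        zmap = {nm: (z_b[zn.index(nm)], z_beta[j]) for j, nm in enumerate(xn)}
        tab = rank_importance(zmap)
        assert tab.table.iloc[0]["covariate_level"] == "transplant_transplant"


class TestUnivariateMode:
    def test_simple_majority(self):
        df = pd.DataFrame({"county_id": ["c"] * 3, "race": ["A", "A", "B"]})
        out = county_univariate_mode(df, ["race"])
        assert out.loc[0, "race"] == "A"

    def test_tie_breaks_to_schema_order(self):
        df = pd.DataFrame({"county_id": ["c"] * 4, "race": ["B", "B", "A", "A"]})
        out = county_univariate_mode(df, ["race"], level_order={"race": ["B", "A"]})
        assert out.loc[0, "race"] == "B"

    def test_planted_majorities_recovered(self, rng):
        rows = []
        planted = {}
        for k in range(10):
            county = f"c{k}"
            maj = ["X", "Y", "Z"][k % 3]
            planted[county] = maj
            rows += [{"county_id": county, "v": maj}] * 6
            rows += [{"county_id": county, "v": "Q"}] * 3
        out = county_univariate_mode(pd.DataFrame(rows), ["v"])
        assert dict(zip(out["county_id"], out["v"])) == planted

    def test_continuous_rounded_before_mode(self):
        df = pd.DataFrame({"county_id": ["c"] * 3, "idx": [1.04, 1.01, 2.5]})
        out = county_univariate_mode(df, ["idx"], continuous_decimals={"idx": 1})
        assert out.loc[0, "idx"] == 1.0


class TestMultivariateMode:
    def test_strict_joint_mode(self):
        df = pd.DataFrame(
            {"county_id": ["c"] * 5, "a": ["A", "A", "A", "A", "B"],
             "b": ["X", "X", "X", "Y", "X"]}
        )
        out = county_multivariate_mode(df, ["a", "b"], ["a", "b"])
        assert out.loc[0, "a"] == "A" and out.loc[0, "b"] == "X"
        assert out.loc[0, "fallback_depth"] == 0

    def test_tie_falls_back_dropping_least_important(self):
        df = pd.DataFrame(
            {"county_id": ["c"] * 4, "a": ["A", "A", "B", "B"],
             "b": ["X", "X", "Y", "Y"]}
        )
        out = county_multivariate_mode(df, ["a", "b"], ["a", "b"],
                                       level_order={"a": ["A", "B"], "b": ["X", "Y"]})
        # joint (A,X) vs (B,Y) tie at 2 -> drop b, but a alone is also tied
        # -> joint mode empty, univariate tiebreak to schema order
        assert out.loc[0, "fallback_depth"] == 2
        assert out.loc[0, "a"] == "A"

    def test_univariate_and_joint_agree_on_homogeneous_counties(self):
        rows = []
        for k in range(6):
            rows += [{"county_id": f"c{k}", "a": "A" if k % 2 else "B",
                      "b": "X"}] * 5
        df = pd.DataFrame(rows)
        uni = county_univariate_mode(df, ["a", "b"])
        multi = county_multivariate_mode(df, ["a", "b"], ["a", "b"])
        pd.testing.assert_frame_equal(
            uni, multi.drop(columns="fallback_depth")
        )


class TestSilvermanBandwidth:
    def test_frozen_reference_values(self):
        # oracle values from R's bw.nrd0 (the default density bandwidth)
        assert silverman_bandwidth([0.0, 1.0]) == pytest.approx(0.2923490698, abs=1e-9)
        assert silverman_bandwidth([1, 2, 2, 3, 5, 8, 9]) == pytest.approx(
            1.9193090961, abs=1e-9
        )

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=100)
        assert silverman_bandwidth(3.7 * x) == pytest.approx(
            3.7 * silverman_bandwidth(x)
        )

    def test_rate_in_n(self, rng):
        x = rng.standard_normal(100_000)
        h1 = silverman_bandwidth(x[:1000])
        h2 = silverman_bandwidth(x)
        assert h1 / h2 == pytest.approx(100 ** 0.2, rel=0.1)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            silverman_bandwidth([2.0, 2.0, 2.0])


class TestScoreModes:
    def test_bimodal_mixture_modes_in_components(self, rng):
        x = np.r_[rng.normal(0.0, 0.5, 700), rng.normal(5.0, 0.5, 300)]
        m1, m2 = county_score_modes(x)
        assert abs(m1 - 0.0) < 1.0
        assert m2 is not None and abs(m2 - 5.0) < 1.0

    def test_unimodal_sample_has_no_second_mode(self, rng):
        x = rng.normal(0.0, 1.0, 500)
        m1, m2 = county_score_modes(x)
        assert abs(m1) < 0.5
        assert m2 is None

    def test_grid_argmax_matches_dense_oracle(self, rng):
        x = np.r_[rng.normal(0, 0.4, 80), rng.normal(3, 0.4, 40)]
        from curemap.spatial import silverman_bandwidth as bw

        m1, m2 = county_score_modes(x, grid_size=512)
        h = bw(x)
        grid, dens = _kde_grid(x, h, 5120)
        oracle = grid[np.argmax(dens)]
        spacing = grid[1] - grid[0]
        assert abs(m1 - oracle) <= 10 * spacing + 1e-12

    def test_constant_scores(self):
        m1, m2 = county_score_modes(np.full(5, 2.5))
        assert m1 == 2.5 and m2 is None


class TestImputation:
    @staticmethod
    def _table():
        return pd.DataFrame(
            {
                "county_id": ["c0", "c1", "c2", "c3"],
                "n_subjects": [50, 3, 40, 60],
                "race": ["White", "SECRET", "White", "Black"],
                "t50": [4.0, 99.0, 6.0, 8.0],
            }
        )

    @staticmethod
    def _adj():
        return [("c0", "c1"), ("c1", "c2"), ("c2", "c3")]

    def test_neighbor_mean_and_mode(self):
        out = impute_suppressed(self._table(), self._adj(), ["race"], ["t50"])
        row = out.set_index("county_id").loc["c1"]
        assert row["t50"] == 5.0  # mean of 4 and 6
        assert row["race"] == "White"
        assert row["suppressed"] == 1 and row["imputed"] == 1

    def test_no_suppressed_value_leaks(self):
        out = impute_suppressed(self._table(), self._adj(), ["race"], ["t50"])
        assert "SECRET" not in set(out["race"])
        assert 99.0 not in set(out["t50"])

    def test_second_ring_fallback(self):
        tab = pd.DataFrame(
            {
                "county_id": ["c0", "c1", "c2"],
                "n_subjects": [2, 3, 40],
                "race": ["S1", "S2", "White"],
                "t50": [99.0, 98.0, 6.0],
            }
        )
        adj = [("c0", "c1"), ("c1", "c2")]
        out = impute_suppressed(tab, adj, ["race"], ["t50"]).set_index("county_id")
        # c0's only neighbor c1 is itself suppressed; second ring reaches c2
        assert out.loc["c0", "race"] == "White"
        assert out.loc["c0", "t50"] == 6.0
        assert out.loc["c0", "unresolved"] == 0

    def test_unresolvable_county_flagged(self):
        tab = pd.DataFrame(
            {"county_id": ["c0", "c1"], "n_subjects": [2, 3],
             "race": ["S1", "S2"], "t50": [1.0, 2.0]}
        )
        out = impute_suppressed(tab, [("c0", "c1")], ["race"], ["t50"])
        assert (out["unresolved"] == 1).all()
        assert out["t50"].isna().all()


class TestRepresentative:
    def test_nearest_score_wins(self):
        df = pd.DataFrame({"id": ["id1", "id2"], "s2y": [0.40, 0.90]})
        rid, _ = representative_individual(df, 0.85, "s2y")
        assert rid == "id2"

    def test_tie_breaks_to_lowest_id(self):
        df = pd.DataFrame({"id": ["b", "a"], "s2y": [1.0, 3.0]})
        rid, _ = representative_individual(df, 2.0, "s2y")
        assert rid == "a"

    def test_empty_county_rejected(self):
        with pytest.raises(ValueError):
            representative_individual(pd.DataFrame({"id": [], "s2y": []}), 0.5, "s2y")


class TestClinicalValidation:
    def test_outlier_fence_and_correlation_sign(self, rng):
        n = 2000
        score = rng.uniform(0, 1, n)
        clin = 2 * score + rng.normal(0, 0.2, n)
        clin[:5] = 50.0  # gross outliers
        df = pd.DataFrame(
            {"county_id": rng.integers(0, 20, n), "s2y": score, "clin": clin}
        )
        out = clinical_score_correlation(df, ["clin"], ["s2y"])
        row = out.iloc[0]
        assert row["n_individuals"] == n - 5
        assert row["r_individual"] > 0.9
        assert row["r_county_mean"] > 0.5
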