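"""GLM machinery: ANCOVA, LSD letters, correlations, slope comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenostab.inference import (
    ancova,
    correlation_matrix,
    correlation_tables,
    log_transform,
    lsd_compare,
    partial_corr,
    pearson_corr,
    significance_stars,
    slope_difference_test,
)


class TestLogTransform:
    def test_known_values(self):
        assert log_transform([1.0])[0] == 0.0
        assert log_transform([np.e])[0] == pytest.approx(1.0)

    def test_monotonicity(self):
        x = np.sort(np.random.default_rng(0).uniform(0.1, 100, 50))
        assert np.all(np.diff(log_transform(x)) >= 0)

    def test_nonpositive_rejected_with_locations(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            log_transform([1.0, -2.0, 3.0])
        s = pd.Series([1.0, 0.0], index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            log_transform(s)


class TestAncova:
    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"g": np.repeat(["a", "b"], 12), "y": rng.normal(0, 1, 24)}
        )
        df.loc[df["g"] == "b", "y"] += 1.0
        aov = ancova(df, "y", ["g"])
        t, _ = stats.ttest_ind(df[df.g == "a"]["y"], df[df.g == "b"]["y"])
        f = aov.set_index("term").loc["g", "F"]
        assert f == pytest.approx(t**2, rel=1e-9)

    def test_matches_projection_oracle(self):
        # Type III SS for each term = RSS(model without term) - RSS(full),
        # with sum-to-zero coding, computed by explicit least squares
        rng = np.random.default_rng(2)
        n = 48
        df = pd.DataFrame(
            {
                "a": np.tile(np.repeat(["a1", "a2"], 12), 2),
                "b": np.repeat(["b1", "b2", "b3"], 16),
                "z": rng.uniform(0, 5, n),
            }
        )
        df["y"] = (
            (df["a"] == "a2") * 1.0
            + (df["b"] == "b2") * 0.5
            + 0.3 * df["z"]
            + rng.normal(0, 0.5, n)
        )
        aov = ancova(df, "y", ["a", "b"], covariate="z").set_index("term")

        def sum_code(col, levels):
            # sum-to-zero contrast columns for a factor
            cols = []
            for lev in levels[:-1]:
                c = (col == lev).astype(float) - (col == levels[-1]).astype(float)
                cols.append(c.to_numpy())
            return np.column_stack(cols)

        xa = sum_code(df["a"], ["a1", "a2"])
        xb = sum_code(df["b"], ["b1", "b2", "b3"])
        xab = np.column_stack([xa[:, i] * xb[:, j] for i in range(1) for j in range(2)])
        one = np.ones((n, 1))
        z = df["z"].to_numpy()[:, None]
        y = df["y"].to_numpy()

        def rss(x):
            beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return r @ r

        full = np.column_stack([one, xa, xb, xab, z])
        blocks = {
            "a": [one, xb, xab, z],
            "b": [one, xa, xab, z],
            "a:b": [one, xa, xb, z],
            "z": [one, xa, xb, xab],
        }
        rss_full = rss(full)
        for term, parts in blocks.items():
            ss = rss(np.column_stack(parts)) - rss_full
            assert aov.loc[term, "sum_sq"] == pytest.approx(ss, rel=1e-9), term

    def test_empty_cell_drops_interaction(self, caplog):
        # 2x2 design with the (a2, b2) cell empty: interaction inestimable,
        # main effects still identified
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "a": ["a1"] * 10 + ["a1"] * 10 + ["a2"] * 10,
                "b": ["b1"] * 10 + ["b2"] * 10 + ["b1"] * 10,
                "y": rng.normal(0, 1, 30),
            }
        )
        with caplog.at_level("WARNING"):
            aov = ancova(df, "y", ["a", "b"])
        terms = set(aov["term"])
        assert "a:b" not in terms
        assert {"a", "b"} <= terms

    def test_pure_noise_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            df = pd.DataFrame(
                {"g": np.repeat(["a", "b", "c"], 10), "y": rng.normal(0, 1, 30)}
            )
            ps.append(ancova(df, "y", ["g"]).set_index("term").loc["g", "p"])
        ps = np.array(ps)
        assert 0.40 < ps.mean() < 0.60
        assert np.mean(ps < 0.05) < 0.12


class TestLSD:
    def test_identical_means_share_letter(self):
        out = lsd_compare({"a": 1.0, "b": 1.0, "c": 1.0}, residual_ms=1.0,
                          df_resid=27, n_per_group={"a": 10, "b": 10, "c": 10})
        assert out["letters"].nunique() == 1

    def test_three_group_letters_match_pairwise_oracle(self):
        means = {"lo": 0.0, "mid": 1.0, "hi": 5.0}
        n = {g: 8 for g in means}
        out = lsd_compare(means, residual_ms=1.0, df_resid=21, n_per_group=n)
        # oracle: direct pairwise t-tests at pooled MS
        def p(a, b):
            se = np.sqrt(1.0 * (1 / 8 + 1 / 8))
            return 2 * stats.t.sf(abs(means[a] - means[b]) / se, 21)

        assert p("lo", "hi") < 0.05 and p("mid", "hi") < 0.05
        assert p("lo", "mid") > 0.05
        letters = dict(zip(out["group"], out["letters"]))
        assert letters["hi"] != letters["lo"]
        assert set(letters["lo"]) & set(letters["mid"])
        assert not set(letters["hi"]) & set(letters["lo"])

    def test_zero_residual_ms_unequal_means_all_differ(self):
        out = lsd_compare({"a": 1.0, "b": 2.0}, residual_ms=0.0, df_resid=5,
                          n_per_group={"a": 3, "b": 3})
        assert out["letters"].nunique() == 2

    def test_boundary_p_equal_alpha_not_significant(self):
        pairwise = lsd_compare(
            {"a": 0.0, "b": 1.0}, residual_ms=1.0, df_resid=10,
            n_per_group={"a": 5, "b": 5}, alpha=0.05,
        ).attrs["pairwise"]
        p = pairwise.loc[0, "p"]
        out = lsd_compare({"a": 0.0, "b": 1.0}, residual_ms=1.0, df_resid=10,
                          n_per_group={"a": 5, "b": 5}, alpha=p)
        # pair with p exactly at alpha shares a letter
        assert out["letters"].nunique() == 1


class TestCorrelations:
    def test_perfect_linear_association(self):
        x = np.arange(1.0, 9.0)
        assert pearson_corr(x, 2 * x).coefficient == pytest.approx(1.0)
        assert pearson_corr(x, -x).coefficient == pytest.approx(-1.0)

    def test_covariance_formula_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 8)
        y = 0.5 * x + rng.normal(0, 1, 8)
        res = pearson_corr(x, y)
        r_oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert res.coefficient == pytest.approx(r_oracle, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_partial_with_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        plain = pearson_corr(x, y)
        partial = partial_corr(x, y, None)
        assert partial.coefficient == pytest.approx(plain.coefficient, rel=1e-12)
        assert partial.p == pytest.approx(plain.p, rel=1e-9)

    def test_constant_covariate_equals_pearson(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="collinear"):
            # constant covariate duplicates the intercept column
            partial_corr(x, y, np.ones((1, 20)))

    def test_covariate_equal_to_x_rejected(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="residual variance"):
            partial_corr(x, y, x[None, :])

    def test_recursion_formula_oracle(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 1, 30)
        x = 0.6 * z + rng.normal(0, 1, 30)
        y = -0.4 * z + rng.normal(0, 1, 30)
        res = partial_corr(x, y, z[None, :])
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert res.coefficient == pytest.approx(oracle, abs=1e-10)

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {"x": rng.normal(0, 1, 25), "y": rng.normal(0, 1, 25),
             "z": rng.normal(0, 1, 25)}
        )
        df["x"] += 0.5 * df["z"]
        df["y"] += 0.5 * df["z"]
        res = partial_corr(df["x"], df["y"], df["z"].to_numpy()[None, :])
        pg = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert res.coefficient == pytest.approx(float(pg["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(pg["p_val"].iloc[0]), abs=1e-9)


class TestSlopeDifference:
    def test_identical_groups_null(self):
        x = np.arange(10.0)
        y = 2 * x + np.sin(x)
        res = slope_difference_test(
            np.concatenate([x, x]), np.concatenate([y, y]),
            ["a"] * 10 + ["b"] * 10,
        )
        assert res.t_interaction == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_opposite_slopes_detected(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0, 1, 15)
        y1 = x + rng.normal(0, 0.01, 15)
        y2 = -x + rng.normal(0, 0.01, 15)
        res = slope_difference_test(
            np.concatenate([x, x]), np.concatenate([y1, y2]),
            ["a"] * 15 + ["b"] * 15,
        )
        assert res.p < 1e-10
        assert res.slopes["a"] == pytest.approx(1.0, abs=0.02)
        assert res.slopes["b"] == pytest.approx(-1.0, abs=0.02)

    def test_per_group_slopes_equal_separate_regressions(self):
        rng = np.random.default_rng(12)
        xa, xb = rng.uniform(0, 1, 12), rng.uniform(0, 2, 12)
        ya = 1 + 2 * xa + rng.normal(0, 0.3, 12)
        yb = 0.5 - xb + rng.normal(0, 0.3, 12)
        res = slope_difference_test(
            np.concatenate([xa, xb]), np.concatenate([ya, yb]),
            ["a"] * 12 + ["b"] * 12,
        )
        sa = stats.linregress(xa, ya).slope
        sb = stats.linregress(xb, yb).slope
        assert res.slopes["a"] == pytest.approx(sa, rel=1e-9)
        assert res.slopes["b"] == pytest.approx(sb, rel=1e-9)

    def test_constant_x_group_rejected(self):
        with pytest.raises(ValueError, match="constant x"):
            slope_difference_test(
                [1.0, 1.0, 1.0, 0.0, 1.0, 2.0],
                [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                ["a"] * 3 + ["b"] * 3,
            )


class TestCorrelationTables:
    @staticmethod
    def species_frame(rng, n_species=8, coupled=False):
        fa10 = rng.uniform(0.2, 0.6, n_species)
        cv_inter_ls = 0.8 * fa10 + rng.normal(0, 0.02, n_species) if coupled \
            else rng.uniform(0.1, 0.4, n_species)
        return pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(n_species)],
                "early_treatment": "E_hom",
                "ls": rng.uniform(8, 12, n_species),
                "fa10": fa10,
                "cv_intra_ls": rng.uniform(0.05, 0.15, n_species),
                "cv_inter_ls": cv_inter_ls,
                "cv_inter_tm": rng.uniform(0.2, 0.5, n_species),
                "initial_size": rng.uniform(40, 60, n_species),
            }
        )

    def test_induced_coupling_detected(self):
        hits = 0
        for seed in range(10):
            df = self.species_frame(np.random.default_rng(seed), coupled=True)
            tab = correlation_tables(df)["first_round"]
            row = tab[(tab.var_a == "fa10") & (tab.var_b == "cv_inter_ls")].iloc[0]
            hits += (row["r"] > 0) and (row["p"] < 0.05)
        assert hits >= 8

    def test_null_star_rate_near_nominal(self):
        count = total = 0
        for seed in range(40):
            df = self.species_frame(np.random.default_rng(100 + seed))
            tab = correlation_tables(df)["first_round"]
            count += (tab["p"] < 0.05).sum()
            total += len(tab)
        assert count / total < 0.15

    def test_single_species_rejected(self):
        df = self.species_frame(np.random.default_rng(0), n_species=1)
        with pytest.raises(ValueError, match="species"):
            correlation_tables(df)

    def test_star_tiers(self):
        assert significance_stars(0.005) == "***"
        assert significance_stars(0.03) == "**"
        assert significance_stars(0.07) == "*"
        assert significance_stars(0.2) == ""

    def test_low_power_flag(self):
        df = self.species_frame(np.random.default_rng(1), n_species=4)
        tab = correlation_matrix(df, ["fa10", "cv_inter_ls"], ("initial_size",))
        assert tab["low_power"].all()
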