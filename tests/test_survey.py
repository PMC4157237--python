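"""Survey geometry: transect positions, cover, rugosity, conversion
factors, and the classical cover ANOVA."""

import numpy as np
import pandas as pd
import pytest

import reefmetab as rm
from reefmetab.synthetic import TRANSECT_POINTS


class TestTransectPositions:
    def test_standard_survey_has_101_points(self):
        pos = rm.transect_positions(50.0, 0.5)
        assert len(pos) == 101
        assert pos[0] == 0.0 and pos[-1] == 50.0

    @pytest.mark.parametrize("length,spacing,n", [(10.0, 0.5, 21),
                                                  (7.0, 7.0, 2)])
    def test_count_formula(self, length, spacing, n):
        assert len(rm.transect_positions(length, spacing)) == n

    def test_non_divisible_spacing_raises(self):
        with pytest.raises(ValueError):
            rm.transect_positions(50.0, 0.3)


def _transects(seqs):
    rows = []
    for t, labels in enumerate(seqs):
        rows += [{"site": "EXP", "season": "Up", "transect_id": t,
                  "point_index": i, "label": lab}
                 for i, lab in enumerate(labels)]
    return pd.DataFrame(rows)


class TestCoverage:
    def test_count_ratio(self):
        seq = ["coral"] * 40 + ["other"] * 61
        cov = rm.coverage_from_transects(_transects([seq]))
        coral = next(c for c in cov if c.category == "coral")
        assert coral.b == pytest.approx(40 / 101)

    def test_single_category(self):
        cov = rm.coverage_from_transects(_transects([["sand"] * 101]))
        sand = next(c for c in cov if c.category == "sand")
        assert sand.b == 1.0

    def test_mean_over_transects(self):
        seqs = [["coral"] * k + ["other"] * (101 - k) for k in (20, 30, 40)]
        cov = rm.coverage_from_transects(_transects(seqs))
        coral = next(c for c in cov if c.category == "coral")
        assert coral.b == pytest.approx(30 / 101)
        assert len(coral.per_transect) == 3

    def test_unknown_label_raises_with_name(self):
        with pytest.raises(ValueError, match="kelp"):
            rm.coverage_from_transects(_transects([["kelp"] * 101]))

    def test_categories_sum_to_one_per_transect(self, tables):
        cov = rm.coverage_from_transects(tables["transects"])
        per = {}
        for c in cov:
            for t, p in enumerate(c.per_transect):
                per.setdefault((c.site, c.season, t), 0.0)
                per[(c.site, c.season, t)] += p
        assert all(abs(v - 1.0) < 1e-12 for v in per.values())

    def test_estimator_unbiased_multinomial(self):
        """Mean cover estimate converges to the multinomial probability."""
        p = 0.3
        scen = rm.default_scenario(seed=13)
        scen.cover_probs[("EXP", "Up")] = {"coral": p, "other": 1 - p}
        n_tr = 10_000
        df = rm.gen_transects(scen, "EXP", "Up", n_transects=n_tr)
        cov = rm.coverage_from_transects(df)
        coral = next(c for c in cov if c.category == "coral")
        se = np.sqrt(p * (1 - p) / (n_tr * TRANSECT_POINTS))
        assert abs(coral.b - p) < 3 * se


class TestRugosity:
    def test_chain_ratio(self):
        df = pd.DataFrame({"site": "EXP", "chain_m": [13.2], "linear_m": [10.0]})
        assert rm.rugosity_factor(df, "EXP").r == pytest.approx(1.32)

    def test_flat_substrate(self):
        df = pd.DataFrame({"site": "EXP", "chain_m": [10.0], "linear_m": [10.0]})
        assert rm.rugosity_factor(df, "EXP").r == 1.0

    def test_mean_of_subtransects(self):
        df = pd.DataFrame({"site": "SHE", "chain_m": [15.0, 15.3, 15.6],
                           "linear_m": 10.0})
        assert rm.rugosity_factor(df, "SHE").r == pytest.approx(1.53)

    def test_short_chain_clamped_with_warning(self, caplog):
        df = pd.DataFrame({"site": "EXP", "chain_m": [9.8], "linear_m": [10.0]})
        with caplog.at_level("WARNING"):
            r = rm.rugosity_factor(df, "EXP")
        assert r.r == 1.0
        assert any("clamped" in m for m in caplog.messages)

    def test_nonpositive_length_raises(self):
        df = pd.DataFrame({"site": "EXP", "chain_m": [0.0], "linear_m": [10.0]})
        with pytest.raises(ValueError):
            rm.rugosity_factor(df, "EXP")


class TestConversionFactor:
    @pytest.mark.parametrize("a2,a3,s", [(10.0, 22.8, 2.28),
                                         (5.0, 21.45, 4.29)])
    def test_single_pair(self, a2, a3, s):
        df = pd.DataFrame({"group": "g", "area2d_cm2": [a2],
                           "area3d_cm2": [a3]})
        assert rm.conversion_factor_estimate(df, "g").s == pytest.approx(s)

    def test_flat_specimens(self):
        df = pd.DataFrame({"group": "g", "area2d_cm2": [3.0, 7.0],
                           "area3d_cm2": [3.0, 7.0]})
        assert rm.conversion_factor_estimate(df, "g").s == 1.0

    def test_nonpositive_area_raises(self):
        df = pd.DataFrame({"group": "g", "area2d_cm2": [0.0],
                           "area3d_cm2": [1.0]})
        with pytest.raises(ValueError):
            rm.conversion_factor_estimate(df, "g")


def _cell_df(means, n=3, noise=None):
    rows = []
    for (site, season), mu in means.items():
        for j in range(n):
            eps = noise[(site, season)][j] if noise else 0.0
            rows.append({"site": site, "season": season, "prop": mu + eps})
    return pd.DataFrame(rows)


class TestCoverANOVA:
    def test_closed_form_two_by_two(self, rng):
        """F statistics match hand-computed balanced two-way sums of
        squares (independent closed-form oracle)."""
        n = 3
        noise = {k: rng.normal(0, 0.05, n) for k in
                 [(s, w) for s in ("EXP", "SHE") for w in ("NoUp", "Up")]}
        means = {("EXP", "NoUp"): 0.40, ("EXP", "Up"): 0.35,
                 ("SHE", "NoUp"): 0.25, ("SHE", "Up"): 0.30}
        df = _cell_df(means, n, noise)
        res = rm.classic_cover_tests(df)

        # closed-form balanced two-way ANOVA from first principles
        y = df["prop"].to_numpy()
        grand = y.mean()
        a_means = df.groupby("site")["prop"].mean()
        b_means = df.groupby("season")["prop"].mean()
        ab_means = df.groupby(["site", "season"])["prop"].mean()
        ss_a = 2 * n * ((a_means - grand) ** 2).sum()
        ss_b = 2 * n * ((b_means - grand) ** 2).sum()
        ss_ab = n * sum(
            (ab_means[(s, w)] - a_means[s] - b_means[w] + grand) ** 2
            for s in ("EXP", "SHE") for w in ("NoUp", "Up"))
        ss_e = sum((y_i - ab_means[(r.site, r.season)]) ** 2
                   for y_i, (_, r) in zip(y, df.iterrows()))
        dfe = len(y) - 4
        expected = {"C(site)": ss_a / (ss_e / dfe),
                    "C(season)": ss_b / (ss_e / dfe),
                    "C(site):C(season)": ss_ab / (ss_e / dfe)}
        for term, f_exp in expected.items():
            assert res["anova"].loc[term, "F"] == pytest.approx(f_exp,
                                                                rel=1e-10)

    def test_equal_cells_give_near_zero_f(self, rng):
        noise = {k: rng.normal(0, 0.05, 4) for k in
                 [(s, w) for s in ("EXP", "SHE") for w in ("NoUp", "Up")]}
        means = {k: 0.3 for k in noise}
        res = rm.classic_cover_tests(_cell_df(means, 4, noise))
        assert (res["anova"]["F"].iloc[:3] < 6).all()

    def test_one_factor_f_equals_t_squared(self, rng):
        """Classical identity: one-factor ANOVA F equals the squared pooled
        two-sample t statistic."""
        from scipy import stats
        import statsmodels.formula.api as smf
        import statsmodels.api as sm
        a = rng.normal(0.3, 0.05, 6)
        b = rng.normal(0.4, 0.05, 6)
        df = pd.DataFrame({"site": ["EXP"] * 6 + ["SHE"] * 6,
                           "prop": np.r_[a, b]})
        model = smf.ols("prop ~ C(site)", data=df).fit()
        f = sm.stats.anova_lm(model, typ=2).loc["C(site)", "F"]
        t, _ = stats.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-10)

    def test_bonferroni_multiplication(self, rng):
        """Pairwise p-values are raw p times the number of comparisons,
        capped at 1."""
        noise = {k: rng.normal(0, 0.02, 5) for k in
                 [(s, w) for s in ("EXP", "SHE") for w in ("NoUp", "Up")]}
        means = {("EXP", "NoUp"): 0.6, ("EXP", "Up"): 0.2,
                 ("SHE", "NoUp"): 0.2, ("SHE", "Up"): 0.6}
        res = rm.classic_cover_tests(_cell_df(means, 5, noise))
        pw = res["pairwise"]
        assert pw is not None and len(pw) == 6
        np.testing.assert_allclose(pw["p_bonferroni"],
                                   np.minimum(1.0, pw["p_raw"] * 6))

    def test_too_few_replicates_raises(self):
        df = _cell_df({("EXP", "NoUp"): 0.3, ("EXP", "Up"): 0.3,
                       ("SHE", "NoUp"): 0.3, ("SHE", "Up"): 0.3}, n=1)
        with pytest.raises(ValueError):
            rm.classic_cover_tests(df)
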