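"""Sampler, DIC, HPD, model averaging and posterior comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reefmetab as rm
from reefmetab.bayes import (CHAIN_PROFILES, ChainSettings, ModelSpec,
                             model_average, pairwise_compare, pmcmc)

FAST = CHAIN_PROFILES["fast"]
TINY = ChainSettings(2100, 100, 5)


class TestGibbs:
    def test_intercept_only_matches_conjugate_closed_form(self, rng):
        """With a vague prior the intercept posterior mean is the sample
        mean (conjugate closed form), within Monte-Carlo error."""
        y = rng.normal(3.7, 1.2, 400)
        X = np.ones((400, 1))
        d = rm.gibbs_fit(y, X, chain=FAST, seed=1)
        mc_se = d.beta[:, 0].std() / np.sqrt(len(d.beta))
        # thinned draws still autocorrelated -> allow a generous factor
        assert abs(d.beta[:, 0].mean() - y.mean()) < 10 * mc_se
        assert abs(d.beta[:, 0].mean() - y.mean()) < 3 * y.std() / 20

    def test_parameter_recovery(self, rng):
        """Known beta = (2, -1), sigma2 = 0.25, n = 200: posterior means
        within 3 posterior SDs of truth."""
        n = 200
        x = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        y = 2.0 - 1.0 * x + rng.normal(0, 0.5, n)
        d = rm.gibbs_fit(y, X, chain=FAST, seed=2)
        for j, truth in enumerate([2.0, -1.0]):
            assert abs(d.beta[:, j].mean() - truth) < 3 * d.beta[:, j].std()
        s2 = d.sigma2.mean()
        assert abs(s2 - 0.25) < 3 * d.sigma2.std()

    def test_same_seed_identical_draws(self, rng):
        y = rng.normal(0, 1, 50)
        X = np.ones((50, 1))
        d1 = rm.gibbs_fit(y, X, chain=TINY, seed=9)
        d2 = rm.gibbs_fit(y, X, chain=TINY, seed=9)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.sigma2, d2.sigma2)

    def test_retained_count_bookkeeping(self, rng):
        d = rm.gibbs_fit(rng.normal(0, 1, 30), np.ones((30, 1)),
                         chain=TINY, seed=0)
        assert d.beta.shape[0] == (2100 - 100) // 5
        assert (d.sigma2 > 0).all()

    def test_nonfinite_response_raises(self):
        with pytest.raises(ValueError):
            rm.gibbs_fit(np.array([1.0, np.nan]), np.ones((2, 1)))


class TestDIC:
    def test_effective_parameters_near_parameter_count(self, rng):
        """For a vague-prior linear model at large n, pD ~ p + 1
        (coefficients plus the variance)."""
        n, p = 2000, 4
        X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, p - 1))])
        beta = np.array([1.0, 0.5, -0.5, 0.25])
        y = X @ beta + rng.normal(0, 1, n)
        d = rm.gibbs_fit(y, X, chain=FAST, seed=3)
        s = rm.dic(d, y, X)
        assert s.p_d == pytest.approx(p + 1, rel=0.2)

    def test_dic_identity_and_determinism(self, rng):
        y = rng.normal(0, 1, 100)
        X = np.ones((100, 1))
        d = rm.gibbs_fit(y, X, chain=TINY, seed=4)
        s1 = rm.dic(d, y, X)
        s2 = rm.dic(d, y, X)
        assert s1.dic == s2.dic
        assert s1.dic == pytest.approx(2 * s1.dbar - s1.d_hat, rel=1e-12)

    def test_noise_predictor_increases_dic_in_expectation(self, rng):
        """Adding a pure-noise column raises DIC on average over seeded
        replicates."""
        diffs = []
        for rep in range(50):
            r = np.random.default_rng(rep)
            n = 80
            y = 1.0 + r.normal(0, 1, n)
            X0 = np.ones((n, 1))
            X1 = np.column_stack([X0, r.normal(0, 1, n)])
            d0 = rm.gibbs_fit(y, X0, chain=TINY, seed=rep)
            d1 = rm.gibbs_fit(y, X1, chain=TINY, seed=rep + 1000)
            diffs.append(rm.dic(d1, y, X1).dic - rm.dic(d0, y, X0).dic)
        assert np.mean(diffs) > 0


class TestHPD:
    def test_constant_samples_degenerate(self):
        lo, hi = rm.hpd(np.full(100, 2.5))
        assert lo == hi == 2.5

    def test_sorted_integers_tie_break(self):
        # all windows of 950 consecutive integers tie; smallest lower bound
        lo, hi = rm.hpd(np.arange(1, 1001), 0.95)
        assert (lo, hi) == (1.0, 950.0)

    def test_normal_quantiles(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = rm.hpd(x, 0.95)
        assert lo == pytest.approx(-1.960, abs=0.05)
        assert hi == pytest.approx(1.960, abs=0.05)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            rm.hpd(np.arange(10))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_shortest_interval_property(self, seed):
        """HPD is never longer than the equal-tailed interval and matches
        a brute-force sliding-window scan."""
        x = np.random.default_rng(seed).gamma(2.0, 1.0, 200)
        lo, hi = rm.hpd(x, 0.9)
        xs = np.sort(x)
        m = int(np.ceil(0.9 * len(xs)))
        brute = min((xs[i + m - 1] - xs[i], xs[i], xs[i + m - 1])
                    for i in range(len(xs) - m + 1))
        assert (lo, hi) == (brute[1], brute[2])
        eq_lo, eq_hi = np.quantile(x, [0.05, 0.95])
        assert hi - lo <= (eq_hi - eq_lo) + 1e-12


class TestPmcmc:
    def test_all_positive_floors_at_two_over_n(self):
        assert pmcmc(np.abs(np.random.default_rng(0).normal(5, 1, 1000))
                     ) == pytest.approx(0.002)

    def test_symmetric_draws_near_one(self):
        d = np.random.default_rng(1).standard_normal(4000)
        assert pmcmc(d) > 0.9

    def test_counting_rule(self):
        d = np.r_[np.full(300, -1.0), np.full(700, 1.0)]
        assert pmcmc(d) == pytest.approx(0.6)


class TestModelAverage:
    def test_dic_weights_formula(self):
        w = rm.dic_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def _fits(self, rng, dics):
        """Fabricate fitted models with controlled DIC values."""
        fits = []
        for i, target in enumerate(dics):
            y = rng.normal(0, 1, 40)
            X = np.ones((40, 1))
            d = rm.gibbs_fit(y, X, chain=TINY, seed=i)
            s = rm.FitSummary(f"m{i}", dbar=target, d_hat=target)
            spec = ModelSpec(("A",), frozenset())
            fits.append((spec, s, d))
        return fits

    def test_single_model_window(self, rng):
        avg = model_average(self._fits(rng, [100.0, 105.0]))
        w = avg.table.set_index("model")["weight"]
        assert w["m0"] == 1.0 and w["m1"] == 0.0
        assert avg.candidate_labels == ["m0"]

    def test_window_excludes_delta_ge_two(self, rng):
        avg = model_average(self._fits(rng, [100.0, 102.0]))
        assert avg.table["weight"].tolist() == [1.0, 0.0]

    def test_two_models_in_window(self, rng):
        avg = model_average(self._fits(rng, [100.0, 101.9]))
        w = np.sort(avg.table["weight"].to_numpy())[::-1]
        expect = rm.dic_weights([0.0, 1.9])
        np.testing.assert_allclose(w, np.sort(expect)[::-1], atol=1e-12)
        assert avg.stacked_beta.shape[0] == TINY.n_retained

    def test_absent_coefficients_average_as_zero(self, rng):
        y = rng.normal(0, 1, 60)
        X1 = np.ones((60, 1))
        X2 = np.column_stack([X1, rng.normal(0, 1, 60)])
        d1 = rm.gibbs_fit(y, X1, ["(Intercept)"], chain=TINY, seed=0)
        d2 = rm.gibbs_fit(y, X2, ["(Intercept)", "x"], chain=TINY, seed=1)
        spec = ModelSpec(("A",), frozenset())
        s1 = rm.FitSummary("m1", 10.0, 10.0)
        s2 = rm.FitSummary("m2", 11.0, 11.0)     # delta 1 -> both in window
        avg = model_average([(spec, s1, d1), (spec, s2, d2)])
        w = rm.dic_weights([0.0, 1.0])
        expect_x = w[1] * d2.beta[:, 1].mean()
        assert avg.coef["x"] == pytest.approx(expect_x, rel=1e-9)


class TestPairwise:
    def test_contrast_recovery_from_known_model(self, rng):
        """Cell-mean differences estimated from the posterior match the
        simulated ground truth."""
        truth = {"a": 0.0, "b": 2.0, "c": -1.0}
        rows, y = [], []
        for g, mu in truth.items():
            for _ in range(40):
                rows.append({"G": g})
                y.append(mu + rng.normal(0, 0.5))
        df, y = pd.DataFrame(rows), np.array(y)
        spec = ModelSpec(("G",), frozenset({("G",)}))
        X, names = rm.design_matrix(df, spec)
        d = rm.gibbs_fit(y, X, names, chain=FAST, seed=5)
        levels = {"G": ["a", "b", "c"]}
        cells = {g: {"G": g} for g in "abc"}
        cmp_ = pairwise_compare(d.beta, names, cells, ("G",), levels)
        got = {(r.cell_a, r.cell_b): r.mean_diff for r in cmp_.itertuples()}
        assert got[("a", "b")] == pytest.approx(-2.0, abs=0.35)
        assert got[("a", "c")] == pytest.approx(1.0, abs=0.35)
        stars = {(r.cell_a, r.cell_b): r.stars for r in cmp_.itertuples()}
        assert stars[("a", "b")] != ""

    def test_unknown_cell_raises(self, rng):
        d = rm.gibbs_fit(rng.normal(0, 1, 30), np.ones((30, 1)),
                         ["(Intercept)"], chain=TINY, seed=0)
        with pytest.raises(KeyError):
            pairwise_compare(d.beta, ["(Intercept)"], {"a": {"G": "a"}},
                             ("G",), {"G": ["a"]}, pairs=[("a", "zz")])

    def test_hpd_and_pmcmc_decisions_agree(self):
        """If zero lies outside the 95% HPD then pMCMC < 0.05 (+ MC
        resolution), across simulated contrasts."""
        g = np.random.default_rng(3)
        for shift in (0.0, 0.5, 1.0, 2.0, 3.0):
            d = g.standard_normal(2000) + shift
            lo, hi = rm.hpd(d, 0.95)
            p = pmcmc(d)
            if lo > 0 or hi < 0:
                assert p < 0.05 + 2 / len(d)


def test_fit_response_end_to_end(fluxes):
    """Full inference chain on synthetic fluxes: sensible model table,
    weights summing to 1, comparisons for every cell pair."""
    data = fluxes.assign(
        group=fluxes["group"].map(lambda g: "coral" if g.startswith("coral")
                                  else g))
    res = rm.fit_response(data, "p_n", chain=FAST, seed=0)
    assert len(res.model_table) == 19
    assert res.model_table["weight"].sum() == pytest.approx(1.0)
    assert (res.model_table["dic"].diff().dropna() >= 0).all()
    n_cells = data.groupby(["group", "site", "season"]).ngroups
    assert len(res.comparisons) == n_cells * (n_cells - 1) // 2
    assert res.comparisons["pmcmc"].between(0, 1).all()
    assert (res.comparisons["hpd_lo"] <= res.comparisons["mean_diff"]).all()
    assert (res.comparisons["mean_diff"] <= res.comparisons["hpd_hi"]).all()
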