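"""Percent-change statistics, prey aggregates, and stability read-outs."""

import numpy as np
import pytest

import atnsim as a
from atnsim.metrics import stability_cv


def scripted_result(web, series_by_guild, years_unfished=None):
    """Wrap hand-written annual end-of-season series into a ScenarioResult."""
    years = len(next(iter(series_by_guild.values())))
    yu = years if years_unfished is None else years_unfished
    biomass = np.zeros((years, 2, web.n_guilds))
    for gid, vals in series_by_guild.items():
        biomass[:, 1, web.index(gid)] = vals
        biomass[:, 0, web.index(gid)] = vals
    cfg = a.ScenarioConfig(years_unfished=yu, years_fished=years - yu)
    fstages = sum(len(sp.stage_ids) for sp in web.fish_species)
    return a.ScenarioResult(web=web, config=cfg, initial_state=np.zeros(web.n_guilds),
                            biomass=biomass, catch=np.zeros((years, fstages)),
                            production=np.zeros((years, fstages)))


@pytest.fixture()
def toy():
    return a.make_toy_web("chain")


class TestPercentChange:
    def test_plus_one_percent(self, toy):
        b = scripted_result(toy, {"prod": [100.0] * 5})
        t = scripted_result(toy, {"prod": [101.0] * 5})
        assert a.percent_change(t, b, "prod", "all") == pytest.approx(1.0)

    def test_identical_runs_exactly_zero(self, toy):
        r1 = scripted_result(toy, {"prod": [3.0, 4.0, 5.0]})
        r2 = scripted_result(toy, {"prod": [3.0, 4.0, 5.0]})
        assert a.percent_change(r1, r2, "prod", "all") == 0.0

    def test_zero_baseline_flagged_nan(self, toy):
        b = scripted_result(toy, {"prod": [0.0, 0.0]})
        t = scripted_result(toy, {"prod": [1.0, 1.0]})
        assert np.isnan(a.percent_change(t, b, "prod", "all"))

    def test_antisymmetry_identity(self, toy):
        """pc(a,b) = −pc(b,a)·a/b: swapping treatment and baseline flips the
        sign and rescales by the base ratio, exactly."""
        av, bv = 7.3, 11.9
        ra = scripted_result(toy, {"prod": [av]})
        rb = scripted_result(toy, {"prod": [bv]})
        lhs = a.percent_change(ra, rb, "prod", "all")
        rhs = -a.percent_change(rb, ra, "prod", "all") * av / bv
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_logistic_closed_form_comparison(self):
        """Doubling a lone producer's r changes the season end-state by the
        analytic logistic amount."""
        K, B0, season = 100.0, 5.0, 90.0
        webs = {r: a.make_toy_web("logistic", K=K, r=r) for r in (0.05, 0.10)}
        results = {}
        for r, web in webs.items():
            cfg = a.ScenarioConfig(years_unfished=1, years_fished=0,
                                   initial_state=np.array([B0]))
            results[r] = a.run_scenario(web, cfg)
        # series are one year long; closed form at t = 90
        logi = lambda r: K / (1 + (K / B0 - 1) * np.exp(-r * season))
        want = 100.0 * (logi(0.10) - logi(0.05)) / logi(0.05)
        got = a.percent_change(results[0.10], results[0.05], "prod", "all", window=1)
        assert got == pytest.approx(want, rel=1e-5)

    def test_mismatched_years_rejected(self, toy):
        r1 = scripted_result(toy, {"prod": [1.0] * 3})
        r2 = scripted_result(toy, {"prod": [1.0] * 4})
        with pytest.raises(ValueError, match="matching year ranges"):
            a.percent_change(r1, r2, "prod", "all")


class TestPreyAggregates:
    def test_adult_group_is_sum_of_members(self, lc_web):
        series = {g: np.arange(1.0, 4.0) * (k + 1) for k, g in enumerate(a.ADULT_PREY_GUILDS)}
        res = scripted_result(lc_web, series)
        want = sum(series.values())
        np.testing.assert_allclose(a.prey_aggregate(res, "adult_prey"), want)

    def test_larval_group_membership(self):
        assert set(a.LARVAL_PREY_GUILDS) == {
            "rotifer_small", "rotifer_medium", "rotifer_large", "daphnia", "cyclopoid"
        }
        assert set(a.ADULT_PREY_GUILDS) == {"daphnia", "cyclopoid", "leptodora"}

    def test_aggregates_are_linear(self, lc_web):
        r1 = scripted_result(lc_web, {g: np.full(3, 2.0) for g in a.ADULT_PREY_GUILDS})
        r2 = scripted_result(lc_web, {g: np.full(3, 5.0) for g in a.ADULT_PREY_GUILDS})
        summed = scripted_result(lc_web, {g: np.full(3, 7.0) for g in a.ADULT_PREY_GUILDS})
        np.testing.assert_allclose(
            a.prey_aggregate(r1, "adult_prey") + a.prey_aggregate(r2, "adult_prey"),
            a.prey_aggregate(summed, "adult_prey"),
        )

    def test_missing_guild_reported(self, toy):
        res = scripted_result(toy, {"prod": [1.0]})
        with pytest.raises(KeyError, match="absent"):
            a.prey_aggregate(res, "adult_prey")
        with pytest.raises(ValueError, match="unknown prey group"):
            a.prey_aggregate(res, "no_such_group")


class TestStability:
    def test_constant_series_zero(self):
        assert np.all(stability_cv(np.full(20, 3.3), 10) == 0.0)

    def test_window_oracle(self):
        s = np.array([1.0, 1.0, 1.0, 3.0])
        want = np.std(s) / np.mean(s)  # population sd convention
        np.testing.assert_allclose(stability_cv(s, 4), [want])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(1, 5, size=30)
        np.testing.assert_allclose(stability_cv(s, 10), stability_cv(1000.0 * s, 10),
                                   rtol=1e-12)

    def test_nonpositive_mean_flagged(self):
        s = np.array([1.0, -1.0, 1.0, -1.0])
        assert np.isnan(stability_cv(s, 4)[0])

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            stability_cv(np.ones(5), 1)


class TestCatchComparison:
    def test_zero_fishing_years_empty(self, fish_toy):
        cfg = a.ScenarioConfig(stocking=a.StockingPlan({"fish": 100.0}),
                               years_unfished=2, years_fished=0)
        r = a.run_scenario(fish_toy, cfg)
        assert a.catch_comparison(r, r) == {}

    def test_identical_arms_zero(self, fish_toy):
        cfg = a.ScenarioConfig(stocking=a.StockingPlan({"fish": 100.0}),
                               harvest=a.HarvestPolicy(), years_unfished=1, years_fished=2)
        r = a.run_scenario(fish_toy, cfg)
        out = a.catch_comparison(r, r)
        caught = [sid for sid in r.fish_ids if r.catch_series(sid)[-1] > 0]
        assert caught  # selective stages do get caught
        for sid in caught:
            assert out[sid] == 0.0
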