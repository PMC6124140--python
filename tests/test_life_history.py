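"""Stage transitions, recruitment, stocking and the production ledger."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import atnsim as a


def species_web(rho=1.0, natural=True):
    guilds = [a.Guild("alga", role="producer", body_mass=1e-4, r=1.0)]
    stage_ids = tuple(f"s{k}" for k in range(5))
    for sid in stage_ids:
        guilds.append(a.Guild(sid, role="fish_stage", body_mass=1e3, x=0.05, y=4.0,
                              B0=10.0, q=1.0, d=0.0))
    links = [a.FeedingLink(sid, "alga", 1.0, 0.85) for sid in stage_ids]
    sp = a.FishSpecies("fish", stage_ids, rho=rho, natural_reproduction=natural)
    return a.FoodWeb(guilds, links, K=100.0, fish_species=[sp])


class TestTransition:
    def test_shift_rule_with_recruitment(self):
        web = species_web(rho=0.7)
        B = np.array([50.0, 1, 2, 3, 4, 5])  # alga + stages (L,J,2,3,4+)
        prod = {"fish": np.array([0.0, 0.0, 0.2, 0.3, 0.5])}  # mature sum = 1.0
        out = a.end_of_season_transition(B, prod, web)
        np.testing.assert_allclose(out, [50.0, 0.7, 1, 2, 3, 9])

    def test_no_spontaneous_recruitment(self):
        web = species_web()
        out = a.end_of_season_transition(np.zeros(6), {"fish": np.zeros(5)}, web)
        np.testing.assert_array_equal(out, 0.0)

    def test_no_natural_reproduction_zeroes_larvae(self):
        web = species_web(rho=0.7, natural=False)
        B = np.array([50.0, 1, 2, 3, 4, 5])
        out = a.end_of_season_transition(B, {"fish": np.full(5, 10.0)}, web)
        assert out[1] == 0.0

    def test_negative_production_floored(self):
        web = species_web(rho=1.0)
        out = a.end_of_season_transition(np.ones(6), {"fish": np.full(5, -3.0)}, web)
        assert out[1] == 0.0  # starving stages recruit nothing

    def test_negative_biomass_rejected(self):
        web = species_web()
        with pytest.raises(ValueError, match="negative"):
            a.end_of_season_transition(np.array([-1.0, 0, 0, 0, 0, 0]), None, web)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1e4), min_size=5, max_size=5),
           st.floats(0, 1e3))
    def test_aging_conserves_biomass_up_to_recruitment(self, stages, mature_prod):
        """Total fish biomass after = total before + new larvae; nothing destroyed."""
        web = species_web(rho=0.5)
        B = np.concatenate([[50.0], stages])
        prod = {"fish": np.array([0, 0, mature_prod, 0, 0.0])}
        out = a.end_of_season_transition(B, prod, web)
        assert out[1:].sum() == pytest.approx(sum(stages) + 0.5 * mature_prod, rel=1e-12)

    def test_accumulator_drains_all_stages(self):
        """With zero recruitment the 4-y+ class absorbs every cohort, total constant."""
        web = species_web(rho=0.0)
        B = np.array([50.0, 1, 2, 3, 4, 5])
        for _ in range(5):
            B = a.end_of_season_transition(B, {"fish": np.zeros(5)}, web)
        np.testing.assert_allclose(B, [50.0, 0, 0, 0, 0, 15])


class TestStocking:
    def test_baseline_injection(self):
        web = species_web()
        out = a.apply_stocking(np.zeros(6), a.StockingPlan({"fish": 200.0}), web)
        assert out[1] == 200.0
        assert np.all(out[[0, 2, 3, 4, 5]] == 0.0)

    def test_zero_plan_is_identity(self):
        web = species_web()
        B = np.arange(6.0)
        np.testing.assert_array_equal(a.apply_stocking(B, a.StockingPlan(), web), B)

    def test_additivity(self):
        web = species_web()
        B = np.full(6, 10.0)
        p1, p2 = a.StockingPlan({"fish": 300.0}), a.StockingPlan({"fish": 50.0})
        twice = a.apply_stocking(a.apply_stocking(B, p1, web), p2, web)
        once = a.apply_stocking(B, p1 + p2, web)
        np.testing.assert_array_equal(twice, once)

    def test_unknown_species_rejected(self):
        web = species_web()
        with pytest.raises(KeyError, match="unknown fish species"):
            a.apply_stocking(np.zeros(6), a.StockingPlan({"pike": 10.0}), web)

    def test_per_year_schedule(self):
        web = species_web()
        plan = a.StockingPlan({"fish": [100.0, 200.0]})
        assert a.apply_stocking(np.zeros(6), plan, web, year=0)[1] == 100.0
        assert a.apply_stocking(np.zeros(6), plan, web, year=5)[1] == 200.0


class TestProductionLedger:
    def test_metabolic_balance_gives_zero(self):
        """A stage whose intake exactly covers metabolism accrues no production."""
        web = species_web()
        # choose alga density so that y·F = 1: F = B/(B0+B) = 1/y → B = B0/(y−1)
        B0, y = 10.0, 4.0
        alga = B0 / (y - 1.0)
        from atnsim.dynamics import build_arrays
        arrays = build_arrays(web)
        from atnsim.life_history import production_rate
        B = np.array([alga, 5, 5, 5, 5, 5.0])
        F = arrays.functional_response_rows(B)
        rate = production_rate(B, F, arrays)
        np.testing.assert_allclose(rate[arrays.fish_idx], 0.0, atol=1e-12)

    def test_one_day_closed_form(self):
        """On a frozen state, P after one day equals x·B·(y·F − 1)·1 analytically."""
        web = species_web()
        from atnsim.dynamics import build_arrays
        from atnsim.life_history import production_rate
        arrays = build_arrays(web)
        B = np.array([40.0, 7, 0, 0, 0, 0.0])
        F = arrays.functional_response_rows(B)
        rate = production_rate(B, F, arrays)
        f = 40.0 / (10.0 + 40.0)
        assert rate[1] == pytest.approx(0.05 * 7 * (4.0 * f - 1.0), rel=1e-12)

    def test_starving_stage_recruits_nothing(self):
        web = species_web(rho=1.0)
        out = a.integrate_season(np.array([0.0, 10, 0, 0, 0, 0]), web, season_length=10.0,
                                 record_days=(10.0,))
        assert out.production[0] < 0  # starving larvae lose mass all season
        nxt = a.end_of_season_transition(
            out.B_end, {"fish": np.maximum(out.production, 0.0)}, web
        )
        assert nxt[1] == 0.0
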