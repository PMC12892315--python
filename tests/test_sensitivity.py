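"""Tornado analysis, lever sweeps, marginal gains and break-even price."""

import numpy as np
import pytest

import silagetea as st

# Published marginal-effect tabulation: ENPV change (£M) per extraction range
SCENARIO1_ENPV_CHANGES = [
    ((0.0, 3.0), 125.0),
    ((3.0, 6.0), 125.0),
    ((6.0, 10.0), 150.0),
    ((10.0, 12.0), 100.0),
    ((12.0, 15.0), 130.0),
]
SCENARIO2_ENPV_CHANGES = [
    ((0.0, 3.0), 120.0),
    ((3.0, 6.0), 150.0),
    ((6.0, 10.0), 150.0),
    ((10.0, 12.0), 100.0),
    ((12.0, 15.0), 110.0),
]


class TestTornado:
    def test_price_swing_matches_affine_slope(self, fixture_params):
        entries = st.oat_tornado(
            "scenario1", fixture_params,
            parameters=[("prices.protein_price", 10.0, 20.0)],
        )
        fin = fixture_params.financial
        af = st.annuity_factor(fin.discount_rate, fin.lifetime)
        mass_kg = (
            st.product_rates(fixture_params.basis, "scenario1")["protein_product"] * 1000
        )
        assert entries[0].swing == pytest.approx(mass_kg * 10.0 * af, rel=1e-6)

    def test_degenerate_range_gives_zero_swing(self, fixture_params):
        entries = st.oat_tornado(
            "scenario1", fixture_params,
            parameters=[("prices.protein_price", 15.0, 15.0)],
        )
        assert entries[0].swing == 0.0

    def test_discount_rate_direction(self, fixture_params):
        entries = st.oat_tornado(
            "scenario1", fixture_params,
            parameters=[("financial.discount_rate", 0.06, 0.12)],
        )
        assert entries[0].enpv_at_low > entries[0].enpv_at_high

    def test_default_list_sorted_by_swing_protein_dominant(self, fixture_params):
        entries = st.oat_tornado("scenario1", fixture_params)
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)
        assert entries[0].name == "prices.protein_price"
        assert {e.name for e in entries} >= {
            "prices.protein_price", "prices.silage_price", "prices.lignin_price",
            "financial.discount_rate",
        }

    def test_montecarlo_mode_agrees_with_deterministic_on_swing(self, fixture_params):
        det = st.oat_tornado(
            "scenario1", fixture_params,
            parameters=[("prices.protein_price", 10.0, 20.0)],
        )[0]
        mc = st.oat_tornado(
            "scenario1", fixture_params,
            parameters=[("prices.protein_price", 10.0, 20.0)],
            method="montecarlo",
            mc=st.MonteCarloConfig(n_draws=4_000, seed=17),
        )[0]
        # swings agree because ENPV is affine and the remaining sampled noise
        # is common to both bounds up to Monte Carlo error
        assert mc.swing == pytest.approx(det.swing, rel=0.05)

    def test_missing_bounds_rejected(self, fixture_params):
        with pytest.raises(st.ConfigError, match="low > high"):
            st.oat_tornado(
                "scenario1", fixture_params,
                parameters=[("prices.protein_price", 20.0, 10.0)],
            )


class TestExtractionSweep:
    def test_protein_only_negative_at_zero_extraction(self, fixture_params):
        sweep = st.extraction_sweep(
            "scenario1", fixture_params, revenue_mode="protein_only"
        )
        assert sweep.enpv[0] < 0.0  # no revenue, full costs
        assert sweep.enpv[-1] > 0.0

    def test_multiproduct_dominates_protein_only(self, fixture_params):
        multi = st.extraction_sweep("scenario1", fixture_params)
        solo = st.extraction_sweep(
            "scenario1", fixture_params, revenue_mode="protein_only"
        )
        assert np.all(multi.enpv >= solo.enpv)

    def test_enpv_nondecreasing_in_efficiency(self, fixture_params):
        sweep = st.extraction_sweep("scenario2", fixture_params)
        assert np.all(np.diff(sweep.enpv) >= 0)

    def test_grid_bounds_validated(self, fixture_params):
        with pytest.raises(st.ConfigError):
            st.extraction_sweep("scenario1", fixture_params, grid=[-1.0, 5.0])


class TestMarginalGains:
    def test_published_scenario1_rows(self):
        table = st.marginal_gains(SCENARIO1_ENPV_CHANGES)
        assert [r.marginal_gain for r in table.rows] == [41.7, 41.7, 37.5, 50.0, 43.3]
        assert round(table.average) == 43

    def test_published_scenario2_rows(self):
        table = st.marginal_gains(SCENARIO2_ENPV_CHANGES)
        assert [r.marginal_gain for r in table.rows] == [40.0, 50.0, 37.5, 50.0, 36.7]
        assert round(table.average) == 43

    def test_single_range_arithmetic(self):
        table = st.marginal_gains([((0.0, 3.0), 125.0)])
        assert table.rows[0].marginal_gain == 41.7
        assert table.sd == 0.0

    def test_zero_width_and_gap_rejected(self):
        with pytest.raises(st.ConfigError):
            st.marginal_gains([((3.0, 3.0), 10.0)])
        with pytest.raises(st.ConfigError, match="contiguous"):
            st.marginal_gains([((0.0, 3.0), 10.0), ((4.0, 6.0), 10.0)])


class TestScaleSweep:
    def test_unit_exponent_removes_scale_economies(self, fixture_params):
        sweep = st.scale_sweep(
            "scenario1", fixture_params,
            capacities=np.geomspace(1_000, 100_000, 7),
            capital_scaling_exponent=1.0,
        )
        assert np.allclose(sweep.unit_cost, sweep.unit_cost[0], rtol=1e-9)

    def test_six_tenths_rule_monotonicity(self, fixture_params):
        sweep = st.scale_sweep(
            "scenario1", fixture_params,
            capacities=np.geomspace(1_000, 100_000, 9),
        )
        assert np.all(np.diff(sweep.unit_cost) < 0)  # unit cost falls with scale
        assert np.all(np.diff(sweep.enpv) > 0)  # ENPV grows with scale
        assert np.all(np.diff(sweep.breakeven_price) < 0)

    def test_base_capacity_reproduces_base_case(self, fixture_params):
        protein0 = st.product_rates(fixture_params.basis, "scenario1")["protein_product"]
        sweep = st.scale_sweep("scenario1", fixture_params, capacities=[protein0])
        base = st.evaluate_deterministic(fixture_params, "scenario1")
        assert sweep.enpv[0] == pytest.approx(base["npv"], rel=1e-12)

    def test_exponent_validated(self, fixture_params):
        with pytest.raises(st.ConfigError):
            st.scale_sweep("scenario1", fixture_params, capital_scaling_exponent=0.0)


class TestBreakevenPrice:
    def test_identity_with_unit_cost_protein_only(self, fixture_params):
        """With protein the sole revenue and CRF annualisation, the break-even
        price is algebraically the unit production cost."""
        res = st.evaluate_deterministic(fixture_params, "scenario1")
        protein_t = st.product_rates(fixture_params.basis, "scenario1")["protein_product"]
        uc = st.unit_cost(res["tci"], res["tpc"], protein_t, fixture_params.financial)
        be = st.breakeven_price(
            "scenario1", fixture_params, revenue_mode="protein_only"
        )
        assert be == pytest.approx(uc, rel=1e-6)

    def test_coproduct_revenue_lowers_breakeven(self, fixture_params):
        solo = st.breakeven_price(
            "scenario1", fixture_params, revenue_mode="protein_only"
        )
        multi = st.breakeven_price("scenario1", fixture_params)
        assert multi < solo

    def test_no_sign_change_reported(self, fixture_params):
        with pytest.raises(st.ConfigError, match="sign change"):
            st.breakeven_price("scenario1", fixture_params, bracket=(50.0, 60.0))


class TestDiscountRateSweep:
    def test_strictly_decreasing_for_profitable_fixture(self, fixture_params):
        sweep = st.discount_rate_sweep("scenario1", fixture_params)
        assert np.all(np.diff(sweep.enpv) < 0)

    def test_base_rate_entry_matches_base_case(self, fixture_params):
        sweep = st.discount_rate_sweep(
            "scenario1", fixture_params, grid=[0.08]
        )
        base = st.evaluate_deterministic(fixture_params, "scenario1")
        assert sweep.enpv[0] == pytest.approx(base["npv"], rel=1e-12)
        assert sweep.grid.size == 1
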