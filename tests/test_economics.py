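"""NPV arithmetic, sampling, summaries and the Monte Carlo engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import silagetea as st
from silagetea.param_space import DistributionSpec


class TestNpv:
    def test_constant_annuity_worked_example(self):
        cash = st.CashflowSeries.constant(revenue=10e6, cost=0.0, lifetime=25)
        assert st.npv(cash, 0.08, 50e6) == pytest.approx(56.748e6, rel=1e-4)

    def test_zero_cashflow_is_minus_tci(self):
        cash = st.CashflowSeries.constant(0.0, 0.0, 25)
        assert st.npv(cash, 0.08, 7.5e6) == -7.5e6

    def test_undiscounted_limit(self):
        cash = st.CashflowSeries.constant(3.0, 1.0, 10)
        assert st.npv(cash, 0.0, 5.0) == pytest.approx(15.0)

    def test_invalid_rate(self):
        with pytest.raises(st.ConfigError):
            st.npv(st.CashflowSeries.constant(1.0, 0.0, 5), -1.5, 0.0)

    @given(
        r=hst.floats(0.001, 0.5),
        t=hst.integers(1, 50),
        a=hst.floats(-1e7, 1e7),
    )
    def test_annuity_closed_form_matches_term_by_term(self, r, t, a):
        cash = st.CashflowSeries.constant(a, 0.0, t)
        closed = a * st.annuity_factor(r, t)
        assert st.npv(cash, r, 0.0) == pytest.approx(closed, rel=1e-10, abs=1e-6)

    def test_npv_decreasing_in_rate_for_positive_cashflows(self):
        cash = st.CashflowSeries.constant(5e6, 1e6, 25)
        rates = np.linspace(0.02, 0.2, 10)
        values = [st.npv(cash, r, 1e6) for r in rates]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestUnitCost:
    def test_design_basis_worked_example(self):
        fin = st.FinancialParams(discount_rate=0.08, lifetime=25)
        assert st.unit_cost(4.8e6, 14e6, 5_000.0, fin) == pytest.approx(2.89, abs=0.005)

    def test_zero_costs(self):
        fin = st.FinancialParams()
        assert st.unit_cost(0.0, 0.0, 5_000.0, fin) == 0.0

    def test_output_proportionality(self):
        fin = st.FinancialParams()
        assert st.unit_cost(4.8e6, 14e6, 10_000.0, fin) == pytest.approx(
            st.unit_cost(4.8e6, 14e6, 5_000.0, fin) / 2
        )


class TestSample:
    def test_point_draws(self):
        spec = DistributionSpec("point", mean=5.0)
        assert np.array_equal(st.sample(spec, 3, seed=0), [5.0, 5.0, 5.0])

    def test_truncated_normal_respects_bounds_and_mean(self):
        spec = DistributionSpec(
            "truncated_normal", mean=15.0, sd=st.sd_from_ci(5.0), lower=10.0, upper=20.0
        )
        draws = st.sample(spec, 10_000, seed=42)
        assert draws.min() >= 10.0 and draws.max() <= 20.0
        assert draws.mean() == pytest.approx(15.0, abs=0.1)

    def test_uniform_midpoint(self):
        spec = DistributionSpec("uniform", lower=0.06, upper=0.10)
        draws = st.sample(spec, 10_000, seed=7)
        assert draws.mean() == pytest.approx(0.08, abs=0.001)

    def test_clip_policy_leaves_atoms_at_bounds(self):
        spec = DistributionSpec(
            "truncated_normal", mean=0.0, sd=1.0, lower=-0.5, upper=0.5
        )
        clipped = st.sample(spec, 5_000, seed=1, truncation_policy="clip")
        assert (clipped == 0.5).sum() > 0  # clipping piles mass on the bound
        resampled = st.sample(spec, 5_000, seed=1, truncation_policy="resample")
        assert (resampled == 0.5).sum() == 0

    def test_seed_reproducibility(self):
        spec = DistributionSpec("normal", mean=1.0, sd=0.5)
        assert np.array_equal(st.sample(spec, 100, seed=9), st.sample(spec, 100, seed=9))


class TestSummarize:
    def test_integer_vector_quantile_oracle(self):
        s = st.summarize(np.arange(1, 101, dtype=float))
        assert s.median == pytest.approx(50.5)
        assert s.ci90_low == pytest.approx(5.95)
        assert s.ci90_high == pytest.approx(95.05)

    def test_constant_vector(self):
        s = st.summarize(np.full(50, 3.25))
        assert (s.median, s.mean, s.ci90_low, s.ci90_high) == (3.25, 3.25, 3.25, 3.25)
        assert s.sd == 0.0

    @given(hst.lists(hst.floats(-1e6, 1e6), min_size=2, max_size=200))
    def test_negation_antisymmetry_and_order(self, xs):
        draws = np.asarray(xs)
        s, sneg = st.summarize(draws), st.summarize(-draws)
        assert sneg.median == pytest.approx(-s.median, rel=1e-9, abs=1e-9)
        assert s.ci90_low <= s.median <= s.ci90_high

    def test_empty_rejected(self):
        with pytest.raises(st.ConfigError):
            st.summarize(np.array([]))


class TestSimulateScenario:
    def test_point_distributions_reproduce_deterministic_exactly(self, point_params):
        det = st.evaluate_deterministic(point_params, "scenario1")
        res = st.simulate_scenario(
            "scenario1", point_params, mc=st.MonteCarloConfig(n_draws=100, seed=0)
        )
        assert np.all(res.npv_draws == det["npv"])
        assert np.all(res.tci_draws == det["tci"])
        assert np.all(res.tpc_draws == det["tpc"])

    def test_seed_determinism(self, fixture_params):
        mc = st.MonteCarloConfig(n_draws=500, seed=11)
        a = st.simulate_scenario("scenario1", fixture_params, mc=mc)
        b = st.simulate_scenario("scenario1", fixture_params, mc=mc)
        assert np.array_equal(a.npv_draws, b.npv_draws)
        assert a.enpv == b.enpv

    def test_scenario2_dominates_scenario1(self, fixture_params):
        mc = st.MonteCarloConfig(n_draws=4_000, seed=5)
        r1 = st.simulate_scenario("scenario1", fixture_params, mc=mc)
        r2 = st.simulate_scenario("scenario2", fixture_params, mc=mc)
        assert r2.summaries["npv"].median > r1.summaries["npv"].median

    def test_enpv_is_mean_of_draws(self, fixture_params):
        res = st.simulate_scenario(
            "scenario1", fixture_params, mc=st.MonteCarloConfig(n_draws=1_000, seed=3)
        )
        assert res.enpv == pytest.approx(res.npv_draws.mean())

    def test_enpv_affine_in_price_mean(self, fixture_params):
        """The analytic slope of ENPV in a product price is stream mass (kg)
        times the annuity factor."""
        fin = fixture_params.financial
        af = st.annuity_factor(fin.discount_rate, fin.lifetime)
        mass_kg = st.product_rates(fixture_params.basis, "scenario1")["protein_product"] * 1000
        lo = st.evaluate_deterministic(
            fixture_params, "scenario1", overrides={"prices.protein_price": 12.0}
        )["npv"]
        hi = st.evaluate_deterministic(
            fixture_params, "scenario1", overrides={"prices.protein_price": 14.5}
        )["npv"]
        assert (hi - lo) / 2.5 == pytest.approx(mass_kg * af, rel=1e-9)

    def test_median_standard_error_halves_when_n_quadruples(self, fixture_params):
        """The sampling sd of the median scales as 1/sqrt(n): quadrupling the
        draw count halves it (checked over repeated seeds)."""
        def median_spread(n, seeds):
            meds = [
                st.simulate_scenario(
                    "scenario1", fixture_params,
                    mc=st.MonteCarloConfig(n_draws=n, seed=s),
                ).summaries["npv"].median
                for s in seeds
            ]
            return np.std(meds, ddof=1)

        seeds = range(40)
        ratio = median_spread(250, seeds) / median_spread(1_000, seeds)
        assert ratio == pytest.approx(2.0, abs=0.65)

    def test_unknown_scenario_errors(self, fixture_params):
        with pytest.raises(st.ConfigError, match="unknown scenario"):
            st.simulate_scenario("scenario9", fixture_params)
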