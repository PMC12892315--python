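"""Discounted-cash-flow valuation and the Monte Carlo engine.

The plant earns constant annual revenues R and pays constant annual costs C
over a T-year life (no ramp-up, no salvage); all capital is spent at t = 0:

    NPV = sum_{t=1..T} (R - C) / (1 + r)^t - TCI
        = (R - C) * AF(r, T) - TCI,       AF = (1 - (1+r)^-T) / r.

Monte Carlo propagation (default n = 10,000) samples every cost and price
distribution independently, evaluates TCI, TPC, revenue and NPV per draw,
and summarizes the resulting distributions (median, 90% CI, mean, sd).  The
expected NPV (ENPV) is the arithmetic mean of the NPV draws.

The deterministic and stochastic paths share one evaluation kernel, so a
fully degenerate (all-point) configuration reproduces the deterministic
pipeline bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .costing import annualise_capital
from .param_space import ConfigError, DistributionSpec, ParameterSet
from .process_model import DesignBasis, product_rates

__all__ = [
    "CashflowSeries",
    "MonteCarloConfig",
    "DistributionSummary",
    "ScenarioResult",
    "annuity_factor",
    "npv",
    "unit_cost",
    "sample",
    "summarize",
    "evaluate_deterministic",
    "simulate_scenario",
]


@dataclass(frozen=True)
class CashflowSeries:
    """Annual revenues and costs, £/y, for operating years t = 1..T."""

    revenues: np.ndarray
    costs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "revenues", np.asarray(self.revenues, dtype=float))
        object.__setattr__(self, "costs", np.asarray(self.costs, dtype=float))
        if self.revenues.shape != self.costs.shape or self.revenues.ndim != 1:
            raise ConfigError("CashflowSeries: revenues and costs must be equal-length 1-d")
        if not (np.isfinite(self.revenues).all() and np.isfinite(self.costs).all()):
            raise ConfigError("CashflowSeries: values must be finite")

    @classmethod
    def constant(cls, revenue: float, cost: float, lifetime: int) -> "CashflowSeries":
        return cls(np.full(lifetime, revenue), np.full(lifetime, cost))


@dataclass(frozen=True)
class MonteCarloConfig:
    """Monte Carlo settings: number of draws, seed and how truncated normals
    are realized (exact resampling vs clipping to the bounds)."""

    n_draws: int = 10_000
    seed: int = 0
    truncation_policy: str = "resample"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigError("n_draws must be >= 1")
        if self.truncation_policy not in ("resample", "clip"):
            raise ConfigError("truncation_policy must be 'resample' or 'clip'")


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number summary of a sampled distribution.  The 90% interval is
    the 5th–95th percentile band under the linear-interpolation quantile
    convention."""

    median: float
    ci90_low: float
    ci90_high: float
    mean: float
    sd: float

    def to_dict(self) -> dict[str, float]:
        return {
            "median": self.median,
            "ci90_low": self.ci90_low,
            "ci90_high": self.ci90_high,
            "mean": self.mean,
            "sd": self.sd,
        }


def summarize(draws: np.ndarray) -> DistributionSummary:
    """Median, 5th/95th percentiles (linear interpolation), mean and sample sd."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ConfigError("summarize: empty vector")
    if np.ptp(draws) == 0.0:  # degenerate vector: exact, no accumulation fuzz
        c = float(draws[0])
        return DistributionSummary(median=c, ci90_low=c, ci90_high=c, mean=c, sd=0.0)
    lo, med, hi = np.percentile(draws, [5.0, 50.0, 95.0])
    sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    return DistributionSummary(
        median=float(med), ci90_low=float(lo), ci90_high=float(hi),
        mean=float(draws.mean()), sd=sd,
    )


def annuity_factor(r: float, lifetime: int) -> float:
    """Present value of a unit annual payment over ``lifetime`` years,
    (1 - (1+r)^-T)/r; the T-year undiscounted limit as r → 0."""
    if r <= -1.0:
        raise ConfigError("discount rate must be > -1")
    if lifetime < 1:
        raise ConfigError("lifetime must be >= 1")
    if r == 0.0:
        return float(lifetime)
    return (1.0 - (1.0 + r) ** (-lifetime)) / r


def npv(cash: CashflowSeries, r: float, tci: float) -> float:
    """Net present value by explicit term-by-term discounting."""
    if r <= -1.0:
        raise ConfigError("discount rate must be > -1")
    t = np.arange(1, cash.revenues.size + 1, dtype=float)
    return float(np.sum((cash.revenues - cash.costs) / (1.0 + r) ** t) - tci)


def unit_cost(tci: float, tpc: float, protein_output_t: float, fin) -> float:
    """Unit production cost of protein, £/kg: (annualised TCI + TPC) divided
    by annual protein output."""
    if protein_output_t <= 0:
        raise ConfigError("protein output must be > 0")
    return (annualise_capital(tci, fin) + tpc) / (protein_output_t * 1000.0)


def sample(
    spec: DistributionSpec,
    n: int,
    seed: int | np.random.Generator = 0,
    truncation_policy: str = "resample",
) -> np.ndarray:
    """Draw ``n`` values from a distribution spec, reproducibly under seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return spec.sample(n, rng, truncation_policy)


# ---------------------------------------------------------------------------
# Shared evaluation kernel
# ---------------------------------------------------------------------------

def _evaluate(
    params: ParameterSet,
    scenario,
    basis: DesignBasis,
    value_of: Callable[[str, DistributionSpec], float | np.ndarray],
    discount_rate,
    revenue_mode: str = "multiproduct",
):
    """Evaluate TCI, TPC, revenue and NPV for one scenario.

    ``value_of(path, spec)`` returns either a scalar (deterministic path) or
    a draw vector (Monte Carlo path); both paths run exactly the same
    accumulation sequence, so point distributions reproduce the
    deterministic result exactly.
    """
    scen = params.scenario(scenario)
    streams = product_rates(basis, scen)

    revenue = 0.0
    for stream_id, price_name in scen.revenue_streams.items():
        if revenue_mode == "protein_only" and stream_id != "protein_product":
            continue
        spec = params.prices[price_name]
        revenue = revenue + streams[stream_id] * 1000.0 * value_of(
            f"prices.{price_name}", spec
        )

    purchase = 0.0
    for item in params.equipment_for(scen):
        purchase = purchase + value_of(f"equipment.{item.name}", item.purchase_cost)
    tci = purchase * params.factors.multiplier()

    tpc = 0.0
    for item in params.operating_for(scen):
        path = (
            f"prices.{item.price_ref}" if item.price_ref is not None
            else f"operating.{item.name}"
        )
        tpc = tpc + item.annual_usage * value_of(path, item.unit_price)

    af = annuity_factor(discount_rate, params.financial.lifetime)
    npv_value = (revenue - tpc) * af - tci
    return tci, tpc, revenue, npv_value


def evaluate_deterministic(
    params: ParameterSet,
    scenario,
    basis: DesignBasis | None = None,
    overrides: Mapping[str, float] | None = None,
    revenue_mode: str = "multiproduct",
) -> dict[str, float]:
    """Deterministic pipeline: every parameter at its distribution median,
    except those pinned by ``overrides`` (keyed by parameter path, e.g.
    ``"prices.protein_price"``, ``"equipment.spray_dryer"``,
    ``"operating.labour"``, ``"financial.discount_rate"``)."""
    basis = basis or params.basis
    overrides = dict(overrides or {})
    r = overrides.pop("financial.discount_rate", params.financial.discount_rate)

    used = set()

    def value_of(path: str, spec: DistributionSpec) -> float:
        if path in overrides:
            used.add(path)
            return float(overrides[path])
        return spec.median()

    tci, tpc, revenue, npv_value = _evaluate(
        params, scenario, basis, value_of, r, revenue_mode
    )
    unused = set(overrides) - used
    if unused:
        raise ConfigError(f"overrides matched no parameter: {sorted(unused)}")
    return {"tci": tci, "tpc": tpc, "revenue": revenue, "npv": npv_value}


@dataclass
class ScenarioResult:
    """Monte Carlo output for one scenario."""

    scenario: str
    tci_draws: np.ndarray
    tpc_draws: np.ndarray
    revenue_draws: np.ndarray
    npv_draws: np.ndarray
    summaries: dict[str, DistributionSummary] = field(default_factory=dict)
    enpv: float = 0.0

    def to_summary_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_draws": int(self.npv_draws.size),
            "enpv": self.enpv,
            "p_npv_positive": float(np.mean(self.npv_draws > 0.0)),
            **{k: s.to_dict() for k, s in self.summaries.items()},
        }

    def cdf_frame(self) -> pd.DataFrame:
        """Empirical cumulative distribution of NPV (sorted value, i/n)."""
        x = np.sort(self.npv_draws)
        return pd.DataFrame(
            {"npv": x, "cumulative_probability": np.arange(1, x.size + 1) / x.size}
        )


def simulate_scenario(
    scenario,
    params: ParameterSet,
    basis: DesignBasis | None = None,
    mc: MonteCarloConfig = MonteCarloConfig(),
) -> ScenarioResult:
    """Monte Carlo simulation of one scenario.

    Samples every equipment cost, operating unit price and product price
    independently (n = ``mc.n_draws``), evaluates TCI, TPC, revenue and NPV
    per draw, and returns draws plus summaries.  Sampling order follows the
    configuration order, so identical (seed, n, params) gives identical
    results.
    """
    basis = basis or params.basis
    scen = params.scenario(scenario)
    rng = np.random.default_rng(mc.seed)
    cache: dict[str, np.ndarray] = {}

    def value_of(path: str, spec: DistributionSpec) -> np.ndarray:
        # one draw vector per parameter path; a shared price-book reference
        # (e.g. the silage price) is sampled once per draw
        if path not in cache:
            try:
                cache[path] = spec.sample(mc.n_draws, rng, mc.truncation_policy)
            except Exception as err:  # pragma: no cover - defensive
                raise ConfigError(f"sampling failed for {path}: {err}") from err
        return cache[path]

    tci, tpc, revenue, npv_draws = _evaluate(
        params, scen, basis, value_of, params.financial.discount_rate
    )
    # with a single revenue stream zeroed everywhere these can be scalars
    tci = np.broadcast_to(np.asarray(tci, dtype=float), (mc.n_draws,)).copy()
    tpc = np.broadcast_to(np.asarray(tpc, dtype=float), (mc.n_draws,)).copy()
    revenue = np.broadcast_to(np.asarray(revenue, dtype=float), (mc.n_draws,)).copy()
    npv_draws = np.broadcast_to(np.asarray(npv_draws, dtype=float), (mc.n_draws,)).copy()

    return ScenarioResult(
        scenario=scen.name,
        tci_draws=tci,
        tpc_draws=tpc,
        revenue_draws=revenue,
        npv_draws=npv_draws,
        summaries={
            "tci": summarize(tci),
            "tpc": summarize(tpc),
            "npv": summarize(npv_draws),
        },
        enpv=float(npv_draws[0]) if np.ptp(npv_draws) == 0.0 else float(npv_draws.mean()),
    )
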