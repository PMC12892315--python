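"""One-at-a-time sensitivity analysis and design-lever sweeps.

Implements the classic tornado construction (vary one input across its
uncertainty range while pinning every other parameter at its median), sweeps
over protein extraction efficiency, plant scale and discount rate, the
marginal-gain tabulation for extraction improvements, and the break-even
(minimum selling) protein price.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .costing import capital_recovery_factor
from .economics import (
    MonteCarloConfig,
    annuity_factor,
    evaluate_deterministic,
    simulate_scenario,
)
from .param_space import ConfigError, ParameterSet
from .process_model import DesignBasis, product_rates, scale_design

__all__ = [
    "TornadoEntry",
    "SweepResult",
    "MarginalGainRow",
    "MarginalGainTable",
    "default_tornado_parameters",
    "oat_tornado",
    "extraction_sweep",
    "marginal_gains",
    "scale_sweep",
    "breakeven_price",
    "discount_rate_sweep",
]

# operating categories that scale linearly with throughput; the rest follow
# the capital-scaling exponent (they track plant size, not material flow)
VARIABLE_CATEGORIES = frozenset({"raw_material", "utility", "membrane_replacement"})


@dataclass(frozen=True)
class TornadoEntry:
    """ENPV evaluated at a parameter's lower and upper bound."""

    name: str
    low: float
    high: float
    enpv_at_low: float
    enpv_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.enpv_at_high - self.enpv_at_low)


@dataclass
class SweepResult:
    """ENPV (and unit cost / break-even price where defined) over a lever grid."""

    lever: str
    grid: np.ndarray
    enpv: np.ndarray
    unit_cost: np.ndarray | None = None
    breakeven_price: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.enpv = np.asarray(self.enpv, dtype=float)
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ConfigError("sweep grid must be strictly increasing")
        if self.grid.shape != self.enpv.shape:
            raise ConfigError("sweep grid and enpv must have equal length")

    def to_frame(self) -> pd.DataFrame:
        d = {self.lever: self.grid, "enpv": self.enpv}
        if self.unit_cost is not None:
            d["unit_cost"] = self.unit_cost
        if self.breakeven_price is not None:
            d["breakeven_price"] = self.breakeven_price
        return pd.DataFrame(d)


@dataclass(frozen=True)
class MarginalGainRow:
    """ENPV gain per extra gram of protein recovered per 100 g silage."""

    range_low: float
    range_high: float
    enpv_change: float  # £M over the range
    marginal_gain: float  # £M per g, rounded to 1 decimal


@dataclass
class MarginalGainTable:
    rows: list[MarginalGainRow]
    average: float  # unweighted mean of row gains
    sd: float  # sample sd across row gains

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])


def default_tornado_parameters(
    params: ParameterSet, scenario
) -> list[tuple[str, float, float]]:
    """Default OAT parameter list: every price-book entry that enters the
    scenario (as revenue or feedstock cost) over its bounds (truncation
    limits, or the 95% normal interval), plus the discount rate over 6–12%."""
    scen = params.scenario(scenario)
    names = set(scen.revenue_streams.values())
    names.update(
        it.price_ref for it in params.operating_for(scen) if it.price_ref is not None
    )
    out = []
    for name in sorted(names):
        lo, hi = params.prices[name].bounds(0.95)
        out.append((f"prices.{name}", lo, hi))
    out.append(("financial.discount_rate", 0.06, 0.12))
    return out


def oat_tornado(
    scenario,
    params: ParameterSet,
    basis: DesignBasis | None = None,
    parameters: Sequence[tuple[str, float, float]] | None = None,
    method: str = "deterministic",
    mc: MonteCarloConfig | None = None,
) -> list[TornadoEntry]:
    """One-at-a-time tornado: ENPV at each parameter's low and high bound.

    ``deterministic`` pins all other parameters at their medians and
    evaluates ENPV directly (exact for a model affine in its inputs);
    ``montecarlo`` re-runs the full simulation per bound with the swept
    parameter degenerate.  Entries are sorted by swing, largest first.
    """
    if parameters is None:
        parameters = default_tornado_parameters(params, scenario)
    if method not in ("deterministic", "montecarlo"):
        raise ConfigError("method must be 'deterministic' or 'montecarlo'")
    mc = mc or MonteCarloConfig()
    entries = []
    for path, lo, hi in parameters:
        if lo > hi:
            raise ConfigError(f"tornado parameter {path}: low > high")
        vals = []
        for bound in (lo, hi):
            if method == "deterministic":
                vals.append(
                    evaluate_deterministic(
                        params, scenario, basis, overrides={path: bound}
                    )["npv"]
                )
            else:
                vals.append(
                    simulate_scenario(
                        scenario, _pin(params, path, bound), basis, mc
                    ).enpv
                )
        entries.append(
            TornadoEntry(name=path, low=lo, high=hi,
                         enpv_at_low=vals[0], enpv_at_high=vals[1])
        )
    return sorted(entries, key=lambda e: e.swing, reverse=True)


def _pin(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Copy of ``params`` with one parameter degenerated to a point value."""
    from .param_space import DistributionSpec, PriceBook, FinancialParams

    pt = DistributionSpec("point", mean=value)
    if path == "financial.discount_rate":
        return dataclasses.replace(
            params, financial=dataclasses.replace(params.financial, discount_rate=value)
        )
    kind, _, name = path.partition(".")
    if kind == "prices":
        book = PriceBook(
            **{
                f: (pt if f == name else getattr(params.prices, f))
                for f in type(params.prices).__dataclass_fields__
            }
        )
        return dataclasses.replace(params, prices=book)
    if kind == "equipment":
        eq = [
            dataclasses.replace(it, purchase_cost=pt) if it.name == name else it
            for it in params.equipment
        ]
        return dataclasses.replace(params, equipment=eq)
    if kind == "operating":
        op = [
            dataclasses.replace(it, unit_price=pt, price_ref=None)
            if it.name == name else it
            for it in params.operating_items
        ]
        return dataclasses.replace(params, operating_items=op)
    raise ConfigError(f"unknown parameter path {path!r}")


def extraction_sweep(
    scenario,
    params: ParameterSet,
    basis: DesignBasis | None = None,
    grid: Sequence[float] | None = None,
    revenue_mode: str = "multiproduct",
) -> SweepResult:
    """ENPV versus protein extraction efficiency (g protein / 100 g silage).

    Protein output is recomputed at each grid point with capacity held
    fixed; ``protein_only`` zeroes all coproduct revenues.
    """
    basis = basis or params.basis
    grid = np.linspace(0.0, 15.0, 16) if grid is None else np.asarray(grid, float)
    if np.any(grid < 0) or np.any(grid > 100):
        raise ConfigError("extraction grid must lie in [0, 100] g/100 g")
    fin = params.financial
    enpv = np.empty(grid.size)
    ucost = np.empty(grid.size)
    for i, e in enumerate(grid):
        b = dataclasses.replace(basis, protein_extraction_efficiency=float(e))
        res = evaluate_deterministic(params, scenario, b, revenue_mode=revenue_mode)
        enpv[i] = res["npv"]
        protein_t = product_rates(b, params.scenario(scenario))["protein_product"]
        ucost[i] = (
            (res["tci"] * capital_recovery_factor(fin.discount_rate, fin.lifetime)
             + res["tpc"]) / (protein_t * 1000.0)
            if protein_t > 0 else np.inf
        )
    return SweepResult(
        lever="protein_extraction_efficiency", grid=grid, enpv=enpv, unit_cost=ucost
    )


def marginal_gains(
    enpv_by_range: Sequence[tuple[tuple[float, float], float]],
) -> MarginalGainTable:
    """Marginal ENPV gain per gram of extra protein recovery.

    Input rows are ``((range_low, range_high), enpv_change_£M)`` with
    contiguous, positive-width ranges.  Row gains are rounded to one decimal
    (matching tabulated reporting convention); the average is the unweighted
    mean of the rounded row gains, with the sample sd across rows.
    """
    if not enpv_by_range:
        raise ConfigError("marginal_gains: empty input")
    rows = []
    prev_high = None
    for (lo, hi), change in enpv_by_range:
        if hi <= lo:
            raise ConfigError(f"marginal_gains: zero/negative-width range {lo}->{hi}")
        if prev_high is not None and not np.isclose(lo, prev_high):
            raise ConfigError("marginal_gains: ranges must be contiguous")
        prev_high = hi
        rows.append(
            MarginalGainRow(
                range_low=float(lo), range_high=float(hi), enpv_change=float(change),
                marginal_gain=round(change / (hi - lo), 1),
            )
        )
    gains = np.array([r.marginal_gain for r in rows])
    sd = float(np.std(gains, ddof=1)) if gains.size > 1 else 0.0
    return MarginalGainTable(rows=rows, average=float(gains.mean()), sd=sd)


def scale_sweep(
    scenario,
    params: ParameterSet,
    capacities: Sequence[float] | None = None,
    capital_scaling_exponent: float = 0.6,
    basis: DesignBasis | None = None,
) -> SweepResult:
    """ENPV, unit cost and break-even protein price versus plant scale.

    ``capacities`` are target protein outputs (t/y).  Relative to the base
    design: TCI and size-tracking operating items scale with capacity ratio
    to the ``capital_scaling_exponent`` power (0.6 = the classic six-tenths
    rule); material- and utility-type items and all product streams scale
    linearly.
    """
    if not 0.0 < capital_scaling_exponent <= 1.0:
        raise ConfigError("capital_scaling_exponent must be in (0, 1]")
    basis = basis or params.basis
    scen = params.scenario(scenario)
    fin = params.financial
    if capacities is None:
        capacities = np.geomspace(1_000.0, 100_000.0, 11)
    capacities = np.asarray(capacities, dtype=float)
    if np.any(capacities <= 0):
        raise ConfigError("capacities must be positive")

    base = evaluate_deterministic(params, scenario, basis)
    protein_base = product_rates(basis, scen)["protein_product"]
    var_cost = sum(
        it.annual_usage * it.unit_price.median()
        for it in params.operating_for(scen) if it.category in VARIABLE_CATEGORIES
    )
    fix_cost = base["tpc"] - var_cost
    coproduct_rev = base["revenue"] - protein_base * 1000.0 * params.prices[
        scen.revenue_streams["protein_product"]
    ].median() if "protein_product" in scen.revenue_streams else base["revenue"]

    af = annuity_factor(fin.discount_rate, fin.lifetime)
    crf = capital_recovery_factor(fin.discount_rate, fin.lifetime)
    k = capacities / protein_base
    tci = base["tci"] * k ** capital_scaling_exponent
    tpc = var_cost * k + fix_cost * k ** capital_scaling_exponent
    revenue = base["revenue"] * k
    enpv = (revenue - tpc) * af - tci
    protein_kg = capacities * 1000.0
    ucost = (tci * crf + tpc) / protein_kg
    breakeven = (tci * crf + tpc - coproduct_rev * k) / protein_kg
    return SweepResult(
        lever="protein_capacity_t_per_y", grid=capacities, enpv=enpv,
        unit_cost=ucost, breakeven_price=breakeven,
    )


def breakeven_price(
    scenario,
    params: ParameterSet,
    basis: DesignBasis | None = None,
    revenue_mode: str = "multiproduct",
    bracket: tuple[float, float] = (0.0, 1000.0),
    rel_tol: float = 1e-8,
) -> float:
    """Protein price (£/kg) at which the deterministic NPV is zero, found by
    bisection; with protein-only revenue under CRF annualisation this equals
    the unit production cost."""
    basis = basis or params.basis

    def f(p: float) -> float:
        return evaluate_deterministic(
            params, scenario, basis,
            overrides={"prices.protein_price": p}, revenue_mode=revenue_mode,
        )["npv"]

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise ConfigError(
            f"breakeven_price: no sign change on bracket {bracket} "
            f"(NPV {flo:.3g} .. {fhi:.3g})"
        )
    while hi - lo > rel_tol * max(abs(lo), abs(hi), 1e-9):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def discount_rate_sweep(
    scenario,
    params: ParameterSet,
    basis: DesignBasis | None = None,
    grid: Sequence[float] | None = None,
) -> SweepResult:
    """ENPV versus discount rate, all other parameters at medians."""
    grid = np.linspace(0.06, 0.12, 7) if grid is None else np.asarray(grid, float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ConfigError("discount-rate grid must lie in (0, 1)")
    enpv = np.array(
        [
            evaluate_deterministic(
                params, scenario, basis, overrides={"financial.discount_rate": float(r)}
            )["npv"]
            for r in grid
        ]
    )
    return SweepResult(lever="discount_rate", grid=grid, enpv=enpv)
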