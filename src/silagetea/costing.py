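"""Factored capital and operating cost evaluation.

Total capital investment (TCI) follows the classic factored approach:
purchased-equipment costs are inflated by additive direct installation
factors (piping, electrical, foundations, utilities, installation) and then
by a multiplicative indirect factor (engineering, contingency),

    TCI = [sum_i C_i * (1 + sum(direct))] * (1 + indirect).

Total production cost (TPC) is the sum of annual usage times unit price over
the operating items, aggregated by category; lump-sum categories (labour,
maintenance, fixed charges, membrane replacement) enter with usage 1 and a
£/y unit price.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from .param_space import ConfigError, DistributionSpec, PriceBook

__all__ = [
    "EquipmentItem",
    "FactorSet",
    "OperatingItem",
    "CapitalEstimate",
    "OperatingEstimate",
    "total_capital_investment",
    "total_production_cost",
    "annualise_capital",
    "capital_recovery_factor",
]

OPERATING_CATEGORIES = (
    "raw_material",
    "utility",
    "labour",
    "maintenance",
    "membrane_replacement",
    "fixed",
)


@dataclass(frozen=True)
class EquipmentItem:
    """A purchased-equipment line with an uncertain purchase cost (£)."""

    name: str
    purchase_cost: DistributionSpec
    scenarios: frozenset[str]

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "purchase_cost": self.purchase_cost.to_dict(),
            "scenarios": sorted(self.scenarios),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], path: str = "equipment") -> "EquipmentItem":
        for key in ("name", "purchase_cost", "scenarios"):
            if key not in d:
                raise ConfigError(f"{path}: missing key {key!r}")
        return cls(
            name=str(d["name"]),
            purchase_cost=DistributionSpec.from_dict(
                d["purchase_cost"], f"{path}.purchase_cost"
            ),
            scenarios=frozenset(d["scenarios"]),
        )


@dataclass(frozen=True)
class FactorSet:
    """Installation cost factors: additive direct multipliers applied to the
    purchased cost, then one multiplicative indirect factor."""

    direct: dict[str, float]
    indirect: float

    def __post_init__(self) -> None:
        for name, v in self.direct.items():
            if v < 0:
                raise ConfigError(f"factors.direct.{name} must be >= 0")
        if self.indirect < 0:
            raise ConfigError("factors.indirect must be >= 0")

    def multiplier(self) -> float:
        """Overall installed-cost multiplier (1 + Σ direct)(1 + indirect)."""
        return (1.0 + sum(self.direct.values())) * (1.0 + self.indirect)

    def to_dict(self) -> dict[str, Any]:
        return {"direct": dict(self.direct), "indirect": self.indirect}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FactorSet":
        if "direct" not in d or "indirect" not in d:
            raise ConfigError("factors: requires 'direct' mapping and 'indirect'")
        return cls(
            direct={k: float(v) for k, v in d["direct"].items()},
            indirect=float(d["indirect"]),
        )


@dataclass(frozen=True)
class OperatingItem:
    """An annual operating-cost line: ``annual_usage`` units at an uncertain
    ``unit_price``.  ``price_ref`` marks items whose unit price is shared with
    a price-book entry (e.g. the silage feedstock price)."""

    name: str
    category: str
    unit_price: DistributionSpec
    annual_usage: float
    scenarios: frozenset[str]
    price_ref: str | None = None

    def __post_init__(self) -> None:
        if self.category not in OPERATING_CATEGORIES:
            raise ConfigError(
                f"operating item {self.name!r}: unknown category {self.category!r}"
            )
        if self.annual_usage < 0:
            raise ConfigError(f"operating item {self.name!r}: usage must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "category": self.category,
            "annual_usage": self.annual_usage,
            "scenarios": sorted(self.scenarios),
        }
        if self.price_ref is not None:
            d["unit_price"] = {"ref": self.price_ref}
        else:
            d["unit_price"] = self.unit_price.to_dict()
        return d

    @classmethod
    def from_dict(
        cls, d: Mapping[str, Any], prices: PriceBook, path: str = "operating_item"
    ) -> "OperatingItem":
        for key in ("name", "category", "unit_price", "annual_usage", "scenarios"):
            if key not in d:
                raise ConfigError(f"{path}: missing key {key!r}")
        up = d["unit_price"]
        if isinstance(up, Mapping) and "ref" in up:
            ref = str(up["ref"])
            spec = prices[ref]  # raises ConfigError for unknown fields
        else:
            ref = None
            spec = DistributionSpec.from_dict(up, f"{path}.unit_price")
        return cls(
            name=str(d["name"]),
            category=str(d["category"]),
            unit_price=spec,
            annual_usage=float(d["annual_usage"]),
            scenarios=frozenset(d["scenarios"]),
            price_ref=ref,
        )


@dataclass
class CapitalEstimate:
    """TCI with a per-item installed-cost breakdown (breakdown sums to total)."""

    total: float
    breakdown: dict[str, float] = field(default_factory=dict)


@dataclass
class OperatingEstimate:
    """TPC (£/y) with per-category and per-item breakdowns."""

    total: float
    by_category: dict[str, float] = field(default_factory=dict)
    by_item: dict[str, float] = field(default_factory=dict)


def total_capital_investment(
    sampled_costs: Mapping[str, float] | Sequence[tuple[str, float]],
    factors: FactorSet,
) -> CapitalEstimate:
    """Factored TCI from sampled purchase costs (£ per item).

    Each item's installed cost is ``cost * (1 + Σ direct) * (1 + indirect)``,
    so the breakdown sums exactly to the total.
    """
    items = list(sampled_costs.items()) if isinstance(sampled_costs, Mapping) else list(
        sampled_costs
    )
    if not items:
        raise ConfigError("total_capital_investment: empty equipment list")
    mult = factors.multiplier()
    breakdown = {name: cost * mult for name, cost in items}
    total = 0.0
    for v in breakdown.values():
        total += v
    return CapitalEstimate(total=total, breakdown=breakdown)


def total_production_cost(
    sampled_items: Sequence[tuple[OperatingItem, float]],
) -> OperatingEstimate:
    """TPC from (item, sampled unit price) pairs: Σ usage × price by category."""
    if not sampled_items:
        raise ConfigError("total_production_cost: empty operating-item list")
    by_category: dict[str, float] = {}
    by_item: dict[str, float] = {}
    total = 0.0
    for item, price in sampled_items:
        annual = item.annual_usage * price
        by_item[item.name] = annual
        by_category[item.category] = by_category.get(item.category, 0.0) + annual
        total += annual
    return OperatingEstimate(total=total, by_category=by_category, by_item=by_item)


def capital_recovery_factor(r: float, lifetime: int) -> float:
    """Annuity factor r(1+r)^T / ((1+r)^T - 1) converting a present sum into
    an equivalent constant annual charge over ``lifetime`` years."""
    if lifetime < 1:
        raise ConfigError("lifetime must be >= 1")
    if r == 0.0:
        return 1.0 / lifetime
    g = (1.0 + r) ** lifetime
    return r * g / (g - 1.0)


def annualise_capital(tci: float, fin) -> float:
    """Equivalent annual capital charge (£/y) for ``tci``.

    Uses the capital recovery factor at the configured discount rate, or a
    straight-line ``TCI / T`` if so configured.  A zero discount rate under
    CRF degenerates to straight-line (the CRF limit as r → 0).
    """
    if tci < 0:
        raise ConfigError("TCI must be >= 0")
    if fin.annualisation_method == "straight_line":
        return tci / fin.lifetime
    return tci * capital_recovery_factor(fin.discount_rate, fin.lifetime)
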