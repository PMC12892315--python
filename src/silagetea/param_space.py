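"""Parameter space: distribution specs, configuration schema and fixtures.

Every uncertain quantity in the assessment — equipment purchase costs,
operating unit prices, product prices — is described by a declarative
:class:`DistributionSpec` (point, normal, truncated normal or uniform).  A
:class:`ParameterSet` bundles the full model configuration and round-trips
through a human-readable YAML dialect.

Because the vendor-quote cost tables behind the published assessment are not
public, :func:`generate_fixture` builds a seeded, explicitly synthetic
parametrization calibrated so that its deterministic (all-median) evaluation
reproduces the published median TCI and TPC for both scenarios.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from scipy.stats import norm, truncnorm

from .process_model import DesignBasis, YieldSet

__all__ = [
    "ConfigError",
    "DistributionSpec",
    "FinancialParams",
    "PriceBook",
    "ScenarioDefinition",
    "FixtureSpec",
    "ParameterSet",
    "sd_from_ci",
    "generate_fixture",
    "load_config",
    "save_config",
    "packaged_fixture",
]

KINDS = ("point", "normal", "truncated_normal", "uniform")

SCENARIO1 = "scenario1"
SCENARIO2 = "scenario2"


class ConfigError(ValueError):
    """Configuration or distribution validation failure (names the offending path)."""


@dataclass(frozen=True)
class DistributionSpec:
    """Declarative description of an uncertain (or fixed) scalar parameter.

    ``mean`` and ``sd`` parametrize the underlying normal for ``normal`` and
    ``truncated_normal`` kinds; ``lower``/``upper`` are hard truncation
    limits (and the support for ``uniform``).
    """

    kind: str
    mean: float | None = None
    sd: float = 0.0
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, path: str = "DistributionSpec") -> None:
        k = self.kind
        if k not in KINDS:
            raise ConfigError(f"{path}: unknown distribution kind {k!r}")
        if self.sd < 0:
            raise ConfigError(f"{path}: sd must be >= 0")
        if k == "point":
            if self.mean is None:
                raise ConfigError(f"{path}: point distribution requires a mean")
        elif k == "normal":
            if self.mean is None:
                raise ConfigError(f"{path}: normal distribution requires a mean")
            if self.sd <= 0:
                raise ConfigError(f"{path}: sd = 0 is only permitted for kind=point")
        elif k == "truncated_normal":
            if self.mean is None or self.lower is None or self.upper is None:
                raise ConfigError(
                    f"{path}: truncated_normal requires mean, lower and upper"
                )
            if self.sd <= 0:
                raise ConfigError(f"{path}: truncated_normal requires sd > 0")
            if not self.lower < self.upper:
                raise ConfigError(f"{path}: requires lower < upper")
        elif k == "uniform":
            if self.lower is None or self.upper is None:
                raise ConfigError(f"{path}: uniform requires lower and upper")
            if not self.lower < self.upper:
                raise ConfigError(f"{path}: requires lower < upper")
        if self.mean is not None:
            if self.lower is not None and self.lower > self.mean:
                raise ConfigError(f"{path}: requires lower <= mean")
            if self.upper is not None and self.mean > self.upper:
                raise ConfigError(f"{path}: requires mean <= upper")

    # -- central values -------------------------------------------------

    def _ab(self) -> tuple[float, float]:
        return (
            (self.lower - self.mean) / self.sd,
            (self.upper - self.mean) / self.sd,
        )

    def median(self) -> float:
        """Median of the distribution (used for deterministic evaluations)."""
        if self.kind in ("point", "normal"):
            return float(self.mean)
        if self.kind == "uniform":
            return 0.5 * (self.lower + self.upper)
        a, b = self._ab()
        return float(truncnorm.ppf(0.5, a, b, loc=self.mean, scale=self.sd))

    def expected(self) -> float:
        """True mean of the distribution (equals ``mean`` except under
        asymmetric truncation)."""
        if self.kind in ("point", "normal"):
            return float(self.mean)
        if self.kind == "uniform":
            return 0.5 * (self.lower + self.upper)
        a, b = self._ab()
        return float(truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    def std(self) -> float:
        if self.kind == "point":
            return 0.0
        if self.kind == "normal":
            return float(self.sd)
        if self.kind == "uniform":
            return (self.upper - self.lower) / np.sqrt(12.0)
        a, b = self._ab()
        return float(truncnorm.std(a, b, loc=self.mean, scale=self.sd))

    def bounds(self, confidence: float = 0.95) -> tuple[float, float]:
        """(low, high) range for one-at-a-time sweeps: the truncation bounds
        when stated, otherwise the two-sided normal interval at ``confidence``."""
        if self.kind == "point":
            return float(self.mean), float(self.mean)
        if self.lower is not None and self.upper is not None:
            return float(self.lower), float(self.upper)
        z = norm.ppf(0.5 + confidence / 2.0)
        return float(self.mean - z * self.sd), float(self.mean + z * self.sd)

    # -- sampling --------------------------------------------------------

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        truncation_policy: str = "resample",
    ) -> np.ndarray:
        """Draw ``n`` samples.

        ``resample`` draws from the exact truncated distribution; ``clip``
        draws from the parent normal and clips to the bounds (leaving
        probability atoms at the limits).
        """
        if self.kind == "point":
            return np.full(n, float(self.mean))
        if self.kind == "normal":
            return rng.normal(self.mean, self.sd, size=n)
        if self.kind == "uniform":
            return rng.uniform(self.lower, self.upper, size=n)
        if truncation_policy == "clip":
            return np.clip(
                rng.normal(self.mean, self.sd, size=n), self.lower, self.upper
            )
        if truncation_policy != "resample":
            raise ConfigError(f"unknown truncation_policy {truncation_policy!r}")
        a, b = self._ab()
        return np.asarray(
            truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"kind": self.kind}
        for name in ("mean", "sd", "lower", "upper"):
            v = getattr(self, name)
            if name == "sd" and self.kind in ("point", "uniform"):
                continue
            if v is not None:
                d[name] = float(v)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], path: str = "distribution") -> "DistributionSpec":
        if not isinstance(d, Mapping) or "kind" not in d:
            raise ConfigError(f"{path}: expected a mapping with a 'kind' key")
        known = {"kind", "mean", "sd", "lower", "upper"}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"{path}: unknown keys {sorted(extra)}")
        try:
            return cls(
                kind=d["kind"],
                mean=None if d.get("mean") is None else float(d["mean"]),
                sd=float(d.get("sd", 0.0)),
                lower=None if d.get("lower") is None else float(d["lower"]),
                upper=None if d.get("upper") is None else float(d["upper"]),
            )
        except ConfigError as err:
            raise ConfigError(str(err).replace("DistributionSpec", path, 1)) from None


def point(value: float) -> DistributionSpec:
    """Shorthand for a degenerate (fixed-value) distribution."""
    return DistributionSpec("point", mean=value)


def sd_from_ci(half_width: float, confidence: float = 0.95) -> float:
    """Standard deviation of a normal whose two-sided ``confidence`` interval
    has the given half-width (e.g. a 95% CI of ±£5/kg about the mean)."""
    if not 0.0 < confidence < 1.0:
        raise ConfigError("confidence must be in (0, 1)")
    if half_width < 0:
        raise ConfigError("half_width must be >= 0")
    return half_width / float(norm.ppf(0.5 + confidence / 2.0))


@dataclass(frozen=True)
class FinancialParams:
    """Discounting assumptions: rate ``discount_rate`` per year over a
    ``lifetime``-year operating life, with capital annualised either by the
    capital recovery factor or straight-line."""

    discount_rate: float = 0.08
    lifetime: int = 25
    base_year: int = 2024
    annualisation_method: str = "capital_recovery_factor"

    def __post_init__(self) -> None:
        if not 0.0 < self.discount_rate < 1.0:
            raise ConfigError("financial.discount_rate must be in (0, 1)")
        if self.lifetime < 1:
            raise ConfigError("financial.lifetime must be >= 1 year")
        if self.annualisation_method not in ("capital_recovery_factor", "straight_line"):
            raise ConfigError(
                "financial.annualisation_method must be 'capital_recovery_factor' "
                "or 'straight_line'"
            )

    def to_dict(self) -> dict[str, Any]:
        return {
            "discount_rate": self.discount_rate,
            "lifetime": self.lifetime,
            "base_year": self.base_year,
            "annualisation_method": self.annualisation_method,
        }


PRICE_FIELDS = (
    "protein_price",
    "lipid_biomass_price",
    "residual_solids_price",
    "lignin_price",
    "silage_price",
)


@dataclass(frozen=True)
class PriceBook:
    """Product and feedstock price distributions, £/kg (silage £/kg wet)."""

    protein_price: DistributionSpec
    lipid_biomass_price: DistributionSpec
    residual_solids_price: DistributionSpec
    lignin_price: DistributionSpec
    silage_price: DistributionSpec

    def __post_init__(self) -> None:
        for name in PRICE_FIELDS:
            spec = getattr(self, name)
            spec.validate(f"prices.{name}")
            if spec.lower is not None and spec.lower < 0:
                raise ConfigError(f"prices.{name}: price bounds must be >= 0")
            if spec.kind == "point" and spec.mean < 0:
                raise ConfigError(f"prices.{name}: price must be >= 0")

    def __getitem__(self, name: str) -> DistributionSpec:
        if name not in PRICE_FIELDS:
            raise ConfigError(f"prices.{name}: unknown price field")
        return getattr(self, name)

    def to_dict(self) -> dict[str, Any]:
        return {name: getattr(self, name).to_dict() for name in PRICE_FIELDS}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PriceBook":
        missing = [f for f in PRICE_FIELDS if f not in d]
        if missing:
            raise ConfigError(f"prices: missing {missing}")
        return cls(
            **{
                f: DistributionSpec.from_dict(d[f], f"prices.{f}")
                for f in PRICE_FIELDS
            }
        )


@dataclass(frozen=True)
class ScenarioDefinition:
    """A biorefinery configuration: which product streams earn revenue and
    whether the lipid fermentation train is included."""

    name: str
    revenue_streams: dict[str, str]  # stream id -> price-book field
    includes_fermentation: bool = False

    def __post_init__(self) -> None:
        for stream, price in self.revenue_streams.items():
            if price not in PRICE_FIELDS:
                raise ConfigError(
                    f"scenarios.{self.name}.revenue_streams.{stream}: "
                    f"unknown price {price!r}"
                )

    def to_dict(self) -> dict[str, Any]:
        return {
            "revenue_streams": dict(self.revenue_streams),
            "includes_fermentation": self.includes_fermentation,
        }


@dataclass(frozen=True)
class FixtureSpec:
    """Request for a synthetic 'published-like' parametrization.

    ``target_medians`` anchors the deterministic TCI/TPC of each scenario
    (keys ``tci_scenario1``, ``tci_scenario2``, ``tpc_scenario1``,
    ``tpc_scenario2``, £ and £/y); ``noise_level`` is the sd/mean ratio of the
    generated cost distributions (0 degenerates everything to point values).
    """

    seed: int = 1
    target_medians: Mapping[str, float] | None = None
    noise_level: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_level < 0.4:
            raise ConfigError("fixture.noise_level must be in [0, 0.4)")


@dataclass
class ParameterSet:
    """The full resolved model configuration."""

    financial: FinancialParams
    basis: DesignBasis
    yields: YieldSet
    prices: PriceBook
    factors: "FactorSet"
    equipment: list
    operating_items: list
    scenarios: dict[str, ScenarioDefinition]
    meta: dict = field(default_factory=dict)

    def scenario(self, name) -> ScenarioDefinition:
        if isinstance(name, ScenarioDefinition):
            return name
        try:
            return self.scenarios[name]
        except KeyError:
            raise ConfigError(f"unknown scenario {name!r}") from None

    def equipment_for(self, scenario) -> list:
        name = self.scenario(scenario).name
        return [it for it in self.equipment if name in it.scenarios]

    def operating_for(self, scenario) -> list:
        name = self.scenario(scenario).name
        return [it for it in self.operating_items if name in it.scenarios]

    def validate(self) -> list[str]:
        """Cross-field checks; returns a human-readable validation report."""
        report: list[str] = []
        if SCENARIO1 in self.scenarios and SCENARIO2 in self.scenarios:
            s1 = self.scenarios[SCENARIO1]
            s2 = self.scenarios[SCENARIO2]
            if not set(s1.revenue_streams) <= set(s2.revenue_streams):
                raise ConfigError(
                    "scenarios.scenario2 must include every scenario1 revenue stream"
                )
            if "lipid_rich_yeast" not in s2.revenue_streams:
                raise ConfigError(
                    "scenarios.scenario2 must include the lipid_rich_yeast stream"
                )
            if not s2.includes_fermentation:
                raise ConfigError("scenarios.scenario2 must include fermentation")
            report.append("scenario2 extends scenario1 with the lipid stream")
        for scen in self.scenarios:
            if not self.equipment_for(scen):
                raise ConfigError(f"scenarios.{scen}: empty equipment list")
            if not self.operating_for(scen):
                raise ConfigError(f"scenarios.{scen}: empty operating-item list")
        report.append(
            f"{len(self.equipment)} equipment items, "
            f"{len(self.operating_items)} operating items validated"
        )
        return report

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "meta": dict(self.meta),
            "financial": self.financial.to_dict(),
            "design_basis": dataclasses.asdict(self.basis),
            "yields": dataclasses.asdict(self.yields),
            "prices": self.prices.to_dict(),
            "factors": self.factors.to_dict(),
            "equipment": [it.to_dict() for it in self.equipment],
            "operating_items": [it.to_dict() for it in self.operating_items],
            "scenarios": {n: s.to_dict() for n, s in self.scenarios.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSet":
        from .costing import EquipmentItem, FactorSet, OperatingItem

        for key in ("financial", "design_basis", "yields", "prices", "factors",
                    "equipment", "operating_items", "scenarios"):
            if key not in d:
                raise ConfigError(f"config: missing top-level key {key!r}")
        try:
            fin = FinancialParams(**d["financial"])
        except TypeError as err:
            raise ConfigError(f"financial: {err}") from None
        try:
            basis = DesignBasis(**d["design_basis"])
            yields = YieldSet(**d["yields"])
        except (TypeError, ValueError) as err:
            raise ConfigError(f"design_basis/yields: {err}") from None
        prices = PriceBook.from_dict(d["prices"])
        factors = FactorSet.from_dict(d["factors"])
        equipment = [
            EquipmentItem.from_dict(e, f"equipment[{i}]")
            for i, e in enumerate(d["equipment"])
        ]
        operating = [
            OperatingItem.from_dict(o, prices, f"operating_items[{i}]")
            for i, o in enumerate(d["operating_items"])
        ]
        scenarios = {}
        for name, sd_ in d["scenarios"].items():
            try:
                scenarios[name] = ScenarioDefinition(name=name, **sd_)
            except TypeError as err:
                raise ConfigError(f"scenarios.{name}: {err}") from None
        ps = cls(
            financial=fin,
            basis=basis,
            yields=yields,
            prices=prices,
            factors=factors,
            equipment=equipment,
            operating_items=operating,
            scenarios=scenarios,
            meta=dict(d.get("meta", {})),
        )
        ps.validate()
        return ps

    def save(self, path: str | Path) -> None:
        save_config(self, path)


def save_config(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set to the YAML config dialect."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=False, default_flow_style=False)
    )


def load_config(path: str | Path) -> ParameterSet:
    """Load and validate a YAML configuration into a :class:`ParameterSet`."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"{p}: YAML parse error: {err}") from None
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{p}: config root must be a mapping")
    return ParameterSet.from_dict(raw)


def packaged_fixture() -> ParameterSet:
    """Load the reference fixture configuration shipped with the package."""
    with resources.as_file(
        resources.files("silagetea").joinpath("data/reference_fixture.yaml")
    ) as p:
        return load_config(p)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

DEFAULT_TARGETS: dict[str, float] = {
    "tci_scenario1": 4.8e6,
    "tci_scenario2": 13.5e6,
    "tpc_scenario1": 14.0e6,
    "tpc_scenario2": 16.0e6,
}

# (name, mean purchase cost £, scenario-2 only?)
_EQUIPMENT_TEMPLATE = [
    ("feed_handling_and_milling", 140_000.0, False),
    ("twin_screw_extruder", 450_000.0, False),
    ("hydrocyclone_separator", 120_000.0, False),
    ("membrane_filtration_skid", 350_000.0, False),
    ("spray_dryer", 380_000.0, False),
    ("pumps_tanks_conveyors", 96_000.0, False),
    ("alkali_pretreatment_reactor", 300_000.0, True),
    ("enzymatic_hydrolysis_tanks", 450_000.0, True),
    ("fermentation_vessels", 1_200_000.0, True),
    ("lipid_recovery_centrifuge", 450_000.0, True),
    ("fermentation_utilities_expansion", 384_000.0, True),
]

# (name, category, unit price £, annual usage, scenario-2 only?, price ref)
_OPERATING_TEMPLATE = [
    ("silage_feedstock", "raw_material", None, 33_333_000.0, False, "silage_price"),
    ("sodium_carbonate", "raw_material", 0.25, 2_000_000.0, False, None),
    ("process_water", "utility", 1.0, 200_000.0, False, None),
    ("electricity", "utility", 100.0, 25_000.0, False, None),
    ("steam", "utility", 30.0, 60_000.0, False, None),
    ("labour", "labour", 1_800_000.0, 1.0, False, None),
    ("maintenance", "maintenance", 1_000_000.0, 1.0, False, None),
    ("membrane_replacement", "membrane_replacement", 800_000.0, 1.0, False, None),
    ("fixed_overheads", "fixed", 733_380.0, 1.0, False, None),
    ("cellulase_enzymes", "raw_material", 5.0, 200_000.0, True, None),
    ("fermentation_nutrients", "raw_material", 0.9, 500_000.0, True, None),
    ("fermentation_temperature_control", "utility", 550_000.0, 1.0, True, None),
]

_DIRECT_FACTORS = {
    "piping": 0.40,
    "electrical": 0.25,
    "foundations": 0.30,
    "utilities": 0.25,
    "installation": 0.30,
}
_INDIRECT_FACTOR = 0.25


def _cost_spec(mean: float, noise_level: float) -> DistributionSpec:
    if noise_level == 0.0 or mean == 0.0:
        return point(mean)
    sd = noise_level * mean
    return DistributionSpec(
        "truncated_normal", mean=mean, sd=sd, lower=mean - 2.5 * sd, upper=mean + 2.5 * sd
    )


def _default_price_book(noise_level: float) -> PriceBook:
    protein = DistributionSpec("normal", mean=15.0, sd=sd_from_ci(5.0, 0.95))
    lipid = DistributionSpec("truncated_normal", mean=3.0, sd=0.75, lower=2.0, upper=5.0)
    residual = DistributionSpec("uniform", lower=0.06, upper=0.10)
    lignin = DistributionSpec(
        "truncated_normal", mean=0.10, sd=0.02, lower=0.04, upper=0.16
    )
    silage = DistributionSpec("uniform", lower=0.10, upper=0.18)
    book = PriceBook(protein, lipid, residual, lignin, silage)
    if noise_level == 0.0:
        book = PriceBook(
            **{f: point(getattr(book, f).median()) for f in PRICE_FIELDS}
        )
    return book


def _default_scenarios() -> dict[str, ScenarioDefinition]:
    s1_streams = {
        "protein_product": "protein_price",
        "lignin": "lignin_price",
        "ad_solids": "residual_solids_price",
    }
    s2_streams = dict(s1_streams)
    s2_streams["lipid_rich_yeast"] = "lipid_biomass_price"
    return {
        SCENARIO1: ScenarioDefinition(SCENARIO1, s1_streams, includes_fermentation=False),
        SCENARIO2: ScenarioDefinition(SCENARIO2, s2_streams, includes_fermentation=True),
    }


def generate_fixture(spec: FixtureSpec = FixtureSpec()) -> ParameterSet:
    """Build a seeded synthetic parametrization of the full assessment.

    Template item means are perturbed by a seeded ±5% factor and then each
    scenario block is rescaled so that the deterministic (all-median)
    evaluation hits the calibration targets exactly.  Identical ``spec``
    (seed, targets, noise level) reproduces an identical parameter set.
    """
    from .costing import EquipmentItem, FactorSet, OperatingItem

    targets = dict(DEFAULT_TARGETS)
    if spec.target_medians:
        for k, v in spec.target_medians.items():
            if k not in DEFAULT_TARGETS:
                raise ConfigError(f"fixture.target_medians: unknown target {k!r}")
            targets[k] = float(v)

    rng = np.random.default_rng(spec.seed)
    factors = FactorSet(direct=dict(_DIRECT_FACTORS), indirect=_INDIRECT_FACTOR)
    mult = factors.multiplier()
    prices = _default_price_book(spec.noise_level)

    # --- equipment: jitter then rescale each scenario block to target ---
    eq_means = [m * (1.0 + rng.uniform(-0.05, 0.05)) for _, m, _ in _EQUIPMENT_TEMPLATE]
    s1_sum = sum(m for m, (_, _, s2only) in zip(eq_means, _EQUIPMENT_TEMPLATE) if not s2only)
    s2_sum = sum(m for m, (_, _, s2only) in zip(eq_means, _EQUIPMENT_TEMPLATE) if s2only)
    tci1, tci2 = targets["tci_scenario1"], targets["tci_scenario2"]
    if tci2 <= tci1:
        raise ConfigError(
            "fixture.target_medians: tci_scenario2 must exceed tci_scenario1"
        )
    scale_s1 = tci1 / mult / s1_sum
    scale_s2 = (tci2 - tci1) / mult / s2_sum
    equipment = []
    for m, (name, _, s2only) in zip(eq_means, _EQUIPMENT_TEMPLATE):
        mean = m * (scale_s2 if s2only else scale_s1)
        scenarios = frozenset({SCENARIO2} if s2only else {SCENARIO1, SCENARIO2})
        equipment.append(
            EquipmentItem(name=name, purchase_cost=_cost_spec(mean, spec.noise_level),
                          scenarios=scenarios)
        )

    # --- operating items: price-referenced items are fixed, rest rescaled ---
    op_means = [
        (m * (1.0 + rng.uniform(-0.05, 0.05)) if m is not None else None)
        for _, _, m, _, _, _ in _OPERATING_TEMPLATE
    ]
    ref_contrib = sum(
        usage * prices[ref].median()
        for (_, _, _, usage, s2only, ref), m in zip(_OPERATING_TEMPLATE, op_means)
        if ref is not None and not s2only
    )
    free1 = sum(
        m * usage
        for (_, _, _, usage, s2only, ref), m in zip(_OPERATING_TEMPLATE, op_means)
        if ref is None and not s2only
    )
    free2 = sum(
        m * usage
        for (_, _, _, usage, s2only, ref), m in zip(_OPERATING_TEMPLATE, op_means)
        if ref is None and s2only
    )
    tpc1, tpc2 = targets["tpc_scenario1"], targets["tpc_scenario2"]
    if tpc1 <= ref_contrib:
        raise ConfigError(
            "fixture.target_medians: tpc_scenario1 below the price-referenced "
            "feedstock contribution — infeasible with non-negative items"
        )
    if tpc2 <= tpc1:
        raise ConfigError(
            "fixture.target_medians: tpc_scenario2 must exceed tpc_scenario1"
        )
    op_scale1 = (tpc1 - ref_contrib) / free1
    op_scale2 = (tpc2 - tpc1) / free2
    operating = []
    for (name, category, _, usage, s2only, ref), m in zip(_OPERATING_TEMPLATE, op_means):
        scenarios = frozenset({SCENARIO2} if s2only else {SCENARIO1, SCENARIO2})
        if ref is not None:
            price_spec = prices[ref]
        else:
            mean = m * (op_scale2 if s2only else op_scale1)
            price_spec = _cost_spec(mean, spec.noise_level)
        operating.append(
            OperatingItem(
                name=name, category=category, unit_price=price_spec,
                annual_usage=usage, scenarios=scenarios, price_ref=ref,
            )
        )

    ps = ParameterSet(
        financial=FinancialParams(),
        basis=DesignBasis(),
        yields=YieldSet(),
        prices=prices,
        factors=factors,
        equipment=equipment,
        operating_items=operating,
        scenarios=_default_scenarios(),
        meta={
            "name": "synthetic-reference-fixture",
            "synthetic": True,
            "seed": spec.seed,
            "noise_level": spec.noise_level,
            "target_medians": {k: float(v) for k, v in targets.items()},
        },
    )
    ps.validate()
    return ps
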