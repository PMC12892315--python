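"""Design-basis mass balance for the silage biorefinery.

Converts the plant design basis (silage throughput and per-100-g yields) into
annual product and residue mass flows.  All masses are tonnes per year on the
plant's wet-equivalent processing basis; dry-matter conversions live in
:mod:`silagetea.spatial_supply`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DesignBasis",
    "YieldSet",
    "StreamTable",
    "product_rates",
    "extraction_streams",
    "scale_design",
]


class ProcessModelError(ValueError):
    """Invalid design basis, yield set or scaling request."""


@dataclass(frozen=True)
class DesignBasis:
    """Plant design basis.

    Parameters
    ----------
    silage_capacity:
        Annual silage processing capacity, t/y (wet-equivalent basis).
    protein_extraction_efficiency:
        Recovered protein, g per 100 g silage processed.  This is the single
        protein-yield knob of the model; the base value corresponds to the
        theoretical-maximum recovery of the crude protein content.
    lipid_yield:
        Lipid-rich yeast biomass, g per 100 g silage (fermentation scenario).
    lignin_yield:
        Lignin-rich residue, g per 100 g silage.
    ad_solids:
        Dry solid residue routed to external anaerobic digestion, t/y.  Taken
        from the plant mass balance rather than computed by difference.
    """

    silage_capacity: float = 33_333.0
    protein_extraction_efficiency: float = 15.0
    lipid_yield: float = 10.0
    lignin_yield: float = 12.0
    ad_solids: float = 28_500.0

    def __post_init__(self) -> None:
        for name in (
            "silage_capacity",
            "protein_extraction_efficiency",
            "lipid_yield",
            "lignin_yield",
            "ad_solids",
        ):
            if getattr(self, name) < 0:
                raise ProcessModelError(f"DesignBasis.{name} must be >= 0")
        if self.protein_extraction_efficiency > 100:
            raise ProcessModelError(
                "DesignBasis.protein_extraction_efficiency must be <= 100 g/100 g"
            )


@dataclass(frozen=True)
class YieldSet:
    """Experimental extraction stream splits (all mass fractions in [0, 1]).

    ``solubilized_fraction`` is the share of biomass solubilized into the
    liquid phase by the mechanochemical step; ``protein_liquid_recovery`` the
    share of total protein recovered in that liquid; ``concentrate_purity``
    the protein content of the membrane concentrate on a dry basis; and
    ``crude_protein_content`` the crude protein fraction of dry silage.
    """

    solubilized_fraction: float = 0.22
    protein_liquid_recovery: float = 0.52
    concentrate_purity: float = 0.60
    crude_protein_content: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "solubilized_fraction",
            "protein_liquid_recovery",
            "concentrate_purity",
            "crude_protein_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ProcessModelError(f"YieldSet.{name} must be in [0, 1], got {v}")


@dataclass
class StreamTable:
    """Annual mass flows keyed by stream id (t/y).  Missing streams read 0."""

    masses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.masses.items():
            if v < 0:
                raise ProcessModelError(f"StreamTable[{k!r}] must be >= 0, got {v}")

    def __getitem__(self, key: str) -> float:
        return self.masses.get(key, 0.0)

    def to_frame(self, scenario: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"stream": list(self.masses), "mass_t_per_y": list(self.masses.values())}
        )
        if scenario is not None:
            df["scenario"] = scenario
        return df


def _includes_fermentation(scenario) -> bool:
    if scenario is None:
        return False
    if isinstance(scenario, str):
        return scenario == "scenario2"
    return bool(getattr(scenario, "includes_fermentation"))


def product_rates(basis: DesignBasis, scenario=None) -> StreamTable:
    """Annual saleable product rates implied by the design basis.

    ``scenario`` may be a :class:`~silagetea.param_space.ScenarioDefinition`,
    the strings ``"scenario1"``/``"scenario2"``, or ``None`` (no fermentation).
    The lipid-rich yeast stream is produced only when the scenario includes
    the fermentation step.
    """
    cap = basis.silage_capacity
    yeast = cap * basis.lipid_yield / 100.0 if _includes_fermentation(scenario) else 0.0
    return StreamTable(
        {
            "protein_product": cap * basis.protein_extraction_efficiency / 100.0,
            "lipid_rich_yeast": yeast,
            "lignin": cap * basis.lignin_yield / 100.0,
            "ad_solids": basis.ad_solids,
        }
    )


def extraction_streams(basis: DesignBasis, yields: YieldSet) -> StreamTable:
    """Diagnostic extraction-step mass balance.

    Splits the feed into solubilized liquid and solid residue and reports the
    protein recovered in the liquid phase together with the mass of membrane
    concentrate at the stated purity.  These splits are diagnostic: revenue
    calculations are driven by ``protein_extraction_efficiency`` alone.
    """
    if yields.concentrate_purity == 0:
        raise ProcessModelError(
            "concentrate_purity = 0: concentrate mass is undefined"
        )
    cap = basis.silage_capacity
    liquid = cap * yields.solubilized_fraction
    recovered = cap * yields.crude_protein_content * yields.protein_liquid_recovery
    return StreamTable(
        {
            "liquid_fraction": liquid,
            "solid_residue": cap - liquid,
            "recovered_protein": recovered,
            "protein_concentrate": recovered / yields.concentrate_purity,
        }
    )


def scale_design(basis: DesignBasis, target_protein: float) -> DesignBasis:
    """Rescale the design basis to a target protein output (t/y).

    Capacity is set to ``target_protein * 100 / e``; the AD solids stream
    scales by the same capacity ratio (per-100-g yields are intensive and
    unchanged).
    """
    if target_protein <= 0:
        raise ProcessModelError("target_protein must be > 0")
    e = basis.protein_extraction_efficiency
    if e == 0:
        raise ProcessModelError("cannot scale a design with zero extraction efficiency")
    new_capacity = target_protein * 100.0 / e
    ratio = new_capacity / basis.silage_capacity
    return dataclasses.replace(
        basis, silage_capacity=new_capacity, ad_solids=basis.ad_solids * ratio
    )
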