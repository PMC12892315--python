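# Methods

## Scope and structure

`silagetea` couples five model stages behind one declarative YAML
configuration:

1. **process_model** — design-basis mass balance (annual product rates from
   per-100-g yields at fixed silage throughput);
2. **costing** — factored total capital investment (TCI) and total
   production cost (TPC);
3. **economics** — discounted-cash-flow valuation and the Monte Carlo
   engine (TCI/TPC/NPV distributions, ENPV);
4. **sensitivity** — one-at-a-time (OAT) tornado, extraction-efficiency,
   plant-scale and discount-rate sweeps, marginal gains, break-even price;
5. **spatial_supply** — radial feedstock-catchment simulation of delivered
   silage cost.

`param_space` defines the configuration schema and the synthetic fixture
generator; `cli` is a thin command-line layer writing CSV/JSON outputs and
run manifests.

## Process model

The plant is characterized by a silage processing capacity (default
33,333 t/y, wet-equivalent basis) and intensive yields per 100 g of silage:
protein extraction efficiency *e* (default 15, the theoretical-maximum
recovery of the crude protein content), lipid-rich yeast (10), lignin (12).
The AD solids stream defaults to the mass-balance figure of 28,500 t/y
rather than capacity minus protein (which would give 28,333 t/y): the
balance includes process additions, so the stated value is treated as
authoritative and scales proportionally with capacity.

*e* is the single protein-yield knob. The experimentally observed stream
splits (22 wt% solubilized, 52% of protein to the liquid, 60 wt% concentrate
purity) are reported by `extraction_streams` as diagnostics but do not feed
revenue: the assessment is yield-driven, not species- or unit-specific.
Capacity is kept on the processing basis throughout; dry-matter conversions
appear only in the spatial module.

## Costing

TCI follows the conventional factored approach — additive direct
installation factors (piping, electrical, foundations, utilities,
installation) applied to each purchase cost, then a single multiplicative
indirect factor covering engineering and contingency:

    TCI = [Σᵢ Cᵢ (1 + Σ f_direct)] (1 + f_indirect).

Direct factors are additive because that is how classic factor tables are
tabulated; contingency sits in the indirect factor. The `FactorSet` makes
both choices auditable and swappable. AD infrastructure is excluded from
TCI and digestate handling from TPC: residual solids are valorised through
external third-party facilities. Membrane replacement is a recurring £/y
operating item, not periodic capital.

TPC sums annual usage × unit price over operating items grouped into
categories (`raw_material`, `utility`, `labour`, `maintenance`,
`membrane_replacement`, `fixed`); lump-sum categories carry usage 1 and a
£/y price. Both TCI and TPC are linear in every sampled value, and their
breakdowns sum exactly to the totals.

Capital is annualised with the capital recovery factor
CRF(r,T) = r(1+r)^T/((1+r)^T − 1) by default (CRF(0.08, 25) = 0.09368); a
straight-line TCI/T option is provided because the annualisation convention
behind published unit costs of this kind is rarely stated. r = 0 under CRF
degenerates to straight line (its analytic limit).

## Economics

Cashflows are constant over the 25 operating years — no ramp-up, no salvage
value, TCI spent at t = 0 — so NPV reduces to (R − C)·AF(r,T) − TCI with
AF = (1 − (1+r)^(−T))/r; the term-by-term form is retained and tested
against the closed form. Revenue is Σ stream mass × sampled price over the
scenario's revenue streams (protein, lignin and AD solids; plus lipid-rich
yeast in scenario 2).

Monte Carlo (default n = 10,000) samples every equipment cost, operating
unit price and product price independently — independence is the stated
modelling assumption at this design stage — and evaluates the pipeline per
draw. ENPV is the arithmetic mean of the NPV draws. Implementation notes:

* Truncated normals sample the exact truncated distribution by default
  (`resample`); a `clip` policy is available but leaves probability atoms at
  the bounds.
* Summaries use the linear-interpolation quantile convention
  (`numpy.percentile` default); the 90% interval is the 5th–95th percentile
  band. Sample sd uses ddof = 1.
* The deterministic and stochastic paths share one evaluation kernel, so an
  all-point configuration reproduces the deterministic result draw-for-draw
  bit-identically (degenerate vectors short-circuit the mean/sd to avoid
  floating-point accumulation fuzz).
* All sampling flows from `numpy.random.default_rng(seed)` in configuration
  order: identical (params, n, seed) gives identical results.

## Sensitivity

OAT evaluations pin every non-swept parameter at its distribution
**median** and evaluate the swept parameter at its bounds deterministically.
Because NPV is affine in each input, this equals ENPV exactly for symmetric
distributions; for the one asymmetric truncation in the default price book
(lipid price, mean £3/kg on [2, 5]) the median understates the truncated
mean by well under 1% of ENPV. An optional `montecarlo` tornado mode re-runs
the full simulation per bound instead. Default tornado ranges are the
truncation bounds where stated, else the two-sided 95% normal interval, with
the discount rate swept over 6–12%.

The extraction sweep varies *e* over 0–15 g/100 g at fixed capacity, with a
`protein_only` mode that zeroes coproduct revenue. Marginal gains divide
tabulated ENPV changes by range width, rounded to one decimal; the average
is the unweighted mean of the row gains with the ddof = 1 sd across rows.

The scale sweep rescales the design to target protein capacities
(1,000–100,000 t/y): TCI and size-tracking operating categories (labour,
maintenance, fixed) scale with the capacity ratio to a configurable exponent
(default 0.6, the six-tenths rule — no scaling law is prescribed by the
source assessment, so the exponent is a visible knob); material and utility
items and all product streams scale linearly. Exponent 1 provably removes
all scale economies.

The break-even protein price solves deterministic NPV = 0 by bisection to
1e-8 relative tolerance; with protein-only revenue under CRF it equals the
unit production cost algebraically, and the test suite asserts that
identity numerically.

## Spatial feedstock supply

Silage is sourced radially around the plant. A central exclusion zone of
radius r₀ = 5 km (urban, infrastructure, forest) is non-harvestable and only
a fraction of the surrounding land (mean 30% in the livestock region) grows
silage, so the outer radius solves

    demand = yield × fraction × 100π (R² − r₀²)        [1 km² = 100 ha].

Mean haul distance is the area-weighted mean radial distance of the annulus,
(2/3)(R³ − r₀³)/(R² − r₀²), scaled by a 1.45 tortuosity factor; the closed
form is verified against a uniform-in-area Monte Carlo oracle to 0.1%.
Delivered cost per wet tonne is the farmgate opportunity-cost price plus
transport rate × haul × 2 (return trips price the empty backhaul at the
loaded rate; the rate is defined per loaded tonne-km to keep that doubling
explicit). n = 1,000 draws over yield, land fraction, transport rate and
farmgate price give the regional distribution, also expressed on a 95% DM
basis via cost × (0.95/0.25) = ×3.8 (equal £ per tonne of dry matter).

Regional transport-rate and farmgate distributions are not published; the
shipped profiles (Wales-like livestock, East-of-England-like arable) are
synthetic calibrations chosen once so the point-evaluated delivered cost
lands near the reported regional means (~£51 and ~£58 per wet tonne at 25%
DM). Their spreads are plausible, not fitted.

## Synthetic fixture

`generate_fixture(FixtureSpec(seed, target_medians, noise_level))` stands in
for the unavailable vendor cost tables. A template of 11 equipment items and
12 operating items is perturbed by a seeded ±5% uniform factor and each
scenario block rescaled so the deterministic evaluation hits the calibration
targets exactly (defaults: TCI £4.8M / £13.5M; TPC £14M / £16M per year).
Cost items become truncated normals with sd = noise_level × mean (default
0.10) and bounds at ±2.5 sd; `noise_level = 0` degenerates every
distribution to a point. The price book follows the stated market
distributions: protein normal, mean £15/kg with sd chosen so the 95% CI
spans £10–20/kg (sd = 5/1.95996 = £2.551); lipid-rich biomass truncated
normal, mean £3/kg on [2, 5] with sd = (upper − lower)/4 = £0.75; residual
solids uniform on £0.06–0.10/kg and silage feedstock uniform on
£0.10–0.18/kg wet (least-informative on a bounded range); lignin truncated
normal, mean £0.10/kg on [0.04, 0.16] (not published; chosen within the
residual-solids decade, and immaterial to ENPV). The protein price is left
untruncated as a plain normal per its stated form; a negative draw is a
~5.9σ event and does not occur at the n used anywhere in the package.

The fixture emulates the *statistical structure* of the assessment —
independent truncated-normal costs, the stated price distributions, the
published central values — but not the unpublished line-item magnitudes.
Consequently distribution-level results (TCI/TPC medians and CIs,
P(NPV > 0), orderings, affine sensitivities) are meaningful on the fixture,
while absolute NPV levels and tornado swing magnitudes are
fixture-dependent and are asserted only directionally in the tests.

## Problem sizes and determinism

Default study sizes are n = 10,000 draws for the TEA simulations and
n = 1,000 for the supply model; the haul-distance oracle uses 10⁶ points.
Property-based tests run derandomized. Every CLI run writes a manifest
(config SHA-256, seeds, package version) and is byte-reproducible for a
given (config, seed).

## Known limitations

* No correlation structure between parameters; no IRR, tax, depreciation,
  working capital or salvage value.
* No per-item equipment cost-capacity curves — scale effects enter only
  through the global exponent in the scale sweep.
* AD is an external off-take: no reactor sizing or biogas yield model.
* The spatial model abstracts road networks by a tortuosity factor; no
  raster land cover, network routing or multi-depot siting.
* Single base year (2024), single currency; no inflation indexing or
  market forecasting.
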