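# silagetea

Stochastic techno-economic assessment (TEA) of grass-silage biorefineries
that turn ensiled pasture biomass into food-grade protein concentrate and,
optionally, microbial lipids.

Grassland is one of the largest under-exploited biomass resources in
temperate regions, but humans cannot digest lignocellulose, so liberating
the protein requires processing: mechanochemical-assisted extraction
(twin-screw extrusion with a mild sodium-carbonate base), membrane
concentration, and — in the integrated configuration — enzymatic hydrolysis
of the residual carbohydrates followed by fermentation with an oleaginous
yeast. `silagetea` models the economics of two such plant configurations:

* **scenario1** — protein extraction only; residual solids are sold to
  external anaerobic digestion (AD).
* **scenario2** — protein plus lipid-rich yeast co-production; lignin-rich
  residue still goes to AD.

The package is aimed at bioprocess TEA practitioners who want a tested,
reproducible, fully seeded version of this class of assessment rather than
a spreadsheet.

## The model

For a plant processing 33,333 t/y of silage (wet-equivalent basis) with a
protein extraction efficiency *e* (g protein per 100 g silage, base 15),
annual product flows follow directly from the design basis (5,000 t/y
protein, 3,333 t/y oil-rich yeast, 4,000 t/y lignin, 28,500 t/y AD solids).

Capital cost uses factored estimation: purchased-equipment costs *Cᵢ* give

    TCI = [Σᵢ Cᵢ (1 + Σ f_direct)] (1 + f_indirect)

and production cost is TPC = Σ usage × unit price over the operating items.
With constant annual revenues *R* and costs *C* over a *T* = 25 y life at
discount rate *r* = 8%,

    NPV = Σ_{t=1..T} (R − C)/(1+r)^t − TCI,
    unit cost = (CRF(r,T)·TCI + TPC) / annual protein output,

with CRF the capital recovery factor. Every uncertain parameter is an
independent point / normal / truncated-normal / uniform distribution;
Monte Carlo propagation (n = 10,000) yields TCI, TPC and NPV distributions,
and ENPV is the mean of the NPV draws. One-at-a-time sensitivity, extraction
and scale sweeps, and a break-even protein price complete the economics.

A separate spatial module simulates radial silage sourcing: the catchment
outer radius solves `demand = yield × land_fraction × 100π (R² − r0²)` with
a 5 km non-harvestable core, haulage uses the area-weighted mean annulus
distance times a 1.45 road-tortuosity factor (return trips), and Monte
Carlo (n = 1,000) over yield, land fraction, transport rate and farmgate
opportunity cost gives a delivered-cost distribution per wet tonne at 25%
dry matter (convertible to a 95% DM basis).

The vendor cost tables behind the published assessment are not public, so
the package ships a seeded **synthetic** fixture
(`silagetea.generate_fixture` / `src/silagetea/data/reference_fixture.yaml`)
calibrated so its deterministic evaluation reproduces the published median
TCI (£4.8M / £13.5M) and TPC (£14M / £16M per year) of the two scenarios.

## Worked example

```
$ silagetea fixture --seed 1 --out fixture.yaml
$ silagetea simulate --config fixture.yaml --scenario scenario1 --n 10000 --seed 1 --out-dir out
scenario1: ENPV £673.5M, median NPV £673.9M (90% CI £452.1M – £896.2M)
$ silagetea simulate --config fixture.yaml --scenario scenario2 --n 10000 --seed 1 --out-dir out
scenario2: ENPV £754.5M, median NPV £754.1M (90% CI £529.7M – £978.1M)
$ silagetea supply --region wales_livestock --n 1000 --seed 1 --out-dir out
wales_livestock: £52.23 ± 14.68 per wet t (25% DM) = £198.5 ± 55.8 per t (95% DM)
```

Both scenarios are profitable across every draw (the 90% NPV intervals sit
well above zero); the integrated lipid scenario adds roughly £80M of ENPV on
this fixture at three times the capital. The supply run says a
livestock-region catchment of ~6.3 km radius delivers silage at ~£52/wet t,
i.e. ~£199/t of dry matter at analysis basis. Equivalent library calls:

```python
import silagetea as st

params = st.packaged_fixture()
result = st.simulate_scenario("scenario1", params,
                              mc=st.MonteCarloConfig(n_draws=10_000, seed=1))
print(result.enpv / 1e6)          # ENPV, £M
print(result.summaries["npv"])    # median / 90% CI / mean / sd
```

Outputs are CSV/JSON plus a `manifest.json` (config hash, seeds, version),
and a given (config, seed) pair reproduces every file byte-identically.

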