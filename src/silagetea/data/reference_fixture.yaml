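meta:
  name: synthetic-reference-fixture
  synthetic: true
  seed: 1
  noise_level: 0.1
  target_medians:
    tci_scenario1: 4800000.0
    tci_scenario2: 13500000.0
    tpc_scenario1: 14000000.0
    tpc_scenario2: 16000000.0
financial:
  discount_rate: 0.08
  lifetime: 25
  base_year: 2024
  annualisation_method: capital_recovery_factor
design_basis:
  silage_capacity: 33333.0
  protein_extraction_efficiency: 15.0
  lipid_yield: 10.0
  lignin_yield: 12.0
  ad_solids: 28500.0
yields:
  solubilized_fraction: 0.22
  protein_liquid_recovery: 0.52
  concentrate_purity: 0.6
  crude_protein_content: 0.15
prices:
  protein_price:
    kind: normal
    mean: 15.0
    sd: 2.5510672846232696
  lipid_biomass_price:
    kind: truncated_normal
    mean: 3.0
    sd: 0.75
    lower: 2.0
    upper: 5.0
  residual_solids_price:
    kind: uniform
    lower: 0.06
    upper: 0.1
  lignin_price:
    kind: truncated_normal
    mean: 0.1
    sd: 0.02
    lower: 0.04
    upper: 0.16
  silage_price:
    kind: uniform
    lower: 0.1
    upper: 0.18
factors:
  direct:
    piping: 0.4
    electrical: 0.25
    foundations: 0.3
    utilities: 0.25
    installation: 0.3
  indirect: 0.25
equipment:
- name: feed_handling_and_milling
  purchase_cost:
    kind: truncated_normal
    mean: 138010.6546847162
    sd: 13801.065468471621
    lower: 103507.99101353715
    upper: 172513.31835589523
  scenarios:
  - scenario1
  - scenario2
- name: twin_screw_extruder
  purchase_cost:
    kind: truncated_normal
    mean: 463041.1111905292
    sd: 46304.11111905292
    lower: 347280.8333928969
    upper: 578801.3889881615
  scenarios:
  - scenario1
  - scenario2
- name: hydrocyclone_separator
  purchase_cost:
    kind: truncated_normal
    mean: 113950.73018351666
    sd: 11395.073018351666
    lower: 85463.0476376375
    upper: 142438.41272939582
  scenarios:
  - scenario1
  - scenario2
- name: membrane_filtration_skid
  purchase_cost:
    kind: truncated_normal
    mean: 360080.56396372366
    sd: 36008.05639637237
    lower: 270060.42297279276
    upper: 450100.70495465456
  scenarios:
  - scenario1
  - scenario2
- name: spray_dryer
  purchase_cost:
    kind: truncated_normal
    mean: 367117.5554697372
    sd: 36711.75554697372
    lower: 275338.1666023029
    upper: 458896.9443371715
  scenarios:
  - scenario1
  - scenario2
- name: pumps_tanks_conveyors
  purchase_cost:
    kind: truncated_normal
    mean: 93799.38450777701
    sd: 9379.938450777701
    lower: 70349.53838083276
    upper: 117249.23063472126
  scenarios:
  - scenario1
  - scenario2
- name: alkali_pretreatment_reactor
  purchase_cost:
    kind: truncated_normal
    mean: 309812.0100270441
    sd: 30981.201002704413
    lower: 232359.00752028308
    upper: 387265.0125338051
  scenarios:
  - scenario2
- name: enzymatic_hydrolysis_tanks
  purchase_cost:
    kind: truncated_normal
    mean: 445886.5184644792
    sd: 44588.65184644792
    lower: 334414.88884835935
    upper: 557358.148080599
  scenarios:
  - scenario2
- name: fermentation_vessels
  purchase_cost:
    kind: truncated_normal
    mean: 1205877.0252334848
    sd: 120587.70252334849
    lower: 904407.7689251136
    upper: 1507346.281541856
  scenarios:
  - scenario2
- name: lipid_recovery_centrifuge
  purchase_cost:
    kind: truncated_normal
    mean: 428713.7743429247
    sd: 42871.37743429247
    lower: 321535.3307571935
    upper: 535892.2179286559
  scenarios:
  - scenario2
- name: fermentation_utilities_expansion
  purchase_cost:
    kind: truncated_normal
    mean: 393710.67193206726
    sd: 39371.06719320673
    lower: 295283.00394905044
    upper: 492138.33991508407
  scenarios:
  - scenario2
operating_items:
- name: silage_feedstock
  category: raw_material
  annual_usage: 33333000.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    ref: silage_price
- name: sodium_carbonate
  category: raw_material
  annual_usage: 2000000.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 0.25201422780136856
    sd: 0.02520142278013686
    lower: 0.1890106708510264
    upper: 0.3150177847517107
- name: process_water
  category: utility
  annual_usage: 200000.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 0.9871276672313937
    sd: 0.09871276672313938
    lower: 0.7403457504235452
    upper: 1.233909584039242
- name: electricity
  category: utility
  annual_usage: 25000.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 103.31912323146192
    sd: 10.331912323146192
    lower: 77.48934242359644
    upper: 129.1489040393274
- name: steam
  category: utility
  annual_usage: 60000.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 29.53388288414051
    sd: 2.953388288414051
    lower: 22.150412163105383
    upper: 36.917353605175634
- name: labour
  category: labour
  annual_usage: 1.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 1799201.8688260787
    sd: 179920.18688260787
    lower: 1349401.4016195592
    upper: 2249002.3360325983
- name: maintenance
  category: maintenance
  annual_usage: 1.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 967475.9577264042
    sd: 96747.59577264043
    lower: 725606.968294803
    upper: 1209344.9471580053
- name: membrane_replacement
  category: membrane_replacement
  annual_usage: 1.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 795597.4468139089
    sd: 79559.74468139089
    lower: 596698.0851104317
    upper: 994496.8085173861
- name: fixed_overheads
  category: fixed
  annual_usage: 1.0
  scenarios:
  - scenario1
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 714639.6837496135
    sd: 71463.96837496135
    lower: 535979.7628122101
    upper: 893299.6046870168
- name: cellulase_enzymes
  category: raw_material
  annual_usage: 200000.0
  scenarios:
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 4.941891964020574
    sd: 0.4941891964020574
    lower: 3.70641897301543
    upper: 6.177364955025717
- name: fermentation_nutrients
  category: raw_material
  annual_usage: 500000.0
  scenarios:
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 0.9340117190193014
    sd: 0.09340117190193015
    lower: 0.700508789264476
    upper: 1.1675146487741268
- name: fermentation_temperature_control
  category: utility
  annual_usage: 1.0
  scenarios:
  - scenario2
  unit_price:
    kind: truncated_normal
    mean: 544615.7476862347
    sd: 54461.57476862347
    lower: 408461.81076467596
    upper: 680769.6846077933
scenarios:
  scenario1:
    revenue_streams:
      protein_product: protein_price
      lignin: lignin_price
      ad_solids: residual_solids_price
    includes_fermentation: false
  scenario2:
    revenue_streams:
      protein_product: protein_price
      lignin: lignin_price
      ad_solids: residual_solids_price
      lipid_rich_yeast: lipid_biomass_price
    includes_fermentation: true
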