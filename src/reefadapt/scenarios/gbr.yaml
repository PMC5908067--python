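# GBR reference scenario: five Acropora millepora populations along the
# latitudinal range of the Great Barrier Reef (north to south):
#   W = Wilkie, S = Sudbury, M = Magnetic, O = Orpheus, K = Keppel.
# Census sizes are the AFS-derived effective sizes (12,500; Keppel five-fold
# smaller).  Thermal offsets are mid-summer monthly-mean differences relative
# to the mild-regime populations: +1.6 C at the warm sites (W, M), -1.8 C at
# the cool southern site (K).
#
# Migration: per-pair immigration fractions fall in the genomically estimated
# 0.1-1% range; the exact per-pair point estimates live in supplementary
# material not bundled here, so every entry below is the 0.5% midpoint
# placeholder.  rates[i][j] = fraction of destination j's offspring with
# parents from source i (source rows, destination columns; order as listed).
populations:
  - {name: W, census_size: 12500, thermal_offset: 1.6}
  - {name: S, census_size: 12500, thermal_offset: 0.0}
  - {name: M, census_size: 12500, thermal_offset: 1.6}
  - {name: O, census_size: 12500, thermal_offset: 0.0}
  - {name: K, census_size: 2500, thermal_offset: -1.8}
migration:
  order: [W, S, M, O, K]
  rates:
    - [0.000, 0.005, 0.005, 0.005, 0.005]
    - [0.005, 0.000, 0.005, 0.005, 0.005]
    - [0.005, 0.005, 0.000, 0.005, 0.005]
    - [0.005, 0.005, 0.005, 0.000, 0.005]
    - [0.005, 0.005, 0.005, 0.005, 0.000]
genetics:
  n_qtl: 10
  effect_sd: 0.2      # SD (C) of new-mutation effect sizes
  mut_rate: 1.0e-6    # per locus per gamete
  esd: 1.0            # non-heritable phenotypic noise SD (C)
  sigma: 1.0          # breadth of the thermal tolerance curve (C)
  dominance: 0.5
environment:
  anomaly_sd: 0.25    # ENSO-like i.i.d. between-generation anomaly (C)
  warming_rate: 0.05  # C per generation ~ 0.1 C per decade at 5-year generations
  burnin_stages:      # [size_divisor, mut_multiplier, generations]
    - [100, 100, 5000]
    - [10, 10, 5000]
    - [1, 1, 10000]
  demography_lead: 500       # fitness-dependent demography precedes warming
  warming_generations: 200
seed: 42
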