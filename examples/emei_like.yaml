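# Default montane-stream scenario: 18 transects spanning 485-2865 m,
# 19 species, mixed turnover/nested occupancy, 3 empty transects,
# water temperature tracking elevation at |rho| ~ 0.81.
n_sites: 18
n_species: 19
elevation_range: [485.0, 2865.0]
regime: mixed
niche_breadth: 700.0
occupancy_noise: 0.02
env_elev_rho: 0.81
n_empty_sites: 3
seed: 42
arc_km: 30.0
habitat_weight_m: 800.0
nested_order_jitter_m: 1000.0
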