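# Example pipeline configuration (all keys optional; these are the defaults
# except for the reduced plot count, which keeps the demo quick).
seed: 1

layout:
  n_transects: 10
  transect_length_m: 100
  spacing_m: 1

landscape:
  n_plots_per_group: 20
  groups:
    - Tussock Grasslands
    - Chenopod Shrublands
    - Acacia Shrublands
    - Eucalypt Woodlands
    - Acacia Forests and Woodlands
  map_range: [129, 1437]        # mean annual precipitation, mm
  shape_intercept: 1.25
  shape_slope:                  # Pareto shape change per mm MAP, by group
    Tussock Grasslands: -0.0004
    Chenopod Shrublands: -0.0004
    Acacia Shrublands: -0.0004
    Eucalypt Woodlands: 0.0
    Acacia Forests and Woodlands: 0.0
  shape_noise_sd: 0.12
  alpha_floor: 0.05
  n_species: 25
  total_cover_target: 60.0
  species_pool_size: 500
  voucher_ratio: 2.0

sad:
  xmin: null                    # null = per-plot observed minimum cover
  bias_correction: true

regression:
  n_replicates: 1000
  level: 0.90
  huber_c: 1.345
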