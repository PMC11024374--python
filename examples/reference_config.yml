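# Reference run configuration: the shipped synthetic scenario plus the
# analysis parameters. `parkequity run --config examples/reference_config.yml`
# is equivalent to `parkequity run` with the defaults.
scenario:
  seed: 7
  extent: [8000, 8000]
  road_grid: {spacing_m: 250, jitter_fraction: 0.2}
  n_residences: 500
  core_density_ratio: 4.0
  households_range: [50, 500]
  price_field:
    base: 9000
    gradient_slope: -0.6     # negative: the old dense core is the cheap side
    noise_amplitude: 800
    correlation_length_m: 600
  park_mix: {community: 10, regional: 4, citywide: 8, comprehensive: 3}
  park_area_ranges:
    community: [0.5, 2]
    regional: [2, 5]
    citywide: [5, 15]
    comprehensive: [25, 30]
  hard_fraction_range: [0.05, 0.30]
  fragmentation_levels: [1, 8]
  n_candidate_parcels: 40
  parcel_area_range_hm2: [0.8, 12]
  blocks: {nx: 8, ny: 8, mean_household_size_range: [2.4, 3.4]}
  landcover_cell_m: 2.0

weights: {w_s: 0.7236, w_fcs: 0.1931, w_esv: 0.0833}

equity: {k: 8, n_perm: 999, alpha: 0.05}

planning:
  k: 6            # planning-context override; "auto" uses the knee rule
  n_particles: 30
  n_iter: 200
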