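# Study constants used by the corrections and intake stages.
verification:
  n_analyzed: 79        # particles put through spectroscopy
  n_verified: 64        # confirmed synthetic-polymer particles
blanks:
  particles: 2          # particles found in procedural blanks
  units: 3              # control petri dishes
counts:
  total_counted: 293    # visually counted particles, all cans
  n_cans: 99            # 33 brands x 3 replicate cans
  subsample_mass_g: 50.0
consumption:
  canned_fish_g_per_week: 0.54
  fish_g_per_week: 16.84
exposure_days_per_year: [52, 156, 260]
monte_carlo:
  iterations: 10000
  percentiles: [5, 95]
composition:
  fragment_share_pct: 57.3
  fiber_share_pct: 42.7
  color_shares_pct:
    blue: 34.8
    black: 27.3
    white: 11.9
    transparent: 10.6
  size_range_mm:
    fragment: [0.06, 5.14]
    fiber: [0.27, 5.89]
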