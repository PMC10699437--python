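# Packaged synthetic end-to-end configuration: a 31-unit, four-zone,
# nine-indicator, 12-year panel with moderate positive spatial
# autocorrelation, scored with the packaged published weight tree.
simulate:
  n_units: 31
  group_sizes: [3, 10, 6, 12]
  group_names: [northeast, east, central, west]
  n_indicators: 9
  n_years: 12
  start_year: 2010
  region_effects: [0.5, -1.0, -0.5, 1.0]
  trend: 0.2
  noise_sd: 1.0
  rho: 0.4
  adjacency_spec: two_block
weights:
  mode: fixture
scope: pooled
c: 1.0
permutations: 999
alpha: 0.05
seed: 42
quadrant_years: [2010, 2021]
moran_years: [2010, 2015, 2018, 2021]
shift_epsilon: true
out_dir: results/pipeline
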