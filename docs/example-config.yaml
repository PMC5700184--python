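# Example modcart pipeline configuration (synthetic cohort).
# Run:  modcart all docs/example-config.yaml
output_dir: runs/example
seed: 1
mode: synthetic

# node lattice: 5 x 5 x 4 = 100 nodes at 6 mm spacing
lattice: [5, 5, 4]
spacing_mm: 6.0

# synthetic cohort
n_subjects: 20
n_timepoints: 120
module_sizes: [25, 25, 25, 25]
within_corr: 0.5
between_corr: 0.1
noise_sd: 1.0
trait_mean: 99.12
trait_sd: 13.23
# trait-linked effects, e.g. participation increasing with the trait at
# the first module's nodes:
effect_map:
  - cluster: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
    metric: p
    r: 0.3

# graph construction
fractions: [0.10, 0.15, 0.20, 0.25, 0.30]
min_dist_mm: 20.0
binary: true

# community detection
louvain_restarts: 5

# association statistics
voxel_p: 0.005
fwe_p: 0.05
n_sims: 2000
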