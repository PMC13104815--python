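{
  "n_cells": 600,
  "moi": 0.3,
  "seed": 42,
  "library_size": 10000,
  "sampled_cells_per_site": 120,
  "molecules_per_cell": 8.0,
  "reads_per_molecule": 2.0,
  "bottleneck_sizes": {"lung": 30, "liver": 30},
  "growth_params": {"concentration": 0.3, "population_size": 4000}
}
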