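"""Count and bin mRNAs along a synthetic neuron.

Generates one neuron with two 150 µm dendrites and a proximally decaying
mRNA density, assigns every spot to soma / dendrite / outside, and prints
per-compartment counts, per-pixel densities and the 25 µm binned
distribution.
"""

import numpy as np

from neurospot import (SyntheticConfig, assign_spots, generate_neuron,
                       place_mrnas, summarize_localization)

cfg = SyntheticConfig(n_branches=2, decay_length_um=60.0, rng_seed=1)
geom, spines = generate_neuron(cfg, np.random.default_rng(1))
mrna, truth = place_mrnas(geom, spines, cfg, np.random.default_rng(2))

assignment = assign_spots(mrna, geom)
summary = summarize_localization(assignment, geom)

print(f"spots: {len(mrna)} total, {summary.soma_count} somatic, "
      f"{summary.dendrite_count} dendritic, {summary.outside_count} outside")
print(f"density per mask pixel: soma {summary.density_soma:.4f}, "
      f"dendrite {summary.density_dendrite:.4f}")
print(f"dendrite/soma density ratio: {summary.ratio_dendrite_to_soma:.3f}")
print("per 25 um bin counts:", [int(c) for c in summary.bin_counts])
print("-> the binned counts fall off with distance from the soma, the "
      "signature of proximally concentrated dendritic mRNA transport")
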