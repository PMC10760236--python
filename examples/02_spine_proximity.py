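"""Is mRNA-spine proximity more frequent than chance?

Plants a threefold mRNA enrichment within 600 nm of PSD95 spine centers,
then compares the observed per-bin spine occupancy against the
count-preserving Monte-Carlo null (100 repeats, spines held fixed).
"""

import numpy as np

from neurospot import (AnalysisConfig, SyntheticConfig, generate_neuron,
                       place_mrnas, spine_proximity_analysis)

cfg = SyntheticConfig(n_branches=2, branch_length_um=75.0,
                      spine_enrichment=3.0, rng_seed=3)
geom, spines = generate_neuron(cfg, np.random.default_rng(3))
mrna, truth = place_mrnas(geom, spines, cfg, np.random.default_rng(4))

res = spine_proximity_analysis(mrna, spines.xyz, geom,
                               AnalysisConfig(), seed=5)
cols = ["bin", "n_spines", "freq_0", "null_mean_freq_0", "p_emp_freq_0"]
print(res[cols].round(3).to_string(index=False))
frac_obs = 1 - res["freq_0"]
frac_null = 1 - res["null_mean_freq_0"]
print(f"-> spines with >=1 mRNA: observed {frac_obs.round(2).tolist()} vs "
      f"null {frac_null.round(2).tolist()} per bin; small p_emp_freq_0 "
      "values flag bins where occupancy beats the random expectation")
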