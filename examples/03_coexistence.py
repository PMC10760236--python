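"""Do two mRNA species co-reside in the same granules?

Plants half of a partner channel within 700 nm of reference molecules
(kappa = 0.5), then contrasts the observed per-bin coexisting fraction with
the Monte-Carlo null in which partner positions are redrawn bin by bin
while the reference channel stays fixed.
"""

import numpy as np

from neurospot import (AnalysisConfig, SyntheticConfig, coexistence_analysis,
                       generate_neuron, place_mrnas, place_partner_channel)

cfg = SyntheticConfig(n_branches=2, branch_length_um=100.0,
                      coexistence_enrichment=0.5,
                      mean_partner_per_branch=50.0, rng_seed=6)
geom, spines = generate_neuron(cfg, np.random.default_rng(6))
mrna, truth = place_mrnas(geom, spines, cfg, np.random.default_rng(7))
dend_ids = truth.loc[truth["compartment"] == "dendrite", "id"].to_numpy()
partner, _ = place_partner_channel(mrna, geom, cfg, np.random.default_rng(8),
                                   reference_dendritic_ids=dend_ids)

res = coexistence_analysis(mrna, partner, geom, AnalysisConfig(), seed=9)
cols = ["bin", "n_reference", "frac_coexisting", "null_mean_frac_coexisting",
        "p_emp_frac_coexisting"]
print(res[cols].round(3).to_string(index=False))
print("-> the observed coexisting fraction sits well above the null mean: "
      "the planted co-packaging is detected as non-random colocalization")
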