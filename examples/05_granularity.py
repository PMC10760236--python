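"""Proteostasis readout: granularity of a folding-reporter signal.

Compares a smooth dendritic ROI against one where the same total intensity
is concentrated into bright aggregates, printing the coefficient of
variation (SD/mean) and the thresholded aggregate sizes.
"""

import numpy as np

from neurospot import aggregate_sizes, granularity_cv

rng = np.random.default_rng(13)
healthy = rng.normal(100.0, 5.0, size=(40, 200)).clip(min=0)

stressed = rng.normal(60.0, 5.0, size=(40, 200)).clip(min=0)
for (r, c, k) in [(10, 30, 5), (20, 90, 3), (28, 150, 2)]:
    stressed[r:r + k, c:c + k] += 2000.0

for name, img in [("healthy", healthy), ("stressed", stressed)]:
    cv = granularity_cv(img)
    sizes = aggregate_sizes(img, threshold_k=2.0)
    top = [int(s) for s in sizes[:4]]
    print(f"{name}: CV = {cv:.3f}, {len(sizes)} components above "
          f"mean + 2 SD, largest (px) = {top}")
print("-> a smooth ROI yields a low CV and only pixel-scale noise specks; "
      "aggregation concentrates signal into few pixels, raising the CV and "
      "producing the planted 25/9/4-pixel components")
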