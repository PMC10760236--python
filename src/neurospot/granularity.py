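"""Proteostasis readout from a folding-reporter fluorescence image.

When proteostasis fails, a soluble GFP-tagged folding reporter aggregates:
the signal becomes grainy. Two readouts per dendritic region of interest
(ROI), both computed on a maximum-intensity projection:

* granularity — the coefficient of variation (sample SD / mean) of the
  pixel intensities; 0 for a perfectly even signal, rising as the same
  total intensity concentrates into fewer pixels;
* aggregate sizes — connected components (8-connectivity) of pixels
  brighter than mean + k*SD of the ROI (default k = 2), in pixels,
  descending. The threshold is ROI-relative, so a uniform additive
  background does not create aggregates.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

__all__ = ["granularity_cv", "aggregate_sizes"]


def granularity_cv(intensities) -> float:
    """Coefficient of variation (sample SD over mean) of ROI intensities.

    Requires >= 2 pixels and a positive mean; a zero mean returns NaN
    (flagged undefined rather than raising, since empty dendrites occur).
    """
    v = np.asarray(intensities, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("granularity needs >= 2 pixels")
    if np.any(v < 0):
        raise ValueError("intensities must be >= 0")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def aggregate_sizes(roi: np.ndarray, threshold_k: float = 2.0,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Sizes (pixels, descending) of bright aggregates in a 2D ROI.

    A pixel is aggregate-bright if its intensity exceeds
    ``mean + threshold_k * SD`` of the ROI (statistics over ``mask`` pixels
    when given). Components use 8-connectivity. A uniform image yields no
    aggregates (SD = 0 and no pixel exceeds the mean).
    """
    img = np.asarray(roi, dtype=float)
    if img.ndim != 2:
        raise ValueError("roi must be a 2D intensity grid")
    if mask is None:
        vals = img.ravel()
        inside = np.ones_like(img, dtype=bool)
    else:
        inside = np.asarray(mask, dtype=bool)
        vals = img[inside]
    if vals.size == 0:
        return np.empty(0, dtype=int)
    thr = vals.mean() + threshold_k * vals.std(ddof=1 if vals.size > 1 else 0)
    bright = (img > thr) & inside
    labels = measure.label(bright, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]  # drop background label 0
    return np.sort(sizes[sizes > 0])[::-1].astype(int)
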