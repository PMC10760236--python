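"""Per-compartment mRNA counts, densities, binned distributions and
transcription-site quantification.

Densities are counts per mask pixel, so the dendrite/soma ratio is a
dimensionless enrichment of dendritic over somatic concentration. Nascent
transcripts at a transcription site are quantified by dividing its
integrated intensity by the unit intensity of a single mRNA, estimated as
the median intensity of cytoplasmic (non-site) spots of the same channel
and cell — the median is robust to the bright-site contamination that would
skew a mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon
import shapely

from .config import AnalysisConfig
from .errors import CalibrationError
from .geometry import NeuronGeometry, compartment_area
from .spots import SpotTable

__all__ = [
    "LocalizationSummary",
    "summarize_localization",
    "ts_nascent_count",
    "call_transcription_sites",
    "fold_enrichment",
    "welch_compare",
]

#: a spot this many times brighter than a single mRNA is a transcription-site
#: candidate
TS_INTENSITY_FACTOR = 1.5


@dataclass
class LocalizationSummary:
    """Counts and densities of one channel in one neuron."""

    soma_count: int
    dendrite_count: int
    branch_counts: np.ndarray          # per branch
    bin_counts: np.ndarray             # per 25 µm bin, trailing zeros kept
    outside_count: int
    soma_area: int                     # pixels
    dendrite_area: int                 # pixels
    density_soma: float                # spots per pixel (nan if area 0)
    density_dendrite: float
    ratio_dendrite_to_soma: float      # nan if soma density 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("soma_count", self.soma_count),
            ("dendrite_count", self.dendrite_count),
            ("outside_count", self.outside_count),
            ("soma_area_px", self.soma_area),
            ("dendrite_area_px", self.dendrite_area),
            ("density_soma", self.density_soma),
            ("density_dendrite", self.density_dendrite),
            ("ratio_dendrite_to_soma", self.ratio_dendrite_to_soma),
        ]
        rows += [(f"bin_{k}_count", int(c)) for k, c in enumerate(self.bin_counts)]
        return pd.DataFrame(rows, columns=["stat", "value"])


def summarize_localization(assignment: pd.DataFrame, geometry: NeuronGeometry,
                           bin_width: float = 25_000.0,
                           n_bins: int | None = None) -> LocalizationSummary:
    """Summarise a spot-to-compartment assignment (see ``assign_spots``).

    ``n_bins`` pads/limits the per-bin vector so distributions from neurons
    of different extents are comparable; default covers the longest branch.
    """
    comp = assignment["compartment"].to_numpy()
    soma_count = int((comp == "soma").sum())
    outside_count = int((comp == "outside").sum())
    dend = assignment[comp == "dendrite"]
    dendrite_count = int(len(dend))

    n_branches = len(geometry.branches)
    branch_counts = np.zeros(n_branches, dtype=int)
    for b, c in dend["branch"].value_counts().items():
        branch_counts[int(b)] = c

    if n_bins is None:
        n_bins = max(geometry.n_bins(bin_width), 1)
    bin_counts = np.zeros(n_bins, dtype=int)
    ks = dend["bin"].to_numpy()
    ks = ks[(ks >= 0) & (ks < n_bins)]
    np.add.at(bin_counts, ks, 1)

    soma_area = compartment_area(geometry, "soma")
    dend_area = compartment_area(geometry, "dendrite")
    density_soma = soma_count / soma_area if soma_area else float("nan")
    density_dend = dendrite_count / dend_area if dend_area else float("nan")
    if density_soma and np.isfinite(density_soma):
        ratio = density_dend / density_soma
    else:
        ratio = float("nan")
    return LocalizationSummary(
        soma_count=soma_count,
        dendrite_count=dendrite_count,
        branch_counts=branch_counts,
        bin_counts=bin_counts,
        outside_count=outside_count,
        soma_area=soma_area,
        dendrite_area=dend_area,
        density_soma=density_soma,
        density_dendrite=density_dend,
        ratio_dendrite_to_soma=ratio,
    )


def ts_nascent_count(ts_intensity: float, unit_mrna_intensity: float) -> int:
    """Nascent transcripts at a transcription site.

    Nearest integer of site intensity over single-mRNA unit intensity,
    floored at 2: a site dimmer than two mRNA equivalents would not have
    been classified as a transcription site.
    """
    if unit_mrna_intensity <= 0:
        raise CalibrationError("unit mRNA intensity must be > 0")
    return max(2, round(ts_intensity / unit_mrna_intensity))


def call_transcription_sites(spots: SpotTable,
                             nucleus: Polygon | None = None,
                             intensity_factor: float = TS_INTENSITY_FACTOR
                             ) -> pd.DataFrame:
    """Identify transcription sites and count nascent transcripts.

    The unit single-mRNA intensity is the median intensity of candidate
    cytoplasmic spots. A spot is a transcription site if its intensity
    exceeds ``intensity_factor`` times the unit and, when a nucleus polygon
    is supplied, it lies inside the nucleus; without a nucleus mask only the
    intensity rule applies.

    Returns a DataFrame ``(id, nascent_count, unit_intensity)``, one row per
    site.
    """
    if len(spots) == 0:
        raise CalibrationError("no spots to calibrate the unit mRNA intensity")
    if nucleus is not None:
        in_nuc = shapely.contains_xy(nucleus, spots.x, spots.y)
        cyto = spots.intensity[~in_nuc]
        candidates = np.flatnonzero(in_nuc)
    else:
        cyto = spots.intensity
        candidates = np.arange(len(spots))
    if len(cyto) == 0:
        raise CalibrationError("no cytoplasmic spots to calibrate against")
    unit = float(np.median(cyto))
    rows = []
    for i in candidates:
        if spots.intensity[i] > intensity_factor * unit:
            rows.append(
                (int(spots.ids[i]),
                 ts_nascent_count(spots.intensity[i], unit),
                 unit)
            )
    return pd.DataFrame(rows, columns=["id", "nascent_count", "unit_intensity"])


def fold_enrichment(values_a, values_b) -> float:
    """Mean of condition b over mean of condition a (same compartment)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ma = a.mean()
    if ma == 0:
        return float("nan")
    return float(b.mean() / ma)


def welch_compare(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t-test.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.
    Identical groups give t = 0, p = 1. Zero variance on both sides with
    different means gives p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
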