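"""Single-mRNA translation calling from two-channel spot tables.

A translating mRNA is one with a nascent-peptide (SunTag IF) spot at its
position; the IF intensity scales with the number of ribosomes reading the
mRNA, in units of the intensity of one fully synthesised peptide. The
pairing pipeline:

1. correct the peptide channel by the mean chromatic offset;
2. assign each peptide to its closest mRNA; discard pairs farther apart
   than the threshold (200 nm base plus the residual registration error);
3. de-duplicate per mRNA keeping the brightest candidate peptide, breaking
   intensity ties by distance, so that the pairing is a partial matching;
4. count ribosomes per kept peptide as round(intensity / unit), >= 1, with
   the unit estimated as the median intensity of "free" peptide spots
   (mature proteins diffused away from any mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .errors import CalibrationError
from .spots import SpotTable

__all__ = [
    "UnitPeptideIntensity",
    "TranslationCalls",
    "estimate_unit_intensity",
    "nascent_count",
    "assign_peptides",
    "percent_translating",
]

#: minimum number of mRNA-free peptide spots for a reliable unit estimate
MIN_FREE_SPOTS = 20


@dataclass
class UnitPeptideIntensity:
    """Intensity of one fully synthesised peptide (AU)."""

    value: float
    method: str = "median_free_spots"
    n_spots: int = 0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise CalibrationError("unit peptide intensity must be > 0")


def estimate_unit_intensity(peptides: SpotTable, mrnas: SpotTable,
                            threshold: float,
                            min_free: int = MIN_FREE_SPOTS
                            ) -> UnitPeptideIntensity:
    """Median intensity of peptide spots farther than ``threshold`` from any
    mRNA — mature single proteins, so their intensity is one peptide unit.

    Raises :class:`CalibrationError` with fewer than ``min_free`` such spots;
    the caller may then supply a unit value directly.
    """
    if len(mrnas):
        d, _ = cKDTree(mrnas.xyz).query(peptides.xyz)
    else:
        d = np.full(len(peptides), np.inf)
    free = d > threshold
    n_free = int(free.sum())
    if n_free < min_free:
        raise CalibrationError(
            f"only {n_free} free peptide spots (need >= {min_free}) "
            "to estimate the unit intensity")
    return UnitPeptideIntensity(
        value=float(np.median(peptides.intensity[free])), n_spots=n_free)


def nascent_count(intensity: float, unit: UnitPeptideIntensity | float) -> int:
    """Ribosomes on one mRNA: nearest integer of intensity / unit, >= 1."""
    u = unit.value if isinstance(unit, UnitPeptideIntensity) else float(unit)
    if u <= 0:
        raise CalibrationError("unit intensity must be > 0")
    return max(1, round(intensity / u))


@dataclass(eq=False)
class TranslationCalls:
    """Result of pairing one mRNA channel with one peptide channel.

    ``pairs`` has one row per mRNA: ``mrna_id``, ``peptide_id`` (-1 when
    untranslated), ``distance`` (nm, NaN when unpaired), ``peptide_intensity``
    and ``ribosomes`` (0 when untranslated). ``free_peptides`` lists peptide
    ids not paired to any mRNA.
    """

    pairs: pd.DataFrame
    free_peptides: np.ndarray
    unit: UnitPeptideIntensity | None
    threshold: float

    @property
    def n_mrnas(self) -> int:
        return len(self.pairs)

    @property
    def n_translating(self) -> int:
        return int((self.pairs["peptide_id"] >= 0).sum())

    def ribosome_histogram(self) -> pd.Series:
        r = self.pairs.loc[self.pairs["ribosomes"] > 0, "ribosomes"]
        return r.value_counts().sort_index()


def assign_peptides(mrnas: SpotTable, peptides: SpotTable,
                    base_threshold: float = 200.0,
                    chromatic_offset=(0.0, 0.0, 0.0),
                    chromatic_residual: float = 0.0,
                    unit: UnitPeptideIntensity | float | None = None,
                    ) -> TranslationCalls:
    """Pair peptide spots with mRNAs and call translating molecules.

    ``chromatic_offset`` is subtracted from peptide coordinates before any
    distance computation; the pairing threshold is
    ``base_threshold + chromatic_residual`` (the registration error that
    remains after the mean offset correction). ``unit`` may be supplied; by
    default it is estimated from the free peptide spots of this cell, and
    ribosome counts are left at 1 per translating mRNA if the estimate is
    impossible but pairing is still wanted (a CalibrationError propagates
    only from :func:`estimate_unit_intensity` when called explicitly).
    """
    if base_threshold < 0:
        raise ValueError("base_threshold must be >= 0")
    threshold = base_threshold + chromatic_residual
    corrected = peptides.shifted(-np.asarray(chromatic_offset, dtype=float))

    n_pep, n_mrna = len(peptides), len(mrnas)
    pep_to_mrna = np.full(n_pep, -1, dtype=int)   # row index into mrnas
    pep_dist = np.full(n_pep, np.nan)
    if n_pep and n_mrna:
        d, j = cKDTree(mrnas.xyz).query(corrected.xyz)
        keep = d <= threshold
        pep_to_mrna[keep] = j[keep]
        pep_dist[keep] = d[keep]

    # per-mRNA dedupe: brightest candidate peptide, then closest
    chosen_pep = np.full(n_mrna, -1, dtype=int)   # row index into peptides
    chosen_dist = np.full(n_mrna, np.nan)
    for mi in range(n_mrna):
        cand = np.flatnonzero(pep_to_mrna == mi)
        if len(cand) == 0:
            continue
        inten = corrected.intensity[cand]
        best = cand[inten == inten.max()]
        if len(best) > 1:
            best = best[np.argsort(pep_dist[best], kind="stable")][:1]
        chosen_pep[mi] = best[0]
        chosen_dist[mi] = pep_dist[best[0]]

    if unit is None:
        try:
            unit = estimate_unit_intensity(corrected, mrnas, threshold)
        except CalibrationError:
            unit = None
    uval = (unit.value if isinstance(unit, UnitPeptideIntensity)
            else unit) if unit is not None else None

    rows = []
    for mi in range(n_mrna):
        pi = chosen_pep[mi]
        if pi >= 0:
            inten = float(corrected.intensity[pi])
            ribs = nascent_count(inten, uval) if uval else 1
            rows.append((int(mrnas.ids[mi]), int(peptides.ids[pi]),
                         float(chosen_dist[mi]), inten, ribs))
        else:
            rows.append((int(mrnas.ids[mi]), -1, np.nan, np.nan, 0))
    pairs = pd.DataFrame(
        rows, columns=["mrna_id", "peptide_id", "distance",
                       "peptide_intensity", "ribosomes"])
    paired = set(pairs.loc[pairs["peptide_id"] >= 0, "peptide_id"])
    free = np.array([int(i) for i in peptides.ids if int(i) not in paired],
                    dtype=int)
    if isinstance(unit, (int, float)):
        unit = UnitPeptideIntensity(value=float(unit), method="supplied")
    return TranslationCalls(pairs=pairs, free_peptides=free, unit=unit,
                            threshold=threshold)


def percent_translating(calls: TranslationCalls,
                        assignment: pd.DataFrame | None = None,
                        scope: str = "cell") -> pd.DataFrame:
    """Percent of mRNAs with a paired nascent-peptide signal.

    ``scope="cell"`` gives one row; ``scope="dendrite"`` requires the mRNA
    compartment assignment and gives one row per branch plus a pooled
    dendritic row. Scopes with zero mRNAs are flagged with NaN percent.
    """
    pairs = calls.pairs
    translating = pairs["peptide_id"] >= 0
    if scope == "cell":
        n = len(pairs)
        pct = 100.0 * translating.sum() / n if n else np.nan
        return pd.DataFrame(
            [("cell", n, int(translating.sum()), pct)],
            columns=["scope", "n_mrnas", "n_translating", "percent"])
    if scope != "dendrite":
        raise ValueError("scope must be 'cell' or 'dendrite'")
    if assignment is None:
        raise ValueError("dendrite scope requires a compartment assignment")
    merged = pairs.merge(assignment, left_on="mrna_id", right_on="id",
                         how="left")
    dend = merged[merged["compartment"] == "dendrite"]
    rows = []
    for br, grp in dend.groupby("branch"):
        n = len(grp)
        t = int((grp["peptide_id"] >= 0).sum())
        rows.append((f"dendrite_{int(br)}", n, t,
                     100.0 * t / n if n else np.nan))
    n = len(dend)
    t = int((dend["peptide_id"] >= 0).sum())
    rows.append(("dendrite_all", n, t, 100.0 * t / n if n else np.nan))
    return pd.DataFrame(
        rows, columns=["scope", "n_mrnas", "n_translating", "percent"])
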