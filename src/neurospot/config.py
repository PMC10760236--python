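"""Analysis configuration shared across the pipeline.

All lengths are nanometres. The defaults reflect the imaging setup the
pipeline targets (widefield smFISH/IF at 107.5 nm xy pixel size, 200 nm
z-step) and the standard thresholds used for dendritic spot statistics:
25 µm dendritic bins, a 600 nm spine-proximity radius around PSD95 centers,
a 700 nm mRNA-mRNA coexistence radius (the approximate diameter of a
neuronal transport granule), and 100 Monte-Carlo repeats for null models.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


@dataclass
class AnalysisConfig:
    """Parameters of the spatial-statistics pipeline.

    Attributes
    ----------
    bin_width:
        Width of a dendritic path-distance bin, nm (default 25 000 = 25 µm).
    spine_radius:
        An mRNA within this 3D distance of a PSD95 center is counted as
        spine-proximal, nm (default 600).
    coexist_radius:
        Two mRNAs of different species within this distance coexist in one
        granule, nm (default 700).
    n_simulations:
        Monte-Carlo repeats for the count-preserving null model (default 100).
    translation_threshold_base:
        Base mRNA-peptide pairing distance, nm (default 200). The residual
        chromatic-registration error magnitude is added on top.
    chromatic_offset:
        Mean (x, y, z) coordinate shift of the peptide channel relative to
        the mRNA channel, nm; subtracted before pairing.
    chromatic_residual:
        Magnitude of the registration error remaining after the mean offset
        correction, nm; widens the pairing threshold.
    pixel_size_xy:
        Camera pixel size in the image plane, nm (default 107.5).
    z_step:
        Spacing of z-slices, nm (default 200).
    rng_seed:
        Root seed; per-neuron streams are derived from it by counter.
    alpha:
        Significance level for null-model comparisons (default 0.05).
    distance_mode:
        "3d" uses (x, y, z) Euclidean distances between observed spots;
        "2d" ignores z everywhere. The Monte-Carlo null draws 2D mask
        pixels, so simulated spots carry a surrogate z (the per-bin median
        of observed z) in "3d" mode.
    """

    bin_width: float = 25_000.0
    spine_radius: float = 600.0
    coexist_radius: float = 700.0
    n_simulations: int = 100
    translation_threshold_base: float = 200.0
    chromatic_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    chromatic_residual: float = 0.0
    pixel_size_xy: float = 107.5
    z_step: float = 200.0
    rng_seed: int = 0
    alpha: float = 0.05
    distance_mode: str = "3d"

    def __post_init__(self) -> None:
        for name in ("bin_width", "spine_radius", "coexist_radius",
                     "translation_threshold_base", "pixel_size_xy", "z_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.distance_mode not in ("2d", "3d"):
            raise ValueError("distance_mode must be '2d' or '3d'")
        if self.chromatic_residual < 0:
            raise ValueError("chromatic_residual must be >= 0")
        self.chromatic_offset = tuple(float(v) for v in self.chromatic_offset)
        if len(self.chromatic_offset) != 3:
            raise ValueError("chromatic_offset must be a 3-vector (x, y, z) in nm")

    @property
    def translation_threshold(self) -> float:
        """Effective pairing threshold: base plus residual aberration."""
        return self.translation_threshold_base + self.chromatic_residual

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromatic_offset"] = list(self.chromatic_offset)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
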