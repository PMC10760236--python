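"""In-memory container for detected single-molecule spots.

A :class:`SpotTable` holds one imaging channel of one cell: spot ids, 3D
coordinates in nanometres, and integrated intensities in arbitrary units.
It is a thin columnar wrapper (numpy arrays) because every downstream step
is vectorised over spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpotTable:
    """Detected spots of one channel, coordinates in nm.

    ``xyz`` is an (n, 3) float array; ``z`` may be zero throughout for 2D
    data. ``intensity`` is the integrated spot intensity (AU, > 0).
    ``ids`` are unique within the table.
    """

    xyz: np.ndarray
    intensity: np.ndarray
    channel_label: str
    cell_id: str = ""
    source_file: str = ""
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float).reshape(-1)
        n = len(self.xyz)
        if len(self.intensity) != n:
            raise ValueError("xyz and intensity lengths differ")
        if self.ids is None:
            self.ids = np.arange(n, dtype=int)
        else:
            self.ids = np.asarray(self.ids, dtype=int).reshape(-1)
            if len(self.ids) != n:
                raise ValueError("ids length differs from xyz")
            if len(np.unique(self.ids)) != n:
                raise ValueError("spot ids must be unique within a table")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("all spot coordinates must be finite")
        if n and not np.all(self.intensity > 0):
            raise ValueError("all spot intensities must be > 0")
        if not self.channel_label:
            raise ValueError("channel_label must be nonempty")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def select(self, mask_or_index) -> "SpotTable":
        """Subset preserving ids and metadata."""
        return SpotTable(
            xyz=self.xyz[mask_or_index],
            intensity=self.intensity[mask_or_index],
            channel_label=self.channel_label,
            cell_id=self.cell_id,
            source_file=self.source_file,
            ids=self.ids[mask_or_index],
        )

    def shifted(self, offset) -> "SpotTable":
        """Return a copy with ``offset`` (3-vector, nm) added to coordinates."""
        off = np.asarray(offset, dtype=float).reshape(3)
        return SpotTable(
            xyz=self.xyz + off,
            intensity=self.intensity.copy(),
            channel_label=self.channel_label,
            cell_id=self.cell_id,
            source_file=self.source_file,
            ids=self.ids.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x_nm": self.xyz[:, 0],
                "y_nm": self.xyz[:, 1],
                "z_nm": self.xyz[:, 2],
                "intensity": self.intensity,
            }
        )
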