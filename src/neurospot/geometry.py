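"""Neuron morphology: soma polygon, dendrite branches, masks and binning.

The morphology model is deliberately simple, matching what manual outlining
tools export: a closed soma polygon plus one polyline skeleton per dendrite
branch with a half-width. All coordinates are nanometres; masks are
rasterised in 2D at the camera pixel size, because the Monte-Carlo null
model places simulated molecules on mask pixels.

Distances "from the soma" are arc lengths along the branch skeleton from
its soma attachment point (the skeleton's first vertex), not straight-line
distances — an mRNA travels along the dendrite. Dendrites are divided into
consecutive path-distance bins of ``bin_width`` (default 25 µm), half-open
``[k*B, (k+1)*B)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from .errors import GeometryError
from .spots import SpotTable

__all__ = [
    "DendriteBranch",
    "NeuronGeometry",
    "GeometryRaster",
    "assign_spots",
    "bin_index",
    "branch_n_bins",
    "capped_bin_index",
    "compartment_area",
    "polyline_distance",
]

#: numerical tolerance (nm) for branch tie-breaking
_TIE_EPS = 1e-9


def polyline_distance(points: np.ndarray, vertices: np.ndarray):
    """Distance of 2D points to a polyline, and arc length of the projection.

    Parameters
    ----------
    points : (n, 2) array, nm
    vertices : (m, 2) array, ordered polyline vertices, nm

    Returns
    -------
    dist : (n,) shortest Euclidean distance to the polyline
    arc : (n,) arc length from the first vertex to the closest point
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    verts = np.asarray(vertices, dtype=float).reshape(-1, 2)
    if len(verts) < 2:
        raise GeometryError("a branch skeleton needs at least 2 vertices")
    seg_vec = np.diff(verts, axis=0)                     # (m-1, 2)
    seg_len = np.hypot(seg_vec[:, 0], seg_vec[:, 1])     # (m-1,)
    if np.any(seg_len == 0):
        keep = seg_len > 0
        seg_vec, seg_len = seg_vec[keep], seg_len[keep]
        verts = np.concatenate([verts[:1], verts[1:][keep]])
        if len(seg_len) == 0:
            raise GeometryError("skeleton has zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])    # (m,)

    best_d2 = np.full(len(pts), np.inf)
    best_arc = np.zeros(len(pts))
    for i in range(len(seg_len)):
        a = verts[i]
        rel = pts - a
        t = (rel @ seg_vec[i]) / (seg_len[i] ** 2)
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * seg_vec[i]
        d2 = np.sum((pts - proj) ** 2, axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_arc[closer] = cum[i] + t[closer] * seg_len[i]
    return np.sqrt(best_d2), best_arc


def branch_n_bins(length: float, bin_width: float) -> int:
    """Bins covering a branch of ``length``: ``ceil(length / B)``."""
    return max(int(np.ceil(length / bin_width)), 1)


def capped_bin_index(path_distance, length: float, bin_width: float):
    """Bin index with the branch tip folded into the terminal bin.

    Bins are half-open ``[kB, (k+1)B)`` except the last, which closes at the
    branch tip so a spot projecting exactly onto the tip still has a
    (nonempty) bin.
    """
    k = bin_index(path_distance, bin_width)
    return np.minimum(k, branch_n_bins(length, bin_width) - 1)


def bin_index(path_distance, bin_width: float):
    """0-based bin of a path distance: ``floor(d / B)`` on ``[kB, (k+1)B)``."""
    d = np.asarray(path_distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("path_distance must be >= 0")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    out = np.floor(d / bin_width).astype(int)
    return out if out.ndim else int(out)


@dataclass(eq=False)
class DendriteBranch:
    """One dendrite: skeleton polyline ordered from the soma outward.

    ``half_width`` (nm) defines the shaft mask: all pixels whose center lies
    within ``half_width`` of the skeleton.
    """

    skeleton: np.ndarray        # (m, 2) nm, [0] = soma attachment
    half_width: float           # nm

    def __post_init__(self) -> None:
        self.skeleton = np.asarray(self.skeleton, dtype=float).reshape(-1, 2)
        if len(self.skeleton) < 2:
            raise GeometryError("branch skeleton needs >= 2 vertices")
        if self.half_width <= 0:
            raise GeometryError("branch half_width must be > 0")
        if self.length <= 0:
            raise GeometryError("branch skeleton length must be > 0")

    @cached_property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.skeleton, axis=0).T)))

    def as_linestring(self) -> LineString:
        return LineString(self.skeleton)


@dataclass(eq=False)
class NeuronGeometry:
    """Soma polygon plus dendrite branches, all in nm.

    Branch skeletons must start at (or within one pixel of) the soma
    boundary; a skeleton starting farther away is re-attached at the nearest
    boundary point with a warning.
    """

    soma: Polygon
    branches: list[DendriteBranch] = field(default_factory=list)
    pixel_size_xy: float = 107.5

    def __post_init__(self) -> None:
        if not isinstance(self.soma, Polygon):
            self.soma = Polygon(np.asarray(self.soma, dtype=float))
        if not self.soma.is_valid:
            raise GeometryError("soma polygon is invalid (self-intersecting?)")
        if self.soma.area <= 0:
            raise GeometryError("soma polygon must have area > 0")
        if self.pixel_size_xy <= 0:
            raise GeometryError("pixel_size_xy must be > 0")
        fixed = []
        for b in self.branches:
            start = Point(b.skeleton[0])
            if self.soma.boundary.distance(start) > self.pixel_size_xy:
                attach = self.soma.boundary.interpolate(
                    self.soma.boundary.project(start))
                warnings.warn(
                    "branch skeleton does not start at the soma boundary; "
                    "re-attached at the nearest boundary point",
                    stacklevel=2,
                )
                b = DendriteBranch(
                    skeleton=np.vstack([[attach.x, attach.y], b.skeleton]),
                    half_width=b.half_width,
                )
            fixed.append(b)
        self.branches = fixed

    @cached_property
    def raster(self) -> "GeometryRaster":
        return GeometryRaster(self)

    def n_bins(self, bin_width: float) -> int:
        """Number of bins needed to cover the longest branch."""
        if not self.branches:
            return 0
        return max(branch_n_bins(b.length, bin_width) for b in self.branches)


class GeometryRaster:
    """2D pixel masks of a :class:`NeuronGeometry`.

    Pixels live on a global grid anchored at ``origin`` with pitch
    ``pixel_size``; pixel ``(i, j)`` has center
    ``origin + (i + 0.5, j + 0.5) * pixel_size``. Masks partition: a pixel
    inside the soma belongs to the soma only, and a pixel reachable from
    several branches is claimed by the lowest branch index.
    """

    def __init__(self, geometry: NeuronGeometry):
        self.geometry = geometry
        ps = geometry.pixel_size_xy
        self.pixel_size = ps

        minx, miny, maxx, maxy = geometry.soma.bounds
        for b in geometry.branches:
            bx0, by0 = b.skeleton.min(axis=0) - b.half_width
            bx1, by1 = b.skeleton.max(axis=0) + b.half_width
            minx, miny = min(minx, bx0), min(miny, by0)
            maxx, maxy = max(maxx, bx1), max(maxy, by1)
        self.origin = (np.floor(minx / ps) * ps, np.floor(miny / ps) * ps)

        self.soma_centers = self._rasterize_soma()
        claimed: set[tuple[int, int]] = set(map(tuple, self._to_ij(self.soma_centers)))
        self.branch_centers: list[np.ndarray] = []
        self.branch_path: list[np.ndarray] = []
        for b in geometry.branches:
            centers, path = self._rasterize_branch(b, claimed)
            claimed.update(map(tuple, self._to_ij(centers)))
            self.branch_centers.append(centers)
            self.branch_path.append(path)

    # -- grid helpers -------------------------------------------------
    def _to_ij(self, centers: np.ndarray) -> np.ndarray:
        if len(centers) == 0:
            return np.empty((0, 2), dtype=int)
        rel = (np.asarray(centers) - np.asarray(self.origin)) / self.pixel_size
        return np.floor(rel).astype(int)

    def _grid_centers(self, minx, miny, maxx, maxy) -> np.ndarray:
        ps = self.pixel_size
        x0, y0 = self.origin
        i0 = int(np.floor((minx - x0) / ps))
        i1 = int(np.ceil((maxx - x0) / ps))
        j0 = int(np.floor((miny - y0) / ps))
        j1 = int(np.ceil((maxy - y0) / ps))
        xs = x0 + (np.arange(i0, i1 + 1) + 0.5) * ps
        ys = y0 + (np.arange(j0, j1 + 1) + 0.5) * ps
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def _rasterize_soma(self) -> np.ndarray:
        centers = self._grid_centers(*self.geometry.soma.bounds)
        inside = shapely.contains_xy(self.geometry.soma, centers[:, 0], centers[:, 1])
        return centers[inside]

    def _rasterize_branch(self, branch: DendriteBranch,
                          claimed: set[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
        hw = branch.half_width
        lo = branch.skeleton.min(axis=0) - hw - self.pixel_size
        hi = branch.skeleton.max(axis=0) + hw + self.pixel_size
        centers = self._grid_centers(lo[0], lo[1], hi[0], hi[1])
        dist, path = polyline_distance(centers, branch.skeleton)
        keep = dist <= hw
        centers, path = centers[keep], path[keep]
        if claimed:
            ij = self._to_ij(centers)
            free = np.fromiter(
                (tuple(p) not in claimed for p in ij), dtype=bool, count=len(ij))
            centers, path = centers[free], path[free]
        order = np.lexsort((centers[:, 1], centers[:, 0]))
        return centers[order], path[order]

    # -- masks --------------------------------------------------------
    def bin_mask(self, branch: int, k: int, bin_width: float) -> np.ndarray:
        """Pixel centers of branch ``branch`` whose path distance is in
        ``[k*B, (k+1)*B)``. The terminal bin also takes the branch-tip cap
        (pixels projecting exactly onto the tip); bins beyond the branch end
        are empty."""
        path = self.branch_path[branch]
        L = self.geometry.branches[branch].length
        sel = (path >= k * bin_width) & (path < (k + 1) * bin_width) \
            & (path < L)
        if k == branch_n_bins(L, bin_width) - 1:
            sel |= path >= L
        return self.branch_centers[branch][sel]

    def bin_pixel_counts(self, bin_width: float, n_bins: int) -> np.ndarray:
        """(n_branches, n_bins) pixel counts per branch and bin."""
        out = np.zeros((len(self.branch_path), n_bins), dtype=int)
        for bi, path in enumerate(self.branch_path):
            if len(path):
                ks = np.floor(path / bin_width).astype(int)
                ks = ks[ks < n_bins]
                np.add.at(out[bi], ks, 1)
        return out

    def to_rle(self) -> str:
        """Masks as run-length-encoded text (debugging aid): one line per
        pixel row, ``<label> <j>: <i0>-<i1> ...`` in grid indices."""
        lines = []
        parts = [("soma", self.soma_centers)]
        parts += [(f"branch{i}", c)
                  for i, c in enumerate(self.branch_centers)]
        for label, centers in parts:
            ij = self._to_ij(centers)
            for j in np.unique(ij[:, 1]):
                cols = np.sort(ij[ij[:, 1] == j, 0])
                runs, start = [], cols[0]
                for a, b in zip(cols, cols[1:]):
                    if b != a + 1:
                        runs.append((start, a))
                        start = b
                runs.append((start, cols[-1]))
                lines.append(f"{label} {j}: "
                             + " ".join(f"{a}-{b}" for a, b in runs))
        return "\n".join(lines) + "\n"

    @property
    def soma_area(self) -> int:
        return len(self.soma_centers)

    @property
    def dendrite_area(self) -> int:
        return int(sum(len(c) for c in self.branch_centers))


def compartment_area(geometry: NeuronGeometry, compartment: str) -> int:
    """Mask area in pixels of ``"soma"`` or ``"dendrite"`` (all branches)."""
    if compartment == "soma":
        return geometry.raster.soma_area
    if compartment == "dendrite":
        return geometry.raster.dendrite_area
    raise ValueError(f"unknown compartment {compartment!r}")


def assign_spots(spots: SpotTable, geometry: NeuronGeometry,
                 bin_width: float = 25_000.0) -> pd.DataFrame:
    """Assign each spot to soma / dendrite / outside with path distance and bin.

    Soma membership is point-in-polygon; otherwise a spot belongs to the
    branch whose shaft (skeleton within ``half_width``) contains it, the
    nearest branch winning and exact ties going to the lowest branch index.
    Dendritic spots get the arc length from the soma attachment to their
    orthogonal projection on the skeleton, and ``bin = floor(d / B)``.
    Soma spots get distance 0 and no bin; spots outside every mask are kept
    with compartment ``"outside"`` so callers can report them in QC.

    Returns a DataFrame with columns ``id, compartment, branch,
    path_distance, bin`` (branch and bin are -1 where not applicable).
    """
    n = len(spots)
    compartment = np.full(n, "outside", dtype=object)
    branch = np.full(n, -1, dtype=int)
    path = np.full(n, np.nan)
    pts2d = spots.xyz[:, :2]

    if n:
        in_soma = shapely.contains_xy(geometry.soma, pts2d[:, 0], pts2d[:, 1])
        compartment[in_soma] = "soma"
        path[in_soma] = 0.0

        rest = ~in_soma
        if rest.any() and geometry.branches:
            margins = np.full((rest.sum(), len(geometry.branches)), np.inf)
            arcs = np.zeros_like(margins)
            for bi, b in enumerate(geometry.branches):
                d, a = polyline_distance(pts2d[rest], b.skeleton)
                margins[:, bi] = d - b.half_width
                arcs[:, bi] = a
            best = (margins <= margins.min(axis=1, keepdims=True) + _TIE_EPS)
            chosen = best.argmax(axis=1)          # first (lowest) tied index
            inside = margins[np.arange(len(chosen)), chosen] <= 0.0
            ridx = np.flatnonzero(rest)
            hit = ridx[inside]
            compartment[hit] = "dendrite"
            branch[hit] = chosen[inside]
            path[hit] = arcs[np.arange(len(chosen)), chosen][inside]

    bins = np.full(n, -1, dtype=int)
    dend = compartment == "dendrite"
    if dend.any():
        lengths = np.array([geometry.branches[b].length
                            for b in branch[dend]])
        bins[dend] = np.minimum(
            bin_index(path[dend], bin_width),
            np.array([branch_n_bins(L, bin_width) for L in lengths]) - 1)
    return pd.DataFrame(
        {
            "id": spots.ids,
            "compartment": compartment,
            "branch": branch,
            "path_distance": path,
            "bin": bins,
        }
    )
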