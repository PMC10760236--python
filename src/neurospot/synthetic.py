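"""Synthetic neurons and spot tables with known ground truth.

The generator emulates the data layout of a single-molecule smFISH/IF
experiment in cultured neurons: a soma with straight dendrites, PSD95
spine centers along the shafts, and per-channel spot tables whose
coordinates are constrained to the neuron masks. Ground truth (true bin,
spine association, coexistence partner, translation flag, ribosome count)
is emitted alongside, so every analysis stage can be verified end to end.

The default preset is scaled to the regime the analyses target: 150 µm
dendrites, on the order of a hundred molecules of an abundant mRNA per
dendrite against a handful of a rare one, one spine per µm of shaft, and a
107.5 nm pixel. Dendritic density decays with path distance (more molecules
proximal to the soma); optional multiplicative enrichment near spines (rho)
or planted cross-channel neighbours (kappa) create the spatial associations
the null models are meant to detect, with rho = 1 / kappa = 0 recovering a
fully random arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import DendriteBranch, NeuronGeometry, capped_bin_index
from .proximity import SpineSet
from .spots import SpotTable

__all__ = [
    "SyntheticConfig",
    "generate_neuron",
    "place_mrnas",
    "place_partner_channel",
    "emit_translation_channels",
    "synthesize_experiment",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic experiment. Lengths in the stated units."""

    # morphology
    n_branches: int = 2
    branch_length_um: float = 150.0
    branch_half_width_um: float = 1.0
    soma_radius_um: float = 10.0
    pixel_size_xy: float = 107.5          # nm
    z_slab_nm: float = 600.0              # spots' z uniform in [0, slab]

    # dendritic mRNA density
    mean_mrnas_per_branch: float = 100.0
    mean_soma_mrnas: float = 150.0
    decay_length_um: float = float("inf")  # exponential decay tau; inf = flat
    spine_density_per_um: float = 1.0
    spine_enrichment: float = 1.0          # rho; 1 = no spine association
    spine_radius_nm: float = 600.0

    # cross-channel coexistence
    mean_partner_per_branch: float = 5.0
    coexistence_enrichment: float = 0.0    # kappa in [0, 1]
    coexist_radius_nm: float = 700.0

    # translation reporter
    p_translating: float = 0.30
    ribosome_mean: float = 3.0
    ribosome_max: int = 30
    unit_peptide_intensity: float = 100.0
    intensity_cv: float = 0.10
    mean_free_peptides: float = 50.0
    colocalization_sd_nm: float = 50.0     # nascent peptide offset from mRNA

    # mRNA channel intensities / transcription sites
    unit_mrna_intensity: float = 50.0
    mrna_intensity_cv: float = 0.10
    n_transcription_sites: int = 1
    ts_nascent_range: tuple[int, int] = (2, 12)

    # imaging imperfections
    chromatic_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    localization_error_sd_nm: float = 30.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_half_width_um * 2 > self.branch_length_um:
            raise ValueError("branch width exceeds branch length")
        if not 0 <= self.coexistence_enrichment <= 1:
            raise ValueError("coexistence_enrichment must be in [0, 1]")
        if not 0 <= self.p_translating <= 1:
            raise ValueError("p_translating must be in [0, 1]")
        if self.spine_enrichment < 0:
            raise ValueError("spine_enrichment must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromatic_offset"] = list(self.chromatic_offset)
        d["ts_nascent_range"] = list(self.ts_nascent_range)
        return d


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _truncated_geometric(rng, mean: float, kmax: int, size: int) -> np.ndarray:
    """Geometric ribosome loads on {1..kmax} with the stated untruncated mean."""
    p = min(1.0, 1.0 / mean)
    k = rng.geometric(p, size=size)
    return np.minimum(k, kmax)


def generate_neuron(config: SyntheticConfig, rng=None
                    ) -> tuple[NeuronGeometry, SpineSet]:
    """Build a soma-disc + straight-branch neuron and its spine set.

    Branches radiate at evenly spaced angles from the soma boundary. Spines
    are a Poisson process along each skeleton at the configured linear
    density, offset perpendicular to the shaft edge (the mask boundary),
    with z uniform in the slab.
    """
    rng = _as_rng(config.rng_seed if rng is None else rng)
    um = 1000.0
    r = config.soma_radius_um * um
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    soma = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    branches = []
    hw = config.branch_half_width_um * um
    L = config.branch_length_um * um
    angles = 2 * np.pi * np.arange(config.n_branches) / max(config.n_branches, 1)
    for a in angles:
        u = np.array([np.cos(a), np.sin(a)])
        start = u * r
        branches.append(DendriteBranch(
            skeleton=np.vstack([start, start + u * L]), half_width=hw))
    geom = NeuronGeometry(soma=soma, branches=branches,
                          pixel_size_xy=config.pixel_size_xy)

    centers = []
    for bi, (a, b) in enumerate(zip(angles, branches)):
        n_sp = rng.poisson(config.spine_density_per_um * config.branch_length_um)
        t = np.sort(rng.uniform(0, L, size=n_sp))
        u = np.array([np.cos(a), np.sin(a)])
        nvec = np.array([-u[1], u[0]])
        side = rng.choice([-1.0, 1.0], size=n_sp)
        xy = b.skeleton[0] + np.outer(t, u) + np.outer(side * hw, nvec)
        z = rng.uniform(0, config.z_slab_nm, size=n_sp)
        centers.append(np.column_stack([xy, z]))
    all_centers = (np.concatenate(centers, axis=0)
                   if centers else np.empty((0, 3)))
    spines = SpineSet.from_points(all_centers, geom)
    return geom, spines


def _sample_pixels(rng, pixels: np.ndarray, weights: np.ndarray,
                   n: int, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` distinct mask pixels with probability ∝ weights and jitter
    within each pixel. Returns (xy positions, chosen pixel row indices)."""
    n = min(n, len(pixels))
    if n == 0:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    p = weights / weights.sum()
    idx = rng.choice(len(pixels), size=n, replace=False, p=p)
    jitter = rng.uniform(-pixel_size / 2, pixel_size / 2, size=(n, 2))
    return pixels[idx] + jitter, idx


def place_mrnas(geometry: NeuronGeometry, spines: SpineSet,
                config: SyntheticConfig, rng=None,
                channel_label: str = "mrna",
                mean_per_branch: float | None = None,
                bin_width: float = 25_000.0
                ) -> tuple[SpotTable, pd.DataFrame]:
    """Place one mRNA channel over the neuron with known ground truth.

    Dendritic molecules are an inhomogeneous Poisson draw over the branch
    mask pixels with weight ``exp(-d / tau) * (rho within spine_radius of a
    spine, 1 elsewhere)``; the Poisson mean equals ``mean_per_branch`` per
    branch when rho = 1 and the profile is flat. Somatic molecules are
    uniform over the soma mask. Gaussian localisation error is added in xy
    and z is uniform in the slab. Intensities are one mRNA unit with
    multiplicative noise; optional nuclear transcription sites pile up k
    units each.

    Returns the spot table and a ground-truth frame with one row per spot:
    ``id, compartment, branch, path_distance, bin, near_spine, is_ts,
    ts_nascent``.
    """
    rng = _as_rng(config.rng_seed if rng is None else rng)
    mean_per_branch = (config.mean_mrnas_per_branch
                       if mean_per_branch is None else mean_per_branch)
    um = 1000.0
    tau = config.decay_length_um * um
    raster = geometry.raster
    ps = geometry.pixel_size_xy

    xs, ys, zs, inten = [], [], [], []
    comp, brs, paths, near_sp = [], [], [], []
    is_ts, ts_n = [], []

    spine_xy = spines.xyz[:, :2] if len(spines) else np.empty((0, 2))

    for bi in range(len(geometry.branches)):
        pixels = raster.branch_centers[bi]
        path = raster.branch_path[bi]
        if len(pixels) == 0:
            continue
        w = np.exp(-path / tau) if np.isfinite(tau) else np.ones(len(path))
        if config.spine_enrichment != 1.0 and len(spine_xy):
            from scipy.spatial import cKDTree
            d, _ = cKDTree(spine_xy).query(pixels)
            w = w * np.where(d <= config.spine_radius_nm,
                             config.spine_enrichment, 1.0)
        # scale so a rho=1 profile yields the requested mean count; spine
        # enrichment raises the local rate (and hence the total) on top
        w0_sum = (np.exp(-path / tau).sum() if np.isfinite(tau)
                  else float(len(path)))
        lam = mean_per_branch * w.sum() / max(w0_sum, 1e-300)
        n = rng.poisson(lam) if w.sum() > 0 else 0
        xy, idx = _sample_pixels(rng, pixels, w, n, ps)
        true_path = path[idx]
        if config.localization_error_sd_nm > 0:
            xy = xy + rng.normal(0, config.localization_error_sd_nm,
                                 size=xy.shape)
        z = rng.uniform(0, config.z_slab_nm, size=len(xy))
        xs.append(xy[:, 0]); ys.append(xy[:, 1]); zs.append(z)
        comp += ["dendrite"] * len(xy)
        brs += [bi] * len(xy)
        paths.append(true_path)
        if len(spine_xy):
            from scipy.spatial import cKDTree
            d, _ = cKDTree(spine_xy).query(xy)
            near_sp.append(d <= config.spine_radius_nm)
        else:
            near_sp.append(np.zeros(len(xy), dtype=bool))
        is_ts += [False] * len(xy)
        ts_n += [0] * len(xy)

    # somatic molecules, uniform over the soma mask
    n_soma = rng.poisson(config.mean_soma_mrnas)
    soma_px = raster.soma_centers
    xy, _ = _sample_pixels(rng, soma_px, np.ones(len(soma_px)), n_soma, ps)
    if config.localization_error_sd_nm > 0 and len(xy):
        xy = xy + rng.normal(0, config.localization_error_sd_nm, size=xy.shape)
    z = rng.uniform(0, config.z_slab_nm, size=len(xy))
    xs.append(xy[:, 0]); ys.append(xy[:, 1]); zs.append(z)
    comp += ["soma"] * len(xy)
    brs += [-1] * len(xy)
    paths.append(np.zeros(len(xy)))
    near_sp.append(np.zeros(len(xy), dtype=bool))
    is_ts += [False] * len(xy)
    ts_n += [0] * len(xy)

    # transcription sites: bright somatic pile-ups of k mRNA units
    for _ in range(config.n_transcription_sites):
        xy, _ = _sample_pixels(rng, soma_px, np.ones(len(soma_px)), 1, ps)
        k = int(rng.integers(config.ts_nascent_range[0],
                             config.ts_nascent_range[1] + 1))
        xs.append(xy[:, 0]); ys.append(xy[:, 1])
        zs.append(rng.uniform(0, config.z_slab_nm, size=1))
        comp += ["soma"]
        brs += [-1]
        paths.append(np.zeros(1))
        near_sp.append(np.zeros(1, dtype=bool))
        is_ts += [True]
        ts_n += [k]

    x = np.concatenate(xs); y = np.concatenate(ys); z = np.concatenate(zs)
    n_total = len(x)
    mult = np.where(np.array(is_ts), np.array(ts_n), 1).astype(float)
    noise = (1.0 + rng.normal(0, config.mrna_intensity_cv, size=n_total)
             if config.mrna_intensity_cv > 0 else np.ones(n_total))
    intensity = np.maximum(config.unit_mrna_intensity * mult * noise, 1e-6)

    spots = SpotTable(
        xyz=np.column_stack([x, y, z]), intensity=intensity,
        channel_label=channel_label, cell_id="synthetic")
    path_arr = np.concatenate(paths)
    comp_arr = np.array(comp)
    br_arr = np.array(brs, dtype=int)
    bins = np.full(len(comp_arr), -1, dtype=int)
    dend_sel = comp_arr == "dendrite"
    bins[dend_sel] = [
        capped_bin_index(p, geometry.branches[b].length, bin_width)
        for p, b in zip(path_arr[dend_sel], br_arr[dend_sel])]
    truth = pd.DataFrame({
        "id": spots.ids,
        "compartment": comp,
        "branch": brs,
        "path_distance": path_arr,
        "bin": bins,
        "near_spine": np.concatenate(near_sp),
        "is_ts": is_ts,
        "ts_nascent": ts_n,
    })
    return spots, truth


def place_partner_channel(reference: SpotTable, geometry: NeuronGeometry,
                          config: SyntheticConfig, rng=None,
                          channel_label: str = "partner",
                          reference_dendritic_ids=None
                          ) -> tuple[SpotTable, pd.DataFrame]:
    """Second mRNA channel with a planted coexistence fraction kappa.

    Each partner molecule is, with probability kappa, placed uniformly
    within ``coexist_radius_nm`` (in the plane, sharing the reference z) of
    a randomly chosen dendritic reference molecule — same-granule
    co-residence — and otherwise uniformly over the dendrite mask. The
    emitted coordinates carry the configured chromatic offset of this
    channel; analyses must correct for it.
    """
    rng = _as_rng(config.rng_seed if rng is None else rng)
    raster = geometry.raster
    ps = geometry.pixel_size_xy
    all_px = (np.concatenate(raster.branch_centers, axis=0)
              if raster.branch_centers else np.empty((0, 2)))

    if reference_dendritic_ids is not None:
        ref_pool = reference.xyz[np.isin(reference.ids,
                                         np.asarray(reference_dendritic_ids))]
    else:
        ref_pool = reference.xyz
    n_total = rng.poisson(config.mean_partner_per_branch
                          * max(len(geometry.branches), 1))
    planted = (rng.uniform(size=n_total) < config.coexistence_enrichment) \
        if len(ref_pool) else np.zeros(n_total, dtype=bool)

    coords = np.empty((n_total, 3))
    partner_of = np.full(n_total, -1, dtype=int)
    n_uniform = int((~planted).sum())
    xy, _ = _sample_pixels(rng, all_px, np.ones(len(all_px)), n_uniform, ps)
    zu = rng.uniform(0, config.z_slab_nm, size=len(xy))
    coords[~planted] = np.column_stack([xy, zu])[:len(xy)]
    for i in np.flatnonzero(planted):
        j = int(rng.integers(len(ref_pool)))
        ang = rng.uniform(0, 2 * np.pi)
        rad = config.coexist_radius_nm * np.sqrt(rng.uniform())
        coords[i] = ref_pool[j] + np.array(
            [rad * np.cos(ang), rad * np.sin(ang), 0.0])
        partner_of[i] = j
    intensity = np.maximum(
        config.unit_mrna_intensity
        * (1.0 + (rng.normal(0, config.mrna_intensity_cv, size=n_total)
                  if config.mrna_intensity_cv > 0 else 0.0)), 1e-6)
    coords = coords + np.asarray(config.chromatic_offset, dtype=float)

    spots = SpotTable(xyz=coords, intensity=np.atleast_1d(intensity),
                      channel_label=channel_label, cell_id="synthetic")
    truth = pd.DataFrame({
        "id": spots.ids,
        "planted_near_reference": planted,
        "reference_partner_row": partner_of,
    })
    return spots, truth


def emit_translation_channels(mrnas: SpotTable, geometry: NeuronGeometry,
                              config: SyntheticConfig, rng=None
                              ) -> tuple[SpotTable, pd.DataFrame]:
    """Peptide (SunTag IF) channel for an mRNA table.

    Each mRNA translates with probability ``p_translating``; a translating
    mRNA gets a nascent-peptide spot displaced by an isotropic Gaussian of
    ``colocalization_sd_nm`` with intensity (ribosome count) x (unit peptide
    intensity) x multiplicative noise. Free mature proteins are placed
    uniformly over the neuron mask at one unit each. The whole peptide
    channel is emitted shifted by the chromatic offset.

    Returns the peptide table and per-mRNA ground truth
    ``(mrna_id, translating, ribosomes, peptide_id)``.
    """
    rng = _as_rng(config.rng_seed if rng is None else rng)
    n = len(mrnas)
    translating = rng.uniform(size=n) < config.p_translating
    ribs = np.zeros(n, dtype=int)
    ribs[translating] = _truncated_geometric(
        rng, config.ribosome_mean, config.ribosome_max,
        int(translating.sum()))

    pep_xyz, pep_int, owner = [], [], []
    for i in np.flatnonzero(translating):
        disp = rng.normal(0, config.colocalization_sd_nm, size=3) \
            if config.colocalization_sd_nm > 0 else np.zeros(3)
        pep_xyz.append(mrnas.xyz[i] + disp)
        noise = (1.0 + rng.normal(0, config.intensity_cv)
                 if config.intensity_cv > 0 else 1.0)
        pep_int.append(max(ribs[i] * config.unit_peptide_intensity * noise,
                           1e-6))
        owner.append(i)

    raster = geometry.raster
    all_px = np.concatenate(
        [raster.soma_centers] + list(raster.branch_centers), axis=0)
    n_free = rng.poisson(config.mean_free_peptides)
    xy, _ = _sample_pixels(rng, all_px, np.ones(len(all_px)), n_free,
                           geometry.pixel_size_xy)
    for k in range(len(xy)):
        z = rng.uniform(0, config.z_slab_nm)
        pep_xyz.append(np.array([xy[k, 0], xy[k, 1], z]))
        noise = (1.0 + rng.normal(0, config.intensity_cv)
                 if config.intensity_cv > 0 else 1.0)
        pep_int.append(max(config.unit_peptide_intensity * noise, 1e-6))
        owner.append(-1)

    pep_xyz = (np.array(pep_xyz).reshape(-1, 3)
               + np.asarray(config.chromatic_offset, dtype=float))
    peptides = SpotTable(
        xyz=pep_xyz, intensity=np.array(pep_int, dtype=float),
        channel_label="peptide", cell_id=mrnas.cell_id)

    owner = np.array(owner, dtype=int)
    pep_of_mrna = np.full(n, -1, dtype=int)
    for pid, oi in zip(peptides.ids, owner):
        if oi >= 0:
            pep_of_mrna[oi] = int(pid)
    truth = pd.DataFrame({
        "mrna_id": mrnas.ids,
        "translating": translating,
        "ribosomes": ribs,
        "peptide_id": pep_of_mrna,
    })
    return peptides, truth


def synthesize_experiment(config: SyntheticConfig, seed: int | None = None
                          ) -> dict:
    """Generate a full synthetic cell: geometry, spines, three channels and
    ground truth, with one deterministic stream per stage."""
    root = np.random.default_rng(config.rng_seed if seed is None else seed)
    streams = root.spawn(4)
    geom, spines = generate_neuron(config, streams[0])
    mrna, mrna_truth = place_mrnas(geom, spines, config, streams[1])
    dend_ids = mrna_truth.loc[
        mrna_truth["compartment"] == "dendrite", "id"].to_numpy()
    partner, partner_truth = place_partner_channel(
        mrna, geom, config, streams[2], reference_dendritic_ids=dend_ids)
    peptides, pep_truth = emit_translation_channels(
        mrna, geom, config, streams[3])
    return {
        "geometry": geom,
        "spines": spines,
        "mrna": mrna,
        "mrna_truth": mrna_truth,
        "partner": partner,
        "partner_truth": partner_truth,
        "peptides": peptides,
        "translation_truth": pep_truth,
        "config": config,
    }
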