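# Methods

## Scope and data model

`neurospot` starts where spot detection ends: per-channel tables of
diffraction-limited spot coordinates (nm) with integrated intensities, plus
a manually outlined neuron geometry (one closed soma polygon and per-branch
dendrite skeletons with a half-width, in image-pixel units, y down). All
internal computation is in nanometres. Compartment masks are 2D — the
morphology is treated in the maximum-projection plane — while spot z
coordinates are kept and used for pairwise distances.

## Geometry and binning

A spot is somatic if it falls inside the soma polygon; otherwise it belongs
to the branch whose shaft (skeleton dilated by the half-width) contains it,
with the nearest branch winning and exact ties (within 1 nm × 10⁻⁹) going
to the lowest branch index. Spots outside every mask are retained with the
label `outside` and excluded from statistics; in dense cultures these are
usually assignment errors and the count is a useful QC signal.

Distance from the soma is the arc length along the skeleton from the soma
attachment point to the spot's orthogonal projection — the distance a
molecule travels, not the straight-line offset. Dendrites are divided into
half-open bins `[kB, (k+1)B)` with `B = 25 µm`. Conventions at the edges:

* a branch of length `L` has `ceil(L/B)` bins; a spot projecting exactly
  onto the branch tip is folded into the terminal bin (otherwise a
  zero-width bin with an empty mask could receive observed spots);
* partial terminal bins are kept with their actual mask area — per-bin
  counts are raw, not length-normalised;
* masks partition: a pixel inside the soma is somatic only, and a pixel
  reachable from several branches belongs to the lowest-indexed one.

Masks are rasterised at the camera pixel size (default 107.5 nm) on a
global grid: pixel centers inside the polygon (soma) or within the
half-width of the skeleton (branches). On a straight branch the path
distance of a near-axis point equals its Euclidean distance from the
attachment to within one pixel, which the tests assert.

## The count-preserving Monte-Carlo null

The null model for spine proximity and two-channel coexistence asks: *given
how many molecules each 25 µm bin holds, how much apparent colocalization
arises by chance?* For every (branch, bin) group with `c` observed
dendritic molecules, each of `n_simulations = 100` repeats draws `c`
distinct mask pixels of that bin uniformly (without replacement within a
repeat) and places one simulated molecule per pixel with uniform sub-pixel
jitter; the jitter avoids distance quantisation at the pixel pitch. Fixed
landmarks — PSD95 centers for the proximity statistic, the reference mRNA
channel for coexistence — are never moved. Conserving per-bin counts means
the simulated concentration profile along the dendrite always matches the
observed one, so proximal enrichment of molecules cannot be mistaken for
spine- or granule-level association.

Statistics recomputed per repeat:

* **spine occupancy** — for each spine, the number of mRNAs within
  `spine_radius = 600 nm` of its center (closed `<=`; each spine counted
  independently, so one mRNA may serve two adjacent spines), tabulated per
  bin as the frequencies of 0, 1, ≥2 mRNAs; a spine's bin is set by its own
  path distance;
* **coexistence** — per reference molecule, the distance to the nearest
  partner molecule; coexisting if `<= coexist_radius = 700 nm` (the
  approximate diameter of a neuronal transport granule); reported per bin
  as the coexisting fraction and the mean nearest-partner distance.

The comparison layer reports, per bin: the null mean ± SD across repeats,
an empirical rank p-value `(1 + #{repeats at least as extreme})/(n + 1)`,
and — when several neurons/dendrites are analysed — a Welch unequal-variance
t-test of observed values against simulated values, the convention used for
group comparisons throughout the package. The empirical p is exact but
discrete (minimum 1/101 at 100 repeats); the Welch comparison gains power
by pooling units.

**Distance dimensionality.** Observed spots carry z, but the null draws 2D
mask pixels. Default (`distance_mode="3d"`): simulated molecules take the
median z of the observed molecules in their (branch, bin) group. This
reconciles 3D detection with the 2D null but makes observed and simulated
distance distributions differ slightly when spots spread over a thick
slab; `distance_mode="2d"` ignores z everywhere and renders observed data
generated uniformly over the mask exactly exchangeable with the null. The
calibration experiments therefore run in 2D mode; with thin imaging slabs
(≤ 600 nm here) the 3D/2D difference is small compared with the 600–700 nm
radii.

**Boundary convention.** "Within r" is the closed condition `<= r`
everywhere; for continuous positions the difference from `< r` has measure
zero.

**Randomness.** One root seed; per-stage and per-neuron streams are spawned
from it, so the order in which neurons are analysed does not change any
result, and identical seeds give byte-identical outputs (asserted down to
the CLI file level).

## Localization summaries and transcription sites

Per neuron and channel: somatic/dendritic counts, counts per mask pixel
("density"), the dendrite/soma density ratio (flagged undefined when the
somatic density is zero), and the per-bin count vector padded with trailing
zeros to a common length. Ratios use densities rather than raw counts so
that compartment size drops out. Fold enrichment between conditions is the
ratio of group means; group comparisons are Welch tests with
Welch–Satterthwaite degrees of freedom, reported per bin without
multiple-testing correction by default (a Benjamini–Hochberg column can be
added by the caller; the per-bin raw-p convention matches how such binned
comparisons are usually displayed).

Transcription sites are bright nuclear pile-ups of nascent transcripts. The
unit single-mRNA intensity is the **median** intensity of cytoplasmic
(non-site) spots — robust to contamination by the sites themselves. A spot
is a site candidate if brighter than 1.5× the unit and, when a nucleus
polygon is supplied, nuclear; its nascent count is `round(intensity/unit)`
floored at 2, since a site dimmer than two mRNA equivalents would not be
distinguishable from a single molecule. The 1.5× factor and the floor are
implementation choices exposed as parameters; the counting itself is
scale-invariant in intensity units.

## Translation calling

The pairing threshold is `200 nm + chromatic_residual`: the mean chromatic
offset between the peptide and mRNA channels (measured with multicolour
beads) is subtracted from the peptide coordinates first, and the residual
registration error magnitude then widens the threshold. Pipeline order:
peptides are each provisionally assigned to their closest mRNA (3D
distance); assignments beyond the threshold are dropped (those peptides are
free mature proteins); per mRNA the brightest candidate peptide is kept,
intensity ties broken by distance. The result is a partial matching — no
mRNA or peptide appears twice. Ribosome counts are
`round(intensity/unit) >= 1`, with the unit peptide intensity estimated as
the median of free spots (≥ 20 required; the caller may supply the unit
directly, e.g. from a calibration cell). Percent translating is
100 × translating/total per cell, per branch, or pooled over dendrites.

Brightest-then-closest dedupe is an interpretation choice for resolving
multiple sub-threshold candidates (the plausible reading of ranking first
by signal, then by distance); the enumeration oracle in the tests applies
the same rules independently with plain loops and agrees on 1000 random
small instances. Note one bias worth knowing: a free mature protein that
happens to fall within the threshold of an untranslated mRNA is counted as
translation. At the default synthetic densities this inflates percent
translating by under one percentage point; in real data the same effect is
part of the measurement.

## Granularity readout

Per ROI (a manually outlined dendrite on a maximum-intensity projection):
CV = sample SD (n−1) / mean of the pixel intensities — 0 for an even
signal, rising as intensity concentrates, invariant to multiplicative
rescaling, undefined (NaN) for a zero-mean ROI. Aggregate sizes are the
connected components (8-connectivity) of pixels brighter than
mean + k·SD of the ROI with k = 2 by default; the threshold is
ROI-relative, so uniform additive background does not create components.
The thresholding rule is this package's own operationalisation of
"aggregate size" — results are comparable within an experiment analysed
with one rule, not across different rules. On noise-only ROIs the rule
yields pixel-scale speckle (≈ 2% of pixels); aggregate sizes are therefore
interpreted jointly with the CV, not alone.

## Synthetic data generator

The generator emulates the *structure* of the imaging data, not the optics:
no PSF, no pixel noise, no detection step. A neuron is a 64-gon soma disc
(radius 10 µm) with straight branches (default 2 × 150 µm, half-width 1 µm)
radiating at even angles; spines are a Poisson process along each skeleton
(default 1/µm) with centers on the mask edge. Channels:

* **mRNA** — inhomogeneous Poisson draw over branch-mask pixels with weight
  `exp(-d/τ) × (ρ within 600 nm of a spine, else 1)`; defaults ρ = 1 and
  flat τ (no decay) for null experiments, and a mean of 100 molecules per
  branch — the regime of an abundant dendritic chaperone transcript —
  against ~5 per branch for a rare partner species. Somatic molecules are
  uniform over the soma mask (mean 150). Optional nuclear transcription
  sites pile up k mRNA units of intensity (k uniform on 2..12). Gaussian
  localisation error (default 30 nm) is added in-plane; z is uniform in a
  600 nm slab.
* **partner channel** — a fraction κ of molecules is placed uniformly
  within 700 nm (in-plane, sharing the reference z) of a random dendritic
  reference molecule, the rest uniformly over the mask; emitted coordinates
  carry the configured chromatic offset.
* **peptide channel** — each mRNA translates with probability 0.30;
  ribosome loads are geometric with mean 3 truncated at 30 (a generator
  parameter, not a biological claim); the nascent-peptide spot sits at the
  mRNA plus isotropic Gaussian displacement (50 nm) with intensity
  load × unit × (1 + Gaussian CV 10%); free mature proteins (mean 50) are
  uniform over the whole mask.

Pixel sampling in the generator is without replacement with jitter — the
same mechanism as the null model — so that under ρ = 1/κ = 0 and zero
localisation error the observed data are exchangeable with the null
conditional on per-bin counts. This is what makes the calibration
experiment a sharp test: the per-bin empirical rejection rate at α = 0.05
must land inside the binomial confidence band around 0.05, and does.
Calibration and the coexistence-null checks are run with zero localisation
error and 2D distances because they test the null machinery against its own
sampling assumption; the defaults elsewhere (30 nm error, 3D, slab z)
exercise the realistic path. What passing these tests does **not** show:
robustness to segmentation errors, detection false positives/negatives,
anisotropic z localisation error, or non-uniform within-bin density — all
properties of real images that the generator deliberately omits.

## Experiment sizes and runtimes

Test-suite experiment sizes were chosen to give sharp statistical checks at
desk scale: calibration uses 200 single-branch neurons (800 bin-level
tests, binomial 95% band ±1.5 points around 5%), power uses 100 independent
five-neuron experiments against ρ = 3, the pairing oracle sweeps 1000
random instances, and parameter-recovery checks use ~1000 molecules. The
full suite runs in about four minutes on one CPU; `scripts/acceptance.py`
(which re-derives the same quantities at slightly reduced replication,
e.g. 100 calibration neurons) takes about one minute.

## Known limitations

* Morphology is 2D; crossing dendrites are resolved by branch order, not
  disambiguated.
* The null draws pixels in 2D; in 3D mode simulated molecules inherit a
  surrogate (median) z rather than a modelled axial distribution.
* Spine positions are treated as points (PSD95 centers); spine morphology
  and head/neck geometry are out of scope.
* Somatic translation efficiency is not quantified — reporter accumulation
  in the soma defeats single-molecule intensity calibration there; the
  translation statistics are per cell and per dendrite.
* Per-bin Welch tests are reported uncorrected by default; with many bins
  and channels the caller should apply the optional FDR column.
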