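# Methods

This note documents the models, conventions and numerical choices behind
`rosella`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Reporter model and autolysosome detection

The tandem reporter fuses a pH-sensitive green fluorophore (pHluorin) and a
pH-stable red one (DsRed) to LC3. In the acidic autolysosome lumen the green
moiety is quenched, so autolysosomes are red-only vesicles; autophagosomes
(pre-fusion) are dual-positive. Because LC3 also decorates the cytoskeleton,
the green channel carries a diffuse cytoplasmic signal.

Detection proceeds per plane:

1. threshold the DsRed channel into a vesicle mask;
2. label 8-connected components within each plane (planes are never linked:
   quantities are defined on in-plane elements, and `voxel` throughout the
   package means one in-plane element whose area is `voxel_area_um2`);
3. keep a component as an autolysosome iff the fraction of its voxels inside
   the bright-green mask is below the dual-positive cutoff (default 0.5) and
   it has at least `min_voxels` voxels (default 2, rejecting single-voxel
   noise).

The 50 % cutoff rather than "zero green voxels" tolerates 1–2 voxel mask
misregistration without admitting genuinely dual-positive vesicles; it is
configurable.

### Thresholding

Four methods are exposed: Otsu (default for well-separated bimodal
channels), fixed, quantile, and a robust background rule
`median + k · MAD/0.6745` (default k = 3). The robust rule assumes a
background-dominated channel, in which case the median estimates the
background level and the scaled MAD the noise SD; on noiseless data MAD is
zero and the mask is exact. It is the recommended method for noisy vesicle
channels: unlike pre-smoothing, it does not erode objects only 2–4 voxels
across (smoothing at σ ≈ 0.7 px costs ~17 % of the small class), and at 3
noise SDs above background the chance of two 8-adjacent false-positive
pixels — the smallest accepted object — is negligible at field scale.
Gaussian pre-smoothing remains available (`smooth_sigma`) and is used only
for the cell-area channel, where structures are hundreds of voxels.

### Size classes

Voxel-count intervals are half-open, boundary to the larger class:
small `[1, s)`, medium `[s, m)`, large `[m, ∞)`, with (s, m) = (8, 25) for
2D neuronal cultures and (25, 80) for midbrain organoids, whose vesicles
image larger. Classification operates on integer voxel counts; areas in µm²
are derived reporting (`voxel_area_um2` defaults to 0.0116 µm², chosen so
25 voxels ≈ 0.29 µm²).

### Per-field metrics

Total autolysosome area per cell area (dimensionless), counts per cell area
(1/µm², total and per class), and the maximum autolysosome area per imaged
field. The "cell area" normalizer is a field-level cytoplasm mask obtained
by thresholding the diffuse reporter channel (or an externally supplied
mask) summed over planes — an interpretation, since per-cell segmentation is
a deliberately out-of-scope alternative. An empty cell mask is a hard error:
a field with no detectable cells is an acquisition failure, and silent zeros
would corrupt the downstream densities.

## Colocalization

Binary-mask overlap only (no intensity correlation): per plane,
`100 × |A∩B| / denominator`, with the denominator selectable as the
reference-marker area (default), the union, or all pixels; triple overlap is
analogous. Per-plane percentages are averaged to one per-field value before
statistics. Planes with an empty denominator yield `nan` (missing), never 0.
Neurite fragmentation is defined here as the number of per-plane skeleton
components with ≥ 5 voxels, per µm² of marker-positive area — a concrete,
reproducible reading of "fragmentation": the same arbor with more gaps gives
more, shorter fragments.

## MEA analysis

Chain per electrode: zero-phase Butterworth band-pass 200–3000 Hz
(2nd order per direction, applied forward–backward, so effectively 4th
order; zero phase keeps spike times unbiased), noise SD estimated on the
filtered trace (plain SD by default — the literal k×SD rule; a
median-|x|/0.6745 estimator is available because the plain SD is inflated
by spikes at high rates), events at |x| > 6·SD with both polarities,
1 ms dead time, spike time at the extremum of each crossing group.
Electrodes averaging ≥ 5 spikes/min (inclusive) are active; the well's mean
fire rate averages spikes/s over active electrodes only, with an explicit
flag when no electrode is active. Bursts are maximal runs of ≥ 5 spikes with
all inter-spike intervals ≤ 100 ms (max-ISI rule; both parameters
configurable). Cumulative longitudinal metrics are running sums over
timepoints ordered by days of differentiation.

## Statistics

Raw per-field values are averaged to one value per (condition, line,
experiment, timepoint, metric). Normalization divides by the control mean
either across all timepoints (one divisor per metric, preserving temporal
trends) or within each timepoint; the control mean of the normalizing
stratum becomes exactly 1. Control-vs-disease comparisons are paired by
(experiment, timepoint): if both groups pass Shapiro–Wilk at α = 0.05 a
paired t-test is used, otherwise the Wilcoxon signed-rank test. Zero
differences are dropped before ranking (Wilcoxon's original convention) and
ties share mid-ranks. For ≤ 12 usable pairs the signed-rank null is built by
enumerating all 2ⁿ sign assignments, which stays exact under ties; above
that, a normal approximation with tie and continuity corrections. All tests
are two-sided; stars use strict cutpoints p < 0.05/0.01/0.001/0.0001. No
multiple-testing correction is applied by default.

Note an intrinsic limit of paired nonparametric testing at small n: with
three paired experiments the smallest achievable two-sided exact p is 0.25,
so experiment-level signed-rank tests cannot reach conventional
significance; the pipeline therefore leaves the unit of analysis (fields vs
experiment means) to the caller rather than guessing.

## Synthetic data: what it emulates, and what it does not

Generators return the rendered data plus exact ground truth.

* **Reporter fields** — circular cells (a configurable fraction carrying
  the reporter, default 0.55, emulating mosaic cultures; non-reporter cells
  render background only), vesicles as filled digital discs/ellipses grown
  pixel-by-pixel to an exact target voxel count drawn uniformly inside the
  requested class interval (lower bound clamped to 2 voxels so noiseless
  renders survive the detector's single-voxel rejection). Footprints are
  padded by 2 px so components can never merge. Intensity levels per channel
  (background/cytoplasm/vesicle, defaults 200/280/520 with the DsRed
  cytoplasm at background) include a camera-offset-like background several
  noise SDs above zero so additive noise is not clipped. Noise: additive
  Gaussian with σ relative to the vesicle–background contrast (default 0.2,
  i.e. contrast = 5σ) or Poisson shot noise.
* **Colocalization fields** — masks built by exact voxel allocation, so
  target pairwise/triple fractions are realized to one voxel of rounding.
* **MEA recordings** — Gaussian noise plus a biphasic 1 ms spike template
  at Poisson or burst-clustered times (≥ 2 ms apart, so detector dead time
  cannot merge true spikes), peak amplitude in units of the noise SD
  (default 12).
* **Cohort tables** — one value per (condition, experiment, timepoint,
  metric), multiplicative disease effect, Gaussian dispersion as a CV.
* **Neurite fields** — sinusoidal 2 px branches with a stated number of
  gaps; fragments = branches × (breaks + 1) by construction.

Every generator is bit-reproducible under (spec, seed). The renders contain
no optical PSF, photobleaching, depth-dependent scattering, cell-to-cell
intensity variability, or autofluorescence; passing the recovery tests
therefore demonstrates correctness of the measurement code under controlled
degradation, not robustness to every real-microscope artifact. Likewise the
MEA traces have white noise and a fixed waveform — no electrode drift, no
overlapping units, no field potentials.

## End-to-end demo conditions

The bundled pipeline config runs 10 independent experiments × 2 conditions,
6 reporter fields (192×192, one plane) per experiment, one 4-electrode 60 s
well per experiment at 12.5 kHz, and one colocalization field per
experiment; the disease group carries a 0.7 multiplicative effect on
vesicle counts and spike rate, while the overlap target is equal in both
groups (a null metric whose false-positive rate is 5 % by construction).
Field counts per experiment follow Poisson draws around the configured
class means, so measurement and biological variability both contribute.
These sizes give near-unit power for the injected 30 % effects under the
normality-gated paired test while keeping a full run to a few seconds.
Acceptance-style checks use 20 fields per imaging condition, a 16-electrode
600 s recording, 1000 null cohorts and 200 power replicates, and 20
end-to-end runs.

## Known limitations

* The cell-area normalizer is field-level, not per-cell; densities are
  comparable across conditions but not interpretable per cell.
* 3D linking of vesicles across planes is out of scope; a vesicle spanning
  planes counts once per plane.
* The colocalization denominator convention must be fixed by the user for
  cross-study comparability; results record the mode used.
* Burst detection uses the standard max-ISI rule; vendor software may use
  adaptive variants, so absolute burst counts are comparable only within a
  fixed parameter set.
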