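# Methods

## Pipeline model and assumptions

The pipeline assumes each mRNA appears as one diffraction-limited dot: a
roughly Gaussian intensity profile whose lateral width is set by the optical
PSF (~0.1–0.15 µm) and whose axial width is 3–4× larger, sampled on an
anisotropic voxel grid (default 0.04 × 0.04 × 0.3 µm).  Counting is purely
morphological — connected components above an intensity threshold — so it
requires dots that are resolvable at the analysis scale; overlapping
transcripts are not deconvolved (a dot at ~2× modal intensity is instead
*flagged* as a probable conglomerate of two transcripts).

### Spot enhancement (negated 3D LoG)

The kernel is built analytically as the negated sum of three separable
second-derivative-of-Gaussian terms, truncated at ±4σ per axis (always odd
extent), then DC-corrected by subtracting the kernel mean so its entries sum
to exactly zero — truncation and sampling otherwise leave a small positive
DC response that would leak background into the counts.  Sigma is given in
µm (defaults σ_xy = 0.13, σ_z = 0.4, roughly PSF-matched for a high-NA
confocal) and converted per axis to voxels, so the kernel is isotropic in
physical space even on 0.04/0.3 µm grids; a sigma below half a voxel on any
axis is rejected as undersampled.  Convolution is FFT-based on a
mirror-padded volume; mirror padding avoids rim artifacts that would spawn
spurious components at high thresholds.

### Normalization

Negative responses are clipped at zero and the stack is divided by its
global maximum.  This is what makes a *fixed* intensity threshold (0.25) and
a *uniform* 100-point threshold grid comparable across equally filtered
images.  A stack with no positive response anywhere raises a dedicated
`NoSignalError`, which the pipeline driver treats as "0 spots".

### Masking

Cell borders are per-slice polygons in (y, x) pixel coordinates, 0-based,
implicitly closed, with no interpolation between slices.  A voxel belongs to
a cell iff its integer-coordinate center is inside or exactly on that
slice's polygon (boundary-inclusive: deterministic and orientation-
independent).  Overlapping ROIs are resolved first-come with a warning.

### Threshold sweep and plateau selection

Counts are taken at thresholds t_k = k/100 (strict `>` binarization,
26-connectivity by default — anisotropic voxels make diagonal z-contacts
within a single PSF common).  The automatic selection picks, among runs of
≥3 consecutive grid points with identical nonzero count, the run of greatest
**log-threshold width** (log of upper/lower threshold ratio), returning its
midpoint; ties go to the lower-threshold run.  Width is measured in log
rather than grid points because the threshold is a scale parameter and dot
amplitudes spread multiplicatively: on a linear grid the terminal band where
only the one or two brightest dots survive can span dozens of grid points
and would outscore the true-count plateau.  If no run qualifies, the modal
nonzero count is used; an all-zero sweep is an explicit "no spots" outcome.
No component-size filter is applied by default (an optional `min_voxels`
style gate is deliberately absent from defaults); single-voxel components
count.

### Dot intensity and conglomerates

Dot intensity is the mean of the member voxels' normalized values at the
fixed 0.25 threshold.  The conglomerate rule takes the modal intensity m
(center of the most populated 0.05-wide bin) and flags dots with intensity
≥ fold·m·(1 − tol), defaults fold = 2.0, tol = 0.15.

**Limitation — fold compression.**  Mean-over-threshold intensity is not
proportional to dot amplitude: the threshold clips a wider cap from a
brighter dot, so a true 2.0× amplitude ratio is measured as a ≈1.5×
mean-intensity ratio for the filtered dot profile (verified on noise-free
renders: means 0.326 vs 0.485 for amplitudes 1× and 2×).  The defaults are
kept at fold 2.0 / tol 0.15, which matches regimes where the modal bin sits
near 0.275 and conglomerates near 0.55; for simulated data the profile-aware
fold can be derived from a clean two-dot render, as the test suite does.

### Colocalization

Candidate pairs are all cross-channel dot pairs with centroid distance
≤ radius (µm); they are accepted greedily in ascending distance, each dot
matched at most once.  Efficiency is reported in both directions
(matched/|A| and matched/|B|).  The radius default follows 3× the lateral
filter sigma (≈0.39 µm); the recovery analyses use 0.5 µm.

### Distribution fitting and KS screening

Closed-form MLEs are used for normal (mean, population sd) and Poisson
(rate = sample mean); gamma (shape, rate), Weibull (shape, scale) and
logistic (location, scale) are optimized numerically to tolerance 1e-8.
Zero counts under gamma/Weibull are replaced by 0.5 with a warning (counts
are integers; both families need positive support).

The KS statistic for continuous families is the classic order-statistic
formula; the p-value comes from the asymptotic Kolmogorov distribution with
the fitted parameters treated as known.  Estimating parameters from the same
sample makes this anti-conservative (families are retained too easily); a
parametric-bootstrap p-value (199 replicates) is available behind a flag as
the corrected alternative.  For the Poisson family the fitted CDF is a step
function and the supremum |F_n − F| is computed exactly over the integer
support, comparing the step functions both at and just below each atom —
running integer data through the continuous formula instead would inflate D
by an O(pmf) term at every atom and reject even exactly-Poisson samples.
For discrete nulls the asymptotic p-value is conservative.  α is 0.05 with
no correction across families/genes by default; a Holm-corrected view is
available behind a flag.  Counts from several embryos are pooled by default;
per-embryo grouping is a CLI option.

### ΔΔCt

Per sample, ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the mean ΔCt of
the calibrator group; relative expression is efficiency^(−ΔΔCt) with
efficiency default 2.0 (perfect doubling).  The calibrator group therefore
has geometric-mean relative expression 1 by construction.

### Probe tiling

0-based half-open intervals; the left-packed greedy tiling
[k(p+g), k(p+g)+p) achieves the maximum ⌊(L+g)/(p+g)⌋ (verified against a
dynamic-programming oracle in the tests).  Sequence-content scoring (GC,
Tm, uniqueness) is out of scope.

## Synthetic data generator

The generator emulates: diffraction-limited dots (separable anisotropic
Gaussians, default PSF σ_xy = 0.1 µm, σ_z = 0.35 µm — dots must span more
than one slice at 0.3 µm z-pitch), lognormal amplitude jitter (σ = 0.1,
≈±10%, giving the intensity histogram a realistic modal peak), a stated
conglomerate fraction with 2× amplitude, autofluorescent background
(default 40 photons) with a fractional linear ramp across X (default 0.2),
Poisson shot noise, additive Gaussian read noise (default sd 4), and
channel-B dropout (default 0.2) for double-labeling experiments.

Cells are convex polygons (perturbed regular polygons) tiled without overlap
on the XY plane and extruded over a z-interval — a deliberate prism-shaped
simplification of real cell geometry.  Spot centers are sampled inside
PSF-eroded masks with a PSF-scaled minimum pairwise separation
(`min_separation_sigma`, default 6.0 in per-axis PSF-sigma units): the
pipeline models the resolved single-molecule regime, and the LoG analysis
scale widens dot responses axially, so a tighter spacing floor would plant
pairs that no threshold can separate.  Default image shape (24, 384, 384)
gives four cells room for 50 such spots each; the double-labeling analyses
use (24, 768, 768) for 250 spots per cell.

What the generator does **not** emulate: Airy rings/spherical aberration,
depth-dependent attenuation, yolk autofluorescence, clustered or nascent
transcription sites, and unresolvably close transcript pairs.  Passing
recovery tests therefore demonstrate correctness of the counting machinery
under the stated imaging model, not segmentation-free performance on
arbitrary real embryos.

Randomness: one seed per call; named child generators are spawned from a
single `SeedSequence` in a fixed order (geometry, counts, placement, marks,
channel_b, noise_a, noise_b), so individual draws (conglomerate flags,
channel-B presence) can be replayed exactly by tests without counting
interleaved draws.

## Problem sizes used in the shipped analyses

Spot-count recovery uses three 4-cell × 50-spot stacks at (24, 384, 384);
colocalization uses one 1000-spot two-channel stack at (24, 768, 768);
model-selection retention uses 50 replicates of 200 counts; MLE recovery
uses n = 10⁴ samples.  Per-cell threshold sweeps run on the mask's bounding
box, which leaves every count unchanged and dominates none of the analyses.
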