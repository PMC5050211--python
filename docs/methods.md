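# Methods

This note documents the models, parameter choices and numerical conventions
behind `biofilmcubes`, and what the synthetic validation does and does not
demonstrate about real microscope data.

## Image-processing chain

**Axis and coordinate conventions.** Stacks are `(channel, z, y, x)` with
0-based indices; the physical coordinate of a voxel is `(index + 0.5) ×
spacing` per axis (voxel-centre convention), with z = 0 at the substratum.
All distances are micrometres.

**Isotropic upsampling.** Confocal stacks are typically sampled coarser
axially than laterally.  The z axis is resampled to the lateral spacing by
linear interpolation with start-aligned sampling: output slice *j* reads the
input at fractional index `j·s_out/s_in`, so a slice inserted midway between
two planes is exactly their mean.  Linear interpolation is convex, hence no
overshoot; the physical extent is preserved to within one output voxel.
Interpolation happens *before* smoothing and segmentation so that cubes and
densities live on an isotropic grid.

**Denoising.** A uniform (box) mean filter of side `2r + 1`, default
`r = 1` (3×3×3).  The kernel size is configurable; the default is the
smallest kernel that suppresses single-voxel shot noise without eroding
cell-scale structure.  Borders use symmetric reflection (the edge voxel is
included in its own mirror image), which avoids darkening at the substratum
plane where the biofilm touches the image border.

**Segmentation.** Per channel, a 256-bin equal-width histogram over the
observed min–max is thresholded by exhaustive 3-class Otsu: the pair
(t₁, t₂) maximizing the between-class variance, ties broken toward the
lexicographically smallest pair.  Thresholds are *upper bin edges*, so the
mask rule `intensity > t₁` is exactly consistent with bin membership.
Class 1 is background; classes 2 and 3 (dim and bright biomass — out-of-focus
or OFF-state material versus bright reporter signal) together form the
foreground.  Volumes with fewer than three distinct values raise an error
rather than silently producing a mask: a constant or two-valued volume
almost always indicates a misconfigured render or a dead channel.

This global-histogram method has an operating regime: each segmented channel
needs a non-negligible signal mass (of order a percent of voxels).  When the
true foreground is vanishingly sparse, the variance criterion gains more
from splitting the background mode than from isolating the signal, and the
threshold collapses into the background.  The synthetic defaults are chosen
to stay inside this regime (see below); the per-run log of (t₁, t₂) and
foreground fraction is the diagnostic for real data.

**Mask merging.** In dual-reporter mode (no constitutive marker) each
channel is segmented independently and the masks are merged by voxelwise
union before dissection, so biomass positive for either reporter is
quantified once.

## Cube-level quantification

**Dissection.** The mask is partitioned into a grid of cubes anchored at
the index origin, default side 5 voxels.  Partial cubes at the far borders
are kept with their true voxel counts — discarding them would bias the
z-profiles at the biofilm top.  Per-cube intensities are means of the *raw*
(unsmoothed, unrescaled) voxel values over the cube's *foreground* voxels
only; averaging over all voxels would couple intensity to occupancy.

**Local density.** The occupied volume fraction inside a solid ball of
radius 3 μm centred on the cube's centre of mass, counting voxel centres.
The denominator includes only in-bounds voxels, so densities at the
substratum (where the densest biomass sits) are not systematically
underestimated.  The estimator is exact with respect to brute-force ball
enumeration; this equivalence is asserted in the test suite on random
(mask, point, radius) triples.

**Surface and roughness.** The height map records the physical z of the
topmost foreground voxel centre per (y, x) column (NaN where empty).
Roughness is the windowed sample standard deviation (ddof = 1) of defined
heights in a centred window, default 11 px, undefined where fewer than two
heights are defined.  Windowed SD was chosen as the simplest
translation-invariant dispersion statistic of a height field; the operation
is isolated so alternatives (e.g. deviation from a fitted plane) can be
swapped without touching callers.  Heights are centred on their global mean
before the moment filters, which makes a flat field's roughness exactly
zero in floating point.

**Positivity labels.** In dual-reporter mode a cube is positive for a
channel iff at least `min_overlap_vox` (default 1) of its voxels are
foreground in that channel's pre-merge mask.  Double-positive cubes can
arise from genuinely co-expressing cells, from distinct cells sharing a
cube, or from PSF blur at boundaries between adjacent opposite-state cells;
with the default optics this spill-over is at the percent level.

**Ratios.** Reporter-to-constitutive and TIMER orange/green ratios are
per-cube ratios of raw mean intensities.  Cubes whose reference channel is
at or below a floor (default 0) are excluded and counted in the log.

## Cytometry

Background subtraction removes the *median* of a user-supplied control
population (robust to control outliers); negative results are retained.
The display scale is `T(x) = asinh(x / c) / ln 10` with cofactor
`c = 150`: linear near zero (so signed values survive), base-10 logarithmic
at large |x|, odd and exactly invertible.  The automatic gate is 2-class
Otsu on the transformed values; events exactly at the threshold count OFF
(conservative ON calls).  Group summaries (mean, SD, n per fraction × time)
are computed on untransformed values — the transform is concave at large
arguments, and summarizing transformed values would bias skewed samples.
Crystal-violet biomass readings are normalized as OD₅₉₅/OD₆₀₀.

## Synthetic scenes

The generator emulates a 24-h static submerged biofilm in a 64 μm cube
(rendered at (1.0, 0.5, 0.5) μm spacing, 64×128×128 voxels, so upsampling
is exercised by default):

- **Aggregates** — 6 clusters of 150 cells packed uniformly in balls of
  radius 5 μm, centres uniform in x/y and confined below 40 μm, mirroring
  the observation that dense structures sit in the lower tens of
  micrometres.  Real aggregate size/count distributions are not known
  quantitatively; these defaults are plausible placeholders and fully
  configurable.
- **Singles** — 1000 cells uniform in the free volume (rejected from
  aggregate balls inflated by one cell length, 2 μm: a single cell cannot
  interpenetrate a dense aggregate).  This density corresponds to a dense
  sedimenting planktonic layer and, importantly, keeps every reporter
  channel within the segmentation operating regime (~1–4% foreground).
  Earlier, sparser defaults put the flagella channel at ~0.1% foreground,
  where global Otsu degenerates.
- **Pellicle** (optional) — a slab of cells in the top 12 μm.
- **Cells** — prolate spheroids, semi-axes (1.0, 0.5, 0.5) μm,
  approximating rod-shaped *E. coli* at confocal resolution.

**Expression model.** Three subpopulations: curli-ON stationary cells
(probability 0.9 in aggregates, 0.05 among singles), flagella-ON motile
cells (0.9 among curli-OFF singles, 0 in aggregates — flagellar expression
is essentially absent inside aggregates), and cells expressing neither.
Curli and flagella are mutually exclusive except that with probability
`epsilon_double` a cell is forced double-positive, so the double-positive
cell fraction equals ε in expectation.  Sigma-S activity is binary
(high = 1, low = 0.05 relative units): curli-OFF cells are high with
probability `p_sigmaS_high_given_curli_off` (default 0.2) and the coupling
`rho_sigmaS ∈ [−1, 1]` interpolates the curli-ON probability between that
baseline (ρ = 0) and certainty (ρ = 1), default 0.8 — deliberately allowing
sigma-S-high/curli-OFF and sigma-S-low/curli-ON cells.  TIMER is modelled
through its ratio: green amount 1, orange amount equal to the class ratio
(aggregates 2.0, singles 0.5, pellicle 1.5).

**Optics.** Solid-spheroid rasterization at state-dependent amplitude
(on-level 150, off-level 0 — OFF cells sit at the autofluorescence
background), amplitudes of overlapping cells add; Gaussian PSF of sigma
(0.4, 0.15, 0.15) μm (typical confocal axial/lateral widths); uniform
background 10; Poisson shot noise plus Gaussian read noise (sd 2).  Blur
conserves integrated intensity away from borders to within 1%.

**Cytometry mixture.** Events are ON with probability `f_on` (default
0.30); ON values are log-normal `exp(N(8, 0.5))` (~3000 a.u. mode), OFF
values normal `N(0, 60)` on the signed, background-subtracted scale.

**What the synthetic validation shows — and does not.** Passing tests
demonstrate that the measurement chain recovers known statistical structure
under a photon-limited Gaussian-PSF imaging model with well-separated
amplitude states.  Real stacks add depth-dependent attenuation, spherical
aberration, spectral bleed-through, heterogeneous per-cell expression
levels, and aggregate morphologies far from spherical; none of these are
modelled, so quantitative recovery rates here do not transfer to real data
— only the correctness of the estimators and their conventions does.

## Validation experiments and problem sizes

The experiments module (shared by the test suite and
`scripts/acceptance.py`) runs: 20 seeds of the default dual-reporter scene
(exclusivity + density association; the script reports 10 seeds), 3 seeds
of a 1200-single sigma-S scene with curli-ON share 0.35 (a bimodal
planktonic population giving both reporters enough signal mass for global
thresholding, and a 1:1 cell-to-cube correspondence so cube fractions are
comparable to cell fractions), 3 noise-free TIMER scenes (class assignment
of cubes by proximity to the known aggregate centres), 20 gating mixtures
of 50 000 events, 5 roughness scenes compared against an ideal flat slab,
and a double execution of the full default pipeline checked for bytewise
identity.  Scene sizes were chosen so the whole suite runs in well under a
minute per experiment on one CPU.

## Known limitations

- Global (per-stack) thresholds; no local/adaptive segmentation, no
  instance segmentation of single cells — the unit of measurement is the
  cube, not the cell.
- The roughness estimator and the averaging-kernel size are conventions,
  stated above, not uniquely determined by the underlying measurement idea.
- The biexponential is the published asinh stand-in, not any vendor's
  proprietary logicle parameterization.
- The generator does not simulate growth, division, chemical gradients or
  non-spherical aggregate shapes.
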