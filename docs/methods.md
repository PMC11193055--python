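# Methods

`cytoscreen` implements an automated viability/cytotoxicity screening
pipeline for adherent cells co-stained with Hoechst 33342 (all nuclei) and
propidium iodide (PI, dead nuclei only) in 96-well plates. This note
documents the models, the numerical choices, and what the bundled synthetic
data can and cannot establish.

## Image-analysis chain

Each well is acquired as one 16-bit grayscale field per channel (optionally
as 12 tiles in meandering order on a 3x4 grid, stitched before analysis so
nuclei straddling tile seams are counted once). Processing per channel:

1. **Unit scaling / grayscale.** Integer images are divided by their dtype
   maximum; color images are collapsed with Rec.709 luminance weights. All
   downstream thresholds are defined on this [0, 1] scale.
2. **Well masking.** Pixels outside the (known) well disk are replaced by
   the mean of the original image so that plate walls and reflections
   cannot seed detections. The geometry comes from the plate configuration,
   not from the image: the acquisition platform knows where the well is,
   and inferring the disk from intensities would add an unspecified
   algorithm with its own failure modes.
3. **Median smoothing.** A 4x4-neighborhood median filter. An even window
   has no central pixel; we anchor it with the extra row/column toward
   increasing index, use reflecting borders, and take the upper-middle
   order statistic as the even-count "median" (the rank-based convention of
   the standard median filters — the output is always a sample value).
   These choices are pinned so results are bit-reproducible.
4. **LoG blob detection.** Candidate nuclei are strict local maxima of the
   scale-normalized negative Laplacian-of-Gaussian response
   `-sigma^2 * Laplacian(G_sigma * I)` over a linear grid of
   `num_sigma = 10` scales on `[min_sigma, max_sigma] = [1.5, 4]` px, with
   response threshold 0.005 and overlap pruning at 0.35. Exact response
   ties within a plateau go to the lexicographically lowest (y, x, scale)
   voxel, so output is deterministic. Border peaks are kept
   (`exclude_borders = False`).
5. **Overlap pruning.** Each blob is modelled as a disk of radius
   `sigma * sqrt(2)`. When two disks share more than 35% of the smaller
   disk's area, the larger-sigma blob survives (ties: higher response, then
   lower (y, x)). The greedy sweep in that priority order is deterministic
   and idempotent.
6. **Live/dead rule.** `viable = max(0, hoechst_count - pi_count)`,
   counts taken on the full reassembled well with identical parameters for
   both channels. PI > Hoechst (spillover artifact) clamps at zero with a
   logged warning.

### Rim artifact of average-masking

Replacing the outside of the well with the image average leaves a circular
intensity step at the mask boundary whenever the global mean differs from
the local background (it always does once nuclei contribute intensity
mass). The LoG detector picks up a ring of barely-above-threshold maxima
exactly on that circle. Since a detection centered on the mask boundary
cannot be a cell, `count_image` discards blobs within 2 px of (or beyond)
the mask radius. This is a property of the masking rule itself, not of the
synthetic data.

### Noise regime of the fixed threshold

The detection threshold (0.005 on the unit-scaled response) implies an
upper bound on tolerable background noise: after the 4x4 median, additive
Gaussian noise of unit-scale sd 0.02 still leaves a LoG response with sd
about 0.003, and its local maxima then flood the detector with false blobs
— for any implementation of this detector. At sd 0.005 and below the
response maxima stay under threshold and false positives vanish. Real
16-bit fluorescence backgrounds unit-scale to noise well below this bound
(camera read noise is tens to hundreds of counts out of 65535), so the
synthetic generator defaults to `noise_sd = 0.005`, the conservative upper
end of the realistic regime. A dedicated test documents the boundary.

## Synthetic scenes

The generator emulates a stained well: nuclei are isotropic 2-D Gaussian
spots (sd = radius / sqrt(2), so the optimal LoG scale equals the spot sd
and detection has a closed-form oracle), placed uniformly in the well disk
by random sequential adsorption with a minimum center separation, on a flat
background (default 0.05) with seeded additive Gaussian noise. Dead nuclei
appear in both channels at the same intensity — the pipeline subtracts
counts, not intensities. Whole nuclei stay inside the well disk and frame
(placement margin = max radius). Defaults: radius 2.1-5.7 px so the optimal
scale falls inside the sigma grid; peak intensity 0.3-0.8; pixels outside
the well at 0 so masking is visibly exercised. Infeasible densities (above
~42% of the random-packing bound) raise instead of silently under-filling.

For the dense "subarea" benchmark scenes (800-2000 nuclei at >= 8 px
separation), radii are capped at 4 px: at the minimum separation two
default-sized nuclei (up to 5.7 px radius) would interpenetrate physically
and merge optically into one intensity maximum, which no counting algorithm
could separate; capping at the touching limit keeps the benchmark a test of
the detector rather than of an impossible geometry.

What the generator does **not** model: illumination gradients and
vignetting, Poisson shot noise (count accuracy, not photometry, is the
target), out-of-focus fields, clumped or overlapping nuclei, debris and
staining artifacts, and intensity differences between live and dead
nuclei. Passing tests on these scenes therefore establish the correctness
of the algorithmic chain and its calibration on well-formed inputs, not
robustness to the full pathology of real plates.

Tile-seam caveat: per-tile detection agrees exactly with mosaic detection
only when every nucleus clears the seams by more than its spot tail length
(about 18 px for the largest default spots at threshold 0.005; reflecting
borders turn a crossing tail into a border maximum). This is why
production counting always runs on the reassembled mosaic.

## Plate-level quantities

- **Growth.** Per condition (cell line, treatment, dose), viable counts
  are aggregated per timepoint as arithmetic mean +/- sd (sd reported as
  NaN for single replicates, never as a fake zero); fold change is the
  ratio of mean viable counts relative to the 0 h reference plate.
- **Survival / killing.** Survival is the ratio of group means (mean
  treated viable / mean untreated viable) — the convention that matches
  pooled plate-level controls; the per-well-ratio mean is reported
  alongside for transparency when groups pair up. Killing = 1 - survival.
  Survival above 1 is reported as-is.

## Dose-response models and ED50

Two families, with dose x and parameters named as in the standard
dose-response frameworks:

- **EXD3** (3-parameter exponential decay):
  `f(x) = c + (d - c) exp(-x / e)`, `e > 0`.
- **LL4** (4-parameter log-logistic):
  `f(x) = c + (d - c) / (1 + exp(b (ln x - ln e)))`, `e > 0`;
  `x = 0` takes the analytic limit (d for b > 0).

Fitting is nonlinear least squares (trust-region reflective, `e` bounded
positive) from data-driven starts (d = max response, c = min response, e =
dose nearest the half-range, b = 1) plus three multiplicative +/-20%
jittered restarts with a fixed seed — LL4 surfaces are multimodal on noisy
small-n data. The best-RSS converged solution wins; non-convergence is
flagged, never silently replaced.

Model choice uses the Gaussian-likelihood AIC
`n ln(RSS/n) + 2(k + 1)`, counting the error variance as a parameter; the
convention only needs to be consistent to rank models, and this is the
standard nonlinear-regression form. Ties (|dAIC| < 1e-9) go to the smaller
model.

ED50 is defined relative to the fitted asymptotes: for LL4 it is `e`
exactly; for EXD3, solving `c + (d - c) exp(-x/e) = (c + d)/2` gives
`x = e ln 2` (requires `c < d`; a degenerate fit raises rather than
extrapolating). The 95% CI is a percentile bootstrap (B = 999, seeded)
resampling responses with replacement within each dose — the plate's
replicate structure — and refitting from the full-data solution; a
delta-method interval from the standard error of `e` is reported for
comparison. Bootstrap was preferred because plate experiments have small
n per dose, where normal-theory intervals are optimistic.

## Statistics

- **Normality**: one-sample Kolmogorov-Smirnov against a normal with
  sample-estimated mean/sd. Estimating parameters from the same sample
  makes the classical p-value anti-conservative (the Lilliefors
  situation); the result carries an explicit flag instead of silently
  substituting a different test.
- **Bonferroni**: `p_adj = min(1, m p)`.
- **Tukey-Kramer HSD**: all-pairs comparisons with pooled within-group
  variance, `q = |mean_i - mean_j| / sqrt(s^2/2 (1/n_i + 1/n_j))`
  (Kramer's unequal-n form), p-values and family-wise intervals from the
  studentized range distribution (numerically integrated CDF; validated
  against a seeded Monte-Carlo reference in the tests, tolerance below
  1e-2 on p).
- **Agreement model**: OLS of `manual ~ software` with t-based 95% CIs
  (df = n - 2), R^2, adjusted R^2, and the standardized beta obtained by
  refitting on z-scored variables.
- Significance convention: p < 0.05; star annotations map * / ** / *** to
  0.05 / 0.01 / 0.001.

## Problem sizes

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the smallest sizes at which each property is meaningfully
exercised: 20 dense subarea images (800-2000 nuclei) for detection
accuracy, 10 clean wells of 300 nuclei for live/dead conservation, 100
simulated dose-response experiments (7 doses x 3 replicates) with B = 999
bootstrap for ED50 recovery in the tests (the acceptance script uses 50
experiments with B = 499 and 8 subarea images), 100 simulations per truth
family for AIC selection, and 1000 null simulations for the family-wise
error of the HSD layer.

## Known limitations

- Touching or overlapping nuclei are not segmented (no watershed); counts
  under-report in pathologically confluent wells.
- The well mask is a configured circle; misconfigured geometry shifts the
  rim-artifact exclusion zone.
- KS normality with estimated parameters is anti-conservative (flagged).
- Survival normalization is per-plate via untreated controls; no
  cross-plate normalization is attempted.
- The bootstrap CI collapses to a point on noiseless (degenerate) data —
  correct, but a reminder that it reflects only within-dose replicate
  scatter.
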