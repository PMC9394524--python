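# Methods

This note documents the models, algorithmic choices and limitations behind
`polarcap`, in the order the pipeline runs.

## Synthetic scenes

The generator emulates a pheromone-responding yeast cell imaged in two
fluorescence channels at 20-min intervals. The cell is a circle of radius
`cell_radius_px` (default 20 px = 3.6 µm at the default 0.18 µm/px); the
membrane is a radial Gaussian band (σ = 1.2 px) whose brightness is
modulated along the arc:

* channel 1 (polarity reference): a wrapped Gaussian in arc length with
  σ = `cap_width_um` (default 0.5 µm) centered at `cap_angle_rad` — the
  polar cap;
* channel 2 (signal): a uniform membrane baseline
  (`signal_baseline_frac` = 0.25 of the membrane amplitude) plus the same
  wrapped-Gaussian bump centered at cap + `offset_um`, minus two symmetric
  wrapped-Gaussian dips (depth 0.2, σ 0.4 µm) at ±1.0 µm from the signal
  peak. The dips emulate the local minima flanking the cap seen for
  peripheral MAPK; with the default widths they are the global minima of
  the noiseless profile. Channel 2 additionally carries a uniform
  cytoplasm (amplitude 30), and a nuclear disk (radius 6 px ≈ 113 px²,
  amplitude 200 above cytoplasm) concentric with the cell.

Noise is additive Gaussian, clipped at zero, re-drawn per frame; the
default σ = 20 gives a membrane peak-to-noise ratio of 5. Defaults were
fixed once from the imaging geometry being emulated (60× objective, sCMOS
camera, 29 frames per cell); with them the nucleus sits ≈3 SD above the
per-cell mean intensity, which is the regime the nuclear-masking rule is
designed for.

What the generator does *not* emulate: shmoo morphology (cells stay
circular; the registration math is shape-agnostic, and closed-form circular
perimeters make ground truth exact), cap wandering or growth over time,
photobleaching, uneven illumination, and segmentation error (masks are
exact). Passing recovery tests therefore demonstrates correctness of the
measurement chain, not robustness to segmentation noise or morphology
change.

`make_population` derives per-cell seeds from a master seed (so cohorts are
reproducible and order-independent) and randomizes each cell's cap angle;
the planted offset is drawn from a constant, uniform-range, or callable
sampler.

## Periphery line-scan

The boundary is the 0.5 iso-contour of the binary mask (marching squares),
with interior holes filled first. The raw iso-contour is jagged at the
pixel scale, which systematically overestimates arc length (~7% for a
20-px disk); the vertex coordinates are therefore smoothed with a circular
Gaussian (σ = 1.5 samples, skipped for contours under 12 points), which
brings perimeters of both disks and squares within ~0.5% of truth. The
contour is oriented counter-clockwise in array coordinates, starts at the
vertex nearest the lexicographically smallest boundary pixel, and is
resampled to uniform ~1 px arc spacing.

The line-scan averages `width_px` samples (default 5) spaced 1 px along
the local normal, centered on the contour — 2 px inward, the contour
point, 2 px outward. The band is symmetric, so inward/outward orientation
does not affect the result; mean (not sum) aggregation keeps values on the
intensity scale. Samples falling outside the image are clamped to the edge
with a logged warning. Bilinear interpolation throughout.

## Registration and normalization

The reference peak is the argmax of the reference profile (ties → smallest
index; an all-equal profile is flagged degenerate and the frame skipped).
Registration is a pure circular shift placing that index at `n // 2`; it
conserves the multiset of values exactly. Normalization subtracts the
profile minimum and divides by the total, so each profile is a fraction
distribution: min 0, sum 1 (enforced to 1e-9 on every constructed
profile).

Cells with different perimeters are pooled by µm distance from the cap:
each profile is linearly (circularly) interpolated onto a symmetric grid
(default 0.1 µm spacing) and all profiles are cropped to the shortest
symmetric half-span present, renormalizing after cropping. Signed
positions (negative/positive side of the cap following contour
orientation) are kept throughout; extremum records also expose absolute
distances.

Cohort averages use all cell×frame profiles with frame ≥ `start_frame`
(default 9; at 20-min spacing this is 180 min, past the window where cells
are often still completing cytokinesis and segmentation is unreliable).
The 95% band is a percentile bootstrap with 10,000 resamplings; the
resampling unit is the **cell** (all retained frames of a drawn cell enter
the resample), which respects within-cell correlation rather than treating
frames as independent. The band is clipped to bracket the point estimate,
making the lower ≤ mean ≤ upper invariant hold even at extreme quantile
noise.

## Nuclear masking

Per cell and frame, on raw intensities: mean and population SD over
cell-mask pixels; candidates are pixels strictly above mean + `k_sd`·SD
(default 1) inside the cell; 8-connected components strictly larger than
`min_size_px` (default 25 px) are kept; the union is dilated by
`dilation_px` (default 1) with a 3×3 square element. The dilated mask may
extend up to `dilation_px` beyond the cell mask — intentional, as its
purpose is to swallow peripheral nuclear signal. Masked pixels are then
replaced with the cell's pre-replacement mean; all other pixels are
untouched. The polar cap is excluded purely by the size/threshold tuning
(the supra-threshold cap region is thin and stays under the size cutoff);
no boundary heuristic is added. The implementation is verified
bit-identical against a naive per-pixel threshold + flood-fill + Chebyshev
dilation oracle.

Detection quality is scored as pixel recovery, |detected ∩ truth|/|truth|,
against the planted nucleus.

## Extrema and distances

Global (not local) extrema of each registered profile are used; exact-value
ties resolve to the position closest to the cap, then to the negative
side. Locations are invariant to the affine normalization, so raw and
fraction profiles give identical records. Distance summaries are the
empirical CDF of absolute distances and its step-function quantiles
(smallest observed distance at which the cumulative fraction reaches q);
signed-position histograms use bins symmetric about 0 with one bin
centered on the cap. A window around the cap is *not* imposed on minima.

## Inference

* **Sliding ANOVA.** One-way ANOVA at each grid position across ≥2 groups
  of per-cell profiles (cells should be time-averaged first —
  pseudo-replication across frames of one cell is the main pitfall), Tukey
  HSD for pairwise contrasts, then Benjamini–Hochberg step-up FDR across
  positions (applied separately to the omnibus track and each pairwise
  track). BH is the concrete "FDR adjustment" implemented; positions with
  zero within-group variance are flagged undefined rather than given a
  p-value.
* **KS test.** D = sup |ECDF difference|; asymptotic two-sided p by
  default, exact method available for small samples.
* **Bootstrap.** Percentile intervals throughout, 10,000 resamples by
  default, all seeded. The difference-in-means test resamples the two
  groups independently and declares significance when 0 falls strictly
  outside the 95% CI. Phenotype-frequency CIs resample the n Bernoulli
  outcomes, implemented exactly as a Binomial(n, k/n) draw. Note the known
  small-sample behavior of percentile intervals: for a normal mean at
  n = 30 the expected coverage is ≈0.936 rather than 0.95; the coverage
  check in the test suite accounts for this.
* **Cosine of orientation.** The growth vector is defined as the net
  displacement of the polarized-growth tip (final minus initial polar-cap
  centroid) and compared with the unit gradient axis; a zero displacement
  is undefined and raises.

## Numerical conventions

* Contour orientation: counter-clockwise in (row, col) array coordinates
  (positive shoelace area with x = col, y = row).
* Argmax ties: smallest index (reference peak); extremum ties: nearest the
  cap, then negative side.
* Fraction-profile invariants (sum = 1 ± 1e-9, values ≥ 0, position 0 at
  the central index) are asserted at construction of every profile object.
* All RNG flows through `numpy.random.default_rng` seeded from explicit
  arguments; population seeds are spawned from the master seed so renders
  are order-independent.

## Problem sizes

The test and acceptance runs use 50-cell cohorts at 29 frames (the cohort
scale the analysis is designed for), 20 replicate seeds for ANOVA
calibration at 3 × 50 cells × 100 positions, 500 simulations × 1,000
resamples for bootstrap coverage, and 1,000 random pairs for KS oracle
equivalence — sizes at which the Monte-Carlo error of each check is well
below its tolerance while a full run completes in well under a minute.

## Known limitations

* Circular cells only; elliptical/shmoo geometry would exercise the
  shape-agnostic claims of the registration but is not rendered.
* No cell tracking or time-warping: frame indices are assumed aligned
  across cells, and mask labels consistent over time.
* The sliding ANOVA treats positions independently (FDR across positions);
  no spatial smoothing or cluster-level inference.
* Storey-type q-values are not implemented; BH only.
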