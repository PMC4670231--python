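# Methods

## The statistic

A grayscale image is read as a particle field: pixel intensity `P_x` is the
number of events co-resident at pixel x (8-bit saturation, 255/pixel).  The
grayscale Ripley K at radius r is

    K(r, n) = |Ω| / (n(n−1)) · Σ_x c_x · P_x · (P_x − 1 + S_x(r)),

with `S_x(r)` the summed intensity of the other pixels within Euclidean
distance r of x, `n` the total intensity over the study region Ω, and `c_x`
an edge-correction factor.  Distances are measured between pixel centers and
disc membership is inclusive (`d ≤ r`); co-resident particles are at
distance zero, hence the within-pixel term `P_x − 1` (also multiplied by
`c_x`).  For binary images the estimator reduces exactly to the classic
point-pattern K.

The standardized form is `K̃ = (K − πr²)/√var{K}`.  The centering constant
is always the analytic CSR expectation `πr²`; the Monte-Carlo mean of the
null is kept only as a diagnostic.

## Edge correction

Three variants are implemented; `A_xr` is the number of Ω-pixels inside the
disc around x, and a pixel is a *border* pixel when its disc is clipped by
the mask (`A_xr < |b(x,r)|`), which covers lattice margins and interior
holes alike:

* `ideal_border` — `πr²/A_xr` on border pixels, 1 elsewhere;
* `pixelated_border` — `|b(x,r)|/A_xr` on border pixels, 1 elsewhere;
* `full_field` — `πr²/A_xr` on every pixel (the default).

Under fixed-n CSR (multinomial placement) `E[P_x(P_x−1+S_x)] =
n(n−1)·A_xr/|Ω|²`, so the full-field factor gives `E[K] = πr²` *exactly*
for any mask geometry, while the border-only variants keep an O(1) bias of
roughly `|b| − πr²` per unit — invisible at low density, but tens to
hundreds of null standard deviations once the variance shrinks at high
density and small radius.  The acceptance battery measures both behaviors.

## The CSR null and critical quantiles

`var{K}` has no closed form under arbitrary masks, so the null is simulated:
B independent CSR fields with *exactly* the observed particle count n
(placement is multinomial over Ω — the statistic conditions on n), K
evaluated on each, and sample mean/variance/skewness recorded together with
the empirical 1%/99% quantiles of K̃.  First-order Cornish-Fisher
approximants `z_p + (z_p² − 1)·γ/6` (γ = Monte-Carlo skewness) are reported
alongside; with 2000 replicates their relative error against the empirical
quantiles is a few percent in typical regimes (radius 10, density 1) and
stays below ~20% even at radius 3 and 8 particles/pixel, where the K̃ null
is visibly skewed.  Default B is 1000 for references and envelopes; the
quantile-accuracy comparisons use 2000.  A K̃ value is only meaningful
against a matched null, so `ktilde` refuses a reference whose mask hash,
radius, correction method or particle count differ; `n_rtol` relaxes the
count match (needed after simulated microscope degradation, which perturbs
n by a fraction of a percent — the variance of K changes negligibly at that
scale).

Every stochastic routine takes an explicit seed; Monte-Carlo replicate i
draws from `SeedSequence(seed, spawn_key=(i,))`, so serial and parallel
evaluation produce identical streams and every artifact is bit-reproducible
from (parameters, seed).

## Numerical evaluation

The inner sums `S_x` are disc convolutions, evaluated with padded real
FFTs whose kernel spectra are precomputed per (mask, radius).  Because
intensities are integers, the convolution output is rounded back to the
exact integer result (FFT error is many orders of magnitude below 0.5), so
the filter path agrees with the direct O(Np²) double sum to the last bit —
the test suite checks equality against an independent double-sum oracle on
hundreds of random fields, and binary fields against an independent
point-pattern implementation.  `A_xr` maps are obtained the same way.
Profile ties in `kmax_radius` break toward the smallest radius (a
conservative cluster-size estimate).

## Synthetic validation fields

* **CSR** — n particles uniform over Ω (n = round(density·|Ω|)); per-pixel
  counts clip at 255 with a warning (never triggered below ~20
  particles/pixel on full masks).
* **Clusters** — a diffuse pool of `b·|field|` particles over the whole
  lattice plus an aggregate pool distributed CSR inside N randomly placed
  radius-r discs (overlap permitted, discs fully inside the lattice).  The
  signal adds to the background: expected intensity inside clusters is
  `b(1+SBR)`.  ADR = aggregate/diffuse particle count; the identity
  `ADR = SBR · A_clusters/A_field` links the three knobs, and exactly one
  of {ADR, cluster count, SBR} is derived from the other two.  When ADR is
  given it is honored exactly; SBR then varies slightly with the quantized
  cluster area.
* **Microscope degradation** — convolution with a normalized 3×3 truncated
  Gaussian (σ = 1 px, reflect padding, rounded back to counts), then
  per-pixel Poisson noise with λ equal to the pixel value.  The Poisson
  rule leaves no free noise amplitude, so SNR is a derived diagnostic
  `S/√(S+B)`; "SNR ≈ 2" conditions use S = 6, B = 2.
* **Decimation** — circular holes of radius 20 px, pairwise non-overlapping
  with ≥1 px offset, fully inside the lattice (rejection sampling, capped
  attempts); particles are placed CSR on the remaining mask.  Hole
  boundaries count as study-region borders for edge correction.
* **Size classes** — 20 flat aggregates at each radius 2, 4, 6, 8 on a
  uniform background, built as a deterministic value map (background level
  2, aggregate level 22, SBR 10): aggregate pixels carry signal plus
  background.  This is the input for granulometric size analysis.

Study conditions used by the acceptance battery, chosen once: centering
grid densities {0.25, 1, 4, 10} × radii {3, 5, 10, 15} at B = 1000;
decimation counts {4, 6, 10, 12} at B = 500; ADR sweeps with background 2,
r_agg 8, N ∈ {4, 8, 16} at SBR 3 and SBR ∈ {1, 3, 6} at N = 8, 30 fields
per condition, with and without noise; K̃max studies at density 0.01 (5
clusters, no diffuse pool) and density 10 (ADR 0.05, SBR 3), radii 2–24,
reference B = 300.  These sizes keep the full battery in a few CPU-minutes
while leaving every bound non-marginal.

## Granulometry and segmentation

The pattern spectrum opens the image with the same pixelated discs used
everywhere else.  Pixelated Euclidean discs are not a perfectly *absorbing*
family — an opening at a larger radius can restore boundary pixels a
smaller one removed (a radius-5 disc loses 8 boundary pixels to the
radius-2 opening and gets them back at radius 5) — so the size distribution
is made properly decreasing by taking, at each radius, the pixelwise
minimum over all openings so far.  This equals the plain opening wherever
absorption holds and removes the restoration artifacts that otherwise split
and blunt size-class troughs.  The derivative entry between radii t−1 and t
is the mass removed by the opening at t; a *trough* (interior local minimum
with prominence ≥ 5% of the derivative range, by default) at t therefore
marks a dominant object class of radius about t−1, which
`extract_size_class(t−1)` isolates as `open(t−1) − open(t)`.

On the clean four-class field the four troughs land within one pixel of the
true radii essentially always.  Under PSF blur each class death splits
across two adjacent radii and Poisson noise adds a large removal ramp at
small radii (the opening erodes the noise texture's lower envelope), so
with classes spaced two pixels apart the troughs merge; granulometric
*size* analysis is therefore performed on undegraded (or denoised) images,
while the segmentation pipeline below is the robust choice for degraded
data.  This is a real limitation of opening-based pattern spectra, not of
the generator.

The segmentation pipeline is background subtraction (grayscale opening with
a large disc — a flat-ball approximation of rolling-ball subtraction, ball
radius default 50 px), Kapur maximum-entropy thresholding on the 256-bin
histogram (ties to the smallest threshold, foreground strictly above), and
a binary close with the image border padded as foreground so border objects
are not eroded.  Accuracy against ground truth uses the bivariate
similarity pair TET = |T∩E|/|T| and TEE = |T∩E|/|E| (TEE ≡ 1 for an empty
estimate).  At high SBR direct segmentation recovers essentially all truth
pixels (TET ≈ 1); at low SBR segmenting a single granulometric size class
first gives higher TET than direct segmentation — both behaviors are
asserted in the tests.

Experimental-image preprocessing: three-class Otsu thresholding (two
thresholds minimizing intra-class variance) zeroes the lower two classes —
the middle, ambiguous class is treated as background — and the surviving
nonzero pixels become the study region for K̃.  K̃ profiles of stacks from
one cell are ensemble-averaged per radius; per-construct summaries report
mean ± SEM across cells.  No routine rescales intensities: K̃ is not
invariant under contrast changes (asserted by test), so any normalization
must be an explicit, recorded caller decision, and images under comparison
must share a bit depth.

## Known limitations

* The Monte-Carlo null costs B field evaluations per (mask, n, radius,
  method) combination; profiles over many radii multiply that cost.
  References are serializable precisely so they can be reused.
* The Cornish-Fisher approximants inherit Monte-Carlo noise through the
  estimated skewness; at extreme density/radius combinations they are
  better at confirming clustering than at ruling it out (the empirical
  quantiles sit closer to the mean than the expansion suggests).
* Degraded images: see the granulometry note above.  K̃ itself is
  unaffected by the granulometric caveat.
* The generators emulate idealized confocal conditions (flat illumination,
  Gaussian PSF, pure Poisson noise, hard 8-bit clipping); camera gain/read
  noise, axial blur and illumination gradients in real data are outside
  the model, so passing simulations demonstrate correctness of the
  statistics, not robustness to every real-world artifact.
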