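# Methods

## The decay model

A pulsed laser at repetition rate 1/P (20 MHz → P = 50,000 ps) excites the
donor fluorophore; photon arrival times relative to the pulse are histogrammed
into `n_bins` bins of width `Δt` covering an acquisition window `W = n_bins·Δt
≤ P`. Because the donor lifetime (≈ 2–3 ns) is not negligible against the
50 ns period, emission from earlier pulses adds to the current window
("incomplete decay"). At steady state the pure decay is the periodic sum

    g(t) = Σ_{m≥0} e^(−(t+mP)/τ) = e^(−t/τ) / (1 − e^(−P/τ)),

and the measured curve is g circularly convolved (period P) with the
instrument response h, sampled at bin centers t_k = (k+½)Δt:

    conv_k = Σ_j h_j · g((t_k − t_j) mod P).

Because g factorizes over the mod-P difference, `conv` is computed exactly in
O(n) with two first-order recursions — a causal filter for j ≤ k and a
rescaled anti-causal filter for the wrapped j > k part. The rescaling (by
e^(−(P−W)/τ) and e^(−W/τ)) keeps every intermediate equal to a partial sum
bounded by 1, so no large exponentials appear anywhere between τ ≈ Δt and
τ ≈ 5P. The recursion is verified against an O(n²) brute-force mod-P sum to
~1e−14 relative error, including the stress case of IRF mass at the window
end.

Expected counts per pixel are then

    λ_k = A·s_k(τ) + b,    s = conv / Σ conv,

so A is exactly the expected number of decay photons in the window and b the
flat background (dark counts/afterpulsing) per bin.

## Fitting

The estimator is Poisson maximum likelihood. At the few hundred to few
thousand photons per (pooled) pixel this assay produces, Gaussian
least-squares weights are biased in low-count tail bins; the Poisson
likelihood is correct at any count level.

For fixed τ the likelihood in (A, b) is concave; it is maximized with the
multiplicative EM fixed point (A ← A·Σ y s/λ, b ← b·mean(y/λ)), which
preserves non-negativity and increases the likelihood monotonically.
Stopping is parameter-based (relative change ≤ 1e−9, max 500 iterations):
likelihood-based rules can fire while EM still crawls along the strongly
anti-correlated A–b ridge, which in testing produced profiled-likelihood
errors large enough to mislead the outer optimizer.

The remaining one-dimensional profiled likelihood in τ is scanned on a
60-point logarithmic grid over [Δt, 5P] and refined by bounded Brent
minimization (xatol = 0.05 ps) between the best grid point's neighbors; the
EM warm start is reset to the best scan point before refinement. With a
neighbor-pixel initialization (used raster-wise in image fits) the scan
narrows to 12 points over [τ_init/3, 3τ_init]. The profiled approach was
chosen over joint 3-parameter quasi-Newton because it is bracketing-robust,
needs no gradient of the convolution, and mirrors the grid-search oracle the
tests compare against (agreement within one 1-ps grid step on simulated
pixels).

Goodness of fit is the reduced Pearson statistic
χ²_ν = (1/ν) Σ (y_k − λ̂_k)² / max(λ̂_k, 0.1) with ν = n_bins − 3. The 0.1
floor prevents division blow-up in empty bins. Note the statistic sits near 1
only when most bins have non-negligible expected counts; the synthetic study
conditions therefore include the default flat background (200 photons/pixel
over the window, ≈ 0.5/bin), a realistic hybrid-detector dark level. A pixel
whose fit does not converge (or pins at the τ bounds) is masked out of the
image result rather than aborting the fit; the all-zero decay is an error.

Misspecification shows up as inflated χ²: fitting a well-separated
bi-exponential mixture with the single-exponential model yields mean
χ²_ν > 2 in the tests, which is the statistic's quality-control role.

## Instrument response

The IRF is represented either as an idealized delta (single unit bin) or as
a discretized Gaussian (center, FWHM). Estimation from a reference-dye
measurement (e.g. rhodamine 6G imaged under acquisition settings) pools all
pixels — the estimate depends on the data only through the pooled histogram —
and maximizes the Poisson likelihood over (center, log FWHM) with the dye
lifetime fixed and amplitude/background profiled out (bounded Nelder–Mead).
The dye lifetime is a required caller input; no literature value is baked in.
A two-parameter parametric fit was chosen over non-parametric deconvolution,
which is ill-posed at these photon counts. The IRF shift parameter is global
(applied by resampling the response), never fitted per pixel, keeping the
pixel problem three-parameter. Pooled references below 1000 photons are
rejected.

## Preprocessing chain

Order is fixed: temporal binning → spatial binning → smoothing/threshold.

- Temporal binning to a target count uses the integer factor
  f = floor(n_bins/target); the first target·f bins are summed in groups of
  f and the remainder discarded. With 4096 input bins and the default target
  of 401, f = 10 and bins 4010–4095 are dropped — the only integer-factor
  scheme consistent with a 401-bin result.
- Spatial binning sums non-overlapping f×f blocks (512×512 → 128×128 at the
  default 4). Non-divisible dimensions are cropped bottom/right with a
  warning.
- Smoothing multiplies the 5×5 boxcar mean by 25, i.e. pools the
  neighborhood's photons per time bin (reflective edge padding, so uniform
  regions are exact and borders are not darkened). The 200-photon threshold
  is applied strictly (">") to *unsmoothed* per-pixel totals: pooling before
  thresholding would make the criterion meaningless. The fitter consumes the
  smoothed stack; the mask decides which pixels are fitted; the intensity
  plane keeps the unsmoothed totals.
- Each stage stamps the stack's processing record. Binning stages may repeat
  (consecutive temporal binnings compose to the product factor, which is
  asserted by test), but nothing may run after smoothing and smoothing may
  not run twice.

Photon conservation over retained ranges holds exactly at every stage and is
asserted by brute-force summation in the tests.

## Downstream products

- FRET efficiency: E = 1 − τ_pixel/τ_ref per masked pixel. τ_ref is the
  unquenched donor lifetime; the conventional choice — and the default here —
  is the mean masked pixel lifetime of donor-only control images
  (`donor_reference_lifetime`), supplied explicitly. A per-image mean can be
  substituted for sensitivity checks. E ≤ 1 always; negative values (pixels
  longer-lived than the reference) are kept, not clipped.
- The "merged τ" rendering maps τ to hue over a fixed range (default
  1500–3500 ps, rainbow colormap) and scales per-pixel brightness by donor
  intensity with the 99th percentile at full scale, resisting hot pixels.
- Pixel-lifetime histograms use fixed-width bins aligned to multiples of the
  bin width so different images share a grid.
- Group comparisons use the equal-variance two-sided Student's t-test on
  per-nucleus mean lifetimes (Welch available behind `equal_var=False`),
  reporting t, p and mean ± s.d. per group.

## Nuclei, registration, profiles

Segmentation on the donor intensity channel is deliberately the simplest
deterministic recipe: Otsu threshold → hole filling → 8-connected components
→ size filter (default min 200 map-grid pixels), labels renumbered in raster
order. Constant images yield zero labels with a warning.

Immunofluorescence channels are rescaled to the lifetime-map grid with
bicubic interpolation, then corrected by a small affine transform
(translation ±10 px around a phase-correlation initialization, rotation
±10°, isotropic scale 0.9–1.1) maximizing normalized cross-correlation
against the donor intensity (Powell). NCC was chosen as the similarity
metric for its insensitivity to the channels' different intensity scales.
Optimizer failure returns the rescale-only image with a flag rather than
raising.

Line profiles sample at unit arc-length spacing; each sample averages
`width` (default 2) bilinear reads spaced 1 px apart perpendicular to the
line, with identical geometry applied to both channels. Endpoints are
user-supplied; `suggest_profile_line` proposes a line through the brightest
co-stain focus but never replaces user input.

## Synthetic data

The phantom is a disc of "euchromatin" at τ_open dotted with compact foci at
τ_compact ≤ τ_open, uniform expected brightness inside the nucleus, plus a
flat background rate over all pixels. FRET is modeled phenomenologically as
the shortened single per-pixel lifetime — not a two-component donor decay —
so ground truth lives in the fitted model's family and recovery is
well-posed. Counts are Poisson draws from the same periodic-excitation model
the fitter uses. Geometry and photon noise use independent seeded
sub-streams, so one phantom can be reused across noise realizations; foci
may overlap each other but always lie wholly inside their nucleus.

Default study conditions: τ_open = 2600 ps, τ_compact = 2100 ps (the typical
donor-only vs donor+acceptor contrast of the chromatin assay), Gaussian IRF
(center 1 ns, FWHM 300 ps), 20 MHz period, 10⁴ expected photons per lit
map-grid pixel, 200 background photons/pixel. The default time axis is the
post-binning grid (401 bins × 122.07 ps — i.e. 4096 raw bins over 50 ns
binned 10×); several studies use shortened windows (64–201 bins at the same
bin width) to keep suite runtimes in minutes, which covers ≥ 10τ of decay
and changes none of the physics.

What the phantom does *not* emulate: optical blur of the donor channel,
photobleaching, triplet-state kinetics, detector afterpulsing structure
beyond a flat rate, spatial brightness variation within a nucleus, a
scattered-laser peak (the real instrument notch-filters it), or 3-D
cross-plane effects (z-stacks are processed plane by plane). Passing tests
therefore demonstrate the correctness of the estimator and pipeline wiring
under Poisson statistics — not robustness to those instrument effects.

## Numerical choices and degenerate inputs

- τ bounds in fitting: [Δt, 5P]; solutions pinned at a bound are flagged.
- EM: stop at relative parameter change ≤ 1e−9 or 500 iterations.
- Brent refinement: xatol = 0.05 ps.
- χ² floor: 0.1 expected counts.
- Gaussian IRFs narrower than ~1/100 bin underflow to a single-bin response.
- Acquisition windows longer than the repetition period are rejected (they
  are unphysical and would break the mod-P factorization).
- Histogram of a constant-τ map occupies exactly one bin; empty masks raise.

## Known limitations

- The fit is pixel-independent (no image-wide shared-τ or multi-exponential
  global analysis) and mono-exponential by design; heterogeneous pixels show
  up in χ², not in extra components.
- The 5×5 photon pooling correlates neighboring fitted pixels and biases τ
  upward inside compact foci smaller than the kernel (photons from
  surrounding euchromatin leak in). Region-level statistics in the tests
  therefore evaluate interiors or uniform phantoms.
- Registration assumes a small rigid-ish misalignment; it will not recover
  large rotations, anisotropic scaling or nonlinear distortion.
- The IRF is global: no wavelength- or position-dependent response.
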