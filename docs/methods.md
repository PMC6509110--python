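# Methods

This note records the models implemented in `sheetloc`, the defaults and why
they were chosen, the numerical choices, and the known limitations —
particularly what the synthetic-data generator does and does not emulate.

## Excitation optics

The excitation sheet is a scanned Bessel beam created by an annular pupil
between NA_in and NA_out.  We use the scalar annular-pupil integral

    E(r) = ∫_{NA_in}^{NA_out} J₀(k·NA·r)·NA dNA,  k = 2π/λ,  I(r) = E(r)²/E(0)²

evaluated by trapezoidal quadrature over 400 NA nodes (the FWHM is stable to
well under 1 nm against refinement).  A vectorial model is unnecessary at
NA 0.5 for an FWHM-level calculator.  The sheet thickness is the full width at
half maximum of the central lobe, found on a 0.25 nm radial grid with linear
interpolation at the half-max crossing; at λ = 637 nm, NA 0.42–0.50 it
evaluates to 494.8 nm (≈ 0.5 µm).  The uniform annular fill is an assumption:
the physical pupil is underfilled and its exact apodization is not modeled.
Beam propagation length is a configuration input (default 20 µm), not
computed — no length formula is part of the model.

Power density assumes uniform illumination of the rectangle scan-range ×
sheet-length; the optimal excitation band for spontaneously blinking dyes is
carried as the configuration default [0.17, 0.33] kW/cm².

## Acquisition geometry and coordinates

The sample is scanned through the static sheet at θ = 32.5° to the coverslip
in steps of s nm per camera frame.  All localization tables use sheet-frame
coordinates: u (camera fast axis, tilt direction), v (camera horizontal),
w (sheet normal, the astigmatic z).  Deskew to coverslip coordinates is

    X = p·s + u·cosθ − w·sinθ,  Y = v,  Z = u·sinθ + w·cosθ

for plane index p (0-based), a rotation plus per-plane translation (isometric
within a plane, exactly invertible).  The scan step default (316 nm) is the
value for which the reconstructed z-interval between adjacent planes is
0.17 µm at 32.5°; it is a free configuration parameter.

## Synthetic acquisitions

The generator produces what the analysis chain assumes, no more:

* **Structures.** Filaments (emitters Poisson-placed on polylines at a linear
  labeling density), NPC rings (n-fold sites on circles of the stated
  diameter, Bernoulli labeling), fiducial beads (always on).  Default NPC
  geometry: 8 sites per 100 nm ring, labeling efficiency 0.8.
* **Blinking.** A three-state chain off ⇄ on → bleached with continuous-time
  rates.  The chain is sampled *exactly* at the frame clock — the per-frame
  transition matrix is expm(Q·Δt) — so the stationary on-fraction equals the
  duty cycle k_on/(k_on+k_off) at any frame rate.  (A naive per-frame
  probability 1−exp(−k·Δt) inflates the on-fraction by O(k_off·Δt): +57% at
  the default k_off = 50 s⁻¹ and 20 ms frames, which would misstate every
  density-derived quantity.)  Sub-frame partial on-times are ignored; a frame
  is wholly on or off.  Defaults k_on = 0.25 s⁻¹, k_off = 50 s⁻¹ give duty
  cycle ≈ 5×10⁻³; 1000 photons per on-frame with Gamma dispersion 0.3.  These
  reproduce the working registered-event density: a labeling density of
  342 µm⁻² × duty cycle ≈ 1.7 events µm⁻² frame⁻¹
  (`simulate.registered_event_density` measures this by direct simulation).
* **Excitation.** Per plane, each emitter is weighted by the sheet profile at
  its sheet-normal offset: a Gaussian of the Bessel central-lobe FWHM
  (default 500 nm), optionally with side-lobe replicas at ±720 nm (the first
  side-lobe position of the reference beam) scaled by `sidelobe_fraction` —
  enough structure to exercise the side-lobe rejection of the filters without
  paying for the full Bessel axial profile.
* **Detection.** Each on-emitter renders an integrated elliptical Gaussian
  with widths from the astigmatic calibration at its sheet-normal offset;
  pixels are round(gain·Poisson(qe·(signal+background)) + N(0, read noise) +
  offset), clipped to 16 bits.  With noise disabled the expectation is
  returned unquantized so photon bookkeeping is exact.  Camera defaults:
  102 nm pixel, gain 2, offset 100, read noise 1.6 counts, QE 0.82.

Not emulated: dipole orientation, depth-dependent aberrations, structured
autofluorescence, sample deformation (only rigid per-frame drift).  Passing
tests therefore demonstrate correctness of the analysis chain under the
stated statistical model, not robustness to every real-sample pathology.

A table-level generator (`simulate_localizations`) skips image formation and
emits localizations at truth ± Gaussian noise of a stated precision.  It is
used where the quantity under test is downstream of fitting (drift, FRC,
particle averaging); localization fidelity itself is always tested through
the full camera-image path.

## Astigmatic calibration

Defocus model per axis: σᵢ(z) = σ₀ᵢ√(1 + u² + Aᵢu³ + Bᵢu⁴) with
u = (z−cᵢ)/dᵢ — the quartic-corrected hyperbola standard in astigmatic SMLM;
the functional form is substitutable and the fitted parameters are stored in
plain YAML.  Fitting is per-axis trust-region least squares; ≥ 15 distinct z
samples are required (bead stacks are conventionally acquired at 40 nm
steps).  Inversion minimizes the root-width distance D(z) on a 1 nm grid
with 3-point parabolic refinement; ties break toward smaller |z|.  A fit is
flagged invalid when min D exceeds 1.0 (√nm scale) — widths inconsistent
with any in-focus position — or when the minimum falls within 20 nm of the
calibration boundary, where out-of-range (defocused or side-lobe) events
fold onto the range edge.  The representative calibration used in simulations
has σ₀ = 150 nm, foci at ±250 nm, depth 400 nm over z ∈ [−600, 600] nm.

## Localization

Detection: difference of Gaussians (scales 1.3 and 2.6 px), 8-neighborhood
maxima above 5 × the robust noise std (1.4826 × MAD of the band-passed
frame), candidates closer than the ROI half-width merged keeping the
brighter.  Fitting: integrated (pixel-averaged) axis-aligned elliptical
Gaussian plus constant background, in photon units, by bounded least
squares.  The ROI is 15×15 px (±4σ for the ≈1.7 px astigmatic PSF); tighter
ROIs truncate the wings, couple the background estimate to the signal, and
measurably inflate low-photon errors above the 1/√N law.  Degenerate fits
are flagged, never raised.

The attached theoretical uncertainty is the Thompson–Larson–Webb form with
σ² taken as the fitted σₓσ_y (geometric mean); the Mortensen MLE form is
available behind `uncertainty_model="mortensen"`.  The axial uncertainty is
an error-propagation estimate: width estimates scatter as σ/√(2N) and the
defocus-curve slopes map width noise to z.  Two caveats are inherent and
documented rather than hidden: the TLW formula describes the photon-limited
regime, so 1/√N scaling of the measured error holds only when background and
read noise are negligible (both act as N-independent floors); and a
least-squares fitter carries a known ≈(16/9)^½ excess over the CRLB, which
the 1.3× acceptance envelope absorbs.

## Drift correction and rendering

Fiducial tracking links each bead to its nearest localization per frame
within 500 nm, following the track (not the static seed) so slow drift
cannot detach it; candidate fiducials are proposed automatically as tracks
covering ≥ 80% of an early frame window.  Per-bead displacements relative to
their track means are averaged, gap-interpolated, and smoothed with a
50-frame centered moving average.  The per-axis standard deviation of the
corrected tracks is reported as the achieved ("actual") localization
precision; residuals are taken against the *smoothed* trace, because the raw
per-frame mean contains 1/n of each bead's own noise and understates the
precision.  Cross-correlation drift renders 10 nm histograms per frame block,
correlates each against the first via FFT, and refines the peak with a
3-point parabolic fit per axis.  Correction interpolates the trace linearly
over frames and subtracts.

Density rendering represents each event as a unit-integral symmetric
Gaussian whose σ is the event's theoretical uncertainty (or a fixed value);
kernels are integrated over pixels and truncated at 6σ, so interior events
conserve weight to better than 10⁻⁶ with no border renormalization.  3D
rendering is a histogram with optional Gaussian smoothing.  Temporal color
coding partitions events by ⌊frame/frames_per_bin⌋ (2000 frames = 40 s at
20 ms is the conventional segment) and sums colormap-weighted per-bin maps.

## Fourier ring correlation

Events are split randomly in half (seeded, averaged over 5 splits) rather
than by odd/even frames, to avoid blinking-correlation bias; re-blinks of
one molecule landing in both halves can still bias FRC optimistically, which
is the standard caveat of localization FRC.  Halves are rendered as plain
10 nm histograms — no Gaussian smoothing, which would inflate correlation —
and correlated ring by ring in Fourier space.  Resolution is 1/q at the
first downward crossing of the fixed 1/7 threshold (linearly interpolated);
a curve that never crosses reports twice the render pixel with a "bound"
flag.  The accumulation analysis pools the first k volumes and recomputes
the resolution, which falls and saturates as events accumulate; FRC is
computed on the 2D projection of the pooled table.

## NPC particle averaging

The point cloud is binned at 10 nm; the candidate mask is (counts > 0) →
morphological hole fill → dilation by a 3×3 square; 8-connected components
with dilated area in [250, 300] px² (inclusive; dilation first, then area
selection — the literal operation order) are kept, their centroids computed,
and 32×32 crops taken (candidates whose crop leaves the image are dropped).
Each crop is fitted with the ring model A·exp(−(r−r₀)²/2σ_r²)+c by least
squares with multi-start r₀ ∈ {30, 50, 70} nm; fits are ranked by RSS
normalized by crop energy so bright and dim pores compete fairly.  Centers
are re-estimated by bivariate Gaussian KDE (per-axis Silverman bandwidth
σ·n^(−1/6), floored at the 2 nm evaluation grid) and the probability-map
centroid; plain KDE is used throughout (no mixture fitting).  The best
n_top = 50 crops are shifted onto a common center with bilinear
interpolation and summed; the pore diameter is 2·r₀ of a final donut fit of
the overlay.

Two quantitative properties of this estimator matter for interpretation:

* **Inward bias.** The radial image density of a ring of radius r₀ observed
  at localization precision σ peaks below r₀ (≈ σ²-scale bias for σ ≪ r₀)
  and loses its ring maximum entirely once r₀ < σ√2.  At σ = 15 nm the
  recovered diameter of a 100 nm ring reads ≈ 91–95 nm.  The procedure is
  meaningful only for σ comfortably below r₀/√2; the simulation default of
  15 nm precision is the regime published NPC-averaging studies operate in.
* **Footprint selection.** The [250, 300] px² window is the dilated footprint
  of a ~100 nm pore at 10 nm binning and 15 nm precision.  Applied to pores
  of a different size it selects an atypical subpopulation and biases the
  averaged diameter; `suggested_area_bounds` scales the window with the
  expected footprint π·(r₀ + 2σ + dilation margin)² and reproduces the
  canonical window at the defaults.

Whether donut fitting operates on binned images or raw event coordinates is
a free choice; binned-image fitting is the default here and the KDE centering
consumes raw events.

## Problem sizes

Defaults in the tests and examples are sized for a single CPU: localization
fidelity uses 64×64 px frames with 9–16 emitters over 8–25 seeds per photon
level; drift uses 2000-frame tables with 3 fiducials; FRC uses ~20 volumes
of 50 frames over 10 seeds; NPC averaging uses 100 pores × 3000 frames over
5 seeds.  All are the package's own test-scale choices; every statistic they
produce is recomputed at run time.

## Known limitations

Single-emitter fitting only (overlapping events are rejected, not
deconvolved), although the working density ≈ 1.7 events µm⁻² frame⁻¹ is near
the high-density limit; no per-pixel sCMOS noise maps in the fit; no
field-dependent calibration or non-rigid drift; the EGFP second color channel
is out of scope; 3D Fourier shell correlation is not implemented.
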