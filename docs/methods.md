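# Methods

This note documents the models, numerical choices and known
limitations of the package, in the spirit of a methods appendix.

## Bar trajectory ensembles

The primary stimulus is Langevin dynamics of the bar velocity with a
linear restoring force on position:

    dv = (−v/τ − ω₀² x) dt + σ dW,      dx = v dt

with defaults σ² = 0.05 m² s⁻³, τ = 50 ms, ω₀ = 9.42 s⁻¹ (read as an
angular frequency; 9.42 ≈ 3π suggests angular units, and the reading
is a config knob).  Integration is Euler–Maruyama at dt = 1 ms — the
O(dt) weak error is invisible at the 60 Hz analysis rate — evaluated
as an equivalent scalar AR(2) recursion through a vectorised linear
filter, so multi-thousand-second paths simulate in seconds.  The
stability guards dt ≤ τ/10 and ω₀·dt ≤ 0.1 reject configurations that
would diverge rather than letting them diverge silently.  Positions
are produced in µm; the SDE is integrated in SI units internally.

Closed forms used for validation: stationary Var(x) = σ²τ/(2ω₀²),
Var(v) = σ²τ/2; with the spring off, the position MSD grows linearly
at lags ≫ τ with slope 2D, D = σ²τ²/2 (= 62.5 mm²/s at the defaults).
These printed dynamics parameters are mutually inconsistent with the
~73 µm bar-position SD the decoding analyses assume (they imply a
multi-millimetre excursion), so the demo encoder uses a separate
trajectory preset: τ and ω₀ as above with σ² set to
2ω₀²·(73 µm)²/τ, giving a stationary position SD of exactly 73 µm
and a position correlation time 1/(ω₀²τ) ≈ 0.23 s.  That is the scale
on which the synthetic retina is calibrated.

The second ensemble draws i.i.d. Gaussian positions (SD 60 µm) every
16.7 ms frame and low-pass filters them at 5 Hz with a zero-phase
(forward–backward) order-4 Butterworth filter.  Zero-phase filtering
is chosen so the ensemble introduces no decoder-lag confound; the
effective power gain of the forward–backward pass is |H(f)|⁴.

## Synthetic retina

Each model cell is a 1-D linear–nonlinear–Poisson unit along the
motion axis (2-D receptive fields projected onto that axis):

* spatial front end: Gaussian center (radius ≡ SD, population mean
  115 µm, ±10 µm across cells) with an antagonistic surround
  (2.5× wider, weight −0.15), sensed through the bar's analytic
  overlap integral; or, for "wide-subunit" cells, an array of small
  (45 µm) rectified subunits tiling ±450 µm around the center;
* temporal kernel: difference of gamma lobes sampled at 1/60 s over
  500 ms, normalised to unit peak *step response*; the second lobe's
  weight controls biphasic vs monophasic dynamics;
* output nonlinearity: rate = baseline + gain·max(0, drive − θ) with a
  high threshold θ, producing sparse event-like firing;
* spiking: inhomogeneous Poisson thinning per 1/60 s bin with an
  absolute refractory dead time (2–5 ms by type).

Six functional presets (biphasic/monophasic/medium/slow OFF, ON,
ON-subunit) differ in polarity, time-to-peak (80–240 ms), second-lobe
weight, and whether they carry the wide subunit array.  ON cells see
the dark bar's trailing edge through biphasic kernels and rectified
subunits, which is why they are as informative as OFF cells here.  The
wide subunit array is one plausible stand-in for far-surround
responses; the biological mechanism is not modelled.

Per-preset thresholds and gains were calibrated once, on the 73 µm
trajectory preset, to the firing statistics the package targets: each
type's threshold is set so the drive exceeds it ~11% of the time
(single-cell activity fraction), and the gain so the type's mean rate
is 1.5 Hz.  The resulting population shows mean rates 1.1–1.9 Hz per
type, a mean single-cell activity fraction ≈ 0.08–0.11 and a
population activity fraction ≈ 0.37; tests assert these within ±30%.
Calibration numbers are frozen in `FUNCTIONAL_PRESETS` and are not
refit at run time.

What the generator does **not** emulate: correlated noise across
cells, adaptation, spike-sorting artifacts, 2-D spatial structure, and
any cell-type asymmetries beyond temporal dynamics.  Passing tests
therefore demonstrate the *analysis chain* on a population with the
right first-order statistics, not a biophysical retina.

## Linear decoder

The reconstruction is p(t) = Σᵢⱼ Kᵢ(t − tᵢⱼ) + C on a 1/60 s bin grid
(the stimulus frame; the bin is a package choice).  The design matrix
has one column per (cell, lag) holding that cell's spike count in the
lagged bin, plus an intercept column; edge bins whose lag window
leaves the recording are dropped, not zero-padded.  Filters span
[−0.5 s, +0.5 s], or [−0.5 s, 0] in the causal variant (the filter of
a spike then only extends backward in time, matching causal encoding:
a spike reports the stimulus that preceded it).

Fitting solves the normal equations; the training-segment Gram matrix
of the *full* population is cached so any cell subset refits by
slicing it — this is what makes subset curves, per-cell solo decoders,
redundancy analyses and the greedy disjoint-subset search affordable.
Rank-deficient systems (e.g. duplicated cells) fall back to the
minimum-norm pseudo-solution, logged.  An optional tiny ridge
(fraction of the mean Gram diagonal) is available for conditioning
only; pure OLS is the default contract, and residual orthogonality to
the design is asserted in tests.

The train/test split is contiguous — first 2/3 train, last 1/3 test —
with no shuffled cross-validation for the headline fit.  Performance
is the zero-lag Pearson CC (the cross-correlogram peak is not
searched); negative or undefined (constant-prediction) test CC is
reported as 0, and clamping events are logged.

## L1-regularised decoder

Objective: ⟨(p−x)²⟩ + λ Σᵢ‖Kᵢ‖₁ with an unpenalised constant.  The
solver is coordinate descent (scikit-learn `Lasso`; the mapping is
α = λ/2 for the mean-squared-error convention used here); every fit is
verified against the KKT subgradient conditions at 1e-6 relative
tolerance, with one automatic retry at tighter solver settings before
raising with iteration diagnostics.  λ_max = (2/n)·max|Xᵀ(y − ȳ)| is
the smallest strength that zeroes every kernel; the default selection
grid is 30 log-spaced values over [λ_max/10⁴, λ_max].

λ* is deliberately *larger* than MSE-optimal: the largest grid value
whose contiguous 5-fold cross-validated CC is within 5% of, and MSE
within 20% of, the unregularised decoder — as many cells zeroed as a
small performance concession allows.  Cell ranking uses the L1 filter
norm (ties broken by cell id); ranked groups are re-trained *without*
regularisation before evaluation.  The greedy disjoint-subset search
consumes cells in amplitude order, refitting an unregularised decoder
after each addition until the held-out test CC (the cross-validated
reading of the subset criterion) reaches the threshold, then restarts
on the remaining cells; it stops when the cells left cannot reach the
threshold even jointly.

On the default 100-cell/40-min synthetic run this yields 3 disjoint
subsets at CC ≥ 0.85: fewer than a real recording would give, because
the synthetic bar's 73 µm excursions sit inside a 1500 µm population
span, so only the central ~30 cells are strongly informative.  The
k-fold-duplication fixture, where redundancy is built in by
construction, recovers ≥ k subsets.

## Neural image

A(x, t) accumulates each cell's spikes at its receptive-field position
(10 µm grid pitch, a package choice), bins time at 16.6 ms and smooths
across space with a Gaussian of SD 21 µm truncated at ±4 SD ("width
21 µm" is read as the SD; the FWHM reading is a config switch).  Peak
readout takes the spatial argmax at every bin with at least one spike,
ties broken toward the smallest coordinate; the weighted-mean readout
uses the rate-weighted average position.  Occupancy normalisation
divides each spatial row by its total spike count (zero-total rows are
masked); temporal augmentation deposits each cell's rectified,
peak-normalised temporal profile over the preceding bins instead of a
unit count.  CC of these sparse estimate streams is computed only over
bins that carry an estimate.

## Error spectra

The error PSD uses Welch averaging (256-sample windows at 60 Hz, 50%
overlap — the same window length as the coherence estimator, for
comparability); Parseval consistency with Var(e) is asserted at 2%.
The position–frequency spectrum band-passes e(t) with a zero-phase
Morlet filter (Gaussian magnitude response in the frequency domain,
centre-frequency parameter ω_c = 6 cycles, a config knob), then
averages the squared filtered signal over the times the bar occupied
each 20 µm position bin.  Each frequency slice is rescaled so that its
occupancy-weighted position average equals the Welch PSD at that
frequency — the normalisation that makes the units µm²·Hz⁻¹ and the
sinusoid interpretation exact; only this constraint (not a particular
wavelet width) is treated as authoritative, and it is enforced to 1%.
The hyperacuity report flags spectrum cells strictly below the squared
20 µm cone spacing and reports the contiguous sub-threshold band at
the minimum-error position.

## Information and redundancy

Magnitude coherence is estimated by multitaper averaging:
non-overlapping 256-sample windows, Slepian tapers at time–bandwidth
3 with 5 tapers (config-exposed).  With n = windows × tapers
independent spectra, the squared-coherence bias floor of independent
signals is 1/n; the debiased estimate is (nγ̂² − 1)/(n − 1) clipped to
[0, 1].  Significance of nonzero coherence uses the analytic null
P(γ̂² > c) = (1 − c)ⁿ⁻¹; the information integral
−∫ log₂(1 − γ²) df runs over the contiguous significant band from
zero frequency (p = 10⁻² by default).  The alternative estimator
relaxes the threshold to 10⁻¹ and removes the residual bias by
estimating on nested data fractions and extrapolating linearly in
inverse sample size.  On an analytic Gaussian channel the direct
estimator lands within a few percent of the closed form, inside the
5–10% envelope asserted for rates above 0.5 bit/s.

Redundancy of a subset is R = 1 − MI_A/Σ Mᵢ, with MI_A and the solo
Mᵢ both measured from held-out-segment predictions of decoders fitted
on the training segment.  The CC–information interpolation
I = −0.5α log₂(1 − CC²) + β is an ordinary least-squares fit in the
transformed variable; the no-temporal-correlation identity holds in
bits *per sample*, so α ≈ 1 recovery tests feed per-sample
information (rate/fs).

## Receptive-field characterisation

Checkerboard mapping uses 1-D flickering bars of 69 µm at 30 Hz; the
STA over a 500 ms pre-spike window is separated into dominant spatial
and temporal factors by SVD.  Polarity is the sign of the temporal
lobe *nearest the spike* (the global extremum is ambiguous for
strongly biphasic kernels).  Typing thresholds: OFF cells with STA
time-to-peak > 183 ms are slow, > 116 ms medium; brisk OFF cells split
biphasic/monophasic at a rebound-lobe ratio of 0.25.  These cuts sit
between the frame-quantised peak times of the presets; the underlying
functional-type criteria are qualitative, so the numbers are config
defaults.
Mapping stimuli drive the encoder much more weakly than the bar, so
`encode_movie` exposes a `threshold_scale` to relax the output
rectifier during characterisation runs (the subunit front end is
linearised in this path).

The normalized distance convolves the rectified spatial profile with a
symmetric, endpoint-half-weighted sampled bar (odd kernel length, so
no half-sample shift), takes the mean m_i and SD s_i of the result,
and reports d = |m_b − m_i|/s_i.  A common optical blur leaves m_i
exact and grows s_i only in quadrature, which is the sense in which d
is blur-invariant.  Bar speed for the spike-triggered speed average is
the central difference of the trajectory at the analysis bin, and the
overall mean speed is reported as a separate baseline rather than
subtracted.  Group comparisons use the two-sided Mann–Whitney U test
(exact enumeration for small tie-free samples, normal approximation
otherwise).

## Problem sizes

The synthetic experiments are desk-scale by design: the shared test
fixture uses 60 cells and 15 minutes of simulated recording; the
headline end-to-end check uses 100 cells and 40 minutes, where the
linear decoder reaches test CC ≈ 0.95, the subset curve saturates
(< 0.05 CC gained by the last doubling of cells) and the neural-image
peak readout stays near CC ≈ 0.1.  The diffusion-constant measurement
averages the MSD over 16 replicate 2000 s paths, which brings the
slope estimator's spread within a few percent.

## Known limitations

* The encoder is phenomenological; its calibration targets first-order
  firing statistics only, and conclusions about real retinas require
  the real recordings.
* The 1-D spatial treatment cannot express motion direction across the
  bar's long axis or 2-D receptive-field structure (the ellipse fields
  in `ReceptiveField` are carried but auxiliary).
* Information rates are Gaussian-channel lower bounds from decoded
  trajectories, not direct spike-train information estimates.
* The trajectory presets inherit the source dynamics' internal
  inconsistency (see above); both readings of ω₀ are exposed rather
  than resolved.
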