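# retinotrack

Tools for studying how a population of retinal ganglion cells encodes
the trajectory of a diffusively moving object, and for decoding that
trajectory back out of the spike trains.

When a dark bar performs a random walk over the retina, the position
signal is carried by 100+ ganglion cells with overlapping receptive
fields.  The classical picture — a "hill" of firing that travels with
the bar, readable by a population-vector decoder — breaks down for
diffusive motion: firing is sparse, event-like and spatially spread,
with cells responding to motion far into their receptive-field
surround.  Yet an *optimal linear decoder* reads the position out with
very high fidelity, and the code is so redundant that several disjoint
cell subsets each suffice.  This package implements the full analysis
chain on a synthetic retina with known ground truth, so every stage
can be validated:

* **trajectory simulation** — Langevin bar dynamics
  `dv = (−v/τ − ω₀²x) dt + σ dW` (velocity relaxation τ = 50 ms, noise
  σ² = 0.05 m²s⁻³, spring ω₀), and a low-pass-filtered white-noise
  positional ensemble (SD 60 µm, 5 Hz Butterworth);
* **synthetic retina** — a linear–nonlinear–Poisson population with
  six functional types (biphasic/monophasic/medium/slow OFF, ON,
  ON-with-rectified-subunits), calibrated to sparse event-like firing
  (mean rates 1–2 Hz, single cells active ~11% of the time);
* **linear decoding** — `p(t) = Σᵢⱼ Kᵢ(t − tᵢⱼ) + C`: each spike adds
  its cell's ±500 ms filter to the reconstruction; filters fitted by
  least squares on the first 2/3 of the recording, scored by the
  normalized cross-correlation (CC) on the last 1/3;
* **L1-regularised decoding** — `⟨(p−x)²⟩ + λ Σᵢ‖Kᵢ‖₁` for sparse cell
  selection, amplitude ranking, and greedy discovery of disjoint
  subsets that each decode above a target CC;
* **neural image** — the space×time population-activity matrix with
  peak and rate-weighted-mean readouts, occupancy normalisation and
  temporal-profile correction — the decoders that *fail* on the sparse
  code;
* **error spectra** — Welch error PSD, per-position RMSE, and a
  zero-phase Morlet position–frequency error spectrum normalised so
  its occupancy-weighted position average reproduces the PSD; compared
  against the 20 µm cone spacing (hyperacuity);
* **information & redundancy** — the Gaussian-channel bound
  `I = −∫₀^fmax log₂(1 − γ²(f)) df` from multitaper coherence, with
  debiasing, extrapolation to infinite data, the empirical
  CC–information relation `I = −0.5α log₂(1 − CC²) + β`, and subset
  redundancy `R = 1 − MI_A / Σᵢ Mᵢ`;
* **cell characterisation** — checkerboard spike-triggered-average
  receptive fields, functional typing from temporal dynamics, the
  blur-invariant normalized distance `d = |m_b − m_i| / s_i`,
  per-cell decoding versus distance, and spike-triggered speed
  averages.

## Worked example

Run the default end-to-end pipeline (40 model cells, 5 minutes of
spring-confined diffusive bar motion) and print the manifest:

```sh
retinotrack pipeline --seed 0 --out demo_run
```

```
completed stages: simulate, encode, decode, l1, neural_image, spectra, info
  cc_test_acausal: 0.8634
  cc_neural_image_peak: 0.2134
  rmse_um: 31.97
  info_rate_bits_per_s: 7.23
```

The linear decoder reconstructs the held-out third of the trajectory
with CC = 0.86 (RMS error 32 µm), while the neural-image peak readout
on the very same spikes only reaches CC = 0.21 — the central contrast
between the optimal linear readout and the classical moving-hill
picture.  The coherence between truth and reconstruction corresponds
to an information rate of 7.2 bits/s.  Larger populations do better:
with 100 cells and 40 minutes of data (the scale exercised in
`tests/test_acceptance.py`) the test CC reaches 0.95 and the
subset-performance curve saturates, so that disjoint groups of cells
each decode above CC = 0.85.

`demo_run/` contains every artifact as delimited text (trajectory,
spikes, fitted filters, predictions, error PSD) plus a
`manifest.yaml` recording config, per-stage seeds, digests and
timings; re-running with the same seed reproduces it bit-identically.

The same stages are available programmatically, statsmodels-style:

```python
from retinotrack.decoding import LinearDecoder
model = LinearDecoder(spikes, trajectory)   # builds the lagged design
result = model.fit()                        # OLS decoder
print(result.summary())                     # CC, RMSE, filter norms
sparse = model.fit_l1(lam)                  # L1 decoder, exact zeros
```

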