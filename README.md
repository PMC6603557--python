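# sepkit

Preprocessing choices change what an evoked potential *measures*. For
median-nerve somatosensory evoked potentials (SEPs), the frontal N30
component — the negative deflection near 30 ms post-stimulus, quantified
peak-to-peak against the preceding positive peak at 15–25 ms — shifts with
the filter class, the passband, and whether ICA-based artifact removal is
applied. `sepkit` implements that comparison as a tested, reusable pipeline
for EEG/ERP researchers:

* **Filters** — Kaiser-windowed sinc FIR designs specified by transition
  bandwidth in Hz (a 60 dB / 0.001-ripple specification gives the window
  parameter β = 5.653; at 2048 Hz, transition widths of 1.5 Hz and 1 Hz
  correspond to orders 4948 and 7420), and 2nd-order Butterworth IIR
  designs; both applied with zero-phase semantics (FIR: one pass with
  group-delay compensation; IIR: forward–backward passes). Band-pass
  filters are realized as a high-pass ∘ low-pass cascade.
* **Standardization** — truncation around the stimulus train, robust
  bad-channel flagging, significance-gated sinusoidal regression for mains
  noise (no notch filters), average reference.
* **Epoching** — stimulus-locked −100…150 ms epochs, baseline-corrected on
  the pre-stimulus interval.
* **Artifact rules** — five epoch-level detectors (absolute voltage > 100 μV,
  windowed peak-to-peak > 150 μV, step statistic > 100 μV, sample-to-sample
  jump > 50 μV, flatline < 2 μV for > 125 ms), each excluding the −2…2 ms
  stimulus-artifact window; epochs are marked, never deleted, with a manual
  mark/unmark override log.
* **ICA cleanup** — application of a precomputed unmixing and removal of
  labelled non-brain components (eye, muscle, line, channel noise) by
  back-projection. The decomposition itself is a pluggable contract.
* **N30 quantification** — average of good epochs at F3; amplitude
  |most-positive peak in 15–25 ms − most-negative peak in 25–35 ms|.
* **Statistics** — paired t-tests on artifact counts, and a gamma
  random-intercept model with log link for the 2 × 3 × 2 condition grid,

      y_ij ~ Gamma(k, μ_ij),  log μ_ij = x_ijᵀβ + z_i,  z_i ~ N(0, σ²),

  fitted by adaptive Gauss–Hermite quadrature, with AICc link selection,
  estimated marginal means, and ratio contrasts under a single-step
  max-|z| multiplicity adjustment.
* **Synthetic data** — a seeded generator producing 62-channel, 2048 Hz
  recordings with 1000 stimuli at 2.3 Hz, a ground-truth SEP template,
  1/f background, blinks, EMG bursts, a stimulus-locked reflex EMG, mains
  noise, stimulus artifacts and flat channels — plus the true mixing
  matrix and component labels, so every stage is testable end to end.

## Worked example

Run one synthetic dataset through the full 12-condition grid
({FIR, IIR} × {0.5–1000, 3–1000, 30–1000 Hz} × {no ICA, ICA}):

```python
from sepkit import SyntheticConfig, generate_condition_grid

config = SyntheticConfig(n_channels=8, n_stimuli=120, edge_s=5.0, seed=1)
grid = generate_condition_grid(config, dataset_id="demo")
print(grid[["filter", "band", "ica", "n30_amplitude_uv", "n_epochs"]].to_string(index=False))
```

prints

```
filter     band ica  n30_amplitude_uv  n_epochs
   FIR 0.5-1000  no          5.467235       116
   FIR 0.5-1000 yes          4.947129       116
   FIR   3-1000  no          5.409124       116
   FIR   3-1000 yes          4.916483       116
   FIR  30-1000  no          4.235488       116
   FIR  30-1000 yes          3.833677       116
   IIR 0.5-1000  no          5.503971       116
   IIR 0.5-1000 yes          5.011250       116
   IIR   3-1000  no          5.470457       116
   IIR   3-1000 yes          4.984093       116
   IIR  30-1000  no          4.023986       116
   IIR  30-1000 yes          3.746598       116
```

Reading the table: the two filter classes give nearly identical amplitudes;
the 30–1000 Hz passband lowers the measured N30 (the evoked complex has
substantial energy below 30 Hz); and removing the ground-truth non-brain
components lowers it further (stimulus-locked reflex EMG and residual noise
inflate the peak-to-peak read-out until they are removed). Feeding many such
per-dataset tables into `sepkit.stats.fit_gamma_lmm` yields the model
coefficients, cell means and ratio contrasts for the grid.

The same steps are available from a shell via the `sepkit` CLI
(`sepkit synth`, `sepkit grid`, `sepkit prep`, `sepkit detect`,
`sepkit ica-apply`, `sepkit n30`, `sepkit stats`).

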