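# sfica — spatial Fourier-ICA for frequency-specific brain networks

`sfica` decomposes ongoing EEG recorded under a continuous naturalistic
stimulus (e.g. a piece of music) into *frequency-specific cortical
networks*: spatial patterns with their own power spectra whose amplitude
envelopes can be tested against 1-Hz stimulus feature series.  It is
aimed at researchers analysing free-listening / free-viewing EEG who want
a fully data-driven alternative to band-limited sensor-space analyses.

## Method

Let `Y0` be preprocessed EEG (`Nc` channels, common-average referenced,
1–30 Hz, 256 Hz).  The pipeline computes:

1. **STFT tensor** — 3-s Hamming windows with 2-s overlap (1-Hz hop) and a
   512-point FFT give the complex tensor `Y1 (Nc, Nf, Nt)`; bins covering
   1–30 Hz are kept (`Nf = 60` at 0.5-Hz spacing).
2. **Source projection** — a depth-weighted minimum-norm inverse
   `G = R Lᵀ (L R Lᵀ + λ²cI)⁻¹` (lead field `L`, `λ² = 0.1`,
   `R_vv = ‖L·,v‖^(−2γ)`, `γ = 0.8`) maps each time–frequency slice to
   `Ns` source points: `Ŷ2 = G Ŷ1`.
3. **Spatial Fourier-ICA** — the source tensor is unfolded into
   `X0 (Nt, Nf·Ns)` and factored as `X0 = Â Ŝ` by complex-valued PCA
   (order 20) followed by complex FastICA (contrast `G(u) = √(ε+u)` on
   `u = |wᴴz|²`, symmetric orthogonalization).  Rows of `Ŝ` are
   spatial–spectral patterns; `|Â|` columns are envelope time courses at
   1 Hz.
4. **Stability (ICASSO)** — ICA is repeated with random initial
   conditions; pooled components are clustered by the |correlation| of
   their magnitudes and each cluster's index
   `Iq = S̄ᵢₙₜ − S̄ₑₓₜ` flags reliably re-estimated components
   (`Iq > 0.7`).
5. **Stimulus correlation** — component envelopes are correlated
   (Pearson) with five long-term musical features (fluctuation centroid
   and entropy, key clarity, mode, pulse clarity; 3-s frames, 67 %
   overlap, 1-Hz series).  The critical |r| controls family-wise error at
   `α = 0.05` via a Monte-Carlo max-statistic over circularly shifted
   surrogates.
6. **Group clustering** — retained spatial maps are z-scored and
   clustered by k-means (deterministic Kaufman seeding, MDL order
   selection); clusters spanning fewer than half the subjects are
   discarded.

A synthetic-data module generates ground-truthed recordings — compact
source patches oscillating at fixed carriers whose envelopes follow the
feature series through a lead field — so every stage can be validated by
parameter recovery.

## Worked example

Recover three planted networks from one synthetic subject:

```python
import numpy as np
from sfica import simulate, inverse, tfr, decomposition, characterize

scenario, L, feats = simulate.three_network_scenario(
    n_channels=64, n_sources=200, duration=512.0, fs=128.0, seed=5)
rec, truth = simulate.simulate_subject(scenario, leadfield=L, features=feats)

inv = inverse.compute_inverse_operator(L, lambda2=0.1, depth_gamma=0.8)
sensor = tfr.select_band(tfr.stft(rec, nfft=256), lo=1.0, hi=30.0)
dm = tfr.build_design_matrix(tfr.project_tfr(sensor, inv))
dec = decomposition.fourier_ica(dm.X0, order=10, seed=0)
summaries = characterize.summarize_components(
    dec.A_hat, dec.S_hat, dm.n_freqs, dm.n_sources)

for net in truth.networks:
    match = max(summaries, key=lambda s: abs(
        np.corrcoef(s.spatial_power, net.weights ** 2)[0, 1]))
    map_r = abs(np.corrcoef(match.spatial_power, net.weights ** 2)[0, 1])
    peak = sensor.freqs[np.argmax(match.spectrum)]
    env_r = np.corrcoef(match.timecourse, net.envelope)[0, 1]
    print(f"planted {net.carrier_freq:4.0f} Hz network -> component "
          f"{match.component_id}: map r={map_r:.3f}, spectral peak "
          f"{peak:.1f} Hz, envelope r={env_r:.3f}")
```

Output:

```
design matrix X0: 512 windows x 12000 source-frequency columns
planted   10 Hz network -> component 8: map r=0.997, spectral peak 9.5 Hz, envelope r=0.984
planted   20 Hz network -> component 9: map r=0.997, spectral peak 20.0 Hz, envelope r=0.995
planted    2 Hz network -> component 7: map r=0.996, spectral peak 2.5 Hz, envelope r=0.988
```

Each planted network is matched by one independent component whose
spatial power map correlates with the true source patch at r ≈ 1, whose
spectrum peaks at the planted carrier (within the 0.5-Hz bin spacing),
and whose envelope time course tracks the true amplitude envelope.

A command-line interface wraps the same workflow
(`sfica simulate | features | run-subject | run-group | run-all`).

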