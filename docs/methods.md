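# Methods

## Model

The pipeline assumes ongoing EEG is a linear sensor-space mixture of a
small number of cortical oscillatory networks plus noise.  Each network
`k` occupies a fixed spatial profile over source points and a narrow
spectral support, and modulates only its amplitude envelope over time.
In the short-time Fourier domain this is the factorization

    X0(t, (v, f)) = sum_k  A[t, k] * S[k, (v, f)],

where `X0` is the source-projected STFT tensor unfolded time-by-
(source, frequency), rows of `S` are complex spatial–spectral patterns
and `|A[:, k]|` is network `k`'s envelope on the 1-s window grid.
Complex ICA estimates `A` and `S` by maximizing non-Gaussianity of the
patterns across the `(v, f)` index — physiological patterns are sparse
(localized in space and frequency), which is exactly the regime in which
ICA separates them.

## Stages and parameter choices

**Preprocessing.** Common-average reference; zero-phase (forward–
backward) Butterworth filters: order-2 band-stop at the 50-Hz line
(±2 Hz, applied twice by filtfilt) and order-4 band-pass 1–30 Hz;
polyphase down-sampling; all filters as second-order sections (a 1-Hz
edge at a 2048-Hz rate is numerically unstable in transfer-function
form).  DC jumps are removed by differentiating, median-filtering only
the first-difference samples exceeding a threshold (default 10× the
median absolute first difference — data-adaptive because jump sizes are
recording-dependent), and reintegrating; smooth signals pass through
bit-exactly.  Bad-channel interpolation and ocular-artifact ICA are out
of scope: inputs are assumed clean or synthetic.

**STFT.** 3-s Hamming windows hopping 1 s give a 1-Hz time grid aligned
with the stimulus features.  The recording is reflect-padded by half a
frame so an N-second recording yields exactly N windows.  A 3-s frame at
256 Hz holds 768 samples but the FFT length is 512; we truncate the
windowed frame to its central 512 samples, which preserves the 0.5-Hz
bin spacing and the 256-bin positive-frequency grid.  (Zero-padding a
shorter window was the rejected alternative; the truncation keeps the
full 3-s Hamming taper's time weighting.)  Band selection keeps bins
with `lo − Δf ≤ f ≤ hi`, so the 1–30 Hz request retains the 60 bins
0.5…30 Hz.

**Inverse operator.** Minimum-norm with depth weighting:
`G = R Lᵀ (L R Lᵀ + λ² c I)⁻¹`, `R_vv = ‖L·,v‖^(−2γ)`, and
`c = trace(L R Lᵀ)/Nc` so that `λ² = 0.1` is meaningful regardless of
lead-field units.  Identity noise covariance (no noise modelling).
Source orientation is fixed (one scalar per source point);
`depth_gamma` defaults to 0.8 and 0 disables weighting, which reduces
`G` to an unweighted ridge inverse.

**Complex PCA / FastICA.** Rows of `X0` are mean-centered; the Nt×Nt
Hermitian covariance is eigendecomposed; the top 20 components are
whitened.  FastICA uses the robust contrast `G(u) = sqrt(ε + u)` with
`ε = 0.1` on `u = |wᴴz|²`, symmetric (parallel) orthogonalization, and
stops when `1 − min_j |⟨w_j⁺, w_j⟩| < 1e−6` (at most 1000 iterations).
Symmetric rather than deflationary updates avoid error accumulation at
order 20 and make runs exchangeable for the stability analysis.  The
model order 20 follows the convention of choosing slightly more
components than expected sources; the package exposes it as a parameter.

**Stability (ICASSO).** ICA is rerun with random unitary initializations
(default 100; 20 in the scaled experiments).  Similarity between pooled
components is the absolute Pearson correlation of their magnitude
vectors (phase-invariant); average-linkage agglomerative clustering into
`order` clusters; `Iq` = mean intra-cluster minus mean extra-cluster
similarity, with the extra term averaged over *all* non-members
(ICASSO's definition; a nearest-cluster variant would be an
alternative).  Singleton intra-similarity is defined as 1.  Components
with `Iq > 0.7` count as stable; the representative decomposition takes
each cluster's centrotype together with the mixing column of its own
run.  Note that even bit-identical runs give `Iq` marginally below 1
because chance similarity between different clusters is positive.

**Stimulus features.** Five long-term features on 3-s frames with 67 %
overlap (hop rounded to 1 s): fluctuation centroid and entropy are the
amplitude-weighted mean frequency and the Shannon entropy of the 0–10 Hz
fluctuation spectrum (log-spaced sub-band Hilbert envelopes, mean
removed, Fourier transformed and summed).  The centroid is implemented
as a spectral centroid, the standard definition of that feature, even
though it is sometimes described as a geometric mean.  Key clarity and
mode correlate a 12-bin FFT-pooled chromagram (A440) with the 24
Krumhansl–Kessler key profiles: clarity is the best correlation, mode
the best-major minus best-minor.  Pulse clarity is the peak normalized
autocorrelation of an onset envelope (spectral flux of a log-compressed
spectrogram, frame RMS-normalized for gain invariance) over lags
0.25–2 s (30–240 BPM).  Exact numerical parity with any particular MIR
toolbox is a non-goal; the features are the standard constructions.

**Stimulus correlation.** Two-sided test on Pearson |r| between
component envelopes and feature series.  The critical value is the
(1−α) quantile of the null maximum |r| over the whole component×feature
family, estimated from surrogates that circularly shift each feature
series (offset ≥ 10 s, preserving its autocorrelation) against
white-noise component series.  With a white component series the
variance of r is 1/n regardless of the feature's autocorrelation, which
makes the white-noise-matched null calibrate the family-wise error; the
calibration test verifies this empirically.

**Group clustering.** Retained spatial maps are z-scored per map.
K-means uses the deterministic Kaufman seeding (most central point
first, then maximal gained coverage), so identical inputs always give
identical partitions.  The order is chosen by a coding-length criterion
`N·d·log(RSS_m/(N·d)) + 2·m·d·log(N)` with maps first projected onto
their top `d = min(N−1, 50)` principal directions — at the raw
source-space dimension the penalty term would swamp the data term.  The
penalty constant 2 makes the criterion stable under duplication of the
data.  Clusters with fewer than `ceil(n_subjects/2)` distinct subjects
are discarded (a 7-of-14 cluster is kept).  Cluster summaries report the
centroid map, mean/SD of pairwise member-map correlations, per-feature
subject counts and member spectra.

## Synthetic data

The generator emulates the study design: a group of subjects hears one
512-s stimulus; 1-Hz feature series are standardized AR(1) processes
(lag-1 correlation 0.95, the smoothness of real long-term features);
each planted network is a Gaussian patch (SD 2–4 % of the source grid)
on a 1-D source ring, oscillating at a carrier in 1–30 Hz, with envelope

    e(t) = max(0, baseline + coupling · feature(t) + noise).

The baseline (default 2 with unit coupling and envelope-noise SD 0.1)
keeps the envelope away from the rectification point so it remains an
essentially linear readout of the feature; without it the envelope of a
standardized feature would be clipped about half the time.  Lead fields
are random channel topographies smoothed circularly along the source
ring — neighbouring sources have correlated topographies, preserving the
ill-posedness a minimum-norm inverse must handle, with no real head
geometry.  Sensor noise is white (SD 0.1 by default against per-channel
signal RMS near 0.8; 0.02 in the high-SNR stability fixtures).  The
group factory plants the three frequency-specific networks the pipeline
is meant to find: 10 Hz occipital-like, 20 Hz temporal-like, and a
frontal-like patch expressed at both 2 and 20 Hz, driven by key clarity,
fluctuation centroid and mode respectively.

What the generator does **not** emulate: cortical geometry and
volume-conduction physics, 1/f background spectra, non-stationary
artifacts (blinks, EMG), inter-subject anatomical variability, or
nonlinear envelope–feature coupling.  Passing the recovery suite
therefore shows the pipeline's statistical machinery is correct under
its own generative assumptions, not that real recordings will yield
equally clean networks.

## Problem sizes

The full-scale configuration (4000 sources, order 20, 100 stability
runs) is exposed through the defaults.  The validation experiments run a
scaled design chosen to keep the whole suite comfortably reproducible on
a single CPU: 14 subjects, 500 (or 200) source points, 128-Hz analysis
rate with a 256-point FFT (same 0.5-Hz bin spacing), ICA order 10, 20
ICASSO runs.  The planted networks are recovered with large margins at
this scale (map correlations ≈ 0.99), so the reduction does not bind the
conclusions.

## Numerical notes and degenerate inputs

- Whitening rejects orders above the numerical covariance rank, and
  FastICA rejects inputs whose covariance deviates from identity by
  more than 1e−3.
- The top-5 % spatial support uses stable sorting (ties resolved toward
  the lower source index) so the mask cardinality is exact and
  deterministic.
- Zero-variance component magnitudes get zero similarity rows (with a
  warning); silent audio frames yield zero features rather than errors.
- All randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

- Fixed source orientation only; no loose-orientation option yet.
- Per-subject ICA followed by map clustering; no group-level (temporally
  concatenated) spatial ICA.
- Correlation screening is two-sided with a single α; no FDR variants.
- EDF can be read but fixtures are written as HDF5/WAV only.
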