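"""Synthetic ground-truthed EEG with planted frequency-specific networks.

The generator emulates the study design the pipeline is built for: a group
of subjects listens to one continuous stimulus; a handful of cortical
networks — compact spatial patches oscillating at fixed carrier frequencies
— have amplitude envelopes that track smooth 1-Hz stimulus-feature series.
Sources are mixed to sensors through a lead field with additive white
sensor noise.  Every downstream stage (inverse projection, Fourier-ICA,
stability, stimulus correlation, clustering) can therefore be checked
against known spatial weights, carrier frequencies and envelopes.

The source space is a 1-D ring: no real geometry, but neighbouring sources
have correlated sensor topographies, which preserves the ill-posedness the
minimum-norm inverse has to cope with.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage, signal

from .io import EEGRecording

__all__ = [
    "PlantedNetwork", "Scenario", "PlantedTruth", "GroundTruth",
    "make_leadfield", "make_feature_series", "simulate_subject",
    "make_audio", "group_scenarios", "save_ground_truth",
]


@dataclass
class PlantedNetwork:
    """One planted oscillatory network.

    The network occupies a Gaussian patch of source weights around
    ``center_source`` (ring distance, SD ``spatial_sd``), oscillates at
    ``carrier_freq`` and its amplitude envelope follows

        e(t) = max(0, baseline + coupling * feature(t) + noise),

    with the driving feature standardized so ``coupling`` reads as an
    envelope signal-to-noise gain.  ``baseline`` keeps the envelope away
    from the rectification point so that it remains an essentially linear
    readout of the feature.
    """

    center_source: int
    spatial_sd: float
    carrier_freq: float
    feature_name: str
    coupling: float = 1.0
    envelope_noise_sd: float = 0.1
    baseline: float = 2.0

    def __post_init__(self) -> None:
        if not (1.0 <= self.carrier_freq <= 30.0):
            raise ValueError("carrier_freq must lie in the analyzed 1-30 Hz band")
        if self.spatial_sd <= 0:
            raise ValueError("spatial_sd must be positive")


@dataclass
class Scenario:
    """Full description of one synthetic subject."""

    n_channels: int
    n_sources: int
    duration: float
    fs: float
    networks: list[PlantedNetwork] = field(default_factory=list)
    sensor_noise_sd: float = 0.1
    feature_rho: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.n_sources < self.n_channels:
            raise ValueError("need n_sources >= n_channels")
        if abs(self.duration - round(self.duration)) > 1e-9:
            raise ValueError("duration must be an integer number of seconds")
        for net in self.networks:
            if net.carrier_freq >= self.fs / 2:
                raise ValueError(
                    f"carrier {net.carrier_freq} Hz is at or above Nyquist")


@dataclass
class PlantedTruth:
    """Ground truth for one planted network of a simulated subject."""

    weights: np.ndarray           # (Ns,) nonnegative spatial profile, unit norm
    carrier_freq: float
    feature_name: str
    envelope: np.ndarray          # (duration,) amplitude envelope at 1 Hz
    feature: np.ndarray           # (duration,) driving feature series at 1 Hz
    sensor_topography: np.ndarray  # (Nc,) L @ weights


@dataclass
class GroundTruth:
    networks: list[PlantedTruth]
    features: dict[str, np.ndarray]   # all 1-Hz feature series by name
    leadfield: np.ndarray


def make_leadfield(n_channels: int, n_sources: int, seed: int = 0) -> np.ndarray:
    """Random smooth lead field on a 1-D source ring.

    Each channel topography is white noise smoothed circularly along the
    source axis, so neighbouring sources have correlated sensor patterns;
    the matrix is full row rank almost surely.  Rows are scaled to unit
    norm on average.

    Returns the (n_channels, n_sources) gain matrix.
    """
    if n_channels < 2 or n_sources < n_channels:
        raise ValueError("require n_sources >= n_channels >= 2")
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n_channels, n_sources))
    sigma = max(1.0, 0.02 * n_sources)
    L = ndimage.gaussian_filter1d(L, sigma=sigma, axis=1, mode="wrap")
    L /= np.mean(np.linalg.norm(L, axis=1))
    return L


def make_feature_series(n: int, rho: float, seed: int = 0) -> np.ndarray:
    """Standardized AR(1) series of length ``n`` (lag-1 correlation ``rho``)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    burn = 100
    e = rng.standard_normal(n + burn)
    x = signal.lfilter([1.0], [1.0, -rho], e)[burn:]
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _ring_weights(n_sources: int, center: int, sd: float) -> np.ndarray:
    idx = np.arange(n_sources)
    d = np.abs(idx - center)
    d = np.minimum(d, n_sources - d)          # circular distance
    w = np.exp(-(d ** 2) / (2.0 * sd ** 2))
    return w / np.linalg.norm(w)


def simulate_subject(
    scenario: Scenario,
    leadfield: np.ndarray | None = None,
    features: dict[str, np.ndarray] | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Simulate one subject's sensor EEG plus ground truth.

    Parameters
    ----------
    scenario : Scenario
        Subject description; ``scenario.seed`` fixes all randomness.
    leadfield : ndarray, optional
        Shared (Nc, Ns) lead field; generated from the scenario seed if
        omitted.
    features : dict, optional
        Shared 1-Hz stimulus feature series (one stimulus for the whole
        group); generated from the scenario seed if omitted.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n_sec = int(round(sc.duration))
    n_samp = int(round(sc.duration * sc.fs))
    t = np.arange(n_samp) / sc.fs

    if leadfield is None:
        leadfield = make_leadfield(sc.n_channels, sc.n_sources,
                                   seed=int(rng.integers(2 ** 31)))
    L = np.asarray(leadfield, dtype=float)

    needed = {net.feature_name for net in sc.networks}
    features = dict(features or {})
    for name in sorted(needed - set(features)):
        features[name] = make_feature_series(n_sec, sc.feature_rho,
                                             seed=int(rng.integers(2 ** 31)))

    sensor = np.zeros((sc.n_channels, n_samp))
    truths: list[PlantedTruth] = []
    sec_centers = np.arange(n_sec) + 0.5
    for net in sc.networks:
        feat = features[net.feature_name]
        env_1hz = np.maximum(
            0.0,
            net.baseline + net.coupling * feat
            + net.envelope_noise_sd * rng.standard_normal(n_sec),
        )
        env_t = np.interp(t, sec_centers, env_1hz)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        sig = env_t * np.sin(2.0 * np.pi * net.carrier_freq * t + phase)
        w = _ring_weights(sc.n_sources, net.center_source, net.spatial_sd)
        topo = L @ w
        sensor += np.outer(topo, sig)
        truths.append(PlantedTruth(weights=w, carrier_freq=net.carrier_freq,
                                   feature_name=net.feature_name,
                                   envelope=env_1hz, feature=feat,
                                   sensor_topography=topo))
    if sc.sensor_noise_sd > 0:
        sensor += sc.sensor_noise_sd * rng.standard_normal(sensor.shape)

    rec = EEGRecording(data=sensor, fs=sc.fs)
    return rec, GroundTruth(networks=truths, features=features, leadfield=L)


def make_audio(kind: str, duration: float, fs: float = 8000.0,
               seed: int = 0, **params) -> np.ndarray:
    """Audio fixtures with known structure for the feature extractor.

    Kinds
    -----
    ``silence``
        All-zero waveform.
    ``amplitude-modulated-noise``
        White noise with sinusoidal amplitude modulation at ``rate`` Hz
        (default 4) and modulation ``depth`` (default 1).
    ``key-tones``
        Sustained triad of the requested ``key`` (default ``"C"``) and
        ``mode`` (default ``"major"``) with a few harmonics.
    ``click-track``
        Short noise-burst clicks at ``bpm`` (default 120).
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    if kind == "silence":
        return np.zeros(n)
    if kind == "amplitude-modulated-noise":
        rate = float(params.get("rate", 4.0))
        depth = float(params.get("depth", 1.0))
        mod = 0.5 * (1.0 + depth * np.sin(2.0 * np.pi * rate * t))
        wave = mod * rng.standard_normal(n)
        return 0.5 * wave / (np.abs(wave).max() + 1e-12)
    if kind == "key-tones":
        # tonal-context chord: the 12 pitch classes of the octave above
        # middle C, weighted by the requested key's tonal hierarchy
        from .features import _KK_MAJOR, _KK_MINOR
        key = str(params.get("key", "C"))
        mode = str(params.get("mode", "major"))
        names = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]
        root = names.index(key)
        profile = np.roll(_KK_MAJOR if mode == "major" else _KK_MINOR, root)
        wave = np.zeros(n)
        for pc in range(12):
            f0 = 440.0 * 2.0 ** ((60 + pc - 69) / 12.0)
            wave += profile[pc] * np.sin(2.0 * np.pi * f0 * t)
        return 0.5 * wave / (np.abs(wave).max() + 1e-12)
    if kind == "click-track":
        bpm = float(params.get("bpm", 120.0))
        period = 60.0 / bpm
        click_len = max(1, int(0.005 * fs))
        wave = np.zeros(n)
        start = 0.0
        while start < duration:
            i = int(round(start * fs))
            j = min(n, i + click_len)
            wave[i:j] = rng.standard_normal(j - i)
            start += period
        return 0.5 * wave / (np.abs(wave).max() + 1e-12)
    raise ValueError(f"unknown audio kind: {kind!r}")


# Feature names follow the five long-term stimulus features the pipeline
# correlates against.
GROUP_FEATURE_NAMES = ("FluctuationCentroid", "FluctuationEntropy",
                       "KeyClarity", "Mode", "PulseClarity")


def group_scenarios(
    n_subjects: int = 14,
    n_channels: int = 64,
    n_sources: int = 500,
    duration: float = 512.0,
    fs: float = 256.0,
    seed: int = 0,
) -> tuple[list[Scenario], np.ndarray, dict[str, np.ndarray]]:
    """Study-design factory: a group sharing one stimulus and three networks.

    Plants the three frequency-specific networks the pipeline is meant to
    recover — a 10-Hz occipital-like patch driven by key clarity, a 20-Hz
    temporal-like patch driven by fluctuation centroid, and a frontal-like
    patch expressed at both 2 and 20 Hz driven by mode.  All subjects share
    the lead field and the 1-Hz feature series (one piece of music for the
    whole group); per-subject seeds vary phases and noise.

    Returns (scenarios, leadfield, features).
    """
    rng = np.random.default_rng(seed)
    lf_seed = int(rng.integers(2 ** 31))
    L = make_leadfield(n_channels, n_sources, seed=lf_seed)
    n_sec = int(round(duration))
    features = {
        name: make_feature_series(n_sec, rho=0.95, seed=int(rng.integers(2 ** 31)))
        for name in GROUP_FEATURE_NAMES
    }
    sd = 0.02 * n_sources
    networks = [
        PlantedNetwork(center_source=int(0.30 * n_sources), spatial_sd=sd,
                       carrier_freq=10.0, feature_name="KeyClarity"),
        PlantedNetwork(center_source=int(0.65 * n_sources), spatial_sd=sd,
                       carrier_freq=20.0, feature_name="FluctuationCentroid"),
        PlantedNetwork(center_source=int(0.90 * n_sources), spatial_sd=sd,
                       carrier_freq=2.0, feature_name="Mode"),
        PlantedNetwork(center_source=int(0.90 * n_sources), spatial_sd=sd,
                       carrier_freq=20.0, feature_name="Mode"),
    ]
    scenarios = [
        Scenario(n_channels=n_channels, n_sources=n_sources, duration=duration,
                 fs=fs, networks=networks, sensor_noise_sd=0.1,
                 seed=int(rng.integers(2 ** 31)))
        for _ in range(n_subjects)
    ]
    return scenarios, L, features


def three_network_scenario(
    n_channels: int = 64,
    n_sources: int = 200,
    duration: float = 512.0,
    fs: float = 128.0,
    sensor_noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[Scenario, np.ndarray, dict[str, np.ndarray]]:
    """A single subject with three single-carrier networks (10, 20, 2 Hz).

    Low sensor noise by default: the fixture for stability and
    parameter-recovery checks where the networks themselves, not the noise
    regime, are under test.  Returns (scenario, leadfield, features).
    """
    rng = np.random.default_rng(seed)
    L = make_leadfield(n_channels, n_sources, seed=int(rng.integers(2 ** 31)))
    n_sec = int(round(duration))
    features = {
        name: make_feature_series(n_sec, rho=0.95,
                                  seed=int(rng.integers(2 ** 31)))
        for name in GROUP_FEATURE_NAMES[:3]
    }
    sd = 0.04 * n_sources
    networks = [
        PlantedNetwork(center_source=int(0.15 * n_sources), spatial_sd=sd,
                       carrier_freq=10.0,
                       feature_name=GROUP_FEATURE_NAMES[0]),
        PlantedNetwork(center_source=int(0.50 * n_sources), spatial_sd=sd,
                       carrier_freq=20.0,
                       feature_name=GROUP_FEATURE_NAMES[1]),
        PlantedNetwork(center_source=int(0.85 * n_sources), spatial_sd=sd,
                       carrier_freq=2.0,
                       feature_name=GROUP_FEATURE_NAMES[2]),
    ]
    scenario = Scenario(n_channels=n_channels, n_sources=n_sources,
                        duration=duration, fs=fs, networks=networks,
                        sensor_noise_sd=sensor_noise_sd,
                        seed=int(rng.integers(2 ** 31)))
    return scenario, L, features


def save_ground_truth(h5_path, json_path, gt: GroundTruth) -> None:
    """Persist ground truth: arrays to HDF5, a summary to JSON."""
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("leadfield", data=gt.leadfield)
        for i, net in enumerate(gt.networks):
            g = f.create_group(f"network{i}")
            g.create_dataset("weights", data=net.weights)
            g.create_dataset("envelope", data=net.envelope)
            g.create_dataset("feature", data=net.feature)
            g.create_dataset("sensor_topography", data=net.sensor_topography)
            g.attrs["carrier_freq"] = net.carrier_freq
            g.attrs["feature_name"] = net.feature_name
        fg = f.create_group("features")
        for name, series in gt.features.items():
            fg.create_dataset(name, data=series)
    summary = {
        "n_networks": len(gt.networks),
        "networks": [
            {"carrier_freq": net.carrier_freq, "feature_name": net.feature_name,
             "peak_source": int(np.argmax(net.weights))}
            for net in gt.networks
        ],
        "features": sorted(gt.features),
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
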