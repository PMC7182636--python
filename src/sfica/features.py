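"""Long-term musical-feature extraction at 1 Hz.

Five features are computed on 3-s frames with 67 % overlap (one frame per
second of audio): two tonal — key clarity and mode, from a chromagram
correlated with the Krumhansl–Kessler key profiles — and three rhythmic —
fluctuation centroid, fluctuation entropy (centroid and Shannon entropy of
the 0–10 Hz fluctuation spectrum of sub-band amplitude envelopes), and
pulse clarity (normalized autocorrelation of an onset-strength envelope
over the 30–240 BPM lag range).

A precomputed feature table can be loaded from CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal

FEATURE_NAMES = ("FluctuationCentroid", "FluctuationEntropy", "KeyClarity",
                 "Mode", "PulseClarity")

__all__ = [
    "FEATURE_NAMES", "FeatureSet", "frame_audio", "fluctuation_spectrum",
    "fluctuation_centroid", "fluctuation_entropy", "chromagram", "key_mode",
    "key_mode_from_chroma", "pulse_clarity", "extract_features",
    "load_features_csv", "save_features_csv",
]

# Krumhansl–Kessler tonal hierarchies (C major / C minor), pitch class C..B.
_KK_MAJOR = np.array([6.35, 2.23, 3.48, 2.33, 4.38, 4.09,
                      2.52, 5.19, 2.39, 3.66, 2.29, 2.88])
_KK_MINOR = np.array([6.33, 2.68, 3.52, 5.38, 2.60, 3.53,
                      2.54, 4.75, 3.98, 2.69, 3.34, 3.17])


@dataclass
class FeatureSet:
    """Feature series at 1 Hz, one row per feature in :data:`FEATURE_NAMES`."""

    names: tuple[str, ...]
    series: np.ndarray          # (n_features, n_seconds)
    rate: float = 1.0

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if len(self.names) != self.series.shape[0]:
            raise ValueError("names/series shape mismatch")
        if not np.isfinite(self.series).all():
            raise ValueError("feature series contain NaN")

    @property
    def n_samples(self) -> int:
        return self.series.shape[1]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: self.series[i] for i, n in enumerate(self.names)}


def frame_audio(wave: np.ndarray, fs: float, frame: float = 3.0,
                overlap_frac: float = 0.67) -> np.ndarray:
    """Slice audio into 3-s frames hopping 1 s (one frame per second).

    The hop is ``frame * (1 - overlap_frac)`` rounded to the nearest
    second; edges are reflection-padded so a ``D``-second waveform yields
    exactly ``round(D)`` frames, frame ``s`` centered on second ``s+0.5``.
    """
    wave = np.asarray(wave, dtype=float)
    if wave.size == 0:
        raise ValueError("empty audio")
    if fs <= 0 or frame * fs < 1:
        raise ValueError("invalid frame configuration")
    hop_s = max(1.0, round(frame * (1.0 - overlap_frac)))
    frame_len = int(round(frame * fs))
    hop_len = int(round(hop_s * fs))
    n_frames = int(round(wave.size / fs / hop_s))
    pad = frame_len // 2
    mode = "reflect" if wave.size > pad else "constant"
    padded = np.pad(wave, pad, mode=mode)
    out = np.empty((n_frames, frame_len))
    for s in range(n_frames):
        center = int(round((s + 0.5) * hop_len))
        start = pad + center - frame_len // 2
        seg = padded[max(0, start):start + frame_len]
        if seg.size < frame_len:          # clip at the far edge
            seg = np.pad(seg, (0, frame_len - seg.size))
        out[s] = seg
    return out


def _band_edges(fs: float, n_bands: int = 10) -> np.ndarray:
    lo, hi = 50.0, fs / 2 * 0.95
    if hi <= lo * 1.5:
        lo = hi / 20.0
    return np.geomspace(lo, hi, n_bands + 1)


def fluctuation_spectrum(frame: np.ndarray, fs: float,
                         n_bands: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Fluctuation spectrum of one frame over 0–10 Hz.

    The frame is split into ``n_bands`` log-spaced frequency bands; each
    band's amplitude envelope (Hilbert magnitude, mean removed) is Fourier
    transformed and the amplitude spectra are summed across bands.

    Returns ``(freqs, spec)`` with ``freqs`` in Hz limited to 10 Hz.
    A silent frame gives an all-zero spectrum.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    n = frame.size
    F = sfft.rfft(frame)
    freqs_audio = sfft.rfftfreq(n, d=1.0 / fs)
    edges = _band_edges(fs, n_bands)
    spec = None
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (freqs_audio >= lo) & (freqs_audio < hi)
        if not mask.any():
            continue
        Fb = np.where(mask, F, 0.0)
        band = sfft.irfft(Fb, n=n)
        env = np.abs(signal.hilbert(band))
        env = env - env.mean()
        amp = np.abs(sfft.rfft(env))
        spec = amp if spec is None else spec + amp
    mod_freqs = sfft.rfftfreq(n, d=1.0 / fs)
    keep = mod_freqs <= 10.0
    return mod_freqs[keep], (spec[keep] if spec is not None else
                             np.zeros(keep.sum()))


def fluctuation_centroid(spec: np.ndarray, freqs: np.ndarray) -> float:
    """Amplitude-weighted mean frequency of the fluctuation spectrum (Hz).

    Zero spectrum returns 0 by convention.
    """
    spec = np.asarray(spec, dtype=float)
    if (spec < 0).any():
        raise ValueError("spectrum must be nonnegative")
    total = spec.sum()
    if total <= 0:
        return 0.0
    return float(np.sum(np.asarray(freqs) * spec) / total)


def fluctuation_entropy(spec: np.ndarray) -> float:
    """Shannon entropy of the normalized fluctuation spectrum (nats)."""
    spec = np.asarray(spec, dtype=float)
    if (spec < 0).any():
        raise ValueError("spectrum must be nonnegative")
    total = spec.sum()
    if total <= 0:
        return 0.0
    p = spec / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def chromagram(frame: np.ndarray, fs: float) -> np.ndarray:
    """12-bin chroma vector (pitch class C..B) by FFT magnitude pooling.

    A440 tuning; spectral content between 55 Hz and 5 kHz contributes.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    mag = np.abs(sfft.rfft(frame * np.hanning(frame.size)))
    freqs = sfft.rfftfreq(frame.size, d=1.0 / fs)
    mask = (freqs >= 55.0) & (freqs <= min(5000.0, fs / 2))
    chroma = np.zeros(12)
    if mask.any():
        midi = 69.0 + 12.0 * np.log2(freqs[mask] / 440.0)
        pc = np.round(midi).astype(int) % 12
        np.add.at(chroma, pc, mag[mask])
    return chroma


def key_mode_from_chroma(chroma: np.ndarray) -> tuple[float, float]:
    """Correlate a chroma vector with the 24 Krumhansl–Kessler profiles.

    Returns ``(key_clarity, mode)``: the maximum profile correlation and
    the best-major minus best-minor correlation.  A flat or silent chroma
    returns (0, 0).
    """
    chroma = np.asarray(chroma, dtype=float)
    if chroma.std() == 0:
        return 0.0, 0.0
    maj = np.array([_pearson(chroma, np.roll(_KK_MAJOR, k)) for k in range(12)])
    mnr = np.array([_pearson(chroma, np.roll(_KK_MINOR, k)) for k in range(12)])
    return float(max(maj.max(), mnr.max())), float(maj.max() - mnr.max())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def key_mode(frame: np.ndarray, fs: float) -> tuple[float, float]:
    """Key clarity and mode of one audio frame (silent frame -> (0, 0))."""
    return key_mode_from_chroma(chromagram(frame, fs))


def _onset_envelope(frame: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Half-wave rectified flux of a log-compressed spectrogram (~100 Hz)."""
    frame = frame / (np.sqrt((frame ** 2).mean()) + 1e-300)  # gain invariance
    nper = max(8, int(round(0.04 * fs)))
    hop = max(1, int(round(0.01 * fs)))
    f, t, S = signal.stft(frame, fs=fs, nperseg=nper, noverlap=nper - hop,
                          boundary=None, padded=False)
    logmag = np.log1p(100.0 * np.abs(S))
    flux = np.diff(logmag, axis=1)
    onset = np.maximum(flux, 0.0).sum(axis=0)
    return onset, fs / hop


def pulse_clarity(frame: np.ndarray, fs: float,
                  return_lag: bool = False):
    """Clarity of the beat: peak normalized onset autocorrelation in [0, 1].

    The onset envelope's autocorrelation is maximized over lags 0.25–2 s
    (30–240 BPM).  Silence returns 0.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if np.abs(frame).max() == 0:
        return (0.0, np.nan) if return_lag else 0.0
    onset, env_fs = _onset_envelope(frame, fs)
    onset = onset - onset.mean()
    if onset.std() == 0:
        return (0.0, np.nan) if return_lag else 0.0
    ac = signal.correlate(onset, onset, mode="full")[onset.size - 1:]
    ac = ac / ac[0]
    lags = np.arange(onset.size) / env_fs
    mask = (lags >= 0.25) & (lags <= 2.0)
    if not mask.any():
        return (0.0, np.nan) if return_lag else 0.0
    idx = np.argmax(ac[mask])
    value = float(np.clip(ac[mask][idx], 0.0, 1.0))
    best_lag = float(lags[mask][idx])
    return (value, best_lag) if return_lag else value


def extract_features(wave: np.ndarray, fs: float) -> FeatureSet:
    """Compute all five long-term features frame by frame at 1 Hz."""
    frames = frame_audio(wave, fs)
    out = np.zeros((len(FEATURE_NAMES), frames.shape[0]))
    for s, frame in enumerate(frames):
        freqs, spec = fluctuation_spectrum(frame, fs)
        kc, mode = key_mode(frame, fs)
        out[0, s] = fluctuation_centroid(spec, freqs)
        out[1, s] = fluctuation_entropy(spec)
        out[2, s] = kc
        out[3, s] = mode
        out[4, s] = pulse_clarity(frame, fs)
    return FeatureSet(names=FEATURE_NAMES, series=out)


def load_features_csv(path) -> FeatureSet:
    """Load a 1-Hz feature table (columns: the five feature names,
    optional ``time_s``); unknown columns and NaN cells are rejected."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError("feature CSV is empty")
    known = set(FEATURE_NAMES) | {"time_s"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown feature columns: {unknown}")
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    block = df[list(FEATURE_NAMES)]
    if block.isna().any().any():
        raise ValueError("feature CSV contains NaN cells")
    return FeatureSet(names=FEATURE_NAMES, series=block.to_numpy().T)


def save_features_csv(path, fs: FeatureSet) -> None:
    df = pd.DataFrame(fs.series.T, columns=list(fs.names))
    df.insert(0, "time_s", np.arange(fs.n_samples, dtype=float))
    df.to_csv(path, index=False)
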