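"""Complex short-time Fourier tensors and the spatial-ICA design matrix.

The EEG is Hamming-windowed in 3-s frames hopping 1 s (1-Hz time grid,
reflect-padded so an N-second recording yields exactly N frames).  Each
windowed frame is truncated to its central ``nfft`` samples before the
``nfft``-point FFT, which fixes the bin spacing at ``fs / nfft``
(0.5 Hz for 256 Hz / 512 points).  The 1-30 Hz band (60 bins at 0.5-Hz
spacing) is kept, projected to source space through the minimum-norm
inverse, and unfolded time-by-(source, frequency) into the design matrix
X0 on which complex ICA runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .inverse import InverseOperator
from .io import EEGRecording

__all__ = ["SensorTFR", "SourceTFR", "DesignMatrix", "stft", "select_band",
           "project_tfr", "build_design_matrix", "refold_design_matrix"]


@dataclass
class SensorTFR:
    """Complex sensor-space TFR: coef (n_channels, n_freqs, n_times)."""

    coef: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window: str = "hamming"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.coef.shape[1:] != (len(self.freqs), len(self.times)):
            raise ValueError("coef shape inconsistent with freqs/times")


@dataclass
class SourceTFR:
    """Complex source-space TFR: coef (n_sources, n_times, n_freqs)."""

    coef: np.ndarray
    freqs: np.ndarray
    times: np.ndarray


@dataclass
class DesignMatrix:
    """Unfolded source TFR: X0 (n_times, n_freqs * n_sources).

    Column ordering is source-major: all frequency bins of source 0, then
    source 1, ...  (ICA is invariant to any fixed column permutation.)
    """

    X0: np.ndarray
    freqs: np.ndarray
    n_sources: int

    @property
    def n_times(self) -> int:
        return self.X0.shape[0]

    @property
    def n_freqs(self) -> int:
        return len(self.freqs)


def stft(rec: EEGRecording, frame_s: float = 3.0, overlap_s: float = 2.0,
         nfft: int = 512) -> SensorTFR:
    """Hamming-window STFT on a 1-s hop grid.

    Frame ``t`` is centered on second ``t + 0.5``; the recording is
    reflect-padded by half a frame at both ends so the number of frames
    equals the duration in seconds.  If the 3-s window holds more than
    ``nfft`` samples, the windowed frame is truncated to its central
    ``nfft`` samples (bin spacing stays ``fs / nfft``).  Only positive
    frequency bins are returned.
    """
    fs = rec.fs
    frame_len = int(round(frame_s * fs))
    hop = int(round((frame_s - overlap_s) * fs))
    if rec.n_samples < frame_len:
        raise ValueError("recording shorter than one STFT frame")
    if hop <= 0:
        raise ValueError("overlap must be smaller than the frame")
    n_frames = int(round(rec.n_samples / fs / (frame_s - overlap_s)))
    pad = frame_len // 2
    data = np.pad(rec.data, ((0, 0), (pad, pad)), mode="reflect")
    win = np.hamming(frame_len)
    n_keep = min(nfft, frame_len)
    lo = (frame_len - n_keep) // 2
    frames = np.empty((rec.n_channels, n_frames, n_keep))
    for t in range(n_frames):
        center = int(round((t + 0.5) * hop))
        start = pad + center - frame_len // 2
        seg = data[:, start:start + frame_len] * win
        frames[:, t, :] = seg[:, lo:lo + n_keep]
    coef = sfft.fft(frames, n=nfft, axis=2)[:, :, 1:nfft // 2 + 1]
    freqs = np.arange(1, nfft // 2 + 1) * fs / nfft
    times = np.arange(n_frames) + 0.5
    return SensorTFR(coef=np.transpose(coef, (0, 2, 1)), freqs=freqs,
                     times=times)


def select_band(tfr: SensorTFR, lo: float = 1.0, hi: float = 30.0) -> SensorTFR:
    """Restrict to bins with ``lo - df <= f <= hi`` (and f > 0).

    At 0.5-Hz spacing the 1-30 Hz request keeps the 60 bins 0.5 ... 30 Hz.
    """
    if not (lo < hi <= tfr.freqs[-1] + 1e-9):
        raise ValueError("require lo < hi <= max frequency")
    df = np.median(np.diff(tfr.freqs))
    keep = (tfr.freqs > 0) & (tfr.freqs >= lo - df - 1e-9) \
        & (tfr.freqs <= hi + 1e-9)
    if not keep.any():
        raise ValueError("band selection is empty")
    return SensorTFR(coef=tfr.coef[:, keep, :], freqs=tfr.freqs[keep],
                     times=tfr.times, window=tfr.window)


def project_tfr(tfr: SensorTFR, inv: InverseOperator) -> SourceTFR:
    """Apply the inverse operator to every time-frequency slice.

    Returns a (n_sources, n_times, n_freqs) complex tensor.
    """
    nc = tfr.coef.shape[0]
    if inv.G.shape[1] != nc:
        raise ValueError(f"TFR has {nc} channels, inverse expects "
                         f"{inv.G.shape[1]}")
    # (Ns, Nc) @ (Nc, Nf*Nt) in one shot, then reorder to (Ns, Nt, Nf)
    nf, nt = tfr.coef.shape[1], tfr.coef.shape[2]
    flat = tfr.coef.reshape(nc, nf * nt)
    src = (inv.G @ flat).reshape(inv.G.shape[0], nf, nt)
    return SourceTFR(coef=np.transpose(src, (0, 2, 1)), freqs=tfr.freqs,
                     times=tfr.times)


def build_design_matrix(src: SourceTFR) -> DesignMatrix:
    """Unfold (Ns, Nt, Nf) into X0 (Nt, Nf*Ns), source-major columns."""
    coef = src.coef
    if not np.isfinite(coef).all():
        raise ValueError("source TFR contains non-finite values")
    ns, nt, nf = coef.shape
    X0 = np.transpose(coef, (1, 0, 2)).reshape(nt, ns * nf)
    return DesignMatrix(X0=X0, freqs=np.asarray(src.freqs), n_sources=ns)


def refold_design_matrix(dm: DesignMatrix) -> np.ndarray:
    """Inverse of :func:`build_design_matrix`: back to (Ns, Nt, Nf)."""
    nt, nf, ns = dm.n_times, dm.n_freqs, dm.n_sources
    return np.transpose(dm.X0.reshape(nt, ns, nf), (1, 0, 2))
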