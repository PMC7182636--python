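"""EEG conditioning: re-reference, notch/band-pass filtering, down-sampling,
and a differentiate/median-filter/reintegrate DC-jump remover.

All filters are zero-phase (forward-backward IIR), so the conditioned EEG
stays aligned with the stimulus clock.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .io import EEGRecording

__all__ = ["rereference_common_average", "filter_chain", "remove_dc_jumps"]


def rereference_common_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def filter_chain(
    rec: EEGRecording,
    notch: float = 50.0,
    hp: float = 1.0,
    lp: float = 30.0,
    fs_out: float = 256.0,
) -> EEGRecording:
    """Notch + band-pass filter, then down-sample.

    4th-order Butterworth band-stop at ``notch`` +/- 2 Hz and band-pass
    ``hp``-``lp``, both applied forward-backward (zero phase), then
    polyphase resampling to ``fs_out``.
    """
    fs = rec.fs
    if not (0 < hp < lp < fs_out / 2 < fs / 2):
        raise ValueError("require hp < lp < fs_out/2 < fs/2")
    if notch >= fs / 2:
        raise ValueError("notch frequency above Nyquist")
    x = rec.data
    # band-stop wide enough that +/-1 Hz around the line sits deep in it;
    # second-order sections keep the near-DC poles numerically stable
    bs = signal.butter(2, [notch - 2.0, notch + 2.0], btype="bandstop",
                       fs=fs, output="sos")
    x = signal.sosfiltfilt(bs, x, axis=1)
    bp = signal.butter(4, [hp, lp], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(bp, x, axis=1)
    up, down = _resample_ratio(fs_out, fs)
    x = signal.resample_poly(x, up, down, axis=1)
    return EEGRecording(data=x, fs=fs_out, channel_labels=list(rec.channel_labels))


def _resample_ratio(fs_out: float, fs_in: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return frac.numerator, frac.denominator


def remove_dc_jumps(x: np.ndarray, kernel: int = 5,
                    thresh: float | None = None) -> np.ndarray:
    """Remove step discontinuities from a single-channel signal.

    The signal is differentiated; first-difference samples whose magnitude
    exceeds ``thresh`` are replaced by a ``kernel``-point median filter of
    the difference series; the result is reintegrated from the original
    first sample.  Smooth signals pass through bit-exactly because no
    difference sample crosses the threshold.

    ``thresh`` defaults to 10x the median absolute first difference.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("remove_dc_jumps operates on a single channel")
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    if x.size < 2:
        return x.copy()
    d = np.diff(x)
    if thresh is None:
        mad = np.median(np.abs(d))
        thresh = 10.0 * mad if mad > 0 else 10.0 * (np.abs(d).mean() + 1e-12)
    spikes = np.abs(d) > thresh
    if not spikes.any():
        return x.copy()
    d_filt = signal.medfilt(d, kernel_size=kernel)
    d = np.where(spikes, d_filt, d)
    return np.concatenate([[x[0]], x[0] + np.cumsum(d)])
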