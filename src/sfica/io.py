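"""Containers and file I/O for multichannel EEG recordings.

EEG is held as a plain ``channels x samples`` float array with a sampling
rate and channel labels.  Recordings can be read from EDF (via :mod:`mne`)
or from flat HDF5 matrices; synthetic fixtures are written as HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["EEGRecording", "read_edf", "read_hdf5", "write_hdf5",
           "read_wav", "write_wav"]


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (or arbitrary consistent units).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or infinite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "EEGRecording":
        if "data" in changes and "channel_labels" not in changes:
            changes.setdefault("channel_labels", list(self.channel_labels))
        return replace(self, **changes)


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (data in µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def read_hdf5(path, dataset: str = "eeg") -> EEGRecording:
    """Read a recording stored by :func:`write_hdf5`."""
    with h5py.File(path, "r") as f:
        d = f[dataset]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in d.attrs.get("channel_labels", [])]
        return EEGRecording(data=d[()], fs=float(d.attrs["fs"]),
                            channel_labels=labels)


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file; returns (waveform in [-1, 1], sample rate)."""
    from scipy.io import wavfile

    fs, wave = wavfile.read(str(path))
    wave = np.asarray(wave)
    if wave.ndim > 1:
        wave = wave.mean(axis=1)
    if np.issubdtype(wave.dtype, np.integer):
        wave = wave / float(np.iinfo(wave.dtype).max)
    return wave.astype(float), float(fs)


def write_wav(path, wave: np.ndarray, fs: float) -> None:
    """Write a mono waveform as 16-bit PCM WAV (clipped to [-1, 1])."""
    from scipy.io import wavfile

    wave = np.clip(np.asarray(wave, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(fs), np.round(wave * 32767).astype(np.int16))


def write_hdf5(path, rec: EEGRecording, dataset: str = "eeg") -> None:
    """Write a recording as a flat HDF5 matrix with rate/label attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset, data=rec.data)
        d.attrs["fs"] = rec.fs
        d.attrs["channel_labels"] = [s.encode() for s in rec.channel_labels]
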