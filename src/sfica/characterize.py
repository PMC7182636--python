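"""Spatial map, spectrum and envelope time course of independent components.

Each row of the source matrix S, refolded to (n_freqs, n_sources), gives a
Fourier-coefficient spectrum per source point.  The spatial power map is
the mean squared magnitude across frequency bins; its top-5 % source
points define the component's support, over which the mean power spectrum
is computed.  The time course is the modulus of the component's mixing
column — the Fourier amplitude envelope on the 1-s window grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ComponentSummary", "spatial_power_map", "component_spectrum",
           "component_timecourse", "summarize_components", "export_map_csv"]


@dataclass
class ComponentSummary:
    spatial_power: np.ndarray    # (n_sources,) mean squared Fourier magnitude
    support_mask: np.ndarray     # (n_sources,) bool, exactly top 5 %
    spectrum: np.ndarray         # (n_freqs,) mean power over the support
    timecourse: np.ndarray       # (n_times,) nonnegative envelope
    subject_id: str = ""
    component_id: int = 0


def _refold(S_row: np.ndarray, n_freqs: int, n_sources: int) -> np.ndarray:
    """Row of S (source-major layout) -> (n_freqs, n_sources)."""
    S_row = np.asarray(S_row)
    if S_row.size != n_freqs * n_sources:
        raise ValueError("row length does not equal n_freqs * n_sources")
    return S_row.reshape(n_sources, n_freqs).T


def spatial_power_map(S_row: np.ndarray, n_freqs: int, n_sources: int,
                      top_frac: float = 0.05
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared Fourier magnitude per source and its top-5 % mask.

    The mask holds exactly ``ceil(top_frac * n_sources)`` points; ties are
    broken toward the lower source index so the count is deterministic.
    """
    mat = _refold(S_row, n_freqs, n_sources)
    power = np.mean(np.abs(mat) ** 2, axis=0)
    n_top = int(np.ceil(top_frac * n_sources))
    # stable sort: among equal powers the lower index wins
    order = np.argsort(-power, kind="stable")
    mask = np.zeros(n_sources, dtype=bool)
    mask[order[:n_top]] = True
    return power, mask


def component_spectrum(S_row: np.ndarray, support_mask: np.ndarray,
                       n_freqs: int | None = None) -> np.ndarray:
    """Mean Fourier power spectrum across the supported source points."""
    support_mask = np.asarray(support_mask, dtype=bool)
    if not support_mask.any():
        raise ValueError("support mask is empty")
    n_sources = support_mask.size
    if n_freqs is None:
        n_freqs = np.asarray(S_row).size // n_sources
    mat = _refold(S_row, n_freqs, n_sources)
    return np.mean(np.abs(mat[:, support_mask]) ** 2, axis=1)


def component_timecourse(A_hat: np.ndarray, k: int) -> np.ndarray:
    """Modulus of mixing column ``k``: the amplitude-envelope time course."""
    A_hat = np.asarray(A_hat)
    if not (0 <= k < A_hat.shape[1]):
        raise IndexError(f"component index {k} out of range")
    return np.abs(A_hat[:, k])


def export_map_csv(path, summary: ComponentSummary) -> None:
    """Write a component's spatial map as per-vertex CSV (for overlays)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "power", "in_support"])
        for v, (p, m) in enumerate(zip(summary.spatial_power,
                                       summary.support_mask)):
            writer.writerow([v, repr(float(p)), int(m)])


def summarize_components(A_hat: np.ndarray, S_hat: np.ndarray, n_freqs: int,
                         n_sources: int, subject_id: str = ""
                         ) -> list[ComponentSummary]:
    """Summaries for every component of a decomposition."""
    out = []
    for k in range(S_hat.shape[0]):
        power, mask = spatial_power_map(S_hat[k], n_freqs, n_sources)
        out.append(ComponentSummary(
            spatial_power=power, support_mask=mask,
            spectrum=component_spectrum(S_hat[k], mask, n_freqs),
            timecourse=component_timecourse(A_hat, k),
            subject_id=subject_id, component_id=k))
    return out
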