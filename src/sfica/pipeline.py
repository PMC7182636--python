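"""Per-subject and group orchestration of the spatial Fourier-ICA workflow.

The per-subject chain is: conditioning -> STFT -> band selection ->
minimum-norm projection -> design matrix -> ICASSO-stabilized complex ICA
-> component summaries -> stimulus correlation.  The group stage pools
every subject's retained components and clusters their spatial maps.

All stages are driven by one :class:`PipelineConfig`, whose defaults are
the study settings (3-s/2-s Hamming STFT, 512-point FFT, 1-30 Hz band,
ICA order 20 with 100 stability runs, Iq threshold 0.7, alpha 0.05,
majority-subject cluster retention); runs are deterministic under a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import characterize, preprocess, stimcorr, tfr
from .cluster import ClusterResult, group_cluster
from .decomposition import FourierICADecomposition
from .features import FeatureSet
from .inverse import InverseOperator
from .io import EEGRecording
from .stability import StabilityReport, run_icasso

__all__ = ["PipelineConfig", "SubjectResult", "GroupResult", "run_subject",
           "run_group"]


@dataclass
class PipelineConfig:
    # conditioning
    filter_eeg: bool = True
    notch: float = 50.0
    hp: float = 1.0
    lp: float = 30.0
    fs_out: float = 256.0
    dejump_kernel: int = 5
    # STFT
    frame_s: float = 3.0
    overlap_s: float = 2.0
    nfft: int = 512
    band_lo: float = 1.0
    band_hi: float = 30.0
    # inverse
    lambda2: float = 0.1
    depth_gamma: float = 0.8
    # ICA / stability
    order: int = 20
    n_runs: int = 100
    iq_thresh: float = 0.7
    ica_max_iter: int = 1000
    ica_tol: float = 1e-6
    # stimulus statistics
    alpha: float = 0.05
    n_surrogates: int = 1000
    # clustering
    M_max: int = 10
    retain_frac: float = 0.5
    # master seed
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SubjectResult:
    subject_id: str
    decomposition: FourierICADecomposition
    stability: StabilityReport
    summaries: list
    correlation: stimcorr.CorrelationResult
    n_freqs: int
    n_sources: int

    @property
    def retained_components(self) -> list[int]:
        return sorted({k for _, k, _ in self.correlation.retained})

    def features_of(self, k: int) -> list[str]:
        return [f for _, kk, f in self.correlation.retained if kk == k]


@dataclass
class GroupResult:
    cluster: ClusterResult | None
    subjects: list[SubjectResult]
    r_crit: float
    subject_of_component: list = field(default_factory=list)
    component_of_entry: list = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return 0 if self.cluster is None else int(self.cluster.kept.sum())


def _condition(rec: EEGRecording, cfg: PipelineConfig) -> EEGRecording:
    rec = preprocess.rereference_common_average(rec)
    if cfg.filter_eeg:
        rec = preprocess.filter_chain(rec, notch=cfg.notch, hp=cfg.hp,
                                      lp=cfg.lp, fs_out=cfg.fs_out)
    data = np.vstack([
        preprocess.remove_dc_jumps(ch, kernel=cfg.dejump_kernel)
        for ch in rec.data])
    return rec.copy_with(data=data)


def run_subject(config: PipelineConfig, rec: EEGRecording,
                inv: InverseOperator, features, r_crit: float,
                subject_id: str = "sub", seed: int | None = None,
                out_dir=None) -> SubjectResult:
    """Run the full per-subject chain on one recording.

    ``features`` is a FeatureSet or dict of 1-Hz series; ``r_crit`` is the
    group-level critical correlation (see :func:`run_group`).
    """
    seed = config.seed if seed is None else seed
    conditioned = _condition(rec, config)
    sensor_tfr = tfr.stft(conditioned, frame_s=config.frame_s,
                          overlap_s=config.overlap_s, nfft=config.nfft)
    sensor_tfr = tfr.select_band(sensor_tfr, lo=config.band_lo,
                                 hi=config.band_hi)
    source_tfr = tfr.project_tfr(sensor_tfr, inv)
    dm = tfr.build_design_matrix(source_tfr)
    del source_tfr
    report, dec = run_icasso(dm.X0, order=config.order, n_runs=config.n_runs,
                             seed=seed, iq_threshold=config.iq_thresh,
                             max_iter=config.ica_max_iter, tol=config.ica_tol)
    summaries = characterize.summarize_components(
        dec.A_hat, dec.S_hat, dm.n_freqs, dm.n_sources, subject_id=subject_id)
    timecourses = np.vstack([s.timecourse for s in summaries])
    corr = stimcorr.select_components(timecourses, features, r_crit,
                                      subject_id=subject_id)
    result = SubjectResult(subject_id=subject_id, decomposition=dec,
                           stability=report, summaries=summaries,
                           correlation=corr, n_freqs=dm.n_freqs,
                           n_sources=dm.n_sources)
    if out_dir is not None:
        _persist_subject(Path(out_dir), result, config, dm.freqs)
    return result


def run_group(config: PipelineConfig, recordings, inv: InverseOperator,
              features, out_dir=None) -> GroupResult:
    """Run every subject, then cluster the retained spatial maps.

    ``recordings`` is a sequence of ``(subject_id, EEGRecording)``.
    Returns an empty-cluster report (not an error) when no component
    survives the correlation threshold.
    """
    recordings = list(recordings)
    if hasattr(features, "as_dict"):
        features = features.as_dict()
    n_feat = len(features)
    n_times = len(next(iter(features.values())))
    r_crit = stimcorr.mc_threshold(
        n=n_times, n_comparisons=config.order * n_feat, alpha=config.alpha,
        n_surrogates=config.n_surrogates, seed=config.seed,
        features=np.vstack(list(features.values())))
    subjects = []
    rng = np.random.default_rng(config.seed)
    for subject_id, rec in recordings:
        subjects.append(run_subject(
            config, rec, inv, features, r_crit, subject_id=subject_id,
            seed=int(rng.integers(2 ** 31)), out_dir=out_dir))

    maps, subj_of, feats_of, spectra, entries = [], [], [], [], []
    for res in subjects:
        for k in res.retained_components:
            maps.append(res.summaries[k].spatial_power)
            spectra.append(res.summaries[k].spectrum)
            subj_of.append(res.subject_id)
            feats_of.append(res.features_of(k))
            entries.append((res.subject_id, k))
    if not maps:
        return GroupResult(cluster=None, subjects=subjects, r_crit=r_crit)
    cluster = group_cluster(np.vstack(maps), subj_of, len(recordings),
                            M_max=config.M_max,
                            features_of_component=feats_of,
                            spectra=np.vstack(spectra))
    result = GroupResult(cluster=cluster, subjects=subjects, r_crit=r_crit,
                         subject_of_component=subj_of,
                         component_of_entry=entries)
    if out_dir is not None:
        _persist_group(Path(out_dir), result, config)
    return result


def _sha(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _persist_subject(out_dir: Path, res: SubjectResult,
                     config: PipelineConfig, freqs: np.ndarray) -> None:
    import h5py

    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{res.subject_id}.h5"
    dec = res.decomposition
    with h5py.File(path, "w") as f:
        for name, arr in (("A_re", dec.A_hat.real), ("A_im", dec.A_hat.imag),
                          ("S_re", dec.S_hat.real), ("S_im", dec.S_hat.imag),
                          ("iq", res.stability.iq), ("r", res.correlation.r),
                          ("freqs", np.asarray(freqs))):
            f.create_dataset(name, data=arr)
    prov = {
        "subject_id": res.subject_id,
        "config": config.to_dict(),
        "r_crit": res.correlation.r_crit,
        "retained": [[s, int(k), f] for s, k, f in res.correlation.retained],
        "checksums": {"A": _sha(dec.A_hat), "S": _sha(dec.S_hat)},
    }
    (out_dir / f"{res.subject_id}.json").write_text(json.dumps(prov, indent=2))


def _persist_group(out_dir: Path, res: GroupResult,
                   config: PipelineConfig) -> None:
    import h5py

    out_dir.mkdir(parents=True, exist_ok=True)
    cl = res.cluster
    with h5py.File(out_dir / "group.h5", "w") as f:
        f.create_dataset("centroids", data=cl.centroids)
        f.create_dataset("assignment", data=cl.assignment)
        f.create_dataset("kept", data=cl.kept.astype(int))
    report = {
        "config": config.to_dict(),
        "r_crit": res.r_crit,
        "M": cl.M,
        "kept": cl.kept.tolist(),
        "clusters": [
            {"cluster_id": s.cluster_id,
             "n_members": len(s.members),
             "subjects": [str(x) for x in sorted(set(s.subjects))],
             "mean_pairwise_r": s.mean_pairwise_r,
             "sd_pairwise_r": s.sd_pairwise_r,
             "feature_subject_counts": s.feature_subject_counts}
            for s in cl.summaries],
    }
    (out_dir / "group.json").write_text(json.dumps(report, indent=2))
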