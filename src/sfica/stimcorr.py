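"""Stimulus-related component selection by thresholded correlation.

Component envelope time courses are correlated (Pearson) with the 1-Hz
stimulus feature series.  The significance cutoff controls the
family-wise error over the whole component x feature family with a
Monte-Carlo max-statistic scheme: each surrogate draw correlates a
white-noise component series against circularly shifted copies of the
feature series (shift >= 10 samples, preserving their autocorrelation)
and records the maximum |r| over the family; the (1 - alpha) quantile of
that null maximum is the critical value r_crit.  A component is retained
for a feature when |r| >= r_crit (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CorrelationResult", "pearson", "mc_threshold",
           "select_components", "save_correlation_csv"]


@dataclass
class CorrelationResult:
    r: np.ndarray                 # (n_components, n_features)
    r_crit: float
    retained: list[tuple] = field(default_factory=list)
    feature_names: tuple[str, ...] = ()
    alpha: float = 0.05
    n_surrogates: int = 0
    seed: int | None = None

    @property
    def retained_mask(self) -> np.ndarray:
        return np.abs(self.r) >= self.r_crit


def save_correlation_csv(path, result: CorrelationResult,
                         subject_id: str = "") -> None:
    """Write one row per component x feature: r and the retention flag."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "component", "feature", "r", "retained"])
        retained = {(k, f) for _, k, f in result.retained}
        for k in range(result.r.shape[0]):
            for j, name in enumerate(result.feature_names):
                writer.writerow([subject_id, k, name,
                                 repr(float(result.r[k, j])),
                                 int((k, name) in retained)])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        raise ValueError("zero-variance input")
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def _corr_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs correlations between rows of X and rows of Y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Xn = Xc / (np.linalg.norm(Xc, axis=1, keepdims=True) + 1e-300)
    Yn = Yc / (np.linalg.norm(Yc, axis=1, keepdims=True) + 1e-300)
    return np.clip(Xn @ Yn.T, -1.0, 1.0)


def mc_threshold(n: int = 512, n_comparisons: int = 1, alpha: float = 0.05,
                 n_surrogates: int = 1000, seed: int | None = None,
                 features: np.ndarray | None = None) -> float:
    """Family-wise critical |r| from the Monte-Carlo max-statistic null.

    Parameters
    ----------
    n : int
        Series length.
    n_comparisons : int
        Size of the comparison family (components x features).
    features : ndarray (n_features, n), optional
        Actual feature series; surrogates circularly shift them (random
        offset >= 10) against fresh white-noise component series, cycling
        through the features to fill the family.  Without ``features``,
        white-noise series stand in.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_comparisons < 1 or n < 10:
        raise ValueError("invalid family size or series length")
    rng = np.random.default_rng(seed)
    if features is not None:
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features[None, :]
        if features.shape[1] != n:
            raise ValueError("feature length does not match n")
    max_r = np.empty(n_surrogates)
    min_shift = 10
    for s in range(n_surrogates):
        x = rng.standard_normal(n)
        if features is not None:
            reps = int(np.ceil(n_comparisons / features.shape[0]))
            fam = np.tile(features, (reps, 1))[:n_comparisons]
        else:
            fam = rng.standard_normal((n_comparisons, n))
        shifts = rng.integers(min_shift, n - min_shift + 1,
                              size=n_comparisons)
        idx = (np.arange(n)[None, :] + shifts[:, None]) % n
        fam = np.take_along_axis(fam, idx, axis=1)
        max_r[s] = np.abs(_corr_rows(x[None, :], fam)).max()
    return float(np.quantile(max_r, 1.0 - alpha))


def select_components(timecourses: np.ndarray, features,
                      r_crit: float, feature_names=None,
                      subject_id: str = "") -> CorrelationResult:
    """Correlate every component time course with every feature series.

    ``timecourses`` is (n_components, n_times); ``features`` is a
    FeatureSet, a dict name -> series, or an (n_features, n_times) array.
    Retained triples are (subject_id, component, feature_name).
    """
    if hasattr(features, "as_dict"):
        features = features.as_dict()
    if isinstance(features, dict):
        feature_names = tuple(features)
        F = np.vstack([features[nm] for nm in feature_names])
    else:
        F = np.atleast_2d(np.asarray(features, dtype=float))
        feature_names = tuple(feature_names or
                              (f"feature{i}" for i in range(F.shape[0])))
    T = np.atleast_2d(np.asarray(timecourses, dtype=float))
    if T.shape[1] != F.shape[1]:
        raise ValueError(f"time-course length {T.shape[1]} does not match "
                         f"feature length {F.shape[1]}")
    r = _corr_rows(T, F)
    retained = [(subject_id, k, feature_names[j])
                for k in range(r.shape[0]) for j in range(r.shape[1])
                if abs(r[k, j]) >= r_crit]
    return CorrelationResult(r=r, r_crit=r_crit, retained=retained,
                             feature_names=feature_names)
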