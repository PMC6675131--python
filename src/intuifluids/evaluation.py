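"""Model-comparison statistics for judgment data.

The response data are a participants x scenes matrix of judgments in
[0, 1].  Model fit is summarized by the Pearson correlation between
per-scene mean responses and model predictions, with a percentile
bootstrap confidence interval (scenes resampled with replacement).
Reliability is the split-half correlation across random participant
halvings.  The stimulus-structure null test fits a beta distribution to
the pooled responses (capturing their marginal variance but no
scene-specific structure), draws synthetic participants from it, and
compares the real and null per-participant correlation distributions with
a two-sample Kolmogorov-Smirnov test.  Task difficulty is summarized by
the variance of deterministic judgments across a damping window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseSet",
    "CorrelationReport",
    "BetaNullReport",
    "PredictionVarianceReport",
    "mean_responses",
    "pearson_bootstrap",
    "split_half",
    "beta_null_test",
    "fit_beta_moments",
    "prediction_variance",
]


@dataclass
class ResponseSet:
    """Participants x scenes matrix of judgments in [0, 1]."""

    matrix: np.ndarray
    scene_labels: List[str]
    participant_ids: List[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2D (participants x scenes)")
        if m.shape[1] < 2:
            raise ValueError("need >= 2 scenes")
        if np.any(m < 0) or np.any(m > 1) or not np.all(np.isfinite(m)):
            raise ValueError("responses must lie in [0, 1]")
        if len(self.scene_labels) != m.shape[1] or len(self.participant_ids) != m.shape[0]:
            raise ValueError("label lengths must match the matrix shape")
        self.matrix = m

    @property
    def n_participants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_scenes(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.participant_ids,
                     columns=self.scene_labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ResponseSet":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns), list(df.index.astype(str)))


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int


@dataclass(frozen=True)
class BetaNullReport:
    real_rs: np.ndarray
    null_rs: np.ndarray
    ks_statistic: float
    p_value: float
    beta_a: float
    beta_b: float


@dataclass(frozen=True)
class PredictionVarianceReport:
    mean_variance: float
    ci_low: float
    ci_high: float
    per_scene: np.ndarray


def mean_responses(rs: ResponseSet) -> np.ndarray:
    """Per-scene means across participants."""
    return rs.matrix.mean(axis=0)


def _pearson_vec(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson r of x against each row of ys (rows with zero variance -> nan)."""
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc @ xc) * np.sum(yc * yc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def pearson_bootstrap(x, y, n_resamples: int = 10_000, seed: int = 0) -> CorrelationReport:
    """Pearson r with a 95% percentile bootstrap CI over paired scene
    resamples (with replacement).  Deterministic given the seed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D arrays, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_resamples, n))
    xs = x[idx]
    ys = y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.sum(xc * yc, axis=1) / np.sqrt(
            np.sum(xc * xc, axis=1) * np.sum(yc * yc, axis=1))
    rs = rs[np.isfinite(rs)]
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return CorrelationReport(r=r, ci_low=float(lo), ci_high=float(hi),
                             n_resamples=n_resamples, seed=seed)


def split_half(rs: ResponseSet, n_splits: int = 100, seed: int = 0) -> float:
    """Average over random participant halvings of the Pearson r between the
    two halves' per-scene means.  No Spearman-Brown correction is applied."""
    p = rs.n_participants
    if p < 2:
        raise ValueError("split-half needs >= 2 participants")
    rng = np.random.default_rng(seed)
    half = p // 2
    vals = []
    for _ in range(n_splits):
        perm = rng.permutation(p)
        m1 = rs.matrix[perm[:half]].mean(axis=0)
        m2 = rs.matrix[perm[half:]].mean(axis=0)
        vals.append(float(stats.pearsonr(m1, m2).statistic))
    return float(np.mean(vals))


def fit_beta_moments(pooled: np.ndarray) -> tuple:
    """Method-of-moments beta fit to pooled responses clipped to
    (0.001, 0.999); the fitted first two moments match the data exactly."""
    z = np.clip(np.asarray(pooled, dtype=float).ravel(), 0.001, 0.999)
    mu = z.mean()
    var = z.var()
    if var <= 0 or var >= mu * (1 - mu):
        raise ValueError("pooled responses admit no beta moment fit")
    nu = mu * (1 - mu) / var - 1.0
    return mu * nu, (1 - mu) * nu


def beta_null_test(rs: ResponseSet, ground_truth, n_null: int = 1000,
                   seed: int = 0) -> BetaNullReport:
    """Do responses carry scene-specific structure beyond their marginal
    distribution?

    Each real participant's Pearson r with the ground truth is compared
    against the r distribution of synthetic participants whose responses
    are i.i.d. draws from a beta distribution fit (method of moments) to
    the pooled real responses.  A two-sample KS test summarizes the
    separation."""
    gt = np.asarray(ground_truth, dtype=float)
    if gt.shape != (rs.n_scenes,):
        raise ValueError("ground_truth length must equal the number of scenes")
    if rs.n_scenes < 2 or np.std(gt) == 0:
        raise ValueError("correlation undefined with < 2 scenes or constant truth")
    a, b = fit_beta_moments(rs.matrix)
    rng = np.random.default_rng(seed)
    null = rng.beta(a, b, size=(n_null, rs.n_scenes))
    real_rs = _pearson_vec(gt, rs.matrix)
    null_rs = _pearson_vec(gt, null)
    real_rs = real_rs[np.isfinite(real_rs)]
    null_rs = null_rs[np.isfinite(null_rs)]
    if len(real_rs) == 0:
        raise ValueError("no participant with defined correlation")
    ks = stats.ks_2samp(real_rs, null_rs)
    return BetaNullReport(real_rs=real_rs, null_rs=null_rs,
                          ks_statistic=float(ks.statistic),
                          p_value=float(ks.pvalue), beta_a=float(a), beta_b=float(b))


def prediction_variance(scene_set, predictor: Callable[[object, float], float],
                        zeta_window: Sequence[float],
                        n_resamples: int = 10_000,
                        seed: int = 0) -> PredictionVarianceReport:
    """Mean across scenes of the population variance of deterministic
    judgments over a damping window, with a bootstrap CI across scenes.

    ``predictor(scene, zeta)`` returns the deterministic J.  High variance
    across the window marks scenes whose outcome is intrinsically hard to
    pin down — the model is less certain, the task harder."""
    zs = np.asarray(list(zeta_window), dtype=float)
    if zs.size == 0:
        raise ValueError("empty damping window")
    per_scene = []
    for _, scene in scene_set:
        js = np.array([predictor(scene, float(z)) for z in zs])
        per_scene.append(float(np.var(js)))  # population variance
    per_scene = np.asarray(per_scene)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(per_scene), size=(n_resamples, len(per_scene)))
    means = per_scene[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return PredictionVarianceReport(mean_variance=float(per_scene.mean()),
                                    ci_low=float(lo), ci_high=float(hi),
                                    per_scene=per_scene)
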