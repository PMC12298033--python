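"""Keypoint evaluation: adaptively normalized PCK and paired t-tests.

PCK (Percentage of Correct Keypoints) counts a prediction correct when
its Euclidean distance to the ground truth, divided by a per-joint
normalization length, falls within a threshold.  Normalization is
adaptive per joint: the image diagonal for the shoulder and the upper-arm
and forearm lengths for the elbow and wrist, with threshold multipliers
0.3 / 0.4 / 0.5 respectively (the joint→threshold pairing is
configurable).  Detection accuracy pools all visible joints at a single
0.5 multiplier and is the per-round scalar tracked during federated
training.  Convergence-series comparisons between strategies use the
classical paired t-test on per-round mean-PCK values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["PCKConfig", "PCKReport", "TTestResult", "pck", "detection_accuracy",
           "paired_t_test"]

NORM_SOURCES = ("image_diagonal", "upper_arm", "forearm")


@dataclass(frozen=True)
class PCKConfig:
    """Per-joint normalization sources and threshold multipliers.

    Defaults pair shoulder ↔ image diagonal @ 0.3, elbow ↔ upper arm
    @ 0.4, wrist ↔ forearm @ 0.5.
    """

    norm_sources: tuple[str, ...] = ("image_diagonal", "upper_arm", "forearm")
    thresholds: tuple[float, ...] = (0.3, 0.4, 0.5)

    def __post_init__(self) -> None:
        if len(self.norm_sources) != len(self.thresholds):
            raise ValueError("one threshold per joint required")
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        for s in self.norm_sources:
            if s not in NORM_SOURCES:
                raise ValueError(f"unknown normalization source {s!r}")

    def source_indices(self) -> np.ndarray:
        return np.array([NORM_SOURCES.index(s) for s in self.norm_sources])


@dataclass
class PCKReport:
    per_joint: np.ndarray     # fraction correct per joint, NaN if none evaluated
    mean: float               # unweighted mean over joints with evaluations
    n_evaluated: np.ndarray   # visible (and valid-norm) count per joint


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def _distances(predictions: np.ndarray, ground_truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(predictions, dtype=np.float64)
    gt = np.asarray(ground_truth, dtype=np.float64)
    if pred.shape[0] != gt.shape[0] or pred.shape[1] != gt.shape[1]:
        raise ValueError("prediction/ground-truth sample counts differ")
    vis = gt[:, :, 2] > 0 if gt.shape[-1] >= 3 else np.ones(gt.shape[:2], dtype=bool)
    dist = np.linalg.norm(pred[:, :, :2] - gt[:, :, :2], axis=-1)
    return dist, vis


def pck(
    predictions: np.ndarray,
    ground_truth: np.ndarray,
    norm_lengths: np.ndarray,
    config: PCKConfig = PCKConfig(),
) -> PCKReport:
    """Per-joint PCK with adaptive normalization.

    ``predictions`` is (N, K, 2); ``ground_truth`` (N, K, 2|3) with an
    optional visibility column; ``norm_lengths`` (N, 3) holds per sample
    [image diagonal, upper arm, forearm].  Joints flagged invisible are
    excluded; samples with a nonpositive normalization length for a joint
    are excluded from that joint with a warning.
    """
    dist, vis = _distances(predictions, ground_truth)
    norms = np.asarray(norm_lengths, dtype=np.float64)
    src = config.source_indices()
    k = dist.shape[1]
    per_joint = np.full(k, np.nan)
    n_eval = np.zeros(k, dtype=np.int64)
    for j in range(k):
        L = norms[:, src[j]]
        valid = vis[:, j] & (L > 0)
        if np.any(vis[:, j] & (L <= 0)):
            warnings.warn("sample with nonpositive normalization length excluded",
                          stacklevel=2)
        n_eval[j] = int(valid.sum())
        if n_eval[j]:
            per_joint[j] = float(
                np.mean(dist[valid, j] / L[valid] <= config.thresholds[j]))
    mean = float(np.nanmean(per_joint)) if np.any(n_eval > 0) else float("nan")
    return PCKReport(per_joint=per_joint, mean=mean, n_evaluated=n_eval)


def detection_accuracy(
    predictions: np.ndarray,
    ground_truth: np.ndarray,
    norm_lengths: np.ndarray,
    threshold: float = 0.5,
    config: PCKConfig = PCKConfig(),
) -> float:
    """Pooled fraction of visible joints within ``threshold`` of the
    normalized distance — the per-round scalar tracked during training."""
    dist, vis = _distances(predictions, ground_truth)
    norms = np.asarray(norm_lengths, dtype=np.float64)
    src = config.source_indices()
    L = norms[:, src]                       # (N, K)
    valid = vis & (L > 0)
    if not np.any(valid):
        return float("nan")
    return float(np.mean(dist[valid] / L[valid] <= threshold))


def paired_t_test(series_a: np.ndarray, series_b: np.ndarray) -> TTestResult:
    """Classical paired t-test on per-round metric series.

    t = mean(d) / (sd(d)/√m) on the differences d = a − b with m−1
    degrees of freedom (sd with ddof=1), two-sided p.  Zero-variance
    differences degenerate: all-zero → (t=0, p=1); constant nonzero →
    t = ±inf, p = 0, flagged.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("series must be equal-length 1-D with at least 2 entries")
    d = a - b
    m = d.size
    mean = d.mean()
    sd = d.std(ddof=1)
    df = m - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, df=df, degenerate=False)
        t = float("inf") if mean > 0 else float("-inf")
        return TTestResult(t=t, p=0.0, df=df, degenerate=True)
    t = mean / (sd / np.sqrt(m))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), p=p, df=df)
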