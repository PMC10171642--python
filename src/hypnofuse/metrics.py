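"""Evaluation suite: agreement metrics, calibration, hypnodensity similarity.

Three families of metrics, all epoch-wise over one subject's night:

* **performance** — accuracy, macro/weighted F1, per-class F1 and Cohen's
  kappa of a discrete hypnogram against the consensus hypnogram (computed
  per subject, then averaged across subjects);
* **calibration** — the expected calibration error (ECE): predictions are
  grouped by their max softmax probability into M equally spaced bins
  ((m−1)/M, m/M], and ECE is the bin-count-weighted mean absolute gap
  between per-bin accuracy and per-bin mean confidence;
* **ACS** (averaged cosine similarity) — the per-epoch cosine similarity
  between the predicted stage distribution and the soft-consensus
  distribution of the scorers' votes, averaged over the night.  ACS is 1
  when the model reproduces the scorers' distribution exactly and 0 when
  the two distributions have disjoint support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score

from .annotations import K, MultiScoredRecording
from .consensus import (
    ConsensusHypnogram,
    ScorerReliability,
    SoftConsensusMatrix,
    majority_vote,
    rank_scorers,
)
from .errors import ConfigurationError, DimensionError, UndefinedValueError

__all__ = [
    "PredictionMatrix",
    "CalibrationBin",
    "CalibrationReport",
    "PerformanceReport",
    "ScorerEvaluation",
    "acs",
    "ece",
    "performance",
    "evaluate_scorers",
]


@dataclass(frozen=True)
class PredictionMatrix:
    """Row-stochastic ``(T, K)`` model output with derived labels/confidence."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise DimensionError("predictions must be a (T, K) matrix")
        if (m < 0).any():
            raise ValueError("prediction entries must be nonnegative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            t = int(np.argmax(np.abs(m.sum(axis=1) - 1.0)))
            raise ValueError(f"prediction row {t} does not sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def labels(self) -> np.ndarray:
        """Per-epoch argmax stage indices."""
        return self.matrix.argmax(axis=1)

    @property
    def confidence(self) -> np.ndarray:
        """Per-epoch max predicted probability."""
        return self.matrix.max(axis=1)

    @property
    def n_epochs(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class CalibrationBin:
    interval: tuple[float, float]  # half-open (lo, hi]
    count: int
    accuracy: float  # nan for empty bins
    confidence: float  # nan for empty bins


@dataclass(frozen=True)
class CalibrationReport:
    """ECE with its per-bin breakdown and the overall mean confidence."""

    ece: float
    mean_confidence: float
    bins: tuple[CalibrationBin, ...] = field(repr=False)


@dataclass(frozen=True)
class PerformanceReport:
    """Standard multiclass agreement scores for one subject."""

    accuracy: float
    macro_f1: float
    weighted_f1: float
    cohens_kappa: float
    per_class_f1: tuple[float, ...]


@dataclass(frozen=True)
class ScorerEvaluation:
    """One scorer's performance against the consensus, with reliability."""

    scorer_id: str
    performance: PerformanceReport
    reliability: ScorerReliability
    is_best: bool


def acs(sc: SoftConsensusMatrix | np.ndarray, pred: PredictionMatrix | np.ndarray
        ) -> float:
    """Averaged cosine similarity between soft-consensus and predictions.

    Mean over epochs of ``<s_i, p_i> / (||s_i|| * ||p_i||)``; lies in
    [0, 1] for nonnegative inputs, and equals 1 iff each predicted row is
    proportional to the corresponding soft-consensus row.
    """
    s = sc.matrix if isinstance(sc, SoftConsensusMatrix) else np.asarray(sc, float)
    p = pred.matrix if isinstance(pred, PredictionMatrix) else np.asarray(pred, float)
    if s.shape != p.shape:
        raise DimensionError(f"shape mismatch: {s.shape} vs {p.shape}")
    if s.shape[0] < 1:
        raise DimensionError("need at least one epoch")
    ns = np.linalg.norm(s, axis=1)
    npred = np.linalg.norm(p, axis=1)
    zero = (ns == 0) | (npred == 0)
    if zero.any():
        raise UndefinedValueError(
            f"cosine undefined at epoch {int(np.flatnonzero(zero)[0])}: "
            "zero-norm row"
        )
    return float(((s * p).sum(axis=1) / (ns * npred)).mean())


def _bin_index(conf: np.ndarray, n_bins: int) -> np.ndarray:
    # bins are ((m-1)/M, m/M]; a confidence of exactly 0 goes to bin 0
    idx = np.ceil(conf * n_bins).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def ece(pred: PredictionMatrix, true_labels: np.ndarray,
        n_bins: int = 10) -> CalibrationReport:
    """Expected calibration error with M equally spaced confidence bins.

    Empty bins contribute nothing; ``mean_confidence`` is the average max
    probability over *all* predictions (the "conf." column of a results
    table), independent of the binning.
    """
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    y = np.asarray(true_labels, dtype=int)
    if y.shape != (pred.n_epochs,):
        raise DimensionError(
            f"{pred.n_epochs} predictions but {y.shape[0]} labels"
        )
    conf = pred.confidence
    correct = pred.labels == y
    idx = _bin_index(conf, n_bins)

    bins: list[CalibrationBin] = []
    total = y.shape[0]
    e = 0.0
    for m in range(n_bins):
        in_bin = idx == m
        n_m = int(in_bin.sum())
        lo, hi = m / n_bins, (m + 1) / n_bins
        if n_m == 0:
            bins.append(CalibrationBin((lo, hi), 0, float("nan"), float("nan")))
            continue
        acc_m = float(correct[in_bin].mean())
        conf_m = float(conf[in_bin].mean())
        e += (n_m / total) * abs(acc_m - conf_m)
        bins.append(CalibrationBin((lo, hi), n_m, acc_m, conf_m))
    return CalibrationReport(ece=float(e), mean_confidence=float(conf.mean()),
                             bins=tuple(bins))


def performance(pred_labels: np.ndarray, ref_labels: np.ndarray,
                n_classes: int = K) -> PerformanceReport:
    """Accuracy, macro/weighted/per-class F1 and Cohen's kappa.

    The weighted F1 weights each class by its number of true instances, the
    convention for heavily imbalanced sleep stages.  A class absent from
    both vectors scores F1 = 0 with a warning.
    """
    yp = np.asarray(pred_labels, dtype=int)
    yr = np.asarray(ref_labels, dtype=int)
    if yp.shape != yr.shape or yp.ndim != 1:
        raise DimensionError(
            f"label vectors disagree: {yp.shape} vs {yr.shape}"
        )
    if (yp < 0).any() or (yr < 0).any():
        raise ValueError("labels must be NC-free valid stage indices")
    classes = list(range(n_classes))
    absent = sorted(set(classes) - set(yr) - set(yp))
    if absent:
        warnings.warn(
            f"classes {absent} absent from both vectors; their F1 is 0",
            stacklevel=2,
        )
    per_class = f1_score(yr, yp, labels=classes, average=None, zero_division=0)
    kappa = cohen_kappa_score(yr, yp, labels=classes)
    if np.isnan(kappa):  # constant and identical vectors
        kappa = 1.0 if np.array_equal(yr, yp) else 0.0
    return PerformanceReport(
        accuracy=float(accuracy_score(yr, yp)),
        macro_f1=float(f1_score(yr, yp, labels=classes, average="macro",
                                zero_division=0)),
        weighted_f1=float(f1_score(yr, yp, labels=classes, average="weighted",
                                   zero_division=0)),
        cohens_kappa=float(kappa),
        per_class_f1=tuple(float(v) for v in per_class),
    )


def evaluate_scorers(rec: MultiScoredRecording,
                     consensus: ConsensusHypnogram | None = None
                     ) -> list[ScorerEvaluation]:
    """Score every physician against the majority-vote consensus.

    Each scorer's labels are compared with the consensus hypnogram on the
    epochs where that scorer gave a valid annotation, and paired with their
    Soft-Agreement reliability.  The scorer with the highest Soft-Agreement
    is flagged best.
    """
    if consensus is None:
        consensus = majority_vote(rec)
    ranking = {sr.scorer_id: sr for sr in rank_scorers(rec)}
    best = min(ranking.values(), key=lambda sr: sr.rank).scorer_id
    out = []
    for sid in rec.scorer_ids:
        own = rec.scorer_labels(sid)
        valid = own >= 0
        perf = performance(own[valid], consensus.labels[valid])
        out.append(ScorerEvaluation(
            scorer_id=sid, performance=perf, reliability=ranking[sid],
            is_best=(sid == best),
        ))
    return out
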