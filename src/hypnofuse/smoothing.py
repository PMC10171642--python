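"""Smoothed training targets and the soft-target cross-entropy loss.

Label smoothing replaces the one-hot training target by a convex
combination with a reference distribution q:

    y_smooth = (1 - alpha) * y_onehot + alpha * q

With q = 1/K (uniform smoothing, ``LS_U``) this is the classical recipe
for calibrating over-confident classifiers.  The variant implemented here
for multi-scored data (``LS_SC``) instead uses the per-epoch soft-consensus
— the empirical distribution of the scorers' votes — so the smoothed target
encodes exactly where and how much the scorers disagreed.

The alpha grids follow the standard protocol: uniform smoothing is only
meaningful for alpha in (0, 0.5] (beyond that the uniform term dominates),
while soft-consensus smoothing admits the full (0, 1] range — alpha = 1
trains on the scorers' distribution alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import K as DEFAULT_K
from .consensus import SoftConsensusMatrix
from .errors import ConfigurationError, DimensionError

__all__ = [
    "SmoothingConfig",
    "UNIFORM_ALPHA_GRID",
    "SOFT_CONSENSUS_ALPHA_GRID",
    "one_hot_targets",
    "smooth_uniform",
    "smooth_soft_consensus",
    "cross_entropy",
]

#: Default alpha grids for the grid search, per smoothing mode.
UNIFORM_ALPHA_GRID: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
SOFT_CONSENSUS_ALPHA_GRID: tuple[float, ...] = tuple(
    round(0.1 * i, 1) for i in range(1, 11)
)

_EPS = 1e-12  # clamp for log arguments


@dataclass(frozen=True)
class SmoothingConfig:
    """Which smoothing to apply and with what weight(s).

    ``alpha`` is the single weight used when training one model;
    ``alpha_grid`` is the candidate list for grid search.
    """

    mode: str = "none"  # none | uniform | soft_consensus
    alpha: float = 0.0
    alpha_grid: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.mode not in ("none", "uniform", "soft_consensus"):
            raise ConfigurationError(f"unknown smoothing mode {self.mode!r}")
        if self.mode == "uniform" and not (0.0 < self.alpha <= 0.5):
            raise ConfigurationError(
                f"uniform smoothing requires alpha in (0, 0.5], got {self.alpha}"
            )
        if self.mode == "soft_consensus" and not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(
                f"soft-consensus smoothing requires alpha in (0, 1], "
                f"got {self.alpha}"
            )
        if not self.alpha_grid:
            grid = {"none": (), "uniform": UNIFORM_ALPHA_GRID,
                    "soft_consensus": SOFT_CONSENSUS_ALPHA_GRID}[self.mode]
            object.__setattr__(self, "alpha_grid", grid)


def one_hot_targets(labels: np.ndarray, n_classes: int = DEFAULT_K) -> np.ndarray:
    """``(T, K)`` one-hot matrix from a vector of class indices."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise DimensionError("labels must be a 1-D vector")
    if (labels < 0).any() or (labels >= n_classes).any():
        raise ValueError("labels must be valid class indices")
    out = np.zeros((labels.shape[0], n_classes), dtype=float)
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def _check_one_hot(targets: np.ndarray) -> np.ndarray:
    t = np.asarray(targets, dtype=float)
    if t.ndim != 2:
        raise DimensionError("targets must be a (T, K) matrix")
    if not (np.isin(t, (0.0, 1.0)).all() and (t.sum(axis=1) == 1.0).all()):
        raise ValueError("input target rows must be one-hot")
    return t


def smooth_uniform(one_hot: np.ndarray, alpha: float,
                   n_classes: int | None = None) -> np.ndarray:
    """Uniform label smoothing: ``(1-alpha) * y + alpha / K`` per row."""
    t = _check_one_hot(one_hot)
    k = n_classes if n_classes is not None else t.shape[1]
    if not (0.0 < alpha <= 0.5):
        raise ConfigurationError(
            f"uniform smoothing requires alpha in (0, 0.5], got {alpha}"
        )
    return t * (1.0 - alpha) + alpha / k


def smooth_soft_consensus(one_hot: np.ndarray, sc: SoftConsensusMatrix | np.ndarray,
                          alpha: float) -> np.ndarray:
    """Soft-consensus label smoothing: ``(1-alpha) * y + alpha * sc`` per row.

    ``alpha = 0`` (boundary) returns the one-hot input bit-exactly; values
    used in training lie in (0, 1].
    """
    t = _check_one_hot(one_hot)
    q = sc.matrix if isinstance(sc, SoftConsensusMatrix) else np.asarray(sc, float)
    if q.shape != t.shape:
        raise DimensionError(
            f"soft-consensus shape {q.shape} != target shape {t.shape}"
        )
    if not (0.0 <= alpha <= 1.0):
        raise ConfigurationError(
            f"soft-consensus smoothing requires alpha in [0, 1], got {alpha}"
        )
    if alpha == 0.0:
        return t.copy()
    return t * (1.0 - alpha) + alpha * q


def cross_entropy(target: np.ndarray, predicted: np.ndarray) -> float:
    """Mean (over rows) cross-entropy ``-sum_k target * ln(predicted)``.

    Natural logarithm; predictions are clamped at 1e-12 before the log so a
    hard zero in a predicted row yields a large finite loss rather than inf.
    """
    t = np.asarray(target, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape:
        raise DimensionError(f"target shape {t.shape} != prediction {p.shape}")
    if t.ndim == 1:
        t = t[None, :]
        p = p[None, :]
    return float(-(t * np.log(np.clip(p, _EPS, None))).sum(axis=1).mean())
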