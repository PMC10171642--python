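"""Synthetic multi-scored sleep databases with controllable ground truth.

The generator emulates the structure of a real multi-scored PSG database
without any signal data:

* a **true hypnogram** per subject from a first-order Markov chain over
  the five stages, whose default transition matrix has the DOD-H stage
  marginals (W 12.5%, N1 5.9%, N2 48.7%, N3 14.0%, R 19.0%) as its exact
  stationary distribution;
* **J scorers** with heterogeneous reliabilities: scorer j reproduces the
  true stage with probability r_j and otherwise draws from a
  stage-conditional confusion kernel concentrated on the clinically
  confusable pairs (W-N1, N1-N2, N2-N3, N2-R).  Missing annotations and NC
  epochs can be injected at configurable rates (the IS-RC preset);
* **class-conditional features** per epoch — isotropic Gaussians centred
  on per-stage means — so a classifier can be trained; the mean separation
  versus the noise scale controls the achievable staging accuracy.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotations import K, MISSING, NC, MultiScoredRecording
from .errors import ConfigurationError, SimulationError

__all__ = [
    "DOD_H_MARGINALS",
    "default_transition_matrix",
    "default_confusion_template",
    "SimulationConfig",
    "SyntheticSubject",
    "SyntheticDataset",
    "isrc_config",
    "simulate_hypnogram",
    "simulate_scorers",
    "simulate_features",
    "simulate_dataset",
]

#: Stage marginals of a healthy-adult multi-scored cohort (fractions of
#: epochs in W, N1, N2, N3, R) used as the default stationary distribution.
DOD_H_MARGINALS: np.ndarray = np.array([0.125, 0.059, 0.487, 0.140, 0.190])
DOD_H_MARGINALS = DOD_H_MARGINALS / DOD_H_MARGINALS.sum()


def default_transition_matrix(stationary: np.ndarray | None = None,
                              switch_rate: float = 0.08) -> np.ndarray:
    """Sticky Markov kernel ``(1 - b) I + b 1 pi^T`` with stationary ``pi``.

    Each epoch the chain stays put with probability 1−b and otherwise
    redraws the stage from ``pi``, giving geometric bout lengths with mean
    1/b epochs (b = 0.08: mean bout ≈ 6 min) and *exactly* ``pi`` as the
    stationary distribution.
    """
    pi = DOD_H_MARGINALS if stationary is None else np.asarray(stationary, float)
    if not (0.0 < switch_rate <= 1.0):
        raise ConfigurationError("switch_rate must be in (0, 1]")
    P = (1.0 - switch_rate) * np.eye(K) + switch_rate * np.tile(pi, (K, 1))
    return P


def default_confusion_template() -> np.ndarray:
    """Stage-conditional error kernel (rows: true stage; zero diagonal).

    Mass concentrates on the adjacent/confusable stages reported to drive
    human inter-scorer disagreement: drowsy wake vs N1, the N1/N2 boundary,
    N2/N3 depth, and N2/R.
    """
    #              W     N1    N2    N3    R
    T = np.array([
        [0.00, 0.70, 0.15, 0.05, 0.10],   # true W
        [0.35, 0.00, 0.45, 0.05, 0.15],   # true N1
        [0.15, 0.30, 0.00, 0.35, 0.20],   # true N2
        [0.07, 0.10, 0.80, 0.00, 0.03],   # true N3
        [0.25, 0.35, 0.35, 0.05, 0.00],   # true R
    ])
    return T


def _default_class_means(dim: int, separation: float) -> np.ndarray:
    means = np.zeros((K, dim))
    for k in range(K):
        means[k, k % dim] = separation
    # when dim < K two classes share an axis; flip the repeat so means differ
    for k in range(dim, K):
        means[k] = -means[k]
    return means


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic multi-scored database.

    Defaults are a DOD-style cohort: 40 subjects of 960 epochs (8 h) each,
    five scorers with reliabilities spanning 0.60-0.90, no missing or NC
    annotations, and 5-dimensional Gaussian features with unit noise and
    mean separation 2.0 (staging accuracy of a good classifier in the
    high-70s %, the realistic range).
    """

    n_subjects: int = 40
    epochs_per_subject: int = 960
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    initial_distribution: np.ndarray = field(
        default_factory=lambda: DOD_H_MARGINALS.copy())
    n_scorers: int = 5
    scorer_reliabilities: tuple[float, ...] = (0.60, 0.675, 0.75, 0.825, 0.90)
    confusion_template: np.ndarray = field(
        default_factory=default_confusion_template)
    missing_rate: float = 0.0
    nc_rate: float = 0.0
    feature_dim: int = 5
    class_means: np.ndarray | None = None
    feature_sd: float = 1.0
    mean_separation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (K, K) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9) \
                or (P < 0).any():
            raise ConfigurationError("transition_matrix must be KxK row-stochastic")
        object.__setattr__(self, "transition_matrix", P)
        pi0 = np.asarray(self.initial_distribution, dtype=float)
        if pi0.shape != (K,) or not np.isclose(pi0.sum(), 1.0) or (pi0 < 0).any():
            raise ConfigurationError("initial_distribution must be a length-K pmf")
        object.__setattr__(self, "initial_distribution", pi0)
        r = tuple(float(v) for v in self.scorer_reliabilities)
        if len(r) != self.n_scorers:
            raise ConfigurationError(
                f"{len(r)} reliabilities for {self.n_scorers} scorers"
            )
        if any(not (0.0 <= v <= 1.0) for v in r):
            raise ConfigurationError("reliabilities must lie in [0, 1]")
        object.__setattr__(self, "scorer_reliabilities", r)
        C = np.asarray(self.confusion_template, dtype=float)
        if C.shape != (K, K) or not np.allclose(C.sum(axis=1), 1.0, atol=1e-9) \
                or (C < 0).any():
            raise ConfigurationError("confusion_template must be KxK row-stochastic")
        object.__setattr__(self, "confusion_template", C)
        if not (0.0 <= self.missing_rate < 1.0 and 0.0 <= self.nc_rate < 1.0):
            raise ConfigurationError("missing_rate and nc_rate must be in [0, 1)")
        if self.class_means is None:
            object.__setattr__(
                self, "class_means",
                _default_class_means(self.feature_dim, self.mean_separation))
        else:
            M = np.asarray(self.class_means, dtype=float)
            if M.shape != (K, self.feature_dim):
                raise ConfigurationError(
                    f"class_means must be ({K}, {self.feature_dim})"
                )
            object.__setattr__(self, "class_means", M)
        if self.feature_sd <= 0:
            raise ConfigurationError("feature_sd must be positive")
        if self.n_subjects < 1 or self.epochs_per_subject < 1:
            raise ConfigurationError("need >= 1 subject and >= 1 epoch")

    @property
    def scorer_ids(self) -> tuple[str, ...]:
        return tuple(f"S{j + 1}" for j in range(self.n_scorers))


def isrc_config(**overrides) -> SimulationConfig:
    """IS-RC-style preset: six scorers, wider reliability spread, partial
    annotations (missing and NC epochs) as in the inter-scorer reliability
    cohort."""
    base = dict(
        n_scorers=6,
        scorer_reliabilities=(0.50, 0.55, 0.65, 0.75, 0.85, 0.92),
        missing_rate=0.05,
        nc_rate=0.02,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    truth: np.ndarray  # length-T true stage indices
    recording: MultiScoredRecording
    features: np.ndarray  # (T, feature_dim)


@dataclass(frozen=True)
class SyntheticDataset:
    subjects: tuple[SyntheticSubject, ...]
    config: SimulationConfig
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def simulate_hypnogram(config: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Sample one night's true stage sequence from the Markov chain."""
    T = config.epochs_per_subject
    P_cum = np.cumsum(config.transition_matrix, axis=1)
    out = np.empty(T, dtype=np.int8)
    out[0] = rng.choice(K, p=config.initial_distribution)
    u = rng.random(T)
    for t in range(1, T):
        out[t] = np.searchsorted(P_cum[out[t - 1]], u[t], side="left")
    return out


def simulate_scorers(truth: np.ndarray, config: SimulationConfig,
                     rng: np.random.Generator) -> MultiScoredRecording:
    """Corrupt the true hypnogram into J scorers' annotations.

    Scorer j keeps the true stage with probability r_j and otherwise draws
    a wrong stage from the confusion row of the true stage.  Missing and NC
    markers are injected i.i.d. afterwards; if that leaves any epoch with
    zero valid annotations the draw is rejected with an error (lower the
    rates or the number of epochs).
    """
    truth = np.asarray(truth)
    T = truth.shape[0]
    J = config.n_scorers
    labels = np.empty((T, J), dtype=np.int8)
    C_cum = np.cumsum(config.confusion_template, axis=1)
    for j, r in enumerate(config.scorer_reliabilities):
        col = truth.astype(np.int8).copy()
        err = rng.random(T) >= r
        n_err = int(err.sum())
        if n_err:
            u = rng.random(n_err)
            rows = C_cum[truth[err]]
            col[err] = np.array(
                [np.searchsorted(rows[i], u[i], side="left")
                 for i in range(n_err)], dtype=np.int8)
        labels[:, j] = col
    if config.missing_rate > 0 or config.nc_rate > 0:
        u = rng.random((T, J))
        labels[u < config.missing_rate] = MISSING
        both = config.missing_rate + config.nc_rate
        labels[(u >= config.missing_rate) & (u < both)] = NC
        if not (labels >= 0).any(axis=1).all():
            raise SimulationError(
                "missing/NC rates left at least one epoch with no valid "
                "annotation; lower the rates"
            )
    return MultiScoredRecording(recording_id="synthetic",
                                scorer_ids=config.scorer_ids, labels=labels)


def simulate_features(truth: np.ndarray, config: SimulationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-epoch Gaussian feature vectors centred on the true stage's mean."""
    truth = np.asarray(truth)
    means = config.class_means[truth]
    return means + config.feature_sd * rng.standard_normal(
        (truth.shape[0], config.feature_dim))


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate the full cohort; bit-reproducible from (config, seed)."""
    seed = config.seed if seed is None else int(seed)
    root = np.random.SeedSequence(seed)
    subjects = []
    for i, child in enumerate(root.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        truth = simulate_hypnogram(config, rng)
        rec = simulate_scorers(truth, config, rng)
        rec = replace(rec, recording_id=f"subj{i + 1:03d}")
        feats = simulate_features(truth, config, rng)
        subjects.append(SyntheticSubject(
            subject_id=f"subj{i + 1:03d}", truth=truth, recording=rec,
            features=feats))
    return SyntheticDataset(subjects=tuple(subjects), config=config, seed=seed)
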