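"""Reference classifier and the base / LS_U / LS_SC experiment protocol.

The point under test in this package is how training *targets* are built
from a group of scorers, not any particular network architecture; target
construction is architecture-agnostic.  The reference model is therefore a
small feed-forward softmax classifier (NumPy, Adam, dropout, soft-target
cross-entropy) operating on per-epoch feature vectors.

:func:`run_experiment` reproduces the three-arm protocol on a synthetic
cohort: subject-level k-fold cross-validation with held-out validation and
test subjects; for each smoothing mode a grid search over the smoothing
weight alpha on validation weighted F1; the winning model of each arm is
then evaluated on the pooled test predictions per subject — performance
against the majority-vote consensus, ECE and mean confidence, and ACS
against the soft-consensus.  Monte-Carlo dropout averaging of several
stochastic forward passes is available at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon
from sklearn.metrics import f1_score

from .annotations import K, filter_nc_epochs
from .consensus import majority_vote, soft_consensus
from .errors import ConfigurationError, TrainingError
from .metrics import (
    CalibrationReport,
    PerformanceReport,
    PredictionMatrix,
    acs,
    ece,
    performance,
)
from .smoothing import (
    SOFT_CONSENSUS_ALPHA_GRID,
    UNIFORM_ALPHA_GRID,
    SmoothingConfig,
    cross_entropy,
    one_hot_targets,
    smooth_soft_consensus,
    smooth_uniform,
)
from .synthetic import SyntheticDataset

__all__ = [
    "TrainConfig",
    "SoftmaxClassifier",
    "train_classifier",
    "predict",
    "ExperimentResult",
    "ModelResult",
    "SubjectEvaluation",
    "run_experiment",
]

MODES = ("base", "ls_uniform", "ls_soft_consensus")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for the reference classifier and the experiment.

    Defaults are sized for a synthetic desk-scale cohort: a single hidden
    layer of 32 units trains in seconds per fold while leaving enough
    capacity for five Gaussian classes.
    """

    hidden_sizes: tuple[int, ...] = (32,)
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_iterations: int = 30
    patience: int = 5
    beta1: float = 0.9
    beta2: float = 0.999
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    folds: int = 4
    val_fraction: float = 0.2
    mc_passes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if not (0 <= self.patience < self.max_iterations):
            raise ConfigurationError("need 0 <= patience < max_iterations")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ConfigurationError("bad optimiser settings")


class SoftmaxClassifier:
    """Feed-forward ReLU network with a K-way softmax head.

    Dropout (inverted) is applied to every hidden layer during training and
    during Monte-Carlo forward passes; deterministic prediction runs with
    dropout off (the masks' expectation).
    """

    def __init__(self, n_features: int, hidden_sizes: tuple[int, ...],
                 dropout_rate: float, rng: np.random.Generator,
                 n_classes: int = K):
        dims = (n_features, *hidden_sizes, n_classes)
        self.dropout_rate = float(dropout_rate)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
            self.weights.append(scale * rng.standard_normal((fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- forward --------------------------------------------------------
    def _forward(self, X: np.ndarray, drop_rng: np.random.Generator | None):
        """Return (activations per layer, softmax probabilities)."""
        acts = [X]
        h = X
        n_hidden = len(self.weights) - 1
        masks: list[np.ndarray | None] = []
        for ell in range(n_hidden):
            h = h @ self.weights[ell] + self.biases[ell]
            np.maximum(h, 0.0, out=h)
            if drop_rng is not None and self.dropout_rate > 0.0:
                keep = 1.0 - self.dropout_rate
                mask = (drop_rng.random(h.shape) < keep) / keep
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return acts, masks, p

    def predict_proba(self, X: np.ndarray,
                      drop_rng: np.random.Generator | None = None) -> np.ndarray:
        """Row-stochastic class probabilities; stochastic iff a rng is given."""
        return self._forward(np.asarray(X, float), drop_rng)[2]

    # -- parameter plumbing --------------------------------------------
    def get_params(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights] + [b.copy() for b in self.biases]

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [p.copy() for p in params[:n]]
        self.biases = [p.copy() for p in params[n:]]


def train_classifier(features: np.ndarray, targets: np.ndarray,
                     val_features: np.ndarray, val_labels: np.ndarray,
                     config: TrainConfig,
                     seed: int | None = None) -> tuple[SoftmaxClassifier, dict]:
    """Train on soft (row-stochastic) targets with Adam and early stopping.

    Validation weighted F1 is evaluated once per pass over the data; when
    it has not improved for ``patience`` evaluations, training stops and
    the parameters of the best-validation-F1 checkpoint are restored.
    Returns the model and a trace with per-epoch train loss and val F1.
    """
    X = np.asarray(features, float)
    Y = np.asarray(targets, float)
    if X.shape[0] != Y.shape[0]:
        raise ConfigurationError("features and targets disagree in length")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    model = SoftmaxClassifier(X.shape[1], config.hidden_sizes,
                              config.dropout_rate, rng, n_classes=Y.shape[1])

    params = model.weights + model.biases
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    step = 0
    lr, b1, b2, eps = config.learning_rate, config.beta1, config.beta2, 1e-8

    best_f1 = -np.inf
    best_params = model.get_params()
    best_epoch = -1
    stall = 0
    trace: dict = {"train_loss": [], "val_f1": []}

    n = X.shape[0]
    for epoch in range(config.max_iterations):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            acts, masks, p = model._forward(xb, rng)
            loss = cross_entropy(yb, p)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, step {step}"
                )
            epoch_loss += loss * len(idx)
            # backprop: d(mean CE)/dlogits = (p - y) / B
            delta = (p - yb) / len(idx)
            grads_w: list[np.ndarray] = [None] * len(model.weights)
            grads_b: list[np.ndarray] = [None] * len(model.biases)
            for ell in range(len(model.weights) - 1, -1, -1):
                grads_w[ell] = acts[ell].T @ delta
                grads_b[ell] = delta.sum(axis=0)
                if ell > 0:
                    delta = delta @ model.weights[ell].T
                    if masks[ell - 1] is not None:
                        delta *= masks[ell - 1]
                    delta[acts[ell] <= 0.0] = 0.0
            step += 1
            grads = grads_w + grads_b
            params = model.weights + model.biases
            for i, (p_i, g) in enumerate(zip(params, grads)):
                m_t[i] = b1 * m_t[i] + (1 - b1) * g
                v_t[i] = b2 * v_t[i] + (1 - b2) * g * g
                mhat = m_t[i] / (1 - b1 ** step)
                vhat = v_t[i] / (1 - b2 ** step)
                p_i -= lr * mhat / (np.sqrt(vhat) + eps)
        trace["train_loss"].append(epoch_loss / n)

        val_pred = model.predict_proba(val_features).argmax(axis=1)
        f1 = f1_score(val_labels, val_pred, average="weighted", zero_division=0)
        trace["val_f1"].append(float(f1))
        if f1 > best_f1:
            best_f1, best_epoch, stall = f1, epoch, 0
            best_params = model.get_params()
        else:
            stall += 1
            if stall > config.patience:
                break
    model.set_params(best_params)
    trace["best_epoch"] = best_epoch
    trace["best_val_f1"] = float(best_f1)
    return model, trace


def predict(model: SoftmaxClassifier, features: np.ndarray,
            mc_passes: int = 0,
            rng: np.random.Generator | None = None) -> PredictionMatrix:
    """Predict stage probabilities, optionally MC-dropout averaged.

    ``mc_passes = 0``: one deterministic pass (dropout off).  ``mc_passes
    = S > 0``: average of S stochastic passes with dropout active; rows are
    renormalised (exact up to float round-off already).
    """
    X = np.asarray(features, float)
    if mc_passes <= 0:
        p = model.predict_proba(X)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        p = np.zeros((X.shape[0], model.weights[-1].shape[1]))
        for _ in range(mc_passes):
            p += model.predict_proba(X, drop_rng=rng)
        p /= mc_passes
    p = p / p.sum(axis=1, keepdims=True)
    return PredictionMatrix(matrix=p)


# ---------------------------------------------------------------------------
# Experiment protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectEvaluation:
    subject_id: str
    performance: PerformanceReport
    calibration: CalibrationReport
    acs: float


@dataclass(frozen=True)
class ModelResult:
    """One experimental arm: chosen alpha, per-subject metrics, predictions."""

    mode: str
    alpha: float | None
    per_subject: dict[str, SubjectEvaluation]
    predictions: dict[str, PredictionMatrix]
    aggregate: dict[str, float]
    alpha_validation_f1: dict[float | None, float]


@dataclass(frozen=True)
class ExperimentResult:
    models: dict[str, ModelResult]
    fold_assignment: dict[str, int]
    reference_labels: dict[str, np.ndarray]
    reference_soft_consensus: dict[str, np.ndarray]
    acs_comparisons: dict[str, float]
    seed: int


def _aggregate(evals: dict[str, SubjectEvaluation]) -> dict[str, float]:
    arr = lambda f: np.array([f(e) for e in evals.values()])
    agg = {
        "accuracy": arr(lambda e: e.performance.accuracy).mean(),
        "macro_f1": arr(lambda e: e.performance.macro_f1).mean(),
        "weighted_f1": arr(lambda e: e.performance.weighted_f1).mean(),
        "cohens_kappa": arr(lambda e: e.performance.cohens_kappa).mean(),
        "ece": arr(lambda e: e.calibration.ece).mean(),
        "mean_confidence": arr(lambda e: e.calibration.mean_confidence).mean(),
        "acs_mean": arr(lambda e: e.acs).mean(),
        "acs_sd": arr(lambda e: e.acs).std(ddof=1) if len(evals) > 1 else 0.0,
    }
    return {k: float(v) for k, v in agg.items()}


def _mode_grid(mode: str, config: TrainConfig) -> list[float | None]:
    if mode == "base":
        return [None]
    if mode == "ls_uniform":
        grid = config.smoothing.alpha_grid if config.smoothing.mode == "uniform" \
            else UNIFORM_ALPHA_GRID
        return list(grid)
    grid = config.smoothing.alpha_grid \
        if config.smoothing.mode == "soft_consensus" else SOFT_CONSENSUS_ALPHA_GRID
    return list(grid)


def _targets_for(mode: str, alpha: float | None, labels: np.ndarray,
                 sc_rows: np.ndarray) -> np.ndarray:
    oh = one_hot_targets(labels)
    if mode == "base":
        return oh
    if mode == "ls_uniform":
        return smooth_uniform(oh, alpha)
    return smooth_soft_consensus(oh, sc_rows, alpha)


def run_experiment(dataset: SyntheticDataset,
                   config: TrainConfig) -> ExperimentResult:
    """Run the three-arm smoothing experiment with subject-level k-fold CV.

    Every subject appears in exactly one test fold; within a fold the
    non-test subjects are split into held-out validation subjects (a
    ``val_fraction`` share, rotating with the fold index) and training
    subjects.  For each arm the smoothing weight alpha is chosen to
    maximise mean validation weighted F1 across folds; the chosen arm's
    pooled test predictions are then scored per subject.
    """
    n = dataset.n_subjects
    if n < config.folds:
        raise ConfigurationError(
            f"{n} subjects cannot populate {config.folds} folds"
        )

    # consensus references, epoch-aligned features
    ids, feats, cons_labels, sc_rows = [], {}, {}, {}
    fold_of: dict[str, int] = {}
    for i, subj in enumerate(dataset.subjects):
        rec, removed = filter_nc_epochs(subj.recording)
        keep = np.setdiff1d(np.arange(subj.recording.n_epochs), removed)
        ids.append(subj.subject_id)
        feats[subj.subject_id] = subj.features[keep]
        cons_labels[subj.subject_id] = majority_vote(rec).labels
        sc_rows[subj.subject_id] = soft_consensus(rec).matrix
        fold_of[subj.subject_id] = i % config.folds

    models: dict[str, ModelResult] = {}
    root_seed = np.random.SeedSequence(config.seed)

    for mode_idx, mode in enumerate(MODES):
        grid = _mode_grid(mode, config)
        val_f1: dict[float | None, list[float]] = {a: [] for a in grid}
        test_preds: dict[float | None, dict[str, PredictionMatrix]] = {
            a: {} for a in grid}

        for f in range(config.folds):
            test_ids = [s for s in ids if fold_of[s] == f]
            rest = [s for s in ids if fold_of[s] != f]
            n_val = max(1, round(config.val_fraction * len(rest)))
            val_ids = [rest[(f * n_val + t) % len(rest)] for t in range(n_val)]
            val_ids = list(dict.fromkeys(val_ids))
            train_ids = [s for s in rest if s not in val_ids]

            Xtr = np.concatenate([feats[s] for s in train_ids])
            ytr = np.concatenate([cons_labels[s] for s in train_ids])
            sctr = np.concatenate([sc_rows[s] for s in train_ids])
            Xval = np.concatenate([feats[s] for s in val_ids])
            yval = np.concatenate([cons_labels[s] for s in val_ids])

            for a_idx, alpha in enumerate(grid):
                seed = np.random.SeedSequence(
                    [config.seed, mode_idx, f, a_idx]).generate_state(1)[0]
                targets = _targets_for(mode, alpha, ytr, sctr)
                model, trace = train_classifier(
                    Xtr, targets, Xval, yval, config, seed=int(seed) % (2**31))
                val_f1[alpha].append(trace["best_val_f1"])
                mc_rng = np.random.default_rng(int(seed) % (2**31) + 1)
                for s in test_ids:
                    test_preds[alpha][s] = predict(
                        model, feats[s], mc_passes=config.mc_passes, rng=mc_rng)

        mean_f1 = {a: float(np.mean(v)) for a, v in val_f1.items()}
        best_alpha = max(grid, key=lambda a: mean_f1[a])
        preds = test_preds[best_alpha]
        evals = {
            s: SubjectEvaluation(
                subject_id=s,
                performance=performance(preds[s].labels, cons_labels[s]),
                calibration=ece(preds[s], cons_labels[s]),
                acs=acs(sc_rows[s], preds[s]),
            )
            for s in ids
        }
        models[mode] = ModelResult(
            mode=mode, alpha=best_alpha, per_subject=evals, predictions=preds,
            aggregate=_aggregate(evals), alpha_validation_f1=mean_f1,
        )

    comparisons: dict[str, float] = {}
    base_acs = np.array([models["base"].per_subject[s].acs for s in ids])
    for other in ("ls_uniform", "ls_soft_consensus"):
        other_acs = np.array([models[other].per_subject[s].acs for s in ids])
        if np.allclose(other_acs, base_acs):
            comparisons[f"{other}_vs_base_p"] = 1.0
        else:
            comparisons[f"{other}_vs_base_p"] = float(
                wilcoxon(other_acs, base_acs).pvalue)

    return ExperimentResult(
        models=models, fold_assignment=fold_of,
        reference_labels=cons_labels, reference_soft_consensus=sc_rows,
        acs_comparisons=comparisons, seed=config.seed,
    )
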