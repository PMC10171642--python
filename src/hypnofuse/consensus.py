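"""Scorer-reliability ranking and consensus construction.

Three related objects are derived from a multi-scored recording:

* the **leave-one-out probabilistic consensus** ``z^j`` — for each scorer
  *j* and epoch *t*, the per-stage vote counts of the other J−1 scorers
  divided by the maximum count, so the majority stage (and every stage tied
  with it) scores exactly 1;
* the **Soft-Agreement** of scorer *j* — the mean of ``z^j`` evaluated at
  *j*'s own labels, a reliability score in [0, 1] (1: always in the
  majority or a tie; 0: never agrees with any majority/tied stage);
* the **soft-consensus** — the per-epoch empirical distribution of the
  valid scorer votes (occurrences over observations), which doubles as the
  hypnodensity ground truth and as the smoothing distribution for training
  targets.

NC and missing annotations are excluded from every count; the number of
observations M therefore varies per epoch in partially annotated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import K, MultiScoredRecording
from .errors import ConfigurationError, UndefinedValueError

__all__ = [
    "ProbabilisticConsensus",
    "ScorerReliability",
    "SoftConsensusMatrix",
    "ConsensusHypnogram",
    "vote_counts",
    "probabilistic_consensus",
    "soft_agreement",
    "rank_scorers",
    "soft_consensus",
    "majority_vote",
]


@dataclass(frozen=True)
class ProbabilisticConsensus:
    """Leave-one-out consensus ``z^j``: ``(K, T)``, column max 1 where valid."""

    matrix: np.ndarray
    excluded_scorer: str
    valid_mask: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ScorerReliability:
    """Per-recording Soft-Agreement and rank (1 = most reliable)."""

    scorer_id: str
    soft_agreement: float
    rank: int


@dataclass(frozen=True)
class SoftConsensusMatrix:
    """Per-epoch empirical scorer-vote distribution, ``(T, K)`` row-stochastic.

    ``observation_count[t]`` is M, the number of valid annotations at epoch
    t (the denominator); every entry of row t is a multiple of 1/M.
    """

    matrix: np.ndarray
    observation_count: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        c = np.asarray(self.observation_count, dtype=int)
        if m.ndim != 2 or m.shape[0] != c.shape[0]:
            raise ValueError("matrix rows must match observation_count length")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("soft-consensus rows must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "observation_count", c)

    @property
    def n_epochs(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ConsensusHypnogram:
    """Majority-vote stage sequence with tie bookkeeping."""

    labels: np.ndarray
    tie_flags: np.ndarray
    tiebreak_scorer: str


def vote_counts(rec: MultiScoredRecording) -> np.ndarray:
    """``(T, K)`` matrix of valid votes per stage per epoch."""
    T = rec.n_epochs
    counts = np.zeros((T, K), dtype=np.int64)
    labels = rec.labels
    for k in range(K):
        counts[:, k] = (labels == k).sum(axis=1)
    return counts


def probabilistic_consensus(
    rec: MultiScoredRecording, excluded: str
) -> ProbabilisticConsensus:
    """Leave-one-out consensus over the J−1 scorers other than ``excluded``.

    For each epoch the valid votes of the remaining scorers are counted per
    stage and divided by the maximum count, so 1 is assigned to the majority
    stage and to every stage tied with it.  Epochs where no remaining scorer
    gave a valid label are masked invalid (all-zero column).
    """
    if rec.n_scorers < 2:
        raise ConfigurationError("leave-one-out consensus needs J >= 2")
    j = rec.scorer_index(excluded)
    others = np.delete(rec.labels, j, axis=1)
    counts = np.zeros((rec.n_epochs, K), dtype=float)
    for k in range(K):
        counts[:, k] = (others == k).sum(axis=1)
    maxc = counts.max(axis=1)
    valid = maxc > 0
    z = np.zeros_like(counts)
    z[valid] = counts[valid] / maxc[valid, None]
    return ProbabilisticConsensus(matrix=z.T, excluded_scorer=excluded,
                                  valid_mask=valid)


def soft_agreement(rec: MultiScoredRecording, scorer: str) -> float:
    """Soft-Agreement of one scorer against the leave-one-out consensus.

    The mean, over contributing epochs, of ``z^j`` evaluated at scorer j's
    own label.  An epoch contributes only if scorer j gave a valid label
    there *and* the remaining scorers produced a valid consensus column;
    the divisor is the number of contributing epochs.
    """
    j = rec.scorer_index(scorer)
    own = rec.labels[:, j]
    pc = probabilistic_consensus(rec, scorer)
    contributing = (own >= 0) & pc.valid_mask
    if not contributing.any():
        raise UndefinedValueError(
            f"Soft-Agreement undefined for scorer {scorer!r}: no epoch has "
            "both a valid label from this scorer and valid co-scorer votes"
        )
    t_idx = np.flatnonzero(contributing)
    return float(pc.matrix[own[t_idx], t_idx].mean())


def rank_scorers(rec: MultiScoredRecording) -> list[ScorerReliability]:
    """Rank scorers by Soft-Agreement, descending; rank 1 = most reliable.

    Ties in score are broken by input scorer order (stable sort), making
    the ranking deterministic.
    """
    scores = [soft_agreement(rec, s) for s in rec.scorer_ids]
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    out = [
        ScorerReliability(scorer_id=rec.scorer_ids[i],
                          soft_agreement=scores[i], rank=r + 1)
        for r, i in enumerate(order)
    ]
    # report in input scorer order
    out.sort(key=lambda sr: rec.scorer_ids.index(sr.scorer_id))
    return out


def soft_consensus(rec: MultiScoredRecording) -> SoftConsensusMatrix:
    """Empirical vote distribution per epoch: occurrences over observations.

    Requires every epoch to have at least one valid annotation (filter
    all-NC epochs first).
    """
    counts = vote_counts(rec)
    M = counts.sum(axis=1)
    if (M == 0).any():
        t = int(np.flatnonzero(M == 0)[0])
        raise UndefinedValueError(
            f"epoch {t} has no valid annotation; run filter_nc_epochs first"
        )
    return SoftConsensusMatrix(matrix=counts / M[:, None], observation_count=M)


def majority_vote(rec: MultiScoredRecording) -> ConsensusHypnogram:
    """Per-epoch most-voted stage, ties resolved by the most reliable scorer.

    The consensus label is the argmax of the soft-consensus row.  Where two
    or more stages tie at the maximum, the label of the highest-ranked
    (Soft-Agreement) scorer whose own label is one of the tied stages is
    taken; the ranking is descended until such a scorer is found (one always
    exists, since each tied stage received at least one vote).
    """
    sc = soft_consensus(rec)
    ranking = sorted(rank_scorers(rec), key=lambda sr: sr.rank)
    rank_cols = [rec.scorer_index(sr.scorer_id) for sr in ranking]

    rowmax = sc.matrix.max(axis=1)
    is_max = np.isclose(sc.matrix, rowmax[:, None], rtol=0.0, atol=1e-12)
    tie_flags = is_max.sum(axis=1) > 1
    labels = sc.matrix.argmax(axis=1).astype(np.int8)
    for t in np.flatnonzero(tie_flags):
        for col in rank_cols:
            lab = rec.labels[t, col]
            if lab >= 0 and is_max[t, lab]:
                labels[t] = lab
                break
    return ConsensusHypnogram(labels=labels, tie_flags=tie_flags,
                              tiebreak_scorer=ranking[0].scorer_id)
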