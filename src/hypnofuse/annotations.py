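"""Domain types and I/O for multi-scorer sleep-stage annotations.

Sleep is scored in 30-s epochs, each assigned one of the five AASM stages
W (wake), N1, N2, N3 (non-REM depths) and R (REM).  In multi-scored
databases each epoch carries one label per scorer, and two sentinel values
appear in real data: ``NC`` ("not classified" — the scorer looked at the
epoch but declined to stage it) and ``-`` (no annotation at all).  Both
sentinels simply reduce the number of valid observations for that epoch;
no downstream computation distinguishes them.

The stage-index convention is fixed package-wide:
W = 0, N1 = 1, N2 = 2, N3 = 3, R = 4.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AnnotationParseError, DimensionError

logger = logging.getLogger(__name__)

#: The five scoreable AASM stages, in the fixed index order.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: Number of scoreable classes.
K: int = len(STAGES)

#: Sentinel codes (never valid class indices).
NC: int = -1
MISSING: int = -2

#: Token used on disk for a missing annotation.
MISSING_TOKEN = "-"

_TOKEN_TO_CODE: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
_TOKEN_TO_CODE["NC"] = NC
_TOKEN_TO_CODE[MISSING_TOKEN] = MISSING

_CODE_TO_TOKEN: dict[int, str] = {i: s for i, s in enumerate(STAGES)}
_CODE_TO_TOKEN[NC] = "NC"
_CODE_TO_TOKEN[MISSING] = MISSING_TOKEN


def stage_to_index(token: str) -> int:
    """Map a stage token (``W``, ``N1``, ..., ``NC``, ``-``) to its code."""
    try:
        return _TOKEN_TO_CODE[token.strip()]
    except KeyError:
        raise AnnotationParseError(f"unknown stage token {token!r}") from None


def index_to_stage(code: int) -> str:
    """Inverse of :func:`stage_to_index`."""
    try:
        return _CODE_TO_TOKEN[int(code)]
    except KeyError:
        raise ValueError(f"unknown stage code {code!r}") from None


def encode_labels(tokens) -> np.ndarray:
    """Encode an iterable (or nested iterable) of stage tokens as int8 codes."""
    arr = np.asarray(tokens)
    out = np.empty(arr.shape, dtype=np.int8)
    for idx, tok in np.ndenumerate(arr):
        out[idx] = stage_to_index(str(tok))
    return out


def decode_labels(codes: np.ndarray) -> np.ndarray:
    """Decode int8 stage codes back to tokens (object array of str)."""
    arr = np.asarray(codes)
    out = np.empty(arr.shape, dtype=object)
    for idx, c in np.ndenumerate(arr):
        out[idx] = index_to_stage(int(c))
    return out


@dataclass(frozen=True)
class MultiScoredRecording:
    """A whole-night recording annotated epoch-by-epoch by several scorers.

    Parameters
    ----------
    recording_id:
        Free-form identifier.
    scorer_ids:
        Ordered scorer names; the order is meaningful (it breaks ties in
        reliability ranking deterministically).
    labels:
        ``(T, J)`` int8 matrix of stage codes, ``NC`` or ``MISSING``.
    epoch_duration_s:
        Length of one epoch in seconds; carried for display, never used in
        any epoch-wise computation.
    """

    recording_id: str
    scorer_ids: tuple[str, ...]
    labels: np.ndarray
    epoch_duration_s: float = 30.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 2:
            raise DimensionError("labels must be a (T, J) matrix")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "scorer_ids", tuple(self.scorer_ids))
        T, J = labels.shape
        if J != len(self.scorer_ids):
            raise DimensionError(
                f"{len(self.scorer_ids)} scorer ids but {J} label columns"
            )
        if J < 2:
            raise ValueError("a multi-scored recording needs J >= 2 scorers")
        # T == 0 is tolerated so that filtering an all-NC recording can
        # return an (explicitly warned-about) empty result.
        if len(set(self.scorer_ids)) != J:
            raise ValueError("scorer ids must be unique")
        bad = (labels < MISSING) | (labels >= K)
        if bad.any():
            t, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid stage code at epoch {t}, scorer column {j}")
        if self.epoch_duration_s <= 0:
            raise ValueError("epoch_duration_s must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def n_scorers(self) -> int:
        return self.labels.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean ``(T, J)`` mask of cells holding a real stage label."""
        return self.labels >= 0

    def scorer_index(self, scorer_id: str) -> int:
        try:
            return self.scorer_ids.index(scorer_id)
        except ValueError:
            raise KeyError(
                f"unknown scorer {scorer_id!r}; known: {list(self.scorer_ids)}"
            ) from None

    def scorer_labels(self, scorer_id: str) -> np.ndarray:
        """The length-T label vector of one scorer (codes, incl. sentinels)."""
        return self.labels[:, self.scorer_index(scorer_id)].copy()


@dataclass(frozen=True)
class OneHotAnnotations:
    """One scorer's annotations as a ``(K, T)`` one-hot matrix.

    Columns where the scorer gave NC or no annotation are all-zero and
    flagged invalid in :attr:`valid`.
    """

    matrix: np.ndarray
    valid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if m.ndim != 2 or m.shape[0] != K:
            raise DimensionError(f"matrix must be (K={K}, T)")
        if v.shape != (m.shape[1],):
            raise DimensionError("validity mask length must equal T")
        sums = m.sum(axis=0)
        if not np.array_equal(sums, v.astype(float)):
            raise ValueError("column sums must equal the validity mask")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "valid", v)


def filter_nc_epochs(
    rec: MultiScoredRecording,
) -> tuple[MultiScoredRecording, list[int]]:
    """Drop epochs in which *no* scorer gave a real stage label.

    Epochs classified by every scorer as NC (or left unannotated) carry no
    label information and are removed; epochs with at least one valid
    annotation are kept unchanged.  Returns the filtered recording and the
    removed epoch indices in the original 0-based coordinates.

    Idempotent: running it twice removes nothing on the second pass.
    """
    keep = rec.valid_mask.any(axis=1)
    removed = np.flatnonzero(~keep).tolist()
    if not removed:
        return rec, []
    if not keep.any():
        logger.warning(
            "recording %s: every epoch was all-NC/missing; empty result",
            rec.recording_id,
        )
    filtered = replace(rec, labels=rec.labels[keep])
    return filtered, removed


def to_one_hot(rec: MultiScoredRecording, scorer_id: str) -> OneHotAnnotations:
    """One-hot encode one scorer's labels as a ``(K, T)`` matrix with mask."""
    col = rec.labels[:, rec.scorer_index(scorer_id)]
    valid = col >= 0
    m = np.zeros((K, rec.n_epochs), dtype=float)
    t_idx = np.flatnonzero(valid)
    m[col[valid], t_idx] = 1.0
    return OneHotAnnotations(matrix=m, valid=valid)


def from_one_hot(oh: OneHotAnnotations) -> np.ndarray:
    """Decode a one-hot matrix back to a label-code vector.

    Invalid columns decode to ``MISSING`` (the NC/MISSING distinction is not
    representable in one-hot form; both are zero columns).
    """
    codes = np.argmax(oh.matrix, axis=0).astype(np.int8)
    codes[~oh.valid] = MISSING
    return codes


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_annotations(path, dialect: str = "auto") -> MultiScoredRecording:
    """Read a multi-scorer annotation table.

    The format is delimited text (comma or tab, autodetected) with header
    ``epoch,<scorer_1>,...,<scorer_J>`` and one row per 30-s epoch; cells
    hold tokens from ``{W, N1, N2, N3, R, NC, -}``.  Row order is epoch
    order with 0-based internal indexing.
    """
    sep = {"auto": None, "csv": ",", "tsv": "\t"}.get(dialect, dialect)
    try:
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                         skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise AnnotationParseError(f"{path}: malformed table: {exc}") from exc
    if df.shape[1] < 3:
        raise AnnotationParseError(
            f"{path}: need an epoch column plus >= 2 scorer columns, "
            f"got columns {list(df.columns)}"
        )
    scorer_ids = tuple(str(c) for c in df.columns[1:])
    T = len(df)
    labels = np.empty((T, len(scorer_ids)), dtype=np.int8)
    for j, col in enumerate(df.columns[1:]):
        for t, tok in enumerate(df[col]):
            if tok is None or (isinstance(tok, float) and np.isnan(tok)):
                raise AnnotationParseError(
                    f"{path}: empty cell at row {t + 2}, column {col!r}"
                )
            try:
                labels[t, j] = stage_to_index(str(tok))
            except AnnotationParseError:
                raise AnnotationParseError(
                    f"{path}: unknown label token {tok!r} at row {t + 2}, "
                    f"column {col!r}"
                ) from None
    rec_id = str(path)
    return MultiScoredRecording(recording_id=rec_id, scorer_ids=scorer_ids,
                                labels=labels)


def write_annotations(rec: MultiScoredRecording, path, sep: str = ",") -> None:
    """Write a recording in the format accepted by :func:`read_annotations`."""
    tokens = decode_labels(rec.labels)
    df = pd.DataFrame(tokens, columns=list(rec.scorer_ids))
    df.insert(0, "epoch", np.arange(rec.n_epochs))
    df.to_csv(path, sep=sep, index=False)


def read_hypnogram(path) -> np.ndarray:
    """Read a single hypnogram: one stage token per line."""
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    toks = [ln.strip() for ln in lines if ln.strip()]
    return encode_labels(toks)


def write_hypnogram(codes: np.ndarray, path) -> None:
    """Write a hypnogram: one stage token per line."""
    toks = decode_labels(np.asarray(codes))
    with open(path, "w") as fh:
        fh.write("\n".join(str(t) for t in toks) + "\n")
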