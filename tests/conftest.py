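import numpy as np
import pytest

from hypnofuse import MultiScoredRecording
from hypnofuse.annotations import MISSING, NC


@pytest.fixture
def worked_example() -> MultiScoredRecording:
    """Five physicians scoring one epoch as [W, W, W, N1, N2]."""
    return MultiScoredRecording(
        recording_id="worked-example",
        scorer_ids=("S1", "S2", "S3", "S4", "S5"),
        labels=np.array([[0, 0, 0, 1, 2]], dtype=np.int8),
    )


@pytest.fixture
def recording_factory():
    """Random recordings with optional NC/missing contamination.

    Guarantees at least one valid label per epoch.
    """

    def make(T=20, J=4, n_classes=5, nc_rate=0.0, missing_rate=0.0, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, n_classes, size=(T, J)).astype(np.int8)
        if nc_rate or missing_rate:
            u = rng.random((T, J))
            labels[u < missing_rate] = MISSING
            labels[(u >= missing_rate) & (u < missing_rate + nc_rate)] = NC
            # re-validate one random cell per all-invalid epoch
            for t in np.flatnonzero(~(labels >= 0).any(axis=1)):
                labels[t, rng.integers(J)] = rng.integers(n_classes)
        return MultiScoredRecording(
            recording_id=f"rand-{seed}",
            scorer_ids=tuple(f"S{j+1}" for j in range(J)),
            labels=labels,
        )

    return make
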