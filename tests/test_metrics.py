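import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypnofuse import (
    PredictionMatrix,
    acs,
    ece,
    evaluate_scorers,
    majority_vote,
    performance,
    soft_consensus,
)
from hypnofuse.errors import DimensionError, UndefinedValueError

from .oracles import oracle_cosine, oracle_ece


def random_predictions(rng, T):
    return PredictionMatrix(rng.dirichlet(np.ones(5), size=T))


class TestPredictionMatrix:
    def test_labels_and_confidence_derived(self):
        pm = PredictionMatrix(np.array([[0.1, 0.6, 0.1, 0.1, 0.1]]))
        assert pm.labels[0] == 1 and pm.confidence[0] == 0.6

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="row 0"):
            PredictionMatrix(np.array([[0.5, 0.1, 0.1, 0.1, 0.1]]))


class TestAcs:
    def test_identical_distributions_score_one(self, recording_factory):
        sc = soft_consensus(recording_factory(T=40, J=5, seed=4))
        assert acs(sc, PredictionMatrix(sc.matrix)) == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self):
        assert acs(np.array([[0, 1, 0, 0, 0.]]),
                   np.array([[1, 0, 0, 0, 0.]])) == 0.0

    def test_hand_worked_single_epoch(self):
        val = acs(np.array([[0.6, 0.2, 0.2, 0, 0]]),
                  np.array([[1.0, 0, 0, 0, 0]]))
        assert val == pytest.approx(0.6 / np.sqrt(0.44))

    def test_scale_invariance_per_epoch(self):
        s = np.array([[0.6, 0.2, 0.2, 0, 0]])
        p = np.array([[0.5, 0.3, 0.2, 0, 0]])
        assert acs(s, p) == pytest.approx(acs(s, p * 1.0), abs=1e-12)
        assert acs(3 * s, p) == pytest.approx(acs(s, p), abs=1e-12)

    def test_matches_per_epoch_cosine_oracle(self):
        rng = np.random.default_rng(8)
        s = rng.dirichlet(np.ones(5), size=25)
        p = rng.dirichlet(np.ones(5), size=25)
        expected = np.mean([oracle_cosine(s[i], p[i]) for i in range(25)])
        assert acs(s, p) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_row_is_an_error(self):
        with pytest.raises(UndefinedValueError, match="epoch 0"):
            acs(np.zeros((1, 5)), np.ones((1, 5)) / 5)

    def test_bounded_unit_interval_for_stochastic_rows(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            v = acs(rng.dirichlet(np.ones(5), size=10),
                    rng.dirichlet(np.ones(5), size=10))
            assert 0.0 <= v <= 1.0


class TestEce:
    def test_perfectly_calibrated_bin(self):
        # ten predictions at confidence 0.60, exactly six correct
        pm = PredictionMatrix(np.tile([0.6, 0.1, 0.1, 0.1, 0.1], (10, 1)))
        y = np.array([0] * 6 + [1] * 4)
        rep = ece(pm, y)
        assert rep.ece == pytest.approx(0.0, abs=1e-12)
        assert rep.mean_confidence == pytest.approx(0.6)

    def test_hand_worked_two_sample_case(self):
        # conf 0.95 correct, conf 0.55 wrong, M=10 -> 0.5*0.35 + 0.5*0.55
        pm = PredictionMatrix(np.array([
            [0.95, 0.02, 0.01, 0.01, 0.01],
            [0.55, 0.15, 0.10, 0.10, 0.10]]))
        y = np.array([0, 1])
        rep = ece(pm, y, n_bins=10)
        assert rep.ece == pytest.approx(0.5 * abs(1 - 0.95)
                                        + 0.5 * abs(0 - 0.55))

    def test_bins_recompose_to_ece_and_counts_to_n(self):
        rng = np.random.default_rng(5)
        pm = random_predictions(rng, 200)
        y = rng.integers(0, 5, 200)
        rep = ece(pm, y, n_bins=10)
        total = sum(b.count for b in rep.bins)
        assert total == 200
        recomputed = sum(
            (b.count / total) * abs(b.accuracy - b.confidence)
            for b in rep.bins if b.count)
        assert rep.ece == pytest.approx(recomputed, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 10**9), st.integers(1, 20))
    def test_matches_per_sample_oracle(self, seed, n_bins):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 60))
        pm = random_predictions(rng, T)
        y = rng.integers(0, 5, T)
        expected = oracle_ece(list(pm.confidence),
                              list(pm.labels == y), n_bins)
        assert ece(pm, y, n_bins=n_bins).ece == pytest.approx(
            expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        pm = PredictionMatrix(np.full((3, 5), 0.2))
        with pytest.raises(DimensionError):
            ece(pm, np.array([0, 1]))


class TestPerformance:
    def test_perfect_agreement(self):
        y = np.array([0, 1, 2, 3, 4, 2, 2])
        rep = performance(y, y)
        assert rep.accuracy == 1.0 and rep.cohens_kappa == 1.0
        assert rep.macro_f1 == 1.0 and all(
            f == 1.0 for f in rep.per_class_f1)

    def test_constant_classifier_has_zero_kappa(self):
        # chance-corrected agreement vanishes for a constant predictor
        ref = np.array([0, 0, 1, 2] * 5)
        pred = np.zeros(20, dtype=int)
        with pytest.warns(UserWarning):
            rep = performance(pred, ref)
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.cohens_kappa == pytest.approx(0.0)

    def test_matches_textbook_formulas_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            T = int(rng.integers(5, 50))
            yr = rng.integers(0, 5, T)
            yp = rng.integers(0, 5, T)
            rep = performance(yp, yr)
            # naive formulas straight from the definitions
            acc = np.mean(yp == yr)
            f1s, weights = [], []
            for k in range(5):
                tp = np.sum((yp == k) & (yr == k))
                fp = np.sum((yp == k) & (yr != k))
                fn = np.sum((yp != k) & (yr == k))
                f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
                f1s.append(f1)
                weights.append(np.sum(yr == k))
            po = acc
            pe = sum(np.mean(yr == k) * np.mean(yp == k) for k in range(5))
            kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
            assert rep.accuracy == pytest.approx(acc, abs=1e-9)
            assert rep.macro_f1 == pytest.approx(np.mean(f1s), abs=1e-9)
            assert rep.weighted_f1 == pytest.approx(
                np.average(f1s, weights=weights), abs=1e-9)
            assert np.allclose(rep.per_class_f1, f1s, atol=1e-9)
            assert rep.cohens_kappa == pytest.approx(kappa, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            performance(np.array([0, 1]), np.array([0]))


class TestEvaluateScorers:
    def test_unanimous_dataset_everyone_perfect(self):
        from hypnofuse import MultiScoredRecording
        rec = MultiScoredRecording(
            "u", ("A", "B", "C"), np.full((10, 3), 2, dtype=np.int8))
        evals = evaluate_scorers(rec)
        for ev in evals:
            assert ev.performance.accuracy == 1.0
            assert ev.reliability.soft_agreement == 1.0

    def test_random_scorer_ranks_below_identical_pair(self):
        rng = np.random.default_rng(0)
        T = 300
        good = rng.integers(0, 5, T).astype(np.int8)
        noisy = rng.integers(0, 5, T).astype(np.int8)
        from hypnofuse import MultiScoredRecording
        rec = MultiScoredRecording(
            "m", ("G1", "G2", "RND"),
            np.column_stack([good, good, noisy]))
        evals = {e.scorer_id: e for e in evaluate_scorers(rec)}
        assert evals["RND"].reliability.rank == 3
        assert evals["RND"].performance.weighted_f1 < \
            evals["G1"].performance.weighted_f1
        assert evals["G1"].is_best

    def test_invariant_to_epoch_permutation(self, recording_factory):
        from hypnofuse import MultiScoredRecording
        rec = recording_factory(T=50, J=4, seed=21)
        perm = np.random.default_rng(1).permutation(50)
        prec = MultiScoredRecording("p", rec.scorer_ids, rec.labels[perm])
        for a, b in zip(evaluate_scorers(rec), evaluate_scorers(prec)):
            assert a.scorer_id == b.scorer_id
            assert a.performance.accuracy == pytest.approx(
                b.performance.accuracy)
            assert a.reliability.soft_agreement == pytest.approx(
                b.reliability.soft_agreement)
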