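import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypnofuse import (
    MultiScoredRecording,
    majority_vote,
    probabilistic_consensus,
    rank_scorers,
    soft_agreement,
    soft_consensus,
)
from hypnofuse.annotations import MISSING, NC
from hypnofuse.errors import UndefinedValueError

from .oracles import (
    oracle_leave_one_out_consensus,
    oracle_soft_agreement,
    oracle_soft_consensus,
)


def make_rec(rows, J=None):
    rows = np.array(rows, dtype=np.int8)
    J = rows.shape[1] if J is None else J
    return MultiScoredRecording("r", tuple(f"S{j+1}" for j in range(J)), rows)


class TestProbabilisticConsensus:
    def test_two_way_tie_both_stages_get_one(self):
        # votes excluding S3: [W, N1]
        rec = make_rec([[0, 1, 4]])
        z = probabilistic_consensus(rec, "S3").matrix[:, 0]
        np.testing.assert_array_equal(z, [1, 1, 0, 0, 0])

    def test_unanimity_is_a_point_mass(self):
        rec = make_rec([[2, 2, 2, 2, 4]])
        z = probabilistic_consensus(rec, "S5").matrix[:, 0]
        np.testing.assert_array_equal(z, [0, 0, 1, 0, 0])

    def test_majority_with_minority_gets_fraction(self):
        # votes excluding S4: [W, W, N1] -> counts/max = [1, 0.5, 0, 0, 0]
        rec = make_rec([[0, 0, 1, 3]])
        z = probabilistic_consensus(rec, "S4").matrix[:, 0]
        np.testing.assert_allclose(z, [1, 0.5, 0, 0, 0])

    def test_no_remaining_votes_masks_epoch(self):
        rec = make_rec([[0, NC, MISSING]])
        pc = probabilistic_consensus(rec, "S1")
        assert not pc.valid_mask[0]
        assert pc.matrix[:, 0].sum() == 0

    def test_valid_columns_have_max_one(self, recording_factory):
        rec = recording_factory(T=50, J=5, nc_rate=0.2, missing_rate=0.1, seed=2)
        for sid in rec.scorer_ids:
            pc = probabilistic_consensus(rec, sid)
            np.testing.assert_allclose(
                pc.matrix[:, pc.valid_mask].max(axis=0), 1.0)


class TestSoftAgreement:
    def test_unanimous_scorer_scores_one(self):
        rec = make_rec(np.full((6, 4), 2))
        assert soft_agreement(rec, "S1") == 1.0

    def test_systematic_disagreement_scores_zero(self):
        labels = np.full((8, 4), 2, dtype=np.int8)
        labels[:, 0] = 4  # S1 always against a unanimous majority
        assert soft_agreement(make_rec(labels), "S1") == 0.0

    def test_hand_worked_three_scorer_case(self):
        # S1=[W,W], S2=[W,N1], S3=[N1,N1]: SA(S1) = (1 + 0) / 2
        rec = make_rec([[0, 0, 1], [0, 1, 1]])
        assert soft_agreement(rec, "S1") == pytest.approx(0.5)

    def test_undefined_without_contributing_epochs(self):
        rec = make_rec([[NC, 0, 1]])
        with pytest.raises(UndefinedValueError):
            soft_agreement(rec, "S1")


class TestRanking:
    def test_sorted_descending_with_rank_one_best(self, recording_factory):
        rec = recording_factory(T=60, J=5, seed=11)
        ranked = rank_scorers(rec)
        by_rank = sorted(ranked, key=lambda r: r.rank)
        scores = [r.soft_agreement for r in by_rank]
        assert scores == sorted(scores, reverse=True)
        assert sorted(r.rank for r in ranked) == [1, 2, 3, 4, 5]

    def test_identical_scorers_tie_broken_by_input_order(self):
        rec = make_rec(np.full((5, 3), 1))
        ranked = rank_scorers(rec)
        assert [r.soft_agreement for r in ranked] == [1.0, 1.0, 1.0]
        assert [r.rank for r in ranked] == [1, 2, 3]

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10**9))
    def test_column_permutation_preserves_scores(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 5, size=(12, 4)).astype(np.int8)
        rec = make_rec(labels)
        perm = rng.permutation(4)
        prec = MultiScoredRecording(
            "p", tuple(rec.scorer_ids[j] for j in perm), labels[:, perm])
        for sid in rec.scorer_ids:
            assert soft_agreement(rec, sid) == pytest.approx(
                soft_agreement(prec, sid))


class TestSoftConsensus:
    def test_worked_example(self, worked_example):
        sc = soft_consensus(worked_example)
        np.testing.assert_allclose(sc.matrix[0], [0.6, 0.2, 0.2, 0, 0])
        assert sc.observation_count[0] == 5

    def test_unanimity(self):
        sc = soft_consensus(make_rec([[4, 4, 4, 4, 4]]))
        np.testing.assert_array_equal(sc.matrix[0], [0, 0, 0, 0, 1])

    def test_missing_votes_shrink_denominator(self):
        # [W, N1, MISSING, NC, N1] -> M=3, [1/3, 2/3, 0, 0, 0]
        sc = soft_consensus(make_rec([[0, 1, MISSING, NC, 1]]))
        assert sc.observation_count[0] == 3
        np.testing.assert_allclose(sc.matrix[0], [1 / 3, 2 / 3, 0, 0, 0])

    def test_all_invalid_epoch_rejected_by_name(self):
        with pytest.raises(UndefinedValueError, match="epoch 1"):
            soft_consensus(make_rec([[0, 1, 2], [NC, NC, MISSING]]))

    def test_rows_stochastic_and_multiples_of_inverse_m(self, recording_factory):
        rec = recording_factory(T=80, J=6, nc_rate=0.2, missing_rate=0.2, seed=7)
        sc = soft_consensus(rec)
        np.testing.assert_allclose(sc.matrix.sum(axis=1), 1.0, atol=1e-12)
        scaled = sc.matrix * sc.observation_count[:, None]
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)


class TestMajorityVote:
    def test_clear_majority(self, worked_example):
        hyp = majority_vote(worked_example)
        assert hyp.labels[0] == 0 and not hyp.tie_flags[0]

    def test_tie_resolved_by_most_reliable_scorer(self):
        # epoch 1 ties W/N1; S3 (reliable: agrees with majority elsewhere)
        labels = np.array([
            [0, 0, 1, 1, 2],
            [2, 2, 2, 2, 0],
            [2, 2, 2, 2, 0],
        ], dtype=np.int8)
        rec = make_rec(labels)
        ranked = {r.scorer_id: r.rank for r in rank_scorers(rec)}
        hyp = majority_vote(rec)
        assert hyp.tie_flags[0] and not hyp.tie_flags[1]
        top = min(
            (s for s in rec.scorer_ids
             if labels[0, rec.scorer_index(s)] in (0, 1)),
            key=lambda s: ranked[s])
        assert hyp.labels[0] == labels[0, rec.scorer_index(top)]

    def test_label_attains_row_maximum(self, recording_factory):
        rec = recording_factory(T=100, J=5, nc_rate=0.1, missing_rate=0.1,
                                seed=13)
        sc = soft_consensus(rec)
        hyp = majority_vote(rec)
        rows = np.arange(rec.n_epochs)
        np.testing.assert_allclose(sc.matrix[rows, hyp.labels],
                                   sc.matrix.max(axis=1))

    def test_invariant_to_scorer_order_off_ties(self, recording_factory):
        rec = recording_factory(T=60, J=5, seed=17)
        hyp = majority_vote(rec)
        perm = np.array([3, 1, 4, 0, 2])
        prec = MultiScoredRecording(
            "p", tuple(rec.scorer_ids[j] for j in perm), rec.labels[:, perm])
        phyp = majority_vote(prec)
        free = ~hyp.tie_flags
        np.testing.assert_array_equal(hyp.labels[free], phyp.labels[free])


class TestOracleEquivalence:
    """Exhaustive + randomised agreement with naive loop implementations."""

    def _check(self, labels, n_classes=5):
        rec = make_rec(labels)
        if (np.array(labels) >= 0).any(axis=1).all():
            sc = soft_consensus(rec)
            # package always carries the full 5-stage alphabet; unused
            # stages must get exactly zero mass
            np.testing.assert_allclose(
                sc.matrix[:, :n_classes],
                oracle_soft_consensus(labels, n_classes), atol=1e-12)
            assert (sc.matrix[:, n_classes:] == 0).all()
        for j, sid in enumerate(rec.scorer_ids):
            z, valid = oracle_leave_one_out_consensus(labels, j, n_classes)
            pc = probabilistic_consensus(rec, sid)
            np.testing.assert_allclose(pc.matrix[:n_classes], z, atol=1e-12)
            np.testing.assert_array_equal(pc.valid_mask, valid)
            sa = oracle_soft_agreement(labels, j, n_classes)
            if sa is None:
                with pytest.raises(UndefinedValueError):
                    soft_agreement(rec, sid)
            else:
                assert soft_agreement(rec, sid) == pytest.approx(sa, abs=1e-12)

    def test_exhaustive_tiny_recordings_reduced_alphabet(self):
        # every recording with J=2..3 scorers, T=1..2 epochs, K=3 stages
        import itertools
        for J in (2, 3):
            for T in (1, 2):
                for flat in itertools.product(range(3), repeat=J * T):
                    labels = np.array(flat, dtype=np.int8).reshape(T, J)
                    self._check(labels, n_classes=3)

    def test_random_instances_with_sentinels(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            T = int(rng.integers(1, 7))
            J = int(rng.integers(2, 5))
            labels = rng.integers(-2, 3, size=(T, J)).astype(np.int8)
            self._check(labels.tolist(), n_classes=3)
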