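"""Replication measures: DTW against brute force, KL arithmetic, invariants."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melodymetrics.errors import DomainError, InsufficientDataError
from melodymetrics.replication import (
    COST_CAP,
    aligned_proportion,
    dtw_align,
    ioi_distribution,
    joint_features,
    kl_similarity,
    length_adjusted,
    pioi_scores,
    pitch_distribution,
    pitch_similarity,
    score_replication,
)
from melodymetrics.simulate import generate_reference

from _oracles import brute_force_subsequence_dtw
from conftest import make_performance


def _pitch_cost(a, b):
    return min(abs(a - b), COST_CAP)


class TestDtwAlign:
    def test_identity_alignment(self):
        seq = [60, 62, 64, 65, 67]
        result = dtw_align(seq, seq)
        assert result.normalized_distance == 0
        assert result.matched_ref_indices == frozenset(range(5))

    def test_exact_fragment_of_longer_reference(self):
        # 5 correct notes out of a 15-note piece: perfect on the
        # aligned segment, only a third of the reference covered
        ref = [60, 62, 64, 65, 67, 69, 67, 65, 64, 62, 60, 62, 64, 65, 67]
        perf = ref[:5]
        result = dtw_align(perf, ref)
        assert result.normalized_distance == 0
        assert len(result.matched_ref_indices) == 5
        assert aligned_proportion(result, len(ref)) == pytest.approx(5 / 15)

    def test_interior_fragment_aligns_freely(self):
        ref = list(range(60, 75))
        perf = ref[6:11]
        result = dtw_align(perf, ref)
        assert result.normalized_distance == 0
        assert result.matched_ref_indices == frozenset(range(6, 11))

    def test_single_substitution_against_oracle(self):
        perf, ref = [60, 61, 64], [60, 62, 64]
        result = dtw_align(perf, ref)
        expected = brute_force_subsequence_dtw(perf, ref, _pitch_cost, COST_CAP)
        assert result.normalized_distance == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InsufficientDataError):
            dtw_align([], [60])

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(60, 72), min_size=1, max_size=6),
        st.lists(st.integers(60, 72), min_size=1, max_size=6),
    )
    def test_matches_brute_force_enumeration(self, perf, ref):
        result = dtw_align(perf, ref)
        expected = brute_force_subsequence_dtw(perf, ref, _pitch_cost, COST_CAP)
        assert result.normalized_distance == pytest.approx(expected)

    def test_path_monotone_property(self, rng):
        for _ in range(20):
            perf = rng.integers(55, 80, size=rng.integers(2, 10)).tolist()
            ref = rng.integers(55, 80, size=rng.integers(2, 12)).tolist()
            path = dtw_align(perf, ref).path
            assert all(
                (i2 - i1, j2 - j1) in {(1, 1), (1, 0), (0, 1)}
                for (i1, j1), (i2, j2) in zip(path, path[1:])
            )


class TestSimilarityAndProportion:
    def test_similarity_endpoints(self):
        identity = dtw_align([60, 62], [60, 62])
        assert pitch_similarity(identity) == 1.0
        far = dtw_align([60], [127])
        assert far.normalized_distance == 1.0
        assert pitch_similarity(far) == 0.0

    def test_semitone_error_matches_oracle(self):
        ref = [60, 62, 64, 65, 67, 69, 71, 72, 74, 76]
        perf = list(ref)
        perf[4] += 1
        expected = brute_force_subsequence_dtw(perf, ref, _pitch_cost, COST_CAP)
        assert pitch_similarity(dtw_align(perf, ref)) == pytest.approx(1 - expected)

    def test_disjoint_pitch_sets_match_nothing(self):
        result = dtw_align([60, 61, 62], [70, 71, 72])
        assert aligned_proportion(result, 3) == 0.0

    def test_length_adjusted_products(self):
        assert length_adjusted(1.0, 1.0) == 1.0
        assert length_adjusted(0.9, 0.5) == pytest.approx(0.45)
        assert length_adjusted(0.7, 0.0) == 0.0
        with pytest.raises(DomainError):
            length_adjusted(1.2, 0.5)


class TestJointFeatures:
    def test_isochronous_log_iois_zero(self, scale_run):
        feats = joint_features(scale_run)
        assert all(f[1] == 0 for f in feats)

    def test_hand_computed_log_ratios(self):
        perf = make_performance([60, 62, 64, 65], iois=[0.5, 1.0, 0.5, 0.5])
        feats = joint_features(perf)
        assert [f[1] for f in feats] == pytest.approx([0.0, 1.0, 0.0])
        assert [f[0] for f in feats] == [60.0, 62.0, 64.0]

    def test_tempo_invariance(self):
        pitches = [60, 64, 62, 67, 65, 69]
        iois = [0.3, 0.6, 0.3, 0.45, 0.3, 0.3]
        slow = make_performance(pitches, iois=[2 * x for x in iois])
        fast = make_performance(pitches, iois=iois)
        assert joint_features(slow) == pytest.approx(joint_features(fast))


class TestPioiScores:
    def test_identity_triple(self, scale_run):
        assert pioi_scores(scale_run, scale_run) == (1.0, 1.0, 1.0)

    def test_uniform_rescale_equals_pitch_only(self):
        pitches = [60, 62, 64, 65, 67]
        iois = [0.25, 0.5, 0.5, 0.25, 0.5]
        ref = make_performance(pitches, iois=iois)
        perf = make_performance(pitches, iois=[3 * x for x in iois])
        sim, prop, ladj = pioi_scores(perf, ref)
        align = dtw_align(perf.pitches, ref.pitches)
        assert sim == pitch_similarity(align)
        assert prop == aligned_proportion(align, len(ref))

    def test_timing_error_lowers_joint_but_not_pitch_score(self):
        pitches = [60, 62, 64, 65, 67, 69]
        ref = make_performance(pitches, iois=0.5)
        iois = [0.5, 0.5, 1.0, 0.5, 0.5, 0.5]  # one IOI doubled
        perf = make_performance(pitches, iois=iois)
        pitch_sim = pitch_similarity(dtw_align(perf.pitches, ref.pitches))
        joint_sim, _, _ = pioi_scores(perf, ref)
        assert pitch_sim == 1.0
        assert joint_sim < pitch_sim


class TestDistributions:
    def test_relative_frequencies(self):
        perf = make_performance([60, 60, 62])
        dist = pitch_distribution(perf)
        assert dist[60] == pytest.approx(2 / 3)
        assert dist[62] == pytest.approx(1 / 3)
        assert dist.sum() == pytest.approx(1.0)

    def test_order_invariance(self, rng):
        pitches = rng.integers(60, 80, size=10)
        a = pitch_distribution(make_performance(pitches))
        b = pitch_distribution(make_performance(pitches[::-1]))
        assert np.allclose(a, b)

    def test_additive_smoothing_arithmetic(self):
        perf = make_performance([60, 60])
        dist = pitch_distribution(perf, support=[60, 62], alpha=0.5)
        assert dist == pytest.approx([2.5 / 3.0, 0.5 / 3.0])

    def test_ioi_histogram_isochronous(self, scale_run):
        dist = ioi_distribution(scale_run)
        assert dist[6] == 1.0  # centre bin holds log-ratio 0

    def test_ioi_histogram_tempo_invariant(self, rng):
        pitches = rng.integers(60, 80, size=8)
        iois = rng.choice([0.25, 0.5, 1.0], size=8)
        a = ioi_distribution(make_performance(pitches, iois=iois))
        b = ioi_distribution(make_performance(pitches, iois=4 * iois))
        assert np.allclose(a, b)

    def test_ioi_binning_hand_case(self):
        perf = make_performance([60, 62, 64, 65], iois=[0.5, 1.0, 0.5, 0.5])
        # log2 ratios to median 0.5: (0, 1, 0) -> centre bin twice,
        # bin of +1 once; bin width 6/13 so +1 falls in bin 8
        dist = ioi_distribution(perf)
        assert dist[6] == pytest.approx(2 / 3)
        assert dist[8] == pytest.approx(1 / 3)


class TestKlSimilarity:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_similarity(p, p) == 1.0

    def test_symmetry(self, rng):
        p = rng.dirichlet(np.ones(6))
        q = rng.dirichlet(np.ones(6))
        assert kl_similarity(p, q) == pytest.approx(kl_similarity(q, p))

    def test_two_bin_closed_form(self):
        p, q = np.array([0.9, 0.1]), np.array([0.1, 0.9])
        j = 0.8 * math.log(9.0)  # (0.9-0.1)*ln(0.9/0.1), symmetrised
        assert kl_similarity(p, q) == pytest.approx(math.exp(-j))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            kl_similarity(np.array([0.5, 0.5]), np.array([1 / 3, 1 / 3, 1 / 3]))
        with pytest.raises(DomainError):
            kl_similarity(np.array([0.7, 0.2]), np.array([0.5, 0.5]))
        with pytest.raises(DomainError):
            kl_similarity(np.array([1.0, 0.0]), np.array([0.5, 0.5]))


class TestScoreReplication:
    def test_self_replication_near_perfect(self):
        ref = generate_reference(20, seed=7)
        scores = score_replication(ref, ref)
        assert scores.pitchdtwsim == 1.0
        assert scores.palignedprop == 1.0
        assert scores.pitchdtwladj == 1.0
        assert scores.pioidtwladj == 1.0
        assert scores.klpitchsim >= 0.98
        assert scores.klioisim >= 0.98

    def test_half_rendition_scores(self):
        ref = generate_reference(30, seed=11)
        from melodymetrics.events import Performance

        half = Performance(ref.notes[:15])
        scores = score_replication(half, ref)
        assert scores.palignedprop == pytest.approx(0.5)
        assert scores.pitchdtwsim == 1.0
        assert scores.pitchdtwladj == pytest.approx(0.5)

    def test_product_invariants_and_ranges(self, rng):
        ref = generate_reference(15, seed=3)
        for _ in range(20):
            perf = make_performance(
                rng.integers(60, 80, size=rng.integers(2, 20)),
                iois=rng.choice([0.25, 0.5, 1.0], size=None),
            )
            s = score_replication(perf, ref)
            for value in s.as_dict().values():
                assert 0.0 <= value <= 1.0
            assert s.pitchdtwladj == pytest.approx(s.pitchdtwsim * s.palignedprop)
            assert s.pioidtwladj == pytest.approx(s.pioidtwsim * s.pioialignedprop)
            assert s.pitchdtwladj <= min(s.pitchdtwsim, s.palignedprop) + 1e-12

    def test_single_note_performance_flags_ioi_fields(self):
        ref = generate_reference(10, seed=5)
        perf = make_performance([int(ref.pitches[0])])
        s = score_replication(perf, ref)
        assert not math.isnan(s.pitchdtwsim)
        assert not math.isnan(s.klpitchsim)
        assert math.isnan(s.pioidtwsim)
        assert math.isnan(s.klioisim)

    def test_tempo_rescaling_changes_nothing(self):
        ref = generate_reference(12, seed=9)
        perf = generate_reference(12, seed=10)
        slowed = make_performance(
            perf.pitches,
            iois=np.append(np.diff(perf.onsets), perf.durations[-1]) * 2.5,
        )
        a = score_replication(perf, ref).as_dict()
        b = score_replication(slowed, ref).as_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9), key

    def test_reversed_melody_scores_below_identity(self):
        ref = generate_reference(12, seed=21)
        reversed_perf = make_performance(ref.pitches[::-1])
        s_rev = score_replication(reversed_perf, ref)
        assert s_rev.pitchdtwsim < 1.0  # DTW is order-sensitive
        # distributional similarity is order-blind
        s_fwd = score_replication(make_performance(ref.pitches), ref)
        assert s_rev.klpitchsim == pytest.approx(s_fwd.klpitchsim)

    def test_random_performances_score_low(self, rng):
        ref = generate_reference(20, seed=2)
        values = []
        for _ in range(100):
            perf = make_performance(rng.integers(60, 80, size=20))
            values.append(score_replication(perf, ref).pitchdtwladj)
        assert np.mean(values) < 0.4
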