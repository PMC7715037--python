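"""Partition optimization, Bayesian updates, threshold selection, loop."""

import numpy as np
import pytest

from shufflespeller import (
    ALPHABET,
    EngineConfig,
    Posterior,
    QueryEvidence,
    bayes_update,
    optimize_partition,
    run_selection,
    select_character,
)
from shufflespeller.engine import DegenerateEvidenceError
from shufflespeller.users import OracleUserModel, UnrecognizedUserModel
from oracles import best_partition_exhaustive, queries_to_threshold


def symmetric_channel(k: int, accuracy: float) -> np.ndarray:
    off = (1.0 - accuracy) / (k - 1)
    return np.full((k, k), off) + np.eye(k) * (accuracy - off)


def small_posterior(probs, alphabet=None):
    probs = np.asarray(probs, dtype=float)
    alphabet = alphabet or tuple(ALPHABET[: len(probs)])
    return Posterior(probabilities=probs / probs.sum(), alphabet=alphabet)


class TestOptimizePartition:
    def test_matches_exhaustive_search_6_chars_2_boxes(self):
        w = symmetric_channel(2, 0.9)
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(6))
        part = optimize_partition(small_posterior(p), w, n_boxes=2)
        best_info, _ = best_partition_exhaustive(
            small_posterior(p).probabilities, w, 2
        )
        assert part.expected_information_bits == pytest.approx(best_info,
                                                               abs=1e-9)

    def test_within_99pct_of_optimum_on_random_instances(self):
        rng = np.random.default_rng(1)
        for trial in range(50):
            n_chars = int(rng.integers(4, 9))
            n_boxes = int(rng.integers(2, 4))
            m = rng.gamma(1.0, size=(n_boxes, n_boxes)) + 0.05
            w = m / m.sum(axis=1, keepdims=True)
            p = rng.dirichlet(np.ones(n_chars))
            post = small_posterior(p)
            part = optimize_partition(post, w, n_boxes=n_boxes)
            best_info, _ = best_partition_exhaustive(post.probabilities, w,
                                                     n_boxes)
            assert part.expected_information_bits >= 0.99 * best_info - 1e-12

    def test_point_mass_posterior_gives_zero_information(self):
        w = symmetric_channel(4, 0.9)
        p = np.zeros(28)
        p[5] = 1.0
        part = optimize_partition(Posterior(probabilities=p), w)
        assert part.expected_information_bits == pytest.approx(0.0, abs=1e-12)
        # Deterministic tie-break: identical inputs give identical output.
        part2 = optimize_partition(Posterior(probabilities=p), w)
        np.testing.assert_array_equal(part.box_of, part2.box_of)

    def test_uniform_4_chars_identity_channel_is_one_per_box(self):
        part = optimize_partition(small_posterior(np.ones(4)), np.eye(4))
        assert sorted(part.box_of.tolist()) == [0, 1, 2, 3]
        assert part.expected_information_bits == pytest.approx(2.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            optimize_partition(Posterior.uniform(), np.eye(3), n_boxes=4)


class TestBayesUpdate:
    def _partition(self, box_of):
        from shufflespeller import Partition

        box_of = np.asarray(box_of)
        return Partition(box_of=box_of, expected_information_bits=0.0,
                         alphabet=tuple(ALPHABET[: len(box_of)]))

    def test_uniform_likelihood_leaves_posterior_unchanged(self):
        post = Posterior.uniform()
        part = self._partition(np.arange(28) % 4)
        ev = QueryEvidence(likelihoods=np.ones(4), recognized=True,
                           trial_duration_s=2.0)
        out = bayes_update(post, part, ev)
        np.testing.assert_allclose(out.probabilities, post.probabilities,
                                   atol=1e-12)
        assert out.query_count == 1

    def test_bayes_rule_arithmetic_four_chars(self):
        post = small_posterior(np.ones(4))
        part = self._partition([0, 1, 2, 3])
        ev = QueryEvidence(likelihoods=np.array([0.7, 0.1, 0.1, 0.1]),
                           recognized=True, trial_duration_s=2.0)
        out = bayes_update(post, part, ev)
        np.testing.assert_allclose(out.probabilities, [0.7, 0.1, 0.1, 0.1],
                                   atol=1e-12)

    def test_unrecognized_evidence_only_counts(self):
        post = Posterior.uniform()
        part = self._partition(np.arange(28) % 4)
        ev = QueryEvidence(likelihoods=np.zeros(4), recognized=False,
                           trial_duration_s=2.0)
        out = bayes_update(post, part, ev)
        np.testing.assert_array_equal(out.probabilities, post.probabilities)
        assert out.unrecognized_count == 1
        assert out.query_count == 0

    def test_all_zero_likelihood_raises(self):
        post = Posterior.uniform()
        part = self._partition(np.arange(28) % 4)
        ev = QueryEvidence(likelihoods=np.zeros(4), recognized=True,
                           trial_duration_s=2.0)
        with pytest.raises(DegenerateEvidenceError):
            bayes_update(post, part, ev)

    def test_normalization_preserved_under_random_updates(self):
        rng = np.random.default_rng(5)
        post = Posterior.uniform()
        part = self._partition(np.arange(28) % 4)
        for _ in range(100):
            ev = QueryEvidence(likelihoods=rng.uniform(0.01, 1, 4),
                               recognized=True, trial_duration_s=2.0)
            post = bayes_update(post, part, ev)
            assert abs(post.probabilities.sum() - 1.0) < 1e-12

    def test_no_underflow_over_200_queries(self):
        # Log-space computation keeps 200 consecutive heavily skewed updates
        # finite and normalized.
        post = Posterior.uniform()
        part = self._partition(np.arange(28) % 4)
        ev = QueryEvidence(likelihoods=np.array([1e-30, 1e-32, 1e-32, 1e-32]),
                           recognized=True, trial_duration_s=2.0)
        for _ in range(200):
            post = bayes_update(post, part, ev)
        assert np.isfinite(post.probabilities).all()
        assert abs(post.probabilities.sum() - 1.0) < 1e-12
        assert post.max_probability > 0.0


class TestSelectCharacter:
    def test_strictly_above_threshold_selects(self):
        p = np.full(28, (1 - 0.86) / 27)
        p[2] = 0.86
        assert select_character(Posterior(probabilities=p)) == "C"

    def test_below_threshold_returns_none(self):
        p = np.full(28, (1 - 0.84) / 27)
        p[2] = 0.84
        assert select_character(Posterior(probabilities=p)) is None

    def test_exactly_at_threshold_returns_none(self):
        # The rule is strict "exceeds 85%".
        p = np.full(28, (1 - 0.85) / 27)
        p[2] = 0.85
        assert select_character(Posterior(probabilities=p)) is None


class TestRunSelection:
    def test_near_noiseless_user_matches_recursion_oracle(self):
        # 19:1 likelihood ratio toward the correct box.
        w = symmetric_channel(4, 0.95)
        user = OracleUserModel(correct=0.95, incorrect=0.05,
                               trial_duration_s=2.0)
        expected_n = queries_to_threshold(28, 4, 0.95, 0.05, 0.85)
        out = run_selection(w, user, "Q")
        assert out.character == "Q"
        assert out.n_queries == expected_n

    def test_085_005_likelihoods_match_recursion_oracle(self):
        w = symmetric_channel(4, 0.85)
        user = OracleUserModel(correct=0.85, incorrect=0.05,
                               trial_duration_s=2.0)
        expected_n = queries_to_threshold(28, 4, 0.85, 0.05, 0.85)
        out = run_selection(w, user, "M")
        assert out.character == "M"
        assert out.n_queries == expected_n

    def test_unrecognized_limit_aborts_with_reason(self):
        w = symmetric_channel(4, 0.9)
        out = run_selection(w, UnrecognizedUserModel(), "A",
                            config=EngineConfig(unrecognized_limit=10))
        assert out.character is None
        assert out.abort_reason == "unrecognized-input"
        assert out.n_queries == 10

    def test_elapsed_time_arithmetic(self):
        # initial display 5 s + n x trial + (n - 1) x 2 s pauses.
        w = symmetric_channel(4, 0.95)
        user = OracleUserModel(correct=0.95, incorrect=0.05,
                               trial_duration_s=2.0)
        out = run_selection(w, user, "Q")
        n = out.n_queries
        assert out.elapsed_s == pytest.approx(5.0 + n * 2.0 + (n - 1) * 2.0)
        if n == 3:
            assert out.elapsed_s == pytest.approx(15.0)

    def test_max_queries_abort(self):
        # Uninformative (uniform) evidence never crosses the threshold.
        w = symmetric_channel(4, 0.25)
        user = OracleUserModel(correct=0.25, incorrect=0.25,
                               trial_duration_s=2.0)
        out = run_selection(w, user, "A", config=EngineConfig(max_queries=7))
        assert out.abort_reason == "max-queries"
        assert out.n_queries == 7

    def test_accumulation_beats_single_decision_and_is_monotone(self):
        # With a symmetric channel of accuracy p > chance, Bayesian evidence
        # accumulation never underperforms a single hard decision: simulated
        # selection accuracy >= p (with binomial slack), and increases in p.
        levels = [0.5, 0.7, 0.9]
        n_sel = 120
        alphabet = list(ALPHABET)
        accs = []
        for accuracy in levels:
            rng = np.random.default_rng(int(accuracy * 100))
            w = symmetric_channel(4, accuracy)
            user = OracleUserModel(correct=0.85, incorrect=0.05, confusion=w,
                                   rng=rng, trial_duration_s=2.0)
            n_correct = 0
            for i in range(n_sel):
                intended = alphabet[i % 28]
                out = run_selection(w, user, intended,
                                    config=EngineConfig(max_queries=40))
                chosen = out.character or out.posterior.argmax_character
                n_correct += chosen == intended
            acc = n_correct / n_sel
            slack = 2.6 * np.sqrt(accuracy * (1 - accuracy) / n_sel)
            assert acc >= accuracy - slack
            accs.append(acc)
        # Non-decreasing in p (saturation at 1.0 makes strict increase
        # unattainable at high p).
        assert accs[0] <= accs[1] + 1e-12 <= accs[2] + 2e-12
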