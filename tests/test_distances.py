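"""Pairwise identity, redundancy pruning and JTT distances."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from plpmine import jtt
from plpmine.alphabet import AMINO_ACIDS
from plpmine.distances import (
    GapDeletionError,
    complete_deletion,
    jtt_distance,
    p_distance_matrix,
    pairwise_identity,
    remove_redundant,
)


def _random_seq(rng, n):
    return "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, n))


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == 100.0

    def test_three_quarters_identity_without_gaps(self):
        assert pairwise_identity("ACDE", "ACDK") == pytest.approx(75.0)

    def test_gap_columns_count_in_denominator(self):
        # optimal alignment pads the shorter sequence; identity < 100
        ident = pairwise_identity("ACDEFGHIKLMNPQ", "ACDEFGHIKL")
        assert ident == pytest.approx(100.0 * 10 / 14)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")


class TestRemoveRedundant:
    def test_identical_collapse_to_one(self):
        seqs = [(f"s{i}", "ACDEFGHIKLMNPQRSTVWY" * 3) for i in range(5)]
        assert len(remove_redundant(seqs)) == 1

    def test_constructed_triplet(self, rng):
        a = _random_seq(rng, 100)
        a_prime = a[:90] + _random_seq(rng, 10)  # ~90% identical to a
        b = _random_seq(rng, 100)                # unrelated
        kept = remove_redundant([("A", a), ("Aprime", a_prime), ("B", b)])
        assert len(kept) == 2
        assert {k for k, _ in kept} == {"A", "B"}  # equal length: later dropped

    def test_no_retained_pair_above_threshold(self, rng):
        base = _random_seq(rng, 80)
        seqs = []
        for i in range(8):
            s = list(base)
            for j in rng.integers(0, 80, size=int(rng.integers(0, 30))):
                s[j] = AMINO_ACIDS[int(rng.integers(0, 20))]
            seqs.append((f"v{i}", "".join(s)))
        kept = remove_redundant(seqs, 70.0)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert pairwise_identity(kept[i][1], kept[j][1]) <= 70.0

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            remove_redundant([("a", "ACD")], 0.0)


class TestCompleteDeletion:
    def test_gap_in_one_row_removes_column_for_all(self):
        coded = complete_deletion(["ACDE", "AC-E", "ACDE"])
        assert coded.shape == (3, 3)  # the gapped column is gone for all

    def test_all_gapped_rejected(self):
        with pytest.raises(GapDeletionError):
            complete_deletion(["A-", "-A"])


class TestJTTDistance:
    def test_identical_rows_zero(self):
        dm = jtt_distance([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKL")])
        assert dm["a", "b"] == 0.0

    def test_correction_exceeds_p_distance(self, rng):
        # 10% observed differences over 200 columns -> ML distance > 0.1
        a = _random_seq(rng, 200)
        b = list(a)
        idx = rng.choice(200, size=20, replace=False)
        for j in idx:
            choices = [c for c in AMINO_ACIDS if c != a[j]]
            b[j] = choices[int(rng.integers(0, 19))]
        dm = jtt_distance([("a", a), ("b", "".join(b))])
        assert dm["a", "b"] > 0.1

    def test_dominates_p_distance_on_random_alignments(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 6))
            length = int(rng.integers(50, 120))
            base = _random_seq(rng, length)
            rows = []
            for i in range(n):
                s = list(base)
                for j in rng.integers(0, length, size=int(rng.integers(0, length // 2))):
                    s[j] = AMINO_ACIDS[int(rng.integers(0, 20))]
                rows.append((f"r{i}", "".join(s)))
            dj = jtt_distance(rows)
            dp = p_distance_matrix(rows)
            assert np.all(dj.data >= dp.data - 1e-9)

    def test_matches_grid_scan_oracle(self, rng):
        # independent 1-D likelihood scan over t for one pair
        a = _random_seq(rng, 150)
        b = list(a)
        for j in rng.choice(150, size=45, replace=False):
            b[j] = AMINO_ACIDS[int(rng.integers(0, 20))]
        b = "".join(b)
        dm = jtt_distance([("a", a), ("b", b)])
        counts = np.zeros((20, 20))
        for x, y in zip(a, b):
            i, j = AMINO_ACIDS.index(x), AMINO_ACIDS.index(y)
            counts[i, j] += 0.5
            counts[j, i] += 0.5
        log_pi = np.log(jtt.JTT_FREQUENCIES)

        def nll(t):
            with np.errstate(divide="ignore"):
                lp = np.log(jtt.transition_probabilities(t))
            return -np.sum((counts * (log_pi[:, None] + lp))[counts > 0])

        grid = np.linspace(0.01, 3.0, 3000)
        t_star = grid[int(np.argmin([nll(t) for t in grid]))]
        assert dm["a", "b"] == pytest.approx(t_star, abs=2e-3)

    def test_saturated_pair_capped_and_flagged(self):
        # maximally scrambled pair: every residue replaced by a fixed shift
        a = AMINO_ACIDS * 10
        b = "".join(AMINO_ACIDS[(AMINO_ACIDS.index(c) + 7) % 20] for c in a)
        dm = jtt_distance([("a", a), ("b", b)])
        if dm["a", "b"] >= jtt.MAX_DISTANCE:
            assert ("a", "b") in dm.saturated_pairs


class TestJTTModel:
    def test_transition_rows_are_distributions(self):
        for t in (0.0, 0.1, 1.0, 5.0):
            p = jtt.transition_probabilities(t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(p >= 0)
        assert np.allclose(jtt.transition_probabilities(0.0), np.eye(20), atol=1e-10)

    def test_stationarity_and_reversibility(self):
        pi = jtt.JTT_FREQUENCIES
        p = jtt.transition_probabilities(0.7)
        assert np.allclose(pi @ p, pi, atol=1e-12)
        flux = pi[:, None] * p
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_pdistance_inversion(self):
        for d in (0.05, 0.3, 0.6):
            t = jtt.time_for_pdistance(d)
            assert jtt.expected_pdistance(t) == pytest.approx(d, abs=1e-9)

    def test_mixture_time_matches_average_pdistance(self):
        rates = np.array([0.3] * 50 + [1.0] * 50)
        t = jtt.time_for_mixture_pdistance(0.4, rates)
        mean_p = 0.5 * (jtt.expected_pdistance(0.3 * t) + jtt.expected_pdistance(t))
        assert mean_p == pytest.approx(0.4, abs=1e-9)
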