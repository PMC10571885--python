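"""Composite loss: analytic values, brute-force oracles, gradient checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndeepsurv import (acceptable_pairs, neg_log_partial_likelihood,
                       ranking_loss, total_loss)
from ndeepsurv.autodiff import Tensor
from ndeepsurv.losses import NoEventsError
from tests.conftest import random_survival_instance


def naive_l1(r, T, E):
    """Brute-force negative log partial likelihood (Breslow)."""
    total = 0.0
    for i in range(len(r)):
        if E[i] == 1:
            denom = sum(math.exp(r[j]) for j in range(len(r)) if T[j] >= T[i])
            total -= r[i] - math.log(denom)
    return total


def naive_l2(r, T, E, sigma=1.0):
    """Brute-force ranking loss over all ordered pairs."""
    total = 0.0
    for i in range(len(r)):
        for j in range(len(r)):
            if i != j and E[i] == 1 and T[i] < T[j]:
                total += math.exp(-(r[i] - r[j]) / sigma)
    return total


class TestPartialLikelihood:
    @pytest.mark.parametrize("n", [2, 10, 100])
    def test_single_event_uniform_risks_gives_log_n(self, n):
        r = np.zeros(n)
        T = np.arange(n, dtype=float)
        E = np.zeros(n, int)
        E[0] = 1
        assert neg_log_partial_likelihood(r, T, E) == pytest.approx(math.log(n))

    def test_three_subject_hand_expansion(self):
        a, b, c = 0.3, -0.2, 0.9
        r = np.array([a, b, c])
        T = np.array([1.0, 2.0, 3.0])
        E = np.array([1, 1, 1])
        expected = -((a - math.log(math.exp(a) + math.exp(b) + math.exp(c)))
                     + (b - math.log(math.exp(b) + math.exp(c)))
                     + (c - math.log(math.exp(c))))
        assert neg_log_partial_likelihood(r, T, E) == pytest.approx(expected)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.floats(-5, 5))
    def test_shift_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        r, T, E = random_survival_instance(rng, 15)
        E[0] = 1
        base = neg_log_partial_likelihood(r, T, E)
        assert neg_log_partial_likelihood(r + shift, T, E) == pytest.approx(base)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            r, T, E = random_survival_instance(rng, 40)
            if E.sum() == 0:
                E[0] = 1
            assert (neg_log_partial_likelihood(r, T, E)
                    == pytest.approx(naive_l1(r, T, E), rel=1e-10))

    def test_no_events_is_error(self):
        with pytest.raises(NoEventsError):
            neg_log_partial_likelihood(np.zeros(3), np.arange(3.0), np.zeros(3, int))


class TestAcceptablePairs:
    def test_small_enumeration(self):
        assert acceptable_pairs([1.0, 2.0], [1, 0]) == [(0, 1)]

    def test_all_censored_empty(self):
        assert acceptable_pairs([1.0, 2.0, 3.0], [0, 0, 0]) == []

    def test_tied_times_not_acceptable(self):
        assert acceptable_pairs([1.0, 1.0], [1, 1]) == []

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_definition(self, seed):
        rng = np.random.default_rng(seed)
        _, T, E = random_survival_instance(rng, 12)
        pairs = set(acceptable_pairs(T, E))
        expected = {(i, j) for i in range(12) for j in range(12)
                    if i != j and E[i] == 1 and T[i] < T[j]}
        assert pairs == expected


class TestRankingLoss:
    def test_equal_risks_count_pairs(self):
        rng = np.random.default_rng(6)
        _, T, E = random_survival_instance(rng, 30)
        r = np.full(30, 1.7)
        assert ranking_loss(r, T, E, sigma=1.0) == pytest.approx(
            len(acceptable_pairs(T, E)))

    def test_no_acceptable_pairs_is_zero(self):
        assert ranking_loss(np.ones(3), [1.0, 1.0, 1.0], [1, 1, 1]) == 0.0

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        for sigma in (0.5, 1.0, 2.0):
            r, T, E = random_survival_instance(rng, 35, with_ties=False)
            assert ranking_loss(r, T, E, sigma=sigma) == pytest.approx(
                naive_l2(r, T, E, sigma), rel=1e-10)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            ranking_loss(np.ones(2), [1.0, 2.0], [1, 0], sigma=0.0)

    def test_raising_event_risk_never_increases_loss(self):
        rng = np.random.default_rng(8)
        r, T, E = random_survival_instance(rng, 20, with_ties=False)
        E[3] = 1
        base = ranking_loss(r, T, E)
        r2 = r.copy()
        r2[3] += 1.0
        assert ranking_loss(r2, T, E) <= base


class TestTotalLoss:
    def test_additivity(self):
        rng = np.random.default_rng(9)
        r, T, E = random_survival_instance(rng, 25)
        E[0] = 1
        assert total_loss(r, T, E, sigma=1.3) == pytest.approx(
            neg_log_partial_likelihood(r, T, E) + ranking_loss(r, T, E, 1.3))

    def test_lambda_zero_reduces_to_cox_loss(self):
        rng = np.random.default_rng(10)
        r, T, E = random_survival_instance(rng, 25)
        E[0] = 1
        assert total_loss(r, T, E, lam=0.0) == pytest.approx(
            neg_log_partial_likelihood(r, T, E))

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            r, T, E = random_survival_instance(rng, 20, with_ties=False)
            E[:2] = 1
            t = Tensor(r, requires_grad=True)
            total_loss(t, T, E).backward()
            eps = 1e-6
            for i in range(20):
                rp, rm = r.copy(), r.copy()
                rp[i] += eps
                rm[i] -= eps
                fd = (total_loss(rp, T, E) - total_loss(rm, T, E)) / (2 * eps)
                assert t.grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)
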