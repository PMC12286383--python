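"""Moment statistics and the reweighted alignment losses.

The reference oracle throughout is a naive scalar-loop implementation of
the element-wise moments and the pairwise distance sums, written
independently of the vectorized code path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camsda.autodiff import Tensor
from camsda.moments import (
    AlignmentLossBreakdown,
    FeatureBatch,
    alignment_loss,
    compute_moments,
    pair_distance,
    source_source_loss,
    source_target_loss,
)

A = np.array([[1.0, 0.0], [3.0, 0.0]])
B = np.array([[0.0, 0.0], [2.0, 0.0]])


# --- independent scalar-loop oracle ----------------------------------

def oracle_moments(values):
    n, d = values.shape
    m1 = [sum(values[i][j] for i in range(n)) / n for j in range(d)]
    m2 = [sum(values[i][j] ** 2 for i in range(n)) / n for j in range(d)]
    return m1, m2


def oracle_distance(x, y):
    m1x, m2x = oracle_moments(x)
    m1y, m2y = oracle_moments(y)
    d1 = math.sqrt(sum((a - b) ** 2 for a, b in zip(m1x, m1y)))
    d2 = math.sqrt(sum((a - b) ** 2 for a, b in zip(m2x, m2y)))
    return d1 + d2


def oracle_ss(batches, w):
    n = len(batches)
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            total += 0.5 * (w[i] + w[j]) * oracle_distance(batches[i], batches[j])
    return 2.0 / (n * (n - 1)) * total


def oracle_st(batches, target, w):
    n = len(batches)
    return 2.0 / n * sum(w[i] * oracle_distance(batches[i], target) for i in range(n))


# --- compute_moments --------------------------------------------------

def test_moments_of_hand_worked_batch():
    mp = compute_moments(A)
    assert np.allclose(mp.m1, [2.0, 0.0])
    assert np.allclose(mp.m2, [5.0, 0.0])


def test_single_row_moments_are_value_and_square():
    c = np.array([[1.5, -2.0, 0.25]])
    mp = compute_moments(c)
    assert np.allclose(mp.m1, c[0])
    assert np.allclose(mp.m2, c[0] ** 2)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_moments_are_invariant_to_row_permutation(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(7, 3))
    perm = rng.permutation(7)
    a, b = compute_moments(x), compute_moments(x[perm])
    assert np.allclose(a.m1, b.m1) and np.allclose(a.m2, b.m2)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_second_moment_dominates_squared_first_moment(seed):
    rng = np.random.default_rng(seed)
    mp = compute_moments(rng.normal(size=(5, 4)) * 3)
    assert np.all(mp.m2 >= mp.m1**2 - 1e-9)


def test_translating_a_batch_shifts_m1_by_exactly_that_vector(rng):
    x = rng.normal(size=(10, 4))
    v = rng.normal(size=4)
    assert np.allclose(compute_moments(x + v).m1, compute_moments(x).m1 + v)


def test_empty_batch_rejected():
    with pytest.raises(ValueError):
        compute_moments(np.empty((0, 3)))
    with pytest.raises(ValueError):
        FeatureBatch(values=np.empty((0, 3)))


def test_non_finite_batch_rejected():
    with pytest.raises(ValueError):
        FeatureBatch(values=np.array([[np.nan, 1.0]]))


# --- pair_distance -----------------------------------------------------

def test_pair_distance_hand_worked_example():
    d = pair_distance(compute_moments(A), compute_moments(B))
    assert d == pytest.approx(4.0)


def test_pair_distance_identity_and_symmetry(rng):
    x, y = rng.normal(size=(6, 3)), rng.normal(size=(8, 3))
    mx, my = compute_moments(x), compute_moments(y)
    assert pair_distance(mx, mx) == 0.0
    assert pair_distance(mx, my) == pytest.approx(pair_distance(my, mx))
    assert pair_distance(mx, my) >= 0.0


def test_pair_distance_dimension_mismatch():
    with pytest.raises(ValueError):
        pair_distance(compute_moments(A), compute_moments(np.ones((2, 3))))


# --- weighted losses ---------------------------------------------------

def test_source_source_loss_identical_batches_is_zero(rng):
    x = rng.normal(size=(5, 3))
    assert source_source_loss([x, x.copy()], [0.4, 0.6]) == pytest.approx(0.0)


def test_source_source_loss_two_domain_hand_example():
    assert source_source_loss([A, B], [0.5, 0.5]) == pytest.approx(2.0)


def test_source_source_loss_doubles_m1_and_quadruples_m2():
    assert source_source_loss([2 * A, 2 * B], [0.5, 0.5]) == pytest.approx(7.0)


def test_source_source_loss_single_domain_guarded():
    with pytest.raises(ValueError):
        source_source_loss([A], [1.0])
    assert source_source_loss([A], [1.0], allow_single=True) == 0.0


def test_source_target_loss_single_source_hand_example():
    assert source_target_loss([A], B, [1.0]) == pytest.approx(8.0)


@pytest.mark.parametrize("mode", ["simplified", "paper-literal"])
def test_source_target_loss_zero_when_target_equals_sources(mode):
    x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
    assert source_target_loss([x, x], x, [0.5, 0.5], mode=mode) == pytest.approx(0.0)


def test_concentrating_weight_on_nearer_source_decreases_loss(rng):
    near = np.zeros((4, 2)) + 0.1
    far = np.zeros((4, 2)) + 3.0
    target = np.zeros((4, 2))
    uniform = source_target_loss([near, far], target, [0.5, 0.5])
    tilted = source_target_loss([near, far], target, [0.9, 0.1])
    assert tilted < uniform


def test_source_target_loss_rejects_empty_target():
    with pytest.raises(ValueError):
        source_target_loss([A], np.empty((0, 2)), [1.0])


def test_weights_must_sum_to_one():
    with pytest.raises(ValueError):
        source_source_loss([A, B], [0.5, 0.7])


# --- alignment_loss ----------------------------------------------------

def test_alignment_total_is_sum_of_components(rng):
    sources = [rng.normal(size=(6, 3)) for _ in range(2)]
    target = sources[1].copy()
    w = [0.5, 0.5]
    breakdown = alignment_loss(sources, target, w)
    assert isinstance(breakdown, AlignmentLossBreakdown)
    ss = source_source_loss(sources, w)
    st = source_target_loss(sources, target, w)
    assert breakdown.total == pytest.approx(ss + st, rel=1e-9)
    assert np.all(breakdown.pairwise_distances >= 0)
    assert breakdown.pairwise_distances.shape == (3, 3)


def test_alignment_zero_when_all_domains_identical(rng):
    x = rng.normal(size=(5, 4))
    breakdown = alignment_loss([x, x.copy(), x.copy()], x.copy(), np.full(3, 1 / 3))
    assert float(breakdown.total) == pytest.approx(0.0, abs=1e-12)


def test_alignment_matches_naive_oracle_on_five_random_domains(rng):
    domains = [rng.normal(size=(20, 3)) for _ in range(5)]
    target = rng.normal(size=(20, 3))
    w = rng.random(5)
    w /= w.sum()
    breakdown = alignment_loss(domains, target, w)
    expected = oracle_ss(domains, w) + oracle_st(domains, target, w)
    assert float(breakdown.total) == pytest.approx(expected, rel=1e-6)


def test_vectorized_losses_match_scalar_oracle_on_many_random_instances():
    """Eq. oracle equivalence over >=100 instances, N in {2,3,4}, dim 1..8."""
    rng = np.random.default_rng(2024)
    checked = 0
    for n in (2, 3, 4):
        for _ in range(35):
            dim = int(rng.integers(1, 9))
            rows = int(rng.integers(2, 12))
            batches = [rng.normal(size=(rows, dim)) * rng.uniform(0.5, 3) for _ in range(n)]
            target = rng.normal(size=(rows, dim))
            w = rng.random(n)
            w /= w.sum()
            assert source_source_loss(batches, w) == pytest.approx(
                oracle_ss(batches, w), rel=1e-6
            )
            assert source_target_loss(batches, target, w) == pytest.approx(
                oracle_st(batches, target, w), rel=1e-6
            )
            checked += 1
    assert checked >= 100


def test_losses_invariant_to_sample_order_within_batches(rng):
    batches = [rng.normal(size=(9, 4)) for _ in range(3)]
    target = rng.normal(size=(9, 4))
    w = np.full(3, 1 / 3)
    base = float(alignment_loss(batches, target, w).total)
    shuffled = [b[rng.permutation(9)] for b in batches]
    tgt_shuffled = target[rng.permutation(9)]
    assert float(alignment_loss(shuffled, tgt_shuffled, w).total) == pytest.approx(base)


@pytest.mark.parametrize("mode", ["simplified", "paper-literal"])
def test_alignment_gradient_matches_central_finite_differences(mode):
    """Autodiff vs central differences on a 2x2 source batch, tol 1e-4."""
    x = np.array([[0.3, -0.2], [1.1, 0.7]])
    target = np.array([[0.5, 0.1], [0.2, -0.3]])

    def value(data):
        return float(alignment_loss([data], target, [1.0], mode=mode, allow_single=True).total)

    t = Tensor(x, requires_grad=True)
    loss = alignment_loss([t], Tensor(target), [1.0], mode=mode, allow_single=True).total
    loss.backward()
    eps = 1e-6
    numeric = np.zeros_like(x)
    for i in range(2):
        for j in range(2):
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            numeric[i, j] = (value(xp) - value(xm)) / (2 * eps)
    assert np.abs(t.grad - numeric).max() < 1e-4
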