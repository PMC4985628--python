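import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln, logsumexp

from neutralsad import (
    CommunitySample,
    build_stirling_table,
    etienne_log_likelihood,
    etienne_mle,
    ewens_log_likelihood,
    ewens_mle,
    i_to_m,
    log_k_series,
    m_to_i,
    simulate_neutral_sample,
    stirling_log_rows,
)
from neutralsad.etienne import M_MAX, _species_log_coeffs


# ---------------------------------------------------------------- Stirling


def test_stirling_hand_values():
    t = build_stirling_table(10)
    # s̄(3,2) = s̄(2,1) + 2·s̄(2,2) = 3, by the recurrence done by hand
    assert t.log(3, 2) == pytest.approx(np.log(3), abs=1e-12)
    assert t.log(4, 1) == pytest.approx(np.log(6), abs=1e-12)  # (n−1)!
    for n in range(1, 11):
        assert t.log(n, n) == 0.0


def test_stirling_first_column_is_factorial():
    t = build_stirling_table(30)
    for n in (5, 12, 30):
        assert t.log(n, 1) == pytest.approx(gammaln(n), rel=1e-12)


@given(st.integers(min_value=2, max_value=60), st.data())
@settings(max_examples=80, deadline=None)
def test_stirling_recurrence_in_log_space(n, data):
    a = data.draw(st.integers(min_value=2, max_value=n))
    t = build_stirling_table(n + 1)
    lhs = t.log(n + 1, a)
    rhs = np.logaddexp(t.log(n, a - 1), np.log(n) + t.log(n, a)) if a <= n else t.log(n, a - 1)
    assert lhs == pytest.approx(rhs, abs=1e-12)


def test_sparse_rows_match_dense_table():
    t = build_stirling_table(40)
    rows = stirling_log_rows([3, 17, 40])
    for n in (3, 17, 40):
        np.testing.assert_allclose(rows[n], t.row(n), rtol=1e-14)


def test_dense_table_guard():
    with pytest.raises(MemoryError):
        build_stirling_table(100_000)


# ---------------------------------------------------------------- K(D, A)


def test_k_series_all_singletons_is_one():
    sad = CommunitySample.from_counts([1] * 6)
    ks = log_k_series(sad)
    assert len(ks) == 1
    assert ks.values[0] == pytest.approx(0.0, abs=1e-12)
    assert (ks.A_min, ks.A_max) == (6, 6)


def test_k_series_single_species_is_stirling_column():
    J = 9
    sad = CommunitySample.from_counts([J])
    ks = log_k_series(sad)
    t = build_stirling_table(J)
    expect = np.array(
        [t.log(J, A) + gammaln(A) - gammaln(J) for A in range(1, J + 1)]
    )
    np.testing.assert_allclose(ks.values, expect, atol=1e-12)


def _brute_force_log_k(sad):
    """Exhaustive enumeration of K(D,A) over allocations {a_i}: the oracle."""
    t = build_stirling_table(max(sad.abundances))
    out = {}
    for alloc in itertools.product(*(range(1, n + 1) for n in sad.abundances)):
        A = sum(alloc)
        term = sum(
            t.log(n, a) + gammaln(a) - gammaln(n)
            for n, a in zip(sad.abundances, alloc)
        )
        out[A] = np.logaddexp(out[A], term) if A in out else term
    return np.array([out[A] for A in range(sad.S, sad.J + 1)])


@pytest.mark.parametrize(
    "abundances", [[2, 1], [3, 2], [4, 2, 1], [5, 3, 3, 1], [2, 2, 2]]
)
def test_k_series_matches_exhaustive_enumeration(abundances):
    sad = CommunitySample.from_counts(abundances)
    np.testing.assert_allclose(
        log_k_series(sad).values, _brute_force_log_k(sad), atol=1e-10
    )


def test_k_series_precondition_on_table():
    sad = CommunitySample.from_counts([5, 1])
    with pytest.raises(ValueError, match="exceeds"):
        log_k_series(sad, build_stirling_table(3))


@given(st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=6))
@settings(max_examples=60, deadline=None)
def test_k_series_is_order_invariant(counts):
    """K(D, A) depends on the abundance multiset only."""
    a = log_k_series(CommunitySample.from_counts(counts))
    b = log_k_series(CommunitySample.from_counts(counts[::-1]))
    np.testing.assert_allclose(a.values, b.values, atol=1e-12)


def test_species_coeff_endpoints():
    # c(1) = s̄(n,1)·0!/(n−1)! = 1 and c(n) = s̄(n,n)·(n−1)!/(n−1)! = 1
    t = build_stirling_table(12)
    c = _species_log_coeffs(12, t.row(12))
    assert c[0] == pytest.approx(0.0, abs=1e-12)
    assert c[-1] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------- likelihood


def test_j2_closed_forms():
    for theta, m in [(5.0, 0.5), (1.3, 0.2), (2.0, 0.9)]:
        I = m_to_i(m, 2)
        p_mono = math.exp(
            etienne_log_likelihood(CommunitySample.from_counts([2]), theta, m)
        )
        p_pair = math.exp(
            etienne_log_likelihood(CommunitySample.from_counts([1, 1]), theta, m)
        )
        assert p_mono == pytest.approx((theta + 1 + I) / ((I + 1) * (theta + 1)), abs=1e-12)
        assert p_pair == pytest.approx(I * theta / ((I + 1) * (theta + 1)), abs=1e-12)
        assert p_mono + p_pair == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("theta", [1.0, 5.0])
@pytest.mark.parametrize("m", [0.2, 0.8])
def test_partition_probabilities_normalize(partition_sads, theta, m):
    for J in range(2, 9):
        total = sum(
            np.exp(etienne_log_likelihood(s, theta, m)) for s in partition_sads[J]
        )
        assert total == pytest.approx(1.0, abs=1e-8), (J, theta, m)


def test_m_domain_errors():
    sad = CommunitySample.from_counts([2, 1])
    for m in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError, match="[mM] must be"):
            etienne_log_likelihood(sad, 1.0, m)


def test_kseries_must_belong_to_sad():
    ks = log_k_series(CommunitySample.from_counts([3, 1]))
    with pytest.raises(ValueError, match="different SAD"):
        etienne_log_likelihood(CommunitySample.from_counts([2, 2]), 1.0, 0.5, ks)


def test_reduces_to_ewens_as_m_approaches_one(rng):
    """Dispersal limitation vanishes as m → 1: Etienne must recover Ewens."""
    for J in (20, 60, 150, 200):
        sad = simulate_neutral_sample(8.0, 40.0, J, rng)
        for theta in (1.5, 10.0, 50.0):
            e_ew = ewens_log_likelihood(sad, theta)
            e_et = etienne_log_likelihood(sad, theta, 1 - 1e-9)
            assert abs(e_et - e_ew) / abs(e_ew) < 1e-4, (J, theta)


def test_i_m_round_trip():
    for m, J in [(0.1, 50), (0.99, 2000), (0.5, 2)]:
        assert i_to_m(m_to_i(m, J), J) == pytest.approx(m, rel=1e-9)


# ---------------------------------------------------------------- MLE


def test_mle_dominates_ewens(rng):
    """Ewens is the m → 1 boundary of Etienne, so the Etienne maximum cannot
    fall below the Ewens maximum."""
    for theta, I, J in [(10, 5.0, 300), (30, np.inf, 500), (5, 100.0, 200)]:
        sad = simulate_neutral_sample(theta, I, J, rng)
        et = etienne_mle(sad)
        ew = ewens_mle(sad)
        assert et.log_likelihood >= ew.log_likelihood - 1e-6
        assert et.log_likelihood <= 0
        assert et.I == pytest.approx(m_to_i(et.m, sad.J), rel=1e-9)


def test_mle_near_one_when_no_dispersal_limitation(rng):
    """Samples from the m = 1 (Ewens) process: m̂ sits at/near the cap and the
    two formulas agree — the no-significant-difference regime."""
    sad = simulate_neutral_sample(20.0, np.inf, 800, rng)
    et = etienne_mle(sad)
    ew = ewens_mle(sad)
    assert et.m > 0.99
    assert abs(et.log_likelihood - ew.log_likelihood) < 0.05
    if et.m == M_MAX:
        assert "m_upper" in et.boundary_flags


def test_mle_recovers_dispersal_limitation():
    """Strongly dispersal-limited samples yield m̂ well below 1 and a real
    median likelihood gain over Ewens (single samples can be weakly
    informative, so the assertion is on medians over replicates)."""
    devs, ms = [], []
    for r in range(10):
        sad = simulate_neutral_sample(
            30.0, m_to_i(0.05, 1500), 1500, np.random.default_rng(300 + r)
        )
        et = etienne_mle(sad)
        ew = ewens_mle(sad)
        devs.append(2 * (et.log_likelihood - ew.log_likelihood))
        ms.append(et.m)
    assert np.median(ms) < 0.5
    assert np.median(devs) > 2.0


def test_fit_invariant_to_abundance_order():
    counts = [8, 4, 4, 2, 1, 1]
    a = etienne_mle(CommunitySample.from_counts(counts))
    b = etienne_mle(CommunitySample.from_counts(counts[::-1]))
    assert a.theta == pytest.approx(b.theta, rel=1e-9)
    assert a.m == pytest.approx(b.m, rel=1e-9)


def test_degenerate_sads_are_flagged_not_raised():
    mono = etienne_mle(CommunitySample.from_counts([50]))
    assert "S_equals_1" in mono.boundary_flags
    singletons = etienne_mle(CommunitySample.from_counts([1] * 12))
    assert "S_equals_J" in singletons.boundary_flags
    for fit in (mono, singletons):
        assert np.isfinite(fit.log_likelihood)
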