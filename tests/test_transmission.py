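"""Mendelian screening, transmission counting and the single-marker TDT."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import triotdt as tdt
from triotdt.transmission import count_transmissions, mendelian_consistent, tally, tdt_test

from conftest import (
    ALL_TRIPLES,
    CONSISTENT_TRIPLES,
    cohort_from_triples,
    oracle_consistent,
    oracle_counts,
)


@pytest.mark.parametrize("triple", ALL_TRIPLES, ids=str)
def test_triple_logic_matches_enumeration(triple):
    """Consistency and het-parent counts agree with brute-force enumeration
    of parental transmissions for every dosage triple."""
    assert mendelian_consistent(*triple) == oracle_consistent(*triple)
    if oracle_consistent(*triple):
        assert count_transmissions(*triple) == oracle_counts(*triple)


def test_counting_is_symmetric_in_parents():
    for f, m, c in CONSISTENT_TRIPLES:
        assert count_transmissions(f, m, c) == count_transmissions(m, f, c)


def test_known_inconsistencies_rejected():
    assert not mendelian_consistent(0, 0, 1)  # two hom-ref parents, carrier child
    assert not mendelian_consistent(1, 0, 2)  # hom-alt child needs alt from both
    with pytest.raises(ValueError, match="inconsistent"):
        count_transmissions(0, 0, 1)
    with pytest.raises(ValueError):
        mendelian_consistent(3, 0, 0)


def test_tdt_statistic_examples():
    stat, p = tdt_test(7, 7)
    assert stat == 0.0 and p == pytest.approx(1.0)
    stat, _ = tdt_test(10, 0)
    assert stat == pytest.approx(10.0)
    stat0, p0 = tdt_test(0, 0)
    assert np.isnan(stat0) and p0 == 1.0
    with pytest.raises(ValueError):
        tdt_test(-1, 2)


@given(st.integers(0, 500), st.integers(0, 500))
def test_tdt_symmetric_and_matches_chisquare(p, q):
    s1, pv1 = tdt_test(p, q)
    s2, pv2 = tdt_test(q, p)
    if p + q == 0:
        assert pv1 == pv2 == 1.0
    else:
        assert s1 == s2 == pytest.approx((p - q) ** 2 / (p + q))
        assert pv1 == pytest.approx(stats.chi2.sf(s1, 1))


def test_tally_pins_single_events():
    cohort = cohort_from_triples([(1, 0, 1), (1, 0, 0), (0, 0, 0), (1, 1, 1), (1, 1, 2)])
    counts = tally(cohort, "true")
    pv = counts.per_variant
    assert list(zip(pv["p"], pv["q"])) == [(1, 0), (0, 1), (0, 0), (1, 1), (2, 0)]
    assert counts.totals == (4, 2)
    assert counts.n_excluded == 0


def test_tally_excludes_inconsistent_and_missing():
    cohort = cohort_from_triples([(1, 0, 1), (0, 0, 1), (1, 0, 1)])
    cohort.genotypes_observed[0, 2, 2] = -1  # missing child call at variant 2
    counts = tally(cohort, "observed")
    assert counts.per_variant["p"].tolist() == [1, 0, 0]
    assert counts.per_variant["n_excluded"].tolist() == [0, 1, 0]
    assert counts.n_excluded == 1 and counts.n_missing == 1


def test_null_transmission_is_balanced():
    """Random transmission: aggregate transmitted fraction 0.5 within 3 SE."""
    panel = tdt.sample_panel(20, 100, maf_cap=0.05, seed=3)
    cohort = tdt.simulate_trios(panel, 400, seed=4)
    counts = tally(cohort, "true")
    P, Q = counts.totals
    n = P + Q
    assert n > 5000
    assert abs(P / n - 0.5) < 3 * np.sqrt(0.25 / n)
    assert counts.n_excluded == 0  # true layer is consistent by construction


def test_event_total_never_grows_under_het_loss():
    """Scenarios 1-2 only remove or flip informative events, so P + Q cannot
    increase."""
    panel = tdt.sample_panel(20, 100, maf_cap=0.05, seed=5)
    cohort = tdt.simulate_trios(panel, 200, seed=6)
    base = sum(tally(cohort, "true").totals)
    for scenario in (1, 2):
        pert = tdt.inject_errors(cohort, tdt.ErrorSpec.make(scenario, 0.10), seed=7)
        assert sum(tally(pert).totals) <= base


def _discrete_pit(p_arr, q_arr, rng):
    """Randomized probability-integral transform of per-variant TDT outcomes.

    For a variant with n = p + q informative events, the null law of
    d = |p - q| comes from Binomial(n, 1/2). The randomized PIT
    U = P(D > d) + V * P(D = d) is exactly Uniform(0, 1) under the null, so
    uniformity of calibration can be KS-tested even though the TDT p-values
    themselves are discrete.
    """
    n = p_arr + q_arr
    d = np.abs(p_arr - q_arr)
    lo = (n - d) // 2
    hi = (n + d) // 2
    # P(D > d) = P(X < lo) + P(X > hi); P(D = d) = P(X = lo) + P(X = hi) (or one term if d = 0)
    p_gt = stats.binom.cdf(lo - 1, n, 0.5) + stats.binom.sf(hi, n, 0.5)
    p_eq = stats.binom.pmf(lo, n, 0.5) + np.where(d > 0, stats.binom.pmf(hi, n, 0.5), 0.0)
    return p_gt + rng.random(len(n)) * p_eq


def test_null_pvalues_uniform_under_exact_transform():
    """With no errors and no causal variants, per-variant transmission
    outcomes follow fair-coin transmission exactly: the randomized PIT of the
    TDT outcome is uniform (KS at 1%) over >= 5,000 informative variants."""
    panel = tdt.sample_panel(
        60, 100, maf_spectrum=lambda rng, k: 0.02 + 0.03 * rng.random(k),
        maf_cap=0.05, seed=8,
    )
    cohort = tdt.simulate_trios(panel, 250, seed=9)
    pv = tally(cohort, "true").per_variant
    keep = (pv["p"] + pv["q"]) >= 10
    assert keep.sum() >= 5000
    u = _discrete_pit(
        pv.loc[keep, "p"].to_numpy(), pv.loc[keep, "q"].to_numpy(),
        np.random.default_rng(10),
    )
    assert stats.kstest(u, "uniform").pvalue > 0.01
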