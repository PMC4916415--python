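"""Error-scenario specification and genotype flip injection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import triotdt as tdt
from triotdt.cohort import CHILD, FATHER, MOTHER
from triotdt.errors import PARENTS

SCENARIO_TARGETS = {1: (FATHER, MOTHER), 2: (CHILD,), 3: (FATHER, MOTHER), 4: (CHILD,)}


def test_spec_invariants_enforced():
    for s, want in ((1, PARENTS), (2, {"child"}), (3, PARENTS), (4, {"child"})):
        assert tdt.ErrorSpec.make(s, 0.05).targets == frozenset(want)
    with pytest.raises(ValueError):
        tdt.ErrorSpec(1, r1=0.01, r2=0.01, targets=PARENTS)  # scenario 1 needs r2 = 0
    with pytest.raises(ValueError):
        tdt.ErrorSpec(2, r1=0.01, targets=PARENTS)  # scenario 2 targets the child
    with pytest.raises(ValueError):
        tdt.ErrorSpec(3, r2=1.5, targets=PARENTS)  # rate out of range
    with pytest.raises(ValueError):
        tdt.ErrorSpec.make(5, 0.01)


def test_zero_rate_is_identity(small_cohort):
    pert = tdt.inject_errors(small_cohort, tdt.ErrorSpec.make(2, 0.0), seed=0)
    assert np.array_equal(pert.genotypes_observed, small_cohort.genotypes_observed)
    assert pert.perturbed


def test_boundary_rate_flips_every_child_het(small_cohort):
    pert = tdt.inject_errors(small_cohort, tdt.ErrorSpec.make(2, 1.0), seed=0)
    child_before = small_cohort.genotypes_observed[:, CHILD, :]
    child_after = pert.genotypes_observed[:, CHILD, :]
    assert not np.any(child_after == 1)
    assert np.array_equal(child_after == 0, (child_before == 0) | (child_before == 1))
    # parents bit-identical; true layer untouched
    assert np.array_equal(
        pert.genotypes_observed[:, :2, :], small_cohort.genotypes_observed[:, :2, :]
    )
    assert np.array_equal(pert.genotypes_true, small_cohort.genotypes_true)


@pytest.mark.parametrize("scenario", [1, 2, 3, 4])
def test_homalt_and_nontargets_untouched(small_cohort, scenario):
    spec = tdt.ErrorSpec.make(scenario, 1.0)
    pert = tdt.inject_errors(small_cohort, spec, seed=1)
    targeted = SCENARIO_TARGETS[scenario]
    untargeted = [m for m in (FATHER, MOTHER, CHILD) if m not in targeted]
    for m in untargeted:
        assert np.array_equal(
            pert.genotypes_observed[:, m, :], small_cohort.genotypes_observed[:, m, :]
        )
    homalt = small_cohort.genotypes_observed == 2
    assert np.array_equal(pert.genotypes_observed[homalt], small_cohort.genotypes_observed[homalt])


def test_flip_fraction_matches_rate():
    """Scenario-3 flips among parental hom-ref cells are Binomial(r2):
    observed fraction within 3 SE and not rejected by an exact test."""
    panel = tdt.sample_panel(10, 200, maf_cap=0.01, seed=2)
    cohort = tdt.simulate_trios(panel, 300, seed=3)
    r2 = 0.01
    pert = tdt.inject_errors(cohort, tdt.ErrorSpec.make(3, r2), seed=4)
    exposed = cohort.genotypes_observed[:, :2, :] == 0
    flipped = pert.genotypes_observed[:, :2, :] == 1
    n_exposed = int(exposed.sum())
    n_flipped = int((flipped & exposed).sum())
    assert abs(n_flipped / n_exposed - r2) < 3 * np.sqrt(r2 * (1 - r2) / n_exposed)
    assert stats.binomtest(n_flipped, n_exposed, r2).pvalue > 1e-4


def test_flips_nested_across_rates(small_cohort):
    """Same seed, increasing r1: every cell flipped at the lower rate is
    flipped at the higher rate (the coupling contract)."""
    lo = tdt.inject_errors(small_cohort, tdt.ErrorSpec.make(2, 0.02), seed=5)
    hi = tdt.inject_errors(small_cohort, tdt.ErrorSpec.make(2, 0.20), seed=5)
    flipped_lo = lo.genotypes_observed != small_cohort.genotypes_observed
    flipped_hi = hi.genotypes_observed != small_cohort.genotypes_observed
    assert np.all(flipped_hi[flipped_lo])


def test_double_injection_rejected(small_cohort):
    pert = tdt.inject_errors(small_cohort, tdt.ErrorSpec.make(1, 0.05), seed=6)
    with pytest.raises(ValueError, match="already"):
        tdt.inject_errors(pert, tdt.ErrorSpec.make(2, 0.05), seed=7)


@given(st.sampled_from([1, 2, 3, 4]), st.floats(0.0, 1.0, allow_nan=False))
def test_make_builds_valid_specs(scenario, rate):
    spec = tdt.ErrorSpec.make(scenario, rate)
    assert spec.scenario == scenario and spec.rate == rate
    if scenario in (1, 2):
        assert spec.r2 == 0.0
    else:
        assert spec.r1 == 0.0
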