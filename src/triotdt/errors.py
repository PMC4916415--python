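"""Non-symmetric genotype-calling error injection.

Two error modes matter for rare variants: a true heterozygote (0/1) called
as reference homozygote (0/0), with rate ``r1`` — by far the dominant mode —
and a true reference homozygote called heterozygote, with rate ``r2``. Four
canonical scenarios place one mode in one generation:

  1. r2 = 0, r1 in parents        3. r1 = 0, r2 in parents
  2. r2 = 0, r1 in offspring      4. r1 = 0, r2 in offspring

Homozygous-alternate calls are never altered: neither mode touches them and
rare-variant 1/1 genotypes are vanishingly rare anyway.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import CHILD, FATHER, MOTHER, TrioCohort

__all__ = ["ErrorSpec", "PARENTS", "inject_errors"]

PARENTS = frozenset({"father", "mother"})
_MEMBER_INDEX = {"father": FATHER, "mother": MOTHER, "child": CHILD}


@dataclasses.dataclass(frozen=True)
class ErrorSpec:
    """One error condition: scenario number, rates, and targeted members."""

    scenario: int
    r1: float = 0.0
    r2: float = 0.0
    targets: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.r1 <= 1.0 or not 0.0 <= self.r2 <= 1.0:
            raise ValueError("error rates must lie in [0, 1]")
        if not self.targets <= {"father", "mother", "child"}:
            raise ValueError(f"unknown target members: {set(self.targets)}")
        expected = {
            1: (self.r2 == 0.0, PARENTS),
            2: (self.r2 == 0.0, frozenset({"child"})),
            3: (self.r1 == 0.0, PARENTS),
            4: (self.r1 == 0.0, frozenset({"child"})),
        }
        if self.scenario not in expected:
            raise ValueError(f"scenario must be 1-4, got {self.scenario}")
        zero_ok, want_targets = expected[self.scenario]
        if not zero_ok or frozenset(self.targets) != want_targets:
            raise ValueError(
                f"scenario {self.scenario} requires "
                f"{'r2' if self.scenario in (1, 2) else 'r1'} = 0 and targets {set(want_targets)}"
            )

    @classmethod
    def make(cls, scenario: int, rate: float) -> "ErrorSpec":
        """Canonical spec for a scenario: ``rate`` is r1 for scenarios 1-2
        (het -> hom-ref) and r2 for scenarios 3-4 (hom-ref -> het)."""
        if scenario == 1:
            return cls(1, r1=rate, targets=PARENTS)
        if scenario == 2:
            return cls(2, r1=rate, targets=frozenset({"child"}))
        if scenario == 3:
            return cls(3, r2=rate, targets=PARENTS)
        if scenario == 4:
            return cls(4, r2=rate, targets=frozenset({"child"}))
        raise ValueError(f"scenario must be 1-4, got {scenario}")

    @property
    def rate(self) -> float:
        return self.r1 if self.scenario in (1, 2) else self.r2

    def label(self) -> str:
        who = "parents" if self.targets == PARENTS else "offspring"
        if self.scenario in (1, 2):
            return f"r2=0; r1={self.r1:g} {who}"
        return f"r1=0; r2={self.r2:g} {who}"


def inject_errors(cohort: TrioCohort, spec: ErrorSpec, seed: int = 0) -> TrioCohort:
    """Return a new cohort whose observed layer carries the scenario's errors.

    Each targeted (individual, variant) cell flips independently: an observed
    0/1 becomes 0/0 with probability r1; an observed 0/0 becomes 0/1 with
    probability r2. All other cells — untargeted members, hom-alt and missing
    calls — are untouched, as is the true layer.

    One uniform draw per (trio, member, variant) cell is consumed in a fixed
    order, so with the same seed the flip sets at two rates r < r' are
    nested: every cell flipped at r is also flipped at r'. Runs that compare
    conditions can therefore share a seed to couple them.

    Refuses to perturb a cohort twice: the error model is defined relative
    to the truth, not to already-corrupted calls.
    """
    if cohort.perturbed:
        raise ValueError("cohort already carries injected errors; inject only once")
    rng = np.random.default_rng(seed)
    u = rng.random(cohort.genotypes_observed.shape)
    obs = cohort.genotypes_observed.copy()
    for member in sorted(spec.targets):
        i = _MEMBER_INDEX[member]
        cell = obs[:, i, :]
        if spec.r1 > 0.0:
            cell[(cell == 1) & (u[:, i, :] < spec.r1)] = 0
        if spec.r2 > 0.0:
            cell[(cell == 0) & (u[:, i, :] < spec.r2)] = 1
    return TrioCohort(
        cohort.panel,
        cohort.genotypes_true,
        obs,
        transmission_record=cohort.transmission_record,
        child_affected=cohort.child_affected,
        perturbed=True,
    )
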