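"""Bayes engine for diagnostic testing.

Positive predictive value (PPV) of a single test, PPV after a battery of
sequentially applied tests (each administered only to positives of the
previous one), and expected fourfold tables for a finite screening
population.

This module is the diagnostic half of the testing analogy that underpins
the whole package: a diagnostic test with sensitivity Sens and specificity
Spec updates a disease prevalence exactly the way a significance test with
power 1-β and level α updates the prior probability of a true association.
The statistical half lives in :mod:`trpcalc.trp`; the two are linked by the
identity ``sequential_ppv(pi, k * [DiagnosticTest(power, 1 - alpha)])[-1]
== trp_after_k(...)`` which the test suite exercises on a grid.

Sequential tests are assumed conditionally independent given disease
status; correlated assays are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ParameterError

__all__ = [
    "DiagnosticTest",
    "FourfoldTable",
    "ppv",
    "expected_fourfold",
    "sequential_ppv",
]


@dataclass(frozen=True)
class DiagnosticTest:
    """Sensitivity/specificity pair characterising one diagnostic assay.

    Parameters
    ----------
    sensitivity : float
        P(test positive | diseased), in (0, 1].
    specificity : float
        P(test negative | healthy), in (0, 1].
    """

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity <= 1.0:
            raise ParameterError(
                f"sensitivity must be in (0, 1], got {self.sensitivity}"
            )
        if not 0.0 < self.specificity <= 1.0:
            raise ParameterError(
                f"specificity must be in (0, 1], got {self.specificity}"
            )


@dataclass(frozen=True)
class FourfoldTable:
    """Expected cell counts of a screening fourfold table.

    Cells are expected (real-valued) counts, not rounded integers, so that
    they sum to ``population_size`` exactly and chained calculations do not
    accumulate rounding error. Round for display only.
    """

    true_positive: float
    false_positive: float
    false_negative: float
    true_negative: float
    population_size: int

    def __post_init__(self) -> None:
        cells = (
            self.true_positive,
            self.false_positive,
            self.false_negative,
            self.true_negative,
        )
        if any(c < 0 for c in cells):
            raise ParameterError(f"fourfold cells must be non-negative, got {cells}")
        if not math.isclose(sum(cells), self.population_size, rel_tol=1e-9, abs_tol=1e-6):
            raise ParameterError(
                f"fourfold cells sum to {sum(cells)}, expected {self.population_size}"
            )

    @property
    def positives(self) -> float:
        """Expected number of individuals testing positive (TP + FP)."""
        return self.true_positive + self.false_positive

    @property
    def negatives(self) -> float:
        return self.false_negative + self.true_negative


def ppv(prevalence: float, test: DiagnosticTest) -> float:
    """Positive predictive value of a single test via Bayes' theorem.

    PPV = prev * Sens / (prev * Sens + (1 - prev) * (1 - Spec)).

    ``prevalence`` must lie strictly inside (0, 1): at the endpoints the
    posterior is trivial (equal to the prior) and the update carries no
    information, so those inputs are rejected rather than silently passed
    through.
    """
    if not 0.0 < prevalence < 1.0:
        raise ParameterError(f"prevalence must be in (0, 1), got {prevalence}")
    true_pos = prevalence * test.sensitivity
    false_pos = (1.0 - prevalence) * (1.0 - test.specificity)
    denom = true_pos + false_pos
    if denom == 0.0:
        raise ParameterError(
            "posterior undefined: the test can produce no positives "
            "(sensitivity and 1 - specificity both zero)"
        )
    return true_pos / denom


def expected_fourfold(
    population_size: int, prevalence: float, test: DiagnosticTest
) -> FourfoldTable:
    """Expected fourfold table for screening a finite population.

    Degenerate prevalences 0 and 1 are allowed here (the expected counts
    remain well defined), in contrast to :func:`ppv`.
    """
    if not isinstance(population_size, (int,)) or population_size < 1:
        raise ParameterError(
            f"population_size must be a positive integer, got {population_size}"
        )
    if not 0.0 <= prevalence <= 1.0:
        raise ParameterError(f"prevalence must be in [0, 1], got {prevalence}")
    n_diseased = population_size * prevalence
    n_healthy = population_size - n_diseased
    return FourfoldTable(
        true_positive=n_diseased * test.sensitivity,
        false_negative=n_diseased * (1.0 - test.sensitivity),
        true_negative=n_healthy * test.specificity,
        false_positive=n_healthy * (1.0 - test.specificity),
        population_size=population_size,
    )


def sequential_ppv(
    prevalence: float, tests: Sequence[DiagnosticTest]
) -> list[float]:
    """PPV after each stage of a battery of sequentially applied tests.

    Stage i is administered only to individuals who tested positive in
    stages 1..i-1, so the PPV after stage i-1 acts as the prevalence for
    stage i. Element ``i`` of the returned list is the PPV after tests
    ``1..i+1``, in application order.
    """
    if len(tests) == 0:
        raise ParameterError("sequential_ppv requires at least one test")
    posteriors: list[float] = []
    current = prevalence
    for test in tests:
        # a posterior can saturate to 1.0 in floating point; 1 is absorbing
        # under Bayes updating, so later stages simply stay there
        if current < 1.0:
            current = ppv(current, test)
        posteriors.append(current)
    return posteriors
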