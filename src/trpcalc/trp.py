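"""True report probability (TRP) calculus for replicated significance tests.

The TRP is the posterior probability that an association is real given a
statistically significant result — the statistical-testing analogue of a
diagnostic test's positive predictive value, with power 1-β playing the
role of sensitivity and the significance level α that of 1-specificity.
Its complement is the false positive report probability (FPRP) of
Wacholder et al.: TRP = 1 - FPRP.

For a single study with prior probability π,

    TRP = π (1-β) / (π (1-β) + (1-π) α).

When the same test (identical α and power) is run in k independent studies
and *all k* come out significant, chaining Bayes updates collapses to the
closed form

    TRP_k = π (1-β)^k / (π (1-β)^k + (1-π) α^k),

which depends only on (π, α, 1-β, k). Inverting for the per-study power
needed to hit a target TRP with k studies gives

    1-β = α [ TRP/(1-TRP) * (1-π)/π ]^(1/k).

Conventions used throughout the package:

* ``k`` counts TOTAL studies, the initial one included — "one replication
  study" means ``k = 2``.
* The closed form is evaluated on the log-odds scale,
  ``logit(TRP_k) = logit(π) + k (log power - log α)``, which cannot
  underflow for large k and makes the monotonicities exact in floating
  point.
* α is held constant across the studies of a design; heterogeneous chains
  are available through the experimental :func:`chain_posteriors` helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.special import expit, logit

from .errors import InfeasibleError, ParameterError

__all__ = [
    "StudyTest",
    "ReplicationDesign",
    "trp_single",
    "fprp",
    "trp_iterative",
    "trp_after_k",
    "required_power",
    "min_studies",
    "chain_posteriors",
]


@dataclass(frozen=True)
class StudyTest:
    """(α, power) pair characterising one statistical significance test.

    ``alpha`` must lie strictly inside (0, 1); ``power`` may equal 1 (the
    "optimal, close to unity" limit) but not 0.
    """

    alpha: float
    power: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.power <= 1.0:
            raise ParameterError(f"power must be in (0, 1], got {self.power}")

    @property
    def is_informative(self) -> bool:
        """Whether a significant result raises the posterior above the prior.

        False when power <= alpha: replication then cannot lift the TRP
        above π (at power == alpha the TRP is pinned at π for every k).
        """
        return self.power > self.alpha


@dataclass(frozen=True)
class ReplicationDesign:
    """Prior π plus k identically-powered studies.

    ``k`` counts total studies including the initial one.
    """

    prior: float
    k: int
    test: StudyTest

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ParameterError(f"prior must be in (0, 1), got {self.prior}")
        if not isinstance(self.k, int) or self.k < 1:
            raise ParameterError(f"k must be a positive integer, got {self.k}")


def chain_posteriors(prior: float, tests: Sequence[StudyTest]) -> list[float]:
    """Posterior after each study of a (possibly heterogeneous) chain.

    Experimental: the published framework assumes identical (α, power)
    across studies; this helper relaxes that, feeding each posterior in as
    the next study's prior. Element i is the TRP after studies 1..i+1.
    """
    if len(tests) == 0:
        raise ParameterError("chain_posteriors requires at least one test")
    if not 0.0 < prior < 1.0:
        raise ParameterError(f"prior must be in (0, 1), got {prior}")
    posteriors: list[float] = []
    current = prior
    for t in tests:
        num = current * t.power
        current = num / (num + (1.0 - current) * t.alpha)
        posteriors.append(current)
    return posteriors


def trp_single(design: ReplicationDesign) -> float:
    """TRP of a single study (k must be 1); use trp_after_k for chains."""
    if design.k != 1:
        raise ParameterError(
            f"trp_single requires k=1, got k={design.k}; use trp_after_k"
        )
    return trp_after_k(design)


def trp_after_k(design: ReplicationDesign) -> float:
    """Closed-form TRP after all k studies of a design are significant.

    Evaluated as ``expit(logit(pi) + k * (log power - log alpha))``;
    identical to iterating the single-study update k times (see
    :func:`trp_iterative`, and the grid identity in the test suite) but
    immune to underflow for large k.
    """
    t = design.test
    log_lr = math.log(t.power) - math.log(t.alpha)
    return float(expit(logit(design.prior) + design.k * log_lr))


def trp_iterative(design: ReplicationDesign) -> float:
    """TRP after k studies by explicit Bayes chaining.

    Applies the single-study update k times, feeding each posterior in as
    the next prior. Mathematically equal to :func:`trp_after_k`; kept as an
    independent route so the equivalence can be asserted rather than
    assumed.
    """
    return chain_posteriors(design.prior, [design.test] * design.k)[-1]


def fprp(design: ReplicationDesign) -> float:
    """False positive report probability: 1 - trp_after_k(design)."""
    return 1.0 - trp_after_k(design)


def required_power(
    prior: float, alpha: float, trp_target: float, k: int
) -> float:
    """Per-study power needed for k studies to reach a target TRP.

    Returns the exact real solution
    ``alpha * (odds(trp_target) / odds(prior)) ** (1/k)``; rounding is left
    to the presentation layer. Raises :class:`InfeasibleError` (naming the
    smallest feasible k) when the solution exceeds 1, i.e. the target is
    unreachable with k studies at this α and π.
    """
    if not 0.0 < prior < 1.0:
        raise ParameterError(f"prior must be in (0, 1), got {prior}")
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if not 0.0 < trp_target < 1.0:
        raise ParameterError(f"trp_target must be in (0, 1), got {trp_target}")
    if not isinstance(k, int) or k < 1:
        raise ParameterError(f"k must be a positive integer, got {k}")
    # log odds-ratio between target and prior
    delta = float(logit(trp_target) - logit(prior))
    log_power = math.log(alpha) + delta / k
    if log_power > 0.0:
        # feasible iff log(alpha) + delta/k <= 0
        min_k = math.ceil(delta / -math.log(alpha))
        raise InfeasibleError(
            f"TRP target {trp_target} is unreachable with k={k} studies at "
            f"alpha={alpha}, prior={prior}: required per-study power would be "
            f"{math.exp(log_power):.4g} > 1; smallest feasible k is {min_k}",
            min_feasible_k=min_k,
        )
    return math.exp(log_power)


def min_studies(
    prior: float,
    alpha: float,
    power: float,
    trp_target: float,
    k_max: int = 25,
) -> int:
    """Smallest k <= k_max with trp_after_k >= trp_target.

    Raises :class:`InfeasibleError` when power <= alpha and the target
    exceeds the prior (the TRP is then pinned at or below π for every k),
    or when no k within the bound suffices (the error reports the TRP
    achieved at k_max).
    """
    if not isinstance(k_max, int) or k_max < 1:
        raise ParameterError(f"k_max must be a positive integer, got {k_max}")
    test = StudyTest(alpha=alpha, power=power)
    if not test.is_informative and trp_target > prior:
        raise InfeasibleError(
            f"power ({power}) <= alpha ({alpha}): the TRP cannot rise above "
            f"the prior {prior}, so target {trp_target} is unreachable for any k"
        )
    for k in range(1, k_max + 1):
        if trp_after_k(ReplicationDesign(prior, k, test)) >= trp_target:
            return k
    best = trp_after_k(ReplicationDesign(prior, k_max, test))
    raise InfeasibleError(
        f"no k <= {k_max} reaches TRP {trp_target}; at k={k_max} the TRP is "
        f"{best:.6f}",
        best_trp=best,
    )
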