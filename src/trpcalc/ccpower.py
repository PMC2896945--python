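"""Power and sample size for a balanced case-control association study.

Links the TRP calculus to concrete study sizes. The design is
parameterised by q, the proportion of the *total* sample having both the
disease and the variant under investigation. With cases and controls in
equal numbers, P(case and variant) = 0.5 * p_case, so q determines the
variant frequency among cases as p_case = 2q; the control frequency
follows from the detectable odds ratio,

    odds(p_control) = odds(p_case) / OR.

Power is computed for the two-sided two-proportion z-test by normal
approximation — pooled variance under the null, unpooled under the
alternative, no continuity correction — with n_total/2 subjects per group.
This is a documented convention of the package, chosen because it
reproduces the anchor points used in the package's validation (total
n = 820 at q = 0.2, OR = 1.5, α = 0.05 gives power ≈ 0.79-0.80) without a
bespoke formula; it is one of several standard conventions that agree to
about ±0.02 at those operating points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ParameterError
from .trp import ReplicationDesign, StudyTest, trp_after_k

__all__ = [
    "CaseControlDesign",
    "implied_frequencies",
    "power_cc",
    "n_for_power",
    "trp_vs_n",
]

_N_MIN = 4  # smallest balanced design: two cases, two controls


@dataclass(frozen=True)
class CaseControlDesign:
    """Balanced case-control design detecting an odds ratio.

    Parameters
    ----------
    n_total : int
        Total subjects, split equally into cases and controls; positive
        and even.
    q : float
        Proportion of the total sample with both disease and variant, in
        (0, 0.5); implies a case-group variant frequency of 2q.
    odds_ratio : float
        Detectable effect size, >= 1 (1 is the null; smaller-than-one
        effects are out of scope).
    alpha : float
        Two-sided significance level, in (0, 1).
    """

    n_total: int
    q: float
    odds_ratio: float = 1.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not isinstance(self.n_total, int) or self.n_total < _N_MIN:
            raise ParameterError(
                f"n_total must be an integer >= {_N_MIN}, got {self.n_total}"
            )
        if self.n_total % 2 != 0:
            raise ParameterError(
                f"n_total must be even (equal allocation), got {self.n_total}"
            )
        if not 0.0 < self.q < 0.5:
            raise ParameterError(f"q must be in (0, 0.5), got {self.q}")
        if self.odds_ratio < 1.0:
            raise ParameterError(
                f"odds_ratio must be >= 1, got {self.odds_ratio}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")


def implied_frequencies(design: CaseControlDesign) -> tuple[float, float]:
    """Variant frequencies (p_case, p_control) implied by (q, odds_ratio).

    p_case = 2q; p_control solves odds(p_control) = odds(p_case) / OR.
    """
    p_case = 2.0 * design.q
    if p_case >= 1.0:
        raise ParameterError(f"2q must be below 1, got {p_case}")
    odds_control = (p_case / (1.0 - p_case)) / design.odds_ratio
    p_control = odds_control / (1.0 + odds_control)
    return p_case, p_control


def power_cc(design: CaseControlDesign) -> float:
    """Two-sided two-proportion z-test power of the design.

    Normal approximation with pooled variance under H0 and unpooled under
    H1; strictly increasing in n_total. Equals α exactly when the odds
    ratio is 1.
    """
    p1, p0 = implied_frequencies(design)
    m = design.n_total // 2
    delta = p1 - p0
    p_bar = 0.5 * (p1 + p0)
    se_null = np.sqrt(2.0 * p_bar * (1.0 - p_bar) / m)
    se_alt = np.sqrt((p1 * (1.0 - p1) + p0 * (1.0 - p0)) / m)
    z_crit = norm.ppf(1.0 - design.alpha / 2.0)
    upper = norm.cdf((delta - z_crit * se_null) / se_alt)
    lower = norm.cdf((-delta - z_crit * se_null) / se_alt)
    return float(upper + lower)


def n_for_power(
    q: float,
    odds_ratio: float,
    alpha: float,
    power_target: float,
) -> int:
    """Smallest even total sample size whose power reaches the target.

    The returned n is the exact threshold: power at n - 2 falls short of
    the target while power at n meets it. Raises for targets at or below
    α, which any balanced design exceeds.
    """
    if not 0.0 < power_target < 1.0:
        raise ParameterError(
            f"power_target must be in (0, 1), got {power_target}"
        )
    if power_target <= alpha:
        raise ParameterError(
            f"power_target ({power_target}) must exceed alpha ({alpha}); "
            "any design attains the significance level"
        )

    def _power(n: int) -> float:
        return power_cc(CaseControlDesign(n, q, odds_ratio, alpha))

    # bracket by doubling, then bisect on even n
    lo, hi = _N_MIN, _N_MIN
    while _power(hi) < power_target:
        lo, hi = hi, hi * 2
        if hi > 100_000_000:
            raise ParameterError(
                f"power target {power_target} unreachable at odds_ratio="
                f"{odds_ratio} (no finite sample size suffices)"
            )
    if _power(lo) >= power_target:
        return lo
    while hi - lo > 2:
        mid = (lo + hi) // 2
        mid -= mid % 2
        if _power(mid) >= power_target:
            hi = mid
        else:
            lo = mid
    return hi


def trp_vs_n(
    prior: float,
    alpha: float,
    k: int,
    q: float,
    odds_ratio: float,
    n_grid: Sequence[int],
) -> pd.DataFrame:
    """Table of (n, power, trp) linking per-study sample size to final TRP.

    For each per-study total n in the grid the power of the case-control
    test is computed and plugged into the k-study TRP closed form. Rows
    keep the grid's order.
    """
    if len(n_grid) == 0:
        raise ParameterError("trp_vs_n requires a non-empty n grid")
    rows = []
    for n in n_grid:
        power = power_cc(CaseControlDesign(int(n), q, odds_ratio, alpha))
        trp = trp_after_k(
            ReplicationDesign(prior, k, StudyTest(alpha=alpha, power=power))
        )
        rows.append({"n": int(n), "power": power, "trp": trp})
    return pd.DataFrame(rows, columns=["n", "power", "trp"])
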