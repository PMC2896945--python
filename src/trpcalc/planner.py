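"""Replication-strategy enumeration and curve-grid generation.

Turns the TRP calculus into study plans: for each candidate number of
studies k the per-study power required to hit the target TRP is inverted
from the closed form, the per-study sample size follows from the
case-control power model, and the plans can be ranked by total sample
size. Also emits the long-format tables behind the package's standard
plots (TRP vs prior, power vs sample size); plotting itself is left to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .ccpower import CaseControlDesign, n_for_power, power_cc
from .errors import InfeasibleError, ParameterError
from .trp import ReplicationDesign, StudyTest, required_power, trp_after_k

__all__ = [
    "Scenario",
    "Strategy",
    "enumerate_strategies",
    "cheapest_strategy",
    "trp_curves",
    "power_sample_grid",
    "strategies_to_frame",
]

_N_MIN = 4


@dataclass(frozen=True)
class Scenario:
    """Fixed parameters of a planning problem.

    Bundles the prior probability of association, the per-study
    significance level, the desired final TRP, the case-control nuisance
    parameters (q, detectable odds ratio), and the inclusive range of
    study counts to consider.
    """

    prior: float
    alpha: float
    trp_target: float
    q: float
    odds_ratio: float = 1.5
    k_range: tuple[int, int] = (1, 4)

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ParameterError(f"prior must be in (0, 1), got {self.prior}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.trp_target < 1.0:
            raise ParameterError(
                f"trp_target must be in (0, 1), got {self.trp_target}"
            )
        k_min, k_max = self.k_range
        if k_min < 1 or k_max < k_min:
            raise ParameterError(
                f"k_range must be a non-empty range of positive ints, got {self.k_range}"
            )


@dataclass(frozen=True)
class Strategy:
    """One replication plan: k studies of a common size and power.

    ``per_study_power`` is the exact (unrounded) required power;
    ``nominal_power`` its two-decimal presentation. ``achieved_power`` is
    the power actually delivered by ``per_study_n`` subjects, which can
    differ slightly because sample sizes are integers. ``achieved_trp`` is
    recomputed from the exact required power, so a feasible strategy
    reproduces the scenario's target by construction.
    """

    k: int
    per_study_n: Optional[int]
    per_study_power: Optional[float]
    achieved_trp: Optional[float]
    achieved_power: Optional[float] = None
    feasible: bool = True
    note: str = ""
    total_n: Optional[int] = field(init=False, default=None)

    def __post_init__(self) -> None:
        if self.feasible:
            if self.per_study_n is None or self.per_study_power is None:
                raise ParameterError("feasible strategies need n and power")
            object.__setattr__(self, "total_n", self.k * self.per_study_n)

    @property
    def nominal_power(self) -> Optional[float]:
        return None if self.per_study_power is None else round(self.per_study_power, 2)


def enumerate_strategies(scenario: Scenario) -> list[Strategy]:
    """All replication plans over the scenario's k range, sorted by k.

    Each feasible k gets the exact required per-study power, the smallest
    even per-study n delivering it, and the achieved TRP. Infeasible k
    (required power above 1) are kept in the list with ``feasible=False``
    so the report is explicit about *why* small k fail. If every k is
    infeasible an :class:`InfeasibleError` is raised rather than an empty
    list returned silently.
    """
    k_min, k_max = scenario.k_range
    strategies: list[Strategy] = []
    for k in range(k_min, k_max + 1):
        try:
            power = required_power(
                scenario.prior, scenario.alpha, scenario.trp_target, k
            )
        except InfeasibleError as err:
            strategies.append(
                Strategy(
                    k=k,
                    per_study_n=None,
                    per_study_power=None,
                    achieved_trp=None,
                    feasible=False,
                    note=str(err),
                )
            )
            continue
        if power > scenario.alpha:
            n = n_for_power(scenario.q, scenario.odds_ratio, scenario.alpha, power)
        else:
            # target already below what the smallest design delivers
            n = _N_MIN
        achieved_power = power_cc(
            CaseControlDesign(n, scenario.q, scenario.odds_ratio, scenario.alpha)
        )
        achieved_trp = trp_after_k(
            ReplicationDesign(
                scenario.prior, k, StudyTest(alpha=scenario.alpha, power=power)
            )
        )
        strategies.append(
            Strategy(
                k=k,
                per_study_n=n,
                per_study_power=power,
                achieved_power=achieved_power,
                achieved_trp=achieved_trp,
            )
        )
    if not any(s.feasible for s in strategies):
        raise InfeasibleError(
            f"no k in {scenario.k_range} can reach TRP {scenario.trp_target} "
            f"at alpha={scenario.alpha}, prior={scenario.prior}; "
            f"smallest feasible k is "
            f"{min(_min_k(s) for s in strategies if _min_k(s) is not None)}"
        )
    return strategies


def _min_k(strategy: Strategy) -> Optional[int]:
    # parse nothing: infeasible strategies were built from InfeasibleError
    # whose min_feasible_k is monotone in k, so recompute is unnecessary;
    # the note already names it. Used only for the aggregate error message.
    import re

    m = re.search(r"smallest feasible k is (\d+)", strategy.note)
    return int(m.group(1)) if m else None


def cheapest_strategy(scenario: Scenario) -> Strategy:
    """The feasible plan with the smallest total sample size.

    Ties are broken toward fewer studies (smaller k): running fewer
    studies at equal total cost is operationally simpler.
    """
    feasible = [s for s in enumerate_strategies(scenario) if s.feasible]
    return min(feasible, key=lambda s: (s.total_n, s.k))


def strategies_to_frame(strategies: Sequence[Strategy]) -> pd.DataFrame:
    """Strategies as a tidy DataFrame (one row per k)."""
    return pd.DataFrame(
        [
            {
                "k": s.k,
                "per_study_n": s.per_study_n,
                "total_n": s.total_n,
                "per_study_power": s.per_study_power,
                "nominal_power": s.nominal_power,
                "achieved_power": s.achieved_power,
                "achieved_trp": s.achieved_trp,
                "feasible": s.feasible,
                "note": s.note,
            }
            for s in strategies
        ]
    )


def trp_curves(
    prior_grid: Sequence[float],
    alpha_list: Sequence[float],
    power_list: Sequence[float],
    k_list: Sequence[int],
) -> pd.DataFrame:
    """Long-format TRP surface over (π, α, power, k) for plotting.

    One row per grid combination, with the closed-form TRP in the ``trp``
    column.
    """
    for name, grid in (
        ("prior_grid", prior_grid),
        ("alpha_list", alpha_list),
        ("power_list", power_list),
        ("k_list", k_list),
    ):
        if len(grid) == 0:
            raise ParameterError(f"{name} must be non-empty")
    rows = []
    for pi in prior_grid:
        for alpha in alpha_list:
            for power in power_list:
                for k in k_list:
                    design = ReplicationDesign(
                        pi, int(k), StudyTest(alpha=alpha, power=power)
                    )
                    rows.append(
                        {
                            "prior": pi,
                            "alpha": alpha,
                            "power": power,
                            "k": int(k),
                            "trp": trp_after_k(design),
                        }
                    )
    return pd.DataFrame(rows, columns=["prior", "alpha", "power", "k", "trp"])


def power_sample_grid(
    prior: float,
    alpha: float,
    trp_targets: Sequence[float],
    k_list: Sequence[int],
    q_list: Sequence[float],
    odds_ratio: float,
    n_grid: Sequence[int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Data for the back-to-back power/sample-size panels.

    Returns ``(power_panel, trp_panel)``: the first maps per-study sample
    size (and q) to power, the second maps (TRP target, k) to the required
    per-study power. Joining the two on the power column reads off the
    sample size a given strategy needs.
    """
    for name, grid in (
        ("trp_targets", trp_targets),
        ("k_list", k_list),
        ("q_list", q_list),
        ("n_grid", n_grid),
    ):
        if len(grid) == 0:
            raise ParameterError(f"{name} must be non-empty")
    power_rows = []
    for q in q_list:
        for n in n_grid:
            power_rows.append(
                {
                    "n": int(n),
                    "q": q,
                    "power": power_cc(
                        CaseControlDesign(int(n), q, odds_ratio, alpha)
                    ),
                }
            )
    trp_rows = []
    for target in trp_targets:
        for k in k_list:
            try:
                power = required_power(prior, alpha, target, int(k))
                feasible = True
            except InfeasibleError:
                power, feasible = float("nan"), False
            trp_rows.append(
                {
                    "trp_target": target,
                    "k": int(k),
                    "required_power": power,
                    "feasible": feasible,
                }
            )
    return (
        pd.DataFrame(power_rows, columns=["n", "q", "power"]),
        pd.DataFrame(
            trp_rows, columns=["trp_target", "k", "required_power", "feasible"]
        ),
    )
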