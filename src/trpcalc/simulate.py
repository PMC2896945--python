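"""Monte-Carlo oracle: forward simulation of research programs.

This module is the package's ground-truth engine. It never calls the
closed-form TRP: it *generates* research programs — a truth status drawn
with probability π, followed by k independent studies — and counts how
often all-significant chains correspond to a true association. Agreement
between these empirical frequencies and the analytic formulas is the
primary validation of the whole calculus.

Three levels of fidelity:

* :func:`simulate_bernoulli_programs` draws study outcomes directly as
  Bernoulli(power) / Bernoulli(α) coins — the distilled probability model.
* :func:`generate_cc_table` / :func:`empirical_power_cc` generate actual
  2x2 case-control tables by binomial sampling and apply the same
  two-proportion z-test the power model assumes.
* :func:`simulate_full_pipeline` composes the two: truth draw, k
  case-control datasets, k tests, empirical TRP — closing the loop between
  the data level and the closed form.

Truth is drawn once per research program: all k studies of a chain share
it, and the empirical TRP conditions on *all* k studies being significant
(the replication-success event), mirroring sequential diagnostic testing
of positives only. Same seed and config give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .ccpower import CaseControlDesign, implied_frequencies
from .errors import ParameterError
from .planner import Scenario
from .trp import ReplicationDesign, StudyTest, required_power

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "RejectionRate",
    "simulate_bernoulli_programs",
    "generate_cc_table",
    "empirical_power_cc",
    "simulate_full_pipeline",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducibility and effort knobs for the Monte-Carlo engine.

    Defaults (500'000 programs for TRP checks, 200'000 per-design study
    replicates for rejection-rate checks) keep 3-standard-error bands
    tighter than the analytic tolerances they validate while running in
    seconds.
    """

    seed: int = 0
    n_programs: int = 500_000
    n_sims: int = 200_000

    def __post_init__(self) -> None:
        if self.n_programs < 1 or self.n_sims < 1:
            raise ParameterError("n_programs and n_sims must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Counts and rates from one batch of simulated research programs.

    ``empirical_trp`` is the fraction of all-significant chains whose
    truth was H1; it is None (with ``trp_defined`` False) when no chain
    was all-significant, never NaN.
    """

    n_programs: int
    n_significant_chains: int
    n_true_among_them: int
    empirical_trp: Optional[float]
    standard_error: Optional[float]
    empirical_power: Optional[float]
    empirical_type1: Optional[float]

    def __post_init__(self) -> None:
        if not 0 <= self.n_true_among_them <= self.n_significant_chains <= self.n_programs:
            raise ParameterError("inconsistent simulation counts")

    @property
    def trp_defined(self) -> bool:
        return self.empirical_trp is not None


def _trp_result(
    truth: np.ndarray, rejects: np.ndarray, n_programs: int
) -> SimulationResult:
    all_sig = rejects.all(axis=1)
    n_sig = int(all_sig.sum())
    n_true = int((all_sig & truth).sum())
    if n_sig > 0:
        trp = n_true / n_sig
        se = float(np.sqrt(trp * (1.0 - trp) / n_sig))
    else:
        trp = se = None
    n_h1 = int(truth.sum())
    emp_power = float(rejects[truth].mean()) if n_h1 > 0 else None
    emp_t1 = float(rejects[~truth].mean()) if n_h1 < n_programs else None
    return SimulationResult(
        n_programs=n_programs,
        n_significant_chains=n_sig,
        n_true_among_them=n_true,
        empirical_trp=trp,
        standard_error=se,
        empirical_power=emp_power,
        empirical_type1=emp_t1,
    )


def simulate_bernoulli_programs(
    design: ReplicationDesign, config: SimulationConfig
) -> SimulationResult:
    """Empirical TRP from programs whose studies are Bernoulli coins.

    Each program draws truth H1 with probability π; each of its k studies
    rejects independently with probability power (under H1) or α (under
    H0). The empirical TRP is the H1 fraction among programs where all k
    studies rejected.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_programs
    truth = rng.random(n) < design.prior
    p_reject = np.where(truth, design.test.power, design.test.alpha)
    rejects = rng.random((n, design.k)) < p_reject[:, None]
    return _trp_result(truth, rejects, n)


def generate_cc_table(
    design: CaseControlDesign,
    truth: str,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One synthetic 2x2 case-control table (rows: case/control; cols:
    variant carrier / non-carrier).

    Under H1 the variant counts are Binomial(n/2, 2q) among cases and
    Binomial(n/2, p_control-from-OR) among controls; under H0 the effect
    is shrunk to the null and both groups share the case frequency 2q.
    Cells always sum to n_total.
    """
    if truth not in ("H0", "H1"):
        raise ParameterError(f"truth must be 'H0' or 'H1', got {truth!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_case, p_control = implied_frequencies(design)
    if truth == "H0":
        p_control = p_case
    m = design.n_total // 2
    case_carriers = int(rng.binomial(m, p_case))
    control_carriers = int(rng.binomial(m, p_control))
    return np.array(
        [
            [case_carriers, m - case_carriers],
            [control_carriers, m - control_carriers],
        ],
        dtype=np.int64,
    )


@dataclass(frozen=True)
class RejectionRate:
    """Empirical rejection fraction with its binomial standard error."""

    rate: float
    standard_error: float
    n_sims: int
    n_degenerate: int


def _z_reject(
    case_carriers: np.ndarray,
    control_carriers: np.ndarray,
    m: int,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided pooled-variance two-proportion z-test.

    Returns (reject, degenerate) boolean arrays; degenerate tables (all
    carriers or none across both groups) cannot reject.
    """
    p1_hat = case_carriers / m
    p0_hat = control_carriers / m
    p_pool = (case_carriers + control_carriers) / (2 * m)
    var = p_pool * (1.0 - p_pool) * (2.0 / m)
    degenerate = var <= 0.0
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1_hat - p0_hat) / np.sqrt(var)
    reject = np.where(degenerate, False, np.abs(z) > z_crit)
    return reject, degenerate


def empirical_power_cc(
    design: CaseControlDesign, truth: str, config: SimulationConfig
) -> RejectionRate:
    """Rejection rate of the two-proportion z-test over simulated tables.

    Under H1 this estimates power, under H0 the type-I error; degenerate
    tables count as non-rejections and are tallied separately.
    """
    if truth not in ("H0", "H1"):
        raise ParameterError(f"truth must be 'H0' or 'H1', got {truth!r}")
    rng = np.random.default_rng(config.seed)
    p_case, p_control = implied_frequencies(design)
    if truth == "H0":
        p_control = p_case
    m = design.n_total // 2
    case_carriers = rng.binomial(m, p_case, size=config.n_sims)
    control_carriers = rng.binomial(m, p_control, size=config.n_sims)
    reject, degenerate = _z_reject(case_carriers, control_carriers, m, design.alpha)
    rate = float(reject.mean())
    return RejectionRate(
        rate=rate,
        standard_error=float(np.sqrt(rate * (1.0 - rate) / config.n_sims)),
        n_sims=config.n_sims,
        n_degenerate=int(degenerate.sum()),
    )


def simulate_full_pipeline(
    scenario: Scenario,
    k: int,
    config: SimulationConfig,
    n_per_study: Optional[int] = None,
) -> SimulationResult:
    """End-to-end empirical TRP: truth draw -> k datasets -> k tests.

    Each program draws one truth status; k case-control datasets of
    ``n_per_study`` subjects are generated accordingly and tested with the
    two-proportion z-test at the scenario's α. When ``n_per_study`` is
    omitted it is derived from the scenario (required power for k studies,
    then the smallest n delivering it).
    """
    from .ccpower import n_for_power  # deferred: avoids cycle at import time

    if n_per_study is None:
        power = required_power(scenario.prior, scenario.alpha, scenario.trp_target, k)
        n_per_study = n_for_power(scenario.q, scenario.odds_ratio, scenario.alpha, power)
    design = CaseControlDesign(
        n_per_study, scenario.q, scenario.odds_ratio, scenario.alpha
    )
    # validates k and the prior through the design type
    ReplicationDesign(scenario.prior, k, StudyTest(scenario.alpha, 0.5))
    rng = np.random.default_rng(config.seed)
    n = config.n_programs
    p_case, p_control = implied_frequencies(design)
    m = design.n_total // 2
    truth = rng.random(n) < scenario.prior
    p0_vec = np.where(truth, p_control, p_case)  # H0 programs carry no effect
    rejects = np.empty((n, k), dtype=bool)
    for j in range(k):
        case_carriers = rng.binomial(m, p_case, size=n)
        control_carriers = rng.binomial(m, p0_vec)
        rejects[:, j], _ = _z_reject(case_carriers, control_carriers, m, design.alpha)
    return _trp_result(truth, rejects, n)
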