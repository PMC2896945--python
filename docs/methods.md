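# Methods

## Probability model

trpcalc treats a significance test as a binary classifier of hypotheses.
A hypothesis is true (H1) with prior probability π; a study rejects H0
with probability 1−β when H1 holds and α when H0 holds. Conditioning on a
rejection gives the true report probability

TRP = π(1−β) / (π(1−β) + (1−π)α),

formally identical to the positive predictive value of a diagnostic test
with sensitivity 1−β, specificity 1−α and prevalence π. The package keeps
both vocabularies as separate modules (`diagnostics`, `trp`) and asserts
their equivalence as a tested identity rather than sharing code, so each
module reads naturally in its own field.

### Replication

For k studies with identical (α, 1−β), each run in an independent sample,
the posterior after conditioning on *all k* being significant follows by
feeding each posterior in as the next study's prior. Because the update
multiplies the odds by the constant likelihood ratio (1−β)/α, the chain
collapses to

odds(TRP_k) = odds(π) · [(1−β)/α]^k.

`trp_after_k` evaluates exactly this log-odds form
(`expit(logit(π) + k·(log power − log α))`): it cannot underflow for
large k, and monotonicity in every argument is exact in floating point up
to saturation of `expit` at 1.0 (which the property tests treat as the
one admissible tie). `trp_iterative` implements the explicit chain and is
kept as an independent route purely so the equivalence can be asserted on
a dense grid (tolerance 1e-12) instead of assumed.

Conventions:

- **k counts total studies**, the initial one included; "one replication
  study" is k = 2. Every docstring repeats this to prevent off-by-one
  planning errors.
- α and power are constant across the studies of a design. Heterogeneous
  chains are available through `chain_posteriors`, which is marked
  experimental and not used by the planner.
- power = 1 is admitted (the perfect-test limit); α ∈ {0, 1} is rejected.
- A test with power ≤ α is flagged (`StudyTest.is_informative` is False):
  significant results then cannot raise the posterior above π, and
  `min_studies` reports such targets as infeasible outright.

### Inversion

`required_power` solves the closed form for the per-study power,
α·[odds(TRP*)/odds(π)]^(1/k), returning the exact real solution; rounding
to two decimals is presentation only, because published plans mix nominal
(rounded) and achieved values and the two are otherwise irreconcilable.
When the solution exceeds 1 the target is unreachable with k studies and
the error names the smallest feasible k, ⌈(logit TRP* − logit π)/(−log α)⌉.

## Case-control power model

The link from power to sample size assumes a balanced case-control study
detecting an odds ratio OR for a binary variant. The parameterisation is
q, the proportion of the *total* sample with both disease and variant;
with half the sample being cases, the variant frequency among cases is
p1 = 2q, and the control frequency solves odds(p0) = odds(p1)/OR. Power
is the two-sided two-proportion z-test normal approximation with pooled
variance under H0 and unpooled variance under H1, n/2 per group, no
continuity correction.

This convention is a documented design choice, not a uniquely determined
formula: chi-square, z and log-OR Wald versions agree to within about
±0.02 at the operating points used for validation (n = 820, q = 0.2,
OR = 1.5 → power 0.790 here vs 0.798 published; n = 860 → 0.809), and a
continuity correction would shift power by more than that discrepancy.
The alternative reading of q as a proportion *among cases* reproduces the
anchors less well and was rejected. Consequences embraced rather than
hidden:

- `n_for_power` returns the exact even-n threshold for *this* convention
  (e.g. 842 for 80% power at q = 0.2, OR = 1.5, vs the published 820);
  tests and the planner treat sample sizes as agreeing within ±40.
- OR = 1 is admitted as the null limit (power = α exactly); OR < 1 is
  out of scope (code the variant so the detectable effect is ≥ 1).
- The default detectable odds ratio is 1.5, the conventional moderate
  effect size for single-variant association planning.

`n_for_power` brackets by doubling and bisects over even n (equal
allocation; odd requests are rounded up by construction), so the returned
n satisfies power(n−2) < target ≤ power(n) exactly — a linear-scan oracle
in the tests confirms this.

One known tension in the published plans themselves: the three-study,
power-0.50 row reports a final TRP of 0.95 where the closed form gives
0.938 (plausibly the achieved power of n = 420, ≈0.507, was used), and a
figure-derived "power 0.60 for three studies at π = 0.01" disagrees with
the inversion's 0.37. The planner always reports the closed-form value
and both the nominal and achieved power so such gaps are visible.

## Planner

`enumerate_strategies` maps each k in the scenario's range through
required_power → n_for_power → achieved TRP. Infeasible k are kept in the
output with an explanatory note instead of being dropped; a scenario with
no feasible k raises. `achieved_trp` is recomputed from the exact
(unrounded) required power, so every feasible row reproduces the target
by construction and self-validates. `cheapest_strategy` minimises total
subjects k·n, breaking ties toward fewer studies. Curve generators emit
long-format DataFrames (one row per grid point) rather than figures;
plotting is left to the caller so outputs stay testable and diffable.

## Monte-Carlo engine

The `simulate` module is the package's ground truth: it never calls the
closed form. A *research program* draws one truth status (H1 with
probability π) shared by all k of its studies; the empirical TRP is the
H1 fraction among programs whose k studies all rejected — the
replication-success event, mirroring sequential diagnostic testing of
positives only. Three fidelity levels:

1. **Bernoulli programs** — study outcomes drawn directly as coins with
   P(reject) = power or α. Validates the TRP algebra in isolation.
2. **Case-control tables** — binomial variant counts per arm, tested with
   the same pooled-variance z-test the power model assumes. Under H0 the
   effect is shrunk to the null with both arms at the case frequency 2q.
   Degenerate tables (no carriers or all carriers) cannot reject and are
   tallied. Validates the power convention and its type-I calibration.
3. **Full pipeline** — truth draw, k generated datasets, k tests,
   conditioning. Closes the loop between the data level and the closed
   form.

Defaults: 500'000 programs for TRP checks and 200'000 replicates for
rejection-rate checks, sizes at which the 3-standard-error agreement
bands are tighter than the analytic tolerances being validated while each
check still runs in seconds. All randomness flows through one
`numpy.random.Generator` seeded from `SimulationConfig.seed`; identical
seed and config give bit-identical results. When no chain is
all-significant the empirical TRP is reported as undefined (None with a
flag), never NaN. Note that rare-event scenarios (e.g. four studies of
power 0.20 at π = 0.015) leave only tens of significant chains out of
500'000 programs, so their empirical TRP carries a wide standard error;
that width is a property of the scenario, and the agreement checks use
the binomial SE computed from the realised chain count.

### What the simulations do and do not show

The generator implements the model's own assumptions: independent
studies, truth fixed per program, binomial sampling, constant α and
power. Passing agreement checks therefore validates the *calculus*, not
the model's fit to real research: publication bias, winner's-curse effect
inflation, between-study heterogeneity, correlated samples and
misspecified priors are all outside the model and outside these
simulations.

## Numerical and interface choices

- Expected fourfold counts are real-valued; rounding is presentation
  (the screening example's 10'940 positives arise exactly).
- `ppv` rejects prevalence 0 and 1 (the update would be vacuous);
  `expected_fourfold` allows them (counts stay well defined). Sequential
  batteries treat a posterior that saturates to 1.0 in floating point as
  absorbing.
- Probabilities are decimals everywhere (0.05, never "5%"); α defaults
  to 0.05.
- CLI exit codes separate usage errors (2), invalid parameter values (3)
  and infeasible targets (4); all numeric flags are validated before any
  computation so errors never leave partial output. Every output embeds a
  run record (subcommand, parameters, version, seed, timestamp); TSV
  outputs carry it as `#` comment lines and round-trip through
  `pandas.read_csv(..., sep="\t", comment="#")`.

## Limitations

- The power/sample-size convention is one reasonable choice among
  near-equivalent ones; sample sizes inherit a ±few-percent ambiguity.
- Only balanced 1:1 designs, allele-coded 2×2 tests, and effects coded as
  OR ≥ 1 are supported; no Hardy-Weinberg modelling, covariates, or
  unequal allocation.
- Prior elicitation is out of scope: π is a user input, and sensitivity
  over a grid of priors (`trp_curves`) is the supported way to explore it.
- Multi-stage designs with early stopping, FWER/FDR control across a
  variant panel, and joint analysis of combined samples are different
  procedures and are not modelled.
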