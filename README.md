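# trpcalc

Replication planning for association studies via the **true report
probability** (TRP) — the posterior probability that a statistically
significant association is real.

Genetic association studies (and "omics" screens generally) test many
hypotheses with low prior probability of being true, so a significant
p-value alone says little: most initial "discoveries" are false positives.
trpcalc quantifies this with a Bayesian calculus borrowed from diagnostic
testing, where the same arithmetic gives the positive predictive value
(PPV) of an assay, and turns it into a planning tool: how many replication
studies, at what power and sample size, does it take to make a significant
finding trustworthy?

## The model

A significance test with level α and power 1−β updates the prior
probability π of a true association exactly as a diagnostic test with
sensitivity 1−β and specificity 1−α updates a disease prevalence:

```
TRP = π(1−β) / (π(1−β) + (1−π)α)            (single study)
```

When the same test is run in k independent studies and **all k** are
significant, chaining the update collapses to a closed form on the odds
scale — the posterior odds are the prior odds times the likelihood ratio
((1−β)/α) to the k-th power:

```
TRP_k = π(1−β)^k / (π(1−β)^k + (1−π)α^k)
1−β   = α · [ TRP/(1−TRP) · (1−π)/π ]^(1/k)   (required per-study power)
```

TRP = 1 − FPRP, the false positive report probability of Wacholder et al.
Here k counts *total* studies, the initial one included. A balanced
case-control power model (two-sided two-proportion z-test, case-group
variant frequency 2q where q is the joint disease-and-variant proportion,
control frequency from the detectable odds ratio) links power to sample
size, so plans can be costed in subjects. A Monte-Carlo engine simulates
whole research programs — truth draw, k studies, conditioning on
all-significant chains — and is the package's independent check on every
formula.

## Worked example

Prior π = 0.015, α = 0.05, desired TRP 0.8, q = 0.2, detectable odds
ratio 1.5:

```
$ trpcalc plan --prior 0.015 --target-trp 0.8 --q 0.2 --k-min 2 --k-max 4 --format tsv
k   per_study_n  total_n  per_study_power  nominal_power  achieved_power  achieved_trp  feasible
2   864          1728     0.8103...        0.81           0.8109...       0.8           True
3   240          720      0.3202...        0.32           0.3205...       0.8           True
4   136          544      0.2012...        0.20           0.2019...       0.8           True
```

Two studies must each be powered at 0.81 (≈860 subjects each, 1728 in
total); four studies need only 0.20 power each (136 subjects each, 544 in
total). Replication beats brute-force size: the four-study plan reaches
the same TRP with less than a third of the subjects, which is why
`--cheapest` picks k = 4. Other entry points:

```
$ trpcalc trp --prior 0.015 --power 0.81 --studies 2     # -> trp 0.7999, rounds to 0.80
$ trpcalc power --target-power 0.8 --q 0.2               # -> n_total 842, power 0.801
$ trpcalc diagnostics --prevalence 0.001 --test 0.95,0.99 --test 0.95,0.99 --population 1000000
```

The last command reproduces the classic HIV screening illustration of the
same arithmetic: one Elisa pass over a million people yields PPV 0.087
with 10'940 expected positives; retesting the positives with a Western
blot of equal accuracy lifts the PPV to 0.9.

Everything the CLI does is a thin layer over the library
(`trpcalc.trp_after_k`, `required_power`, `power_cc`, `n_for_power`,
`enumerate_strategies`, `simulate_bernoulli_programs`, ...), which returns
plain floats, dataclasses and pandas DataFrames.

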