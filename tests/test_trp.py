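"""True report probability calculus: closed form, chaining, inversion."""

import math

import pytest

from trpcalc import (
    InfeasibleError,
    ParameterError,
    ReplicationDesign,
    StudyTest,
    chain_posteriors,
    fprp,
    min_studies,
    required_power,
    trp_after_k,
    trp_iterative,
    trp_single,
)


def design(prior, alpha, power, k=1):
    return ReplicationDesign(prior, k, StudyTest(alpha=alpha, power=power))


class TestSingleStudy:
    def test_high_power_still_below_half_at_low_prior(self):
        """Even 95% power cannot push a 1% prior past a coin toss."""
        value = trp_single(design(0.01, 0.01, 0.95))
        assert value == pytest.approx(0.4897, abs=5e-5)
        assert value < 0.5

    def test_uninformative_test_returns_prior(self):
        for c in (0.05, 0.3, 0.9):
            assert trp_single(design(0.27, c, c)) == pytest.approx(0.27, abs=1e-12)

    def test_half_prior_oracle(self):
        # hand Bayes arithmetic: 0.8 / (0.8 + 0.05)
        assert trp_single(design(0.5, 0.05, 0.8)) == pytest.approx(
            0.8 / 0.85, abs=1e-12
        )

    def test_rejects_multi_study_designs(self):
        with pytest.raises(ParameterError):
            trp_single(design(0.1, 0.05, 0.8, k=3))


class TestClosedForm:
    @pytest.mark.parametrize(
        "prior, alpha, power, k, expected",
        [
            (0.015, 0.05, 0.81, 2, 0.80),  # published two-study plan
            (0.015, 0.05, 0.50, 2, 0.60),
            (0.015, 0.05, 0.20, 4, 0.80),
        ],
    )
    def test_published_plan_trps(self, prior, alpha, power, k, expected):
        assert round(trp_after_k(design(prior, alpha, power, k)), 2) == expected

    def test_perfect_power_capped_at_low_prior(self):
        """With a 0.001 prior, even a perfect test replicated once stays <= 0.5."""
        value = trp_after_k(design(0.001, 0.05, 1.0, 2))
        assert value == pytest.approx(0.2859, abs=5e-5)
        assert value <= 0.5

    def test_no_underflow_for_huge_k(self):
        value = trp_after_k(design(1e-6, 1e-4, 0.9, 500))
        assert value == pytest.approx(1.0)
        assert not math.isnan(value)


class TestIterativeEqualsClosedForm:
    def test_grid_identity(self):
        """Chaining Bayes k times equals the closed form everywhere tested."""
        priors = [0.001, 0.01, 0.1, 0.5, 0.9]
        alphas = [0.001, 0.01, 0.05, 0.2]
        powers = [0.05, 0.2, 0.5, 0.8, 0.99, 1.0]
        for prior in priors:
            for alpha in alphas:
                for power in powers:
                    for k in (1, 2, 3, 5, 8):
                        d = design(prior, alpha, power, k)
                        assert trp_iterative(d) == pytest.approx(
                            trp_after_k(d), abs=1e-12
                        )

    def test_k_equal_one_matches_single(self):
        d = design(0.03, 0.05, 0.7)
        assert trp_iterative(d) == trp_single(d)

    def test_published_two_study_iteration(self):
        assert round(trp_iterative(design(0.015, 0.05, 0.81, 2)), 2) == 0.80


class TestFprp:
    def test_complement_identity(self):
        d = design(0.015, 0.05, 0.81, 2)
        assert fprp(d) + trp_after_k(d) == pytest.approx(1.0, abs=1e-15)

    def test_single_study_oracle(self):
        assert fprp(design(0.5, 0.05, 0.8)) == pytest.approx(1 - 0.8 / 0.85, abs=1e-12)

    def test_uninformative_complement(self):
        assert fprp(design(0.2, 0.1, 0.1, 4)) == pytest.approx(0.8, abs=1e-12)


class TestRequiredPower:
    @pytest.mark.parametrize(
        "prior, k, expected",
        [(0.015, 2, 0.81), (0.015, 3, 0.32), (0.015, 4, 0.20), (0.01, 2, 0.99)],
    )
    def test_published_required_powers(self, prior, k, expected):
        assert round(required_power(prior, 0.05, 0.8, k), 2) == expected

    def test_round_trip(self):
        # k=1 is infeasible for this target at prior 0.015 (power would be 13)
        for k in (2, 3, 6):
            power = required_power(0.015, 0.05, 0.8, k)
            achieved = trp_after_k(design(0.015, 0.05, power, k))
            assert achieved == pytest.approx(0.8, abs=1e-10)
        power = required_power(0.3, 0.05, 0.8, 1)
        assert trp_after_k(design(0.3, 0.05, power, 1)) == pytest.approx(0.8, abs=1e-10)

    def test_infeasible_names_smallest_feasible_k(self):
        with pytest.raises(InfeasibleError) as excinfo:
            required_power(1e-6, 0.05, 0.999, 1)
        k_min = excinfo.value.min_feasible_k
        assert k_min is not None
        # verify feasibility flips exactly at k_min
        assert required_power(1e-6, 0.05, 0.999, k_min) <= 1.0
        with pytest.raises(InfeasibleError):
            required_power(1e-6, 0.05, 0.999, k_min - 1)


class TestMinStudies:
    def test_published_scenario_needs_three(self):
        # Eq-by-hand oracle: TRP at k=1,2,3 is 0.132, 0.604, 0.938
        assert min_studies(0.015, 0.05, 0.5, 0.8) == 3

    def test_already_achieved_returns_one(self):
        assert min_studies(0.5, 0.05, 0.9, 0.6) == 1

    def test_power_equal_alpha_is_infeasible(self):
        with pytest.raises(InfeasibleError):
            min_studies(0.1, 0.05, 0.05, 0.5)

    def test_k_max_exhausted_reports_best(self):
        with pytest.raises(InfeasibleError) as excinfo:
            min_studies(1e-5, 0.05, 0.2, 0.999, k_max=2)
        assert excinfo.value.best_trp == pytest.approx(
            trp_after_k(design(1e-5, 0.05, 0.2, 2))
        )


class TestStudyTest:
    def test_informative_flag(self):
        assert StudyTest(0.05, 0.8).is_informative
        assert not StudyTest(0.05, 0.05).is_informative
        assert not StudyTest(0.05, 0.01).is_informative

    @pytest.mark.parametrize("alpha, power", [(0.0, 0.8), (1.0, 0.8), (0.05, 0.0), (0.05, 1.1)])
    def test_field_validation(self, alpha, power):
        with pytest.raises(ParameterError):
            StudyTest(alpha, power)

    def test_power_one_admitted(self):
        assert StudyTest(0.05, 1.0).power == 1.0


def test_chain_posteriors_heterogeneous():
    """Mixed chains multiply likelihood ratios on the odds scale."""
    tests = [StudyTest(0.05, 0.8), StudyTest(0.01, 0.5)]
    posteriors = chain_posteriors(0.1, tests)
    odds = 0.1 / 0.9 * (0.8 / 0.05) * (0.5 / 0.01)
    assert posteriors[-1] == pytest.approx(odds / (1 + odds), abs=1e-12)
    assert len(posteriors) == 2
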