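import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adipometry import (
    PriorSpec,
    TwoTestCounts,
    TwoTestSimConfig,
    cell_probabilities,
    elicit_beta_prior,
    generate_two_test_counts,
    grid_posterior_oracle,
    log_likelihood,
    posterior_predictive_check,
    sample_posterior,
)
from adipometry.errors import ConfigurationError, DomainError

unit = st.floats(0.0, 1.0, allow_nan=False)

#: sharply concentrated Beta priors standing in for fixed perfect tests
NEAR_PERFECT = (1e6, 1e-3)


class TestCellProbabilities:
    def test_degenerate_corners(self):
        assert cell_probabilities(1, 1, 0.5, 1, 0.5) == pytest.approx((1, 0, 0, 0))
        pi = 0.3
        assert cell_probabilities(pi, 1, 1, 1, 1) == pytest.approx((pi, 0, 0, 1 - pi))

    def test_hand_computed_mixture(self):
        p11, p10, p01, p00 = cell_probabilities(0.5, 0.9, 0.8, 0.7, 0.6)
        assert p11 == pytest.approx(0.355)

    @given(pi=unit, d1=unit, g1=unit, d2=unit, g2=unit)
    def test_sums_to_one(self, pi, d1, g1, d2, g2):
        assert sum(cell_probabilities(pi, d1, g1, d2, g2)) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            cell_probabilities(1.2, 0.5, 0.5, 0.5, 0.5)


class TestLogLikelihood:
    def test_certain_event_has_zero_loglik(self):
        assert log_likelihood(TwoTestCounts(1, 0, 0, 0), (1, 1, 0.5, 1, 0.5)) == 0.0

    def test_uniform_cells(self):
        # (π, δ1, γ1, δ2, γ2) = (.5, .5, .5, .5, .5) puts mass 1/4 on each cell
        ll = log_likelihood(TwoTestCounts(1, 1, 1, 1), (0.5, 0.5, 0.5, 0.5, 0.5))
        assert ll == pytest.approx(4 * math.log(0.25))

    def test_impossible_cell_gives_minus_infinity(self):
        assert log_likelihood(TwoTestCounts(0, 1, 0, 5), (0.5, 1, 1, 1, 1)) == -np.inf

    def test_matches_direct_composition(self, rng):
        for _ in range(20):
            params = rng.random(5)
            counts = TwoTestCounts(*(int(k) for k in rng.integers(0, 30, 4) + 1))
            probs = cell_probabilities(*params)
            direct = sum(n * math.log(p) for n, p in zip(counts.as_array(), probs))
            assert log_likelihood(counts, params) == pytest.approx(direct, rel=1e-12)


class TestPriors:
    def test_uniform_from_center_half(self):
        assert elicit_beta_prior(0.5, 2) == pytest.approx((1.0, 1.0))

    def test_arithmetic(self):
        assert elicit_beta_prior(0.9, 100) == pytest.approx((90.0, 10.0))

    @given(center=st.floats(0.01, 0.99), ess=st.floats(0.5, 500))
    def test_beta_mean_equals_center(self, center, ess):
        a, b = elicit_beta_prior(center, ess)
        assert a / (a + b) == pytest.approx(center, rel=1e-9)

    def test_degenerate_center_rejected(self):
        with pytest.raises(DomainError):
            elicit_beta_prior(0.0, 10)


class TestSampler:
    def test_conjugate_closed_form_with_perfect_tests(self):
        """With perfect tests the model collapses to Beta-binomial: the
        posterior of π must match Beta(n11+1, n00+1) quantiles."""
        counts = TwoTestCounts(30, 0, 0, 70)
        priors = PriorSpec(
            pi=(1.0, 1.0),
            sens1=NEAR_PERFECT,
            spec1=NEAR_PERFECT,
            sens2=NEAR_PERFECT,
            spec2=NEAR_PERFECT,
        )
        post = sample_posterior(counts, priors, chains=4, warmup=2000, iters=2000, seed=7)
        draws = post.flat("pi")
        ref = stats.beta(31, 71)
        for q in (0.025, 0.25, 0.5, 0.75, 0.975):
            assert np.quantile(draws, q) == pytest.approx(ref.ppf(q), abs=0.02)

    def test_determinism(self):
        counts = TwoTestCounts(12, 5, 7, 76)
        priors = PriorSpec.from_accuracy(0.9, 0.9, 0.85, 0.9, ess=30)
        a = sample_posterior(counts, priors, chains=2, warmup=200, iters=300, seed=11)
        b = sample_posterior(counts, priors, chains=2, warmup=200, iters=300, seed=11)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_all_uniform_priors_refused_without_override(self):
        counts = TwoTestCounts(10, 5, 5, 80)
        with pytest.raises(ConfigurationError, match="non-identified"):
            sample_posterior(counts, PriorSpec(), seed=0)
        post = sample_posterior(
            counts, PriorSpec(), seed=0, chains=2, warmup=200, iters=200, allow_uniform=True
        )
        assert post.flat("pi").size == 400

    def test_draws_in_unit_interval_and_ci_ordered(self):
        counts = TwoTestCounts(12, 5, 7, 76)
        priors = PriorSpec.from_accuracy(0.9, 0.9, 0.85, 0.9, ess=30)
        post = sample_posterior(counts, priors, chains=2, warmup=500, iters=500, seed=2)
        for name in post.draws:
            x = post.flat(name)
            assert np.all((x >= 0) & (x <= 1))
        lo, hi = post.credible_interval("pi")
        assert lo <= np.median(post.flat("pi")) <= hi

    def test_parameter_recovery_at_survey_scale(self):
        """π = 0.094 with 90%-accurate tests at n = 50,000 is recovered
        within ±0.01 under informative accuracy priors."""
        cfg = TwoTestSimConfig(
            n=50000, prevalence=0.094, sens1=0.9, spec1=0.9, sens2=0.9, spec2=0.9, seed=99
        )
        counts = generate_two_test_counts(cfg)
        priors = PriorSpec.from_accuracy(0.9, 0.9, 0.9, 0.9, ess=50)
        post = sample_posterior(counts, priors, chains=4, warmup=1000, iters=2000, seed=5)
        assert post.flat("pi").mean() == pytest.approx(0.094, abs=0.01)
        # label-switching guard: the sensitivity mode, not its reflection
        assert post.flat("sens1").mean() > 1 - post.flat("spec1").mean()

    def test_interval_coverage_across_replicates(self):
        """95% credible interval covers the generating prevalence in ≥ 90%
        of replicate simulations at survey scale."""
        priors = PriorSpec.from_accuracy(0.9, 0.9, 0.9, 0.9, ess=50)
        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = TwoTestSimConfig(
                n=50000, prevalence=0.094, sens1=0.9, spec1=0.9, sens2=0.9, spec2=0.9,
                seed=1000 + rep,
            )
            counts = generate_two_test_counts(cfg)
            post = sample_posterior(
                counts, priors, chains=2, warmup=400, iters=800, seed=rep
            )
            lo, hi = post.credible_interval("pi")
            covered += lo <= 0.094 <= hi
        assert covered >= 0.90 * n_rep


class TestGridOracle:
    def test_perfect_test_counts_match_beta_closed_form(self):
        counts = TwoTestCounts(30, 0, 0, 70)
        priors = PriorSpec(
            pi=(1.0, 1.0),
            sens1=NEAR_PERFECT,
            spec1=NEAR_PERFECT,
            sens2=NEAR_PERFECT,
            spec2=NEAR_PERFECT,
        )
        out = grid_posterior_oracle(counts, priors, grid_size=201)
        assert out["mean"] == pytest.approx(31 / 102, abs=1e-3)

    def test_sampler_agrees_with_oracle_on_small_counts(self, rng):
        """Gibbs posterior mean of π within 0.005 of the lattice integral
        on random small-count instances (chains long enough that the
        Monte-Carlo standard error is a fraction of the tolerance)."""
        for _ in range(4):
            cells = rng.integers(0, 14, 4)
            if cells.sum() == 0:
                cells[3] = 5
            counts = TwoTestCounts(*(int(c) for c in cells))
            priors = PriorSpec.from_accuracy(0.85, 0.9, 0.8, 0.85, ess=25)
            oracle = grid_posterior_oracle(counts, priors)
            post = sample_posterior(
                counts, priors, chains=4, warmup=2000, iters=25000, seed=int(cells.sum())
            )
            assert post.flat("pi").mean() == pytest.approx(oracle["mean"], abs=0.005)

    def test_test_role_symmetry(self):
        """Swapping the two tests' roles (n10 ↔ n01, priors swapped)
        leaves the posterior of π unchanged."""
        priors = PriorSpec.from_accuracy(0.9, 0.8, 0.7, 0.95, ess=20)
        swapped = PriorSpec.from_accuracy(0.7, 0.95, 0.9, 0.8, ess=20)
        a = grid_posterior_oracle(TwoTestCounts(8, 6, 2, 40), priors)
        b = grid_posterior_oracle(TwoTestCounts(8, 2, 6, 40), swapped)
        assert a["mean"] == pytest.approx(b["mean"], abs=1e-12)

    def test_symmetric_counts_give_exchangeable_accuracy_posteriors(self):
        counts = TwoTestCounts(10, 4, 4, 60)
        priors = PriorSpec.from_accuracy(0.85, 0.9, 0.85, 0.9, ess=25)
        post = sample_posterior(counts, priors, chains=4, warmup=1500, iters=3000, seed=1)
        assert post.flat("sens1").mean() == pytest.approx(post.flat("sens2").mean(), abs=0.01)
        assert post.flat("spec1").mean() == pytest.approx(post.flat("spec2").mean(), abs=0.01)

    def test_runtime_guard(self):
        with pytest.raises(ConfigurationError, match="grid_size"):
            grid_posterior_oracle(TwoTestCounts(1, 1, 1, 1), PriorSpec(), grid_size=11)
        with pytest.raises(ConfigurationError, match="sample_posterior"):
            grid_posterior_oracle(TwoTestCounts(1000, 1000, 1000, 1000), PriorSpec())


class TestPosteriorPredictive:
    @pytest.fixture(scope="class")
    def well_specified(self):
        cfg = TwoTestSimConfig(
            n=5000, prevalence=0.15, sens1=0.9, spec1=0.9, sens2=0.85, spec2=0.9, seed=4
        )
        counts = generate_two_test_counts(cfg)
        priors = PriorSpec.from_accuracy(0.9, 0.9, 0.85, 0.9, ess=50)
        post = sample_posterior(counts, priors, chains=4, warmup=1000, iters=1000, seed=4)
        return post, counts

    def test_self_consistency(self, well_specified):
        post, counts = well_specified
        ppc = posterior_predictive_check(post, counts, n_rep=1000, seed=0)
        assert ((ppc["tail_prob"] > 0.05) & (ppc["tail_prob"] < 0.95)).all()
        assert (ppc["rep_q2.5"] <= ppc["rep_q97.5"]).all()

    def test_conditional_dependence_detected(self):
        """Counts generated with strong within-stratum error dependence
        misfit the independence model in at least one cell tail.  The
        check needs strong accuracy priors: with only three degrees of
        freedom in the data, weakly constrained accuracies can absorb
        the dependence instead of exposing it."""
        cfg = TwoTestSimConfig(
            n=20000, prevalence=0.15, sens1=0.8, spec1=0.9, sens2=0.8, spec2=0.9,
            dependence_pos=0.12, dependence_neg=0.05, seed=10,
        )
        counts = generate_two_test_counts(cfg)
        priors = PriorSpec.from_accuracy(0.8, 0.9, 0.8, 0.9, ess=1000)
        post = sample_posterior(counts, priors, chains=4, warmup=1000, iters=1000, seed=10)
        ppc = posterior_predictive_check(post, counts, n_rep=1000, seed=1)
        assert ((ppc["tail_prob"] <= 0.05) | (ppc["tail_prob"] >= 0.95)).any()

    def test_single_replicate_degenerate(self, well_specified):
        post, counts = well_specified
        ppc = posterior_predictive_check(post, counts, n_rep=1, seed=0)
        assert (ppc["rep_q2.5"] == ppc["rep_q97.5"]).all()

    def test_insufficient_draws_rejected(self, well_specified):
        post, counts = well_specified
        with pytest.raises(ConfigurationError):
            posterior_predictive_check(post, counts, n_rep=10**7)


class TestCounts:
    def test_validation(self):
        with pytest.raises(DomainError):
            TwoTestCounts(-1, 0, 0, 5)
        with pytest.raises(DomainError):
            TwoTestCounts(0, 0, 0, 0)

    def test_from_labels(self):
        c = TwoTestCounts.from_labels([1, 1, 0, 0, 1], [1, 0, 1, 0, 1])
        assert (c.n11, c.n10, c.n01, c.n00) == (2, 1, 1, 1)
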