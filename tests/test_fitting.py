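"""Moment-matching objective, golden box search, likelihood CIs, KS utility."""

import numpy as np
import pytest

from ringrupture import (
    BondModel,
    PullingProtocol,
    RuptureSample,
    bootstrap_stability,
    golden_search_fit,
    ks_two_sample,
    likelihood_ci,
    simulate_rupture_distribution,
    summary_objective,
)

HEAD = BondModel(0.0027, 1.23)


class TestSummaryObjective:
    def test_zero_at_exact_crn_self_match(self, protocol):
        """With identical seed and size, the candidate reproduces the observed
        moments exactly, so the negative-log-likelihood objective is zero."""
        obs = simulate_rupture_distribution(PullingProtocol(seed=5), HEAD, n=1500)
        val = summary_objective(HEAD, obs, protocol, n_sim=1500, seed=5)
        assert val == pytest.approx(0.0, abs=1e-20)

    def test_small_at_self_match_with_independent_seeds(self, protocol, head_sample_4k):
        """At the generating parameters the objective is at its noise floor."""
        val = summary_objective(HEAD, head_sample_4k, protocol, n_sim=4000, seed=900)
        # each moment mismatch is O(1) in z-score units => objective O(1)
        assert val < 25.0

    def test_increases_away_from_generator_on_k0_slice(self, protocol, head_sample_4k):
        k0s = [0.0027, 0.006, 0.015, 0.04]
        vals = [
            summary_objective(BondModel(k, 1.23), head_sample_4k, protocol, n_sim=1000, seed=77)
            for k in k0s
        ]
        assert np.all(np.diff(vals) > 0)

    def test_permutation_invariance(self, protocol, head_sample_89):
        rng = np.random.default_rng(0)
        shuffled = RuptureSample.from_forces(rng.permutation(head_sample_89.forces_pn))
        a = summary_objective(HEAD, head_sample_89, protocol, n_sim=500, seed=3)
        b = summary_objective(HEAD, shuffled, protocol, n_sim=500, seed=3)
        assert a == b

    def test_degenerate_observed_sample_rejected(self, protocol):
        flat = RuptureSample.from_forces(np.full(20, 21.0))
        with pytest.raises(ValueError):
            summary_objective(HEAD, flat, protocol, n_sim=100, seed=0)

    def test_raw_scaling_uses_variances(self, protocol, head_sample_89):
        val = summary_objective(
            HEAD, head_sample_89, protocol, n_sim=500, seed=3, scaling="raw"
        )
        assert val >= 0.0
        with pytest.raises(ValueError):
            summary_objective(HEAD, head_sample_89, protocol, n_sim=500, scaling="nope")


class TestGoldenSearch:
    def test_point_bounds_return_that_point(self, protocol, head_sample_89):
        fit = golden_search_fit(
            head_sample_89,
            protocol,
            bounds_k0=(0.0027, 0.0027),
            bounds_delta=(1.23, 1.23),
            n_sim=300,
            seed=1,
        )
        assert fit.k0_hat == pytest.approx(0.0027)
        assert fit.delta_hat == pytest.approx(1.23)
        assert fit.objective_value >= 0.0

    def test_deterministic_given_seed(self, protocol, head_sample_89):
        kwargs = dict(
            bounds_k0=(1e-4, 1e-2), bounds_delta=(0.8, 1.8), n_sim=400, seed=9,
            grid=4, tol_log_k0=0.2, tol_delta_nm=0.05,
        )
        a = golden_search_fit(head_sample_89, protocol, **kwargs)
        b = golden_search_fit(head_sample_89, protocol, **kwargs)
        assert (a.k0_hat, a.delta_hat) == (b.k0_hat, b.delta_hat)

    def test_recovers_generator_within_published_intervals(self, protocol, head_sample_4k):
        """Fitting head-generated data lands inside the published 90% CIs."""
        fit = golden_search_fit(head_sample_4k, protocol, n_sim=1200, seed=17)
        assert 0.0023 < fit.k0_hat < 0.0036
        assert 1.17 < fit.delta_hat < 1.29
        assert not fit.at_bound

    def test_invalid_bounds_rejected(self, protocol, head_sample_89):
        with pytest.raises(ValueError):
            golden_search_fit(head_sample_89, protocol, bounds_k0=(0.0, 1.0))


class TestLikelihoodCi:
    def test_interval_contains_optimum(self, protocol, head_sample_89):
        ci = likelihood_ci(
            head_sample_89, HEAD, "delta", protocol, n_samples=200, n_sim=300, seed=2
        )
        assert ci[0] < HEAD.delta_nm < ci[1]

    def test_width_shrinks_with_observed_sample_size(self, protocol):
        obs30 = simulate_rupture_distribution(PullingProtocol(seed=31), HEAD, n=30)
        obs300 = simulate_rupture_distribution(PullingProtocol(seed=32), HEAD, n=300)
        w = {}
        for name, obs in (("n30", obs30), ("n300", obs300)):
            lo, hi = likelihood_ci(
                obs, HEAD, "delta", protocol, n_samples=150, n_sim=300, seed=8
            )
            w[name] = hi - lo
        assert w["n300"] < w["n30"]

    def test_delta_interval_width_comparable_to_published(self, protocol, head_sample_89):
        """At the experimental n=89 the delta CI width is ~0.12 nm (factor 2)."""
        lo, hi = likelihood_ci(
            head_sample_89, HEAD, "delta", protocol, n_samples=200, n_sim=400, seed=4
        )
        assert 0.06 < hi - lo < 0.24

    def test_unknown_parameter_rejected(self, protocol, head_sample_89):
        with pytest.raises(ValueError):
            likelihood_ci(head_sample_89, HEAD, "gamma", protocol)


class TestBootstrap:
    def test_full_fraction_without_replacement_has_zero_dispersion(self, protocol, head_sample_89):
        table = bootstrap_stability(
            head_sample_89,
            n_subsamples=2,
            subsample_fraction=1.0,
            protocol=protocol,
            seed=0,
            bounds_k0=(1e-4, 1e-2),
            bounds_delta=(0.8, 1.8),
            n_sim=300,
            grid=4,
            tol_log_k0=0.2,
            tol_delta_nm=0.05,
        )
        assert table["k0_hat"].std(ddof=1) == 0.0
        assert table["delta_hat"].std(ddof=1) == 0.0

    def test_dispersion_decreases_with_subsample_size(self, protocol):
        obs = simulate_rupture_distribution(PullingProtocol(seed=55), HEAD, n=400)
        sds = {}
        for frac in (0.2, 0.9):
            table = bootstrap_stability(
                obs,
                n_subsamples=3,
                subsample_fraction=frac,
                protocol=protocol,
                seed=1,
                bounds_k0=(1e-4, 1e-2),
                bounds_delta=(0.8, 1.8),
                n_sim=300,
                grid=4,
                tol_log_k0=0.1,
                tol_delta_nm=0.02,
            )
            sds[frac] = table["delta_hat"].std(ddof=1)
        assert sds[0.9] < sds[0.2]

    def test_small_sample_rejected(self, protocol):
        tiny = RuptureSample.from_forces(np.arange(5.0))
        with pytest.raises(ValueError):
            bootstrap_stability(tiny, protocol=protocol)


class TestKsTwoSample:
    def test_identical_samples(self, head_sample_89):
        stat, p = ks_two_sample(head_sample_89, head_sample_89)
        assert stat == 0.0
        assert p == 1.0

    def test_null_calibration_rejects_at_nominal_rate(self):
        """Same-distribution pairs are rejected at alpha=0.05 about 5% of the time."""
        rng = np.random.default_rng(123)
        rejections = 0
        for _ in range(200):
            a, b = rng.normal(20.0, 8.0, (2, 400))
            _, p = ks_two_sample(a, b)
            rejections += p < 0.05
        assert 2 <= rejections <= 20  # ~5% of 200, 3 sigma band

    def test_power_head_vs_hinge_at_experimental_sizes(self):
        """Head (n=89) vs hinge (n=21) samples separate in most repetitions."""
        hinge = BondModel(0.0025, 1.61)
        hits = 0
        reps = 11
        for i in range(reps):
            a = simulate_rupture_distribution(PullingProtocol(seed=600 + i), HEAD, n=89)
            b = simulate_rupture_distribution(PullingProtocol(seed=700 + i), hinge, n=21)
            _, p = ks_two_sample(a, b)
            hits += p < 0.05
        assert hits > reps / 2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample(np.array([]), np.array([1.0]))
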