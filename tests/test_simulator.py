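"""Stochastic rupture engine: Bell kinetics, waiting times, distributions."""

import numpy as np
import pytest

from ringrupture import (
    BondModel,
    PullingProtocol,
    WLCParams,
    dissociation_rate,
    detachment_time,
    simulate_rupture_distribution,
    simulate_single_pull,
    simulate_two_dna_pull,
)
from ringrupture.fitting import ks_two_sample


class TestDissociationRate:
    def test_zero_force_returns_k0(self):
        assert dissociation_rate(BondModel(0.0027, 1.23), 0.0) == pytest.approx(0.0027)

    @pytest.mark.parametrize(
        "bond,f,expected",
        [
            (BondModel(0.0027, 1.23), 20.0, 1.067),  # e^(24.6/4.114) * 0.0027
            (BondModel(2.7e-5, 0.8), 70.0, 22.1),  # e^(56/4.114) * 2.7e-5
        ],
    )
    def test_bell_examples(self, bond, f, expected):
        assert dissociation_rate(bond, f, 4.114) == pytest.approx(expected, rel=5e-3)

    def test_strictly_increasing_in_force(self):
        forces = np.linspace(0, 80, 50)
        rates = dissociation_rate(BondModel(1e-3, 1.0), forces)
        assert np.all(np.diff(rates) > 0)

    def test_exponent_overflow_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            r = dissociation_rate(BondModel(1.0, 100.0), 1e5)
        assert np.isfinite(r)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            dissociation_rate(BondModel(1.0, 1.0), -1.0)


class TestDetachmentTime:
    def test_r_zero_gives_zero_time(self):
        assert detachment_time(5.0, 0.0) == 0.0

    def test_analytic_inversion(self):
        assert detachment_time(1.0, 1.0 - np.e**-1) == pytest.approx(1.0)

    def test_r_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            detachment_time(1.0, 1.0)
        with pytest.raises(ValueError):
            detachment_time(1.0, -0.1)

    def test_empirical_mean_matches_exponential(self):
        rng = np.random.default_rng(0)
        times = detachment_time(2.0, rng.random(100_000))
        se = 0.5 / np.sqrt(100_000)
        assert abs(times.mean() - 0.5) < 3 * se


class TestSinglePull:
    def test_huge_k0_ruptures_immediately_at_negligible_force(self):
        ev = simulate_single_pull(PullingProtocol(seed=0), BondModel(1e3, 1.23))
        assert ev.rupture_time_s == pytest.approx(0.01)
        assert ev.rupture_force_pn < 0.01

    def test_force_independent_limit_is_poissonian(self):
        """With delta = 0 the rupture times are exponential with rate k0."""
        k0 = 0.3
        s = simulate_rupture_distribution(
            PullingProtocol(seed=1), BondModel(k0, 0.0), n=3000
        )
        times = s.events.loc[~s.events.censored, "time_s"].to_numpy()
        assert s.n_censored == 0
        se = (1 / k0) / np.sqrt(times.size)
        assert abs(times.mean() - 1 / k0) < 3 * se

    def test_seed_determinism_bit_for_bit(self):
        a = simulate_rupture_distribution(PullingProtocol(seed=7), BondModel(0.0027, 1.23), n=200)
        b = simulate_rupture_distribution(PullingProtocol(seed=7), BondModel(0.0027, 1.23), n=200)
        np.testing.assert_array_equal(a.forces_pn, b.forces_pn)

    def test_summary_statistics_recomputable_from_forces(self):
        s = simulate_rupture_distribution(PullingProtocol(seed=3), BondModel(0.0027, 1.23), n=300)
        assert s.n == s.forces_pn.size
        assert s.mean == pytest.approx(np.mean(s.forces_pn))
        assert s.median == pytest.approx(np.median(s.forces_pn))


class TestDistributionShape:
    def test_mean_force_decreases_with_k0(self):
        means = [
            simulate_rupture_distribution(
                PullingProtocol(seed=11), BondModel(k0, 1.23), n=2000
            ).mean
            for k0 in (5e-4, 5e-3, 5e-2)
        ]
        assert means[0] > means[1] > means[2]

    def test_mean_force_decreases_with_delta(self):
        means = [
            simulate_rupture_distribution(
                PullingProtocol(seed=12), BondModel(0.0027, d), n=2000
            ).mean
            for d in (0.8, 1.23, 1.8)
        ]
        assert means[0] > means[1] > means[2]

    def test_mean_force_increases_with_velocity(self):
        means = [
            simulate_rupture_distribution(
                PullingProtocol(seed=13, velocity_nm_per_s=v), BondModel(0.0027, 1.23), n=2000
            ).mean
            for v in (80.0, 160.0, 320.0)
        ]
        assert means[0] < means[1] < means[2]


class TestTwoDnaPull:
    def test_degenerate_limit_matches_single_dna_distribution(self):
        """Shrinking the bead-proximal contour reproduces the single-DNA pull."""
        tiny = WLCParams(50.0, 5.0)
        two = simulate_two_dna_pull(
            PullingProtocol(seed=21), 0.0027, {1.23: 1.0}, wlc1=tiny, n=1500
        )
        single = simulate_rupture_distribution(
            PullingProtocol(seed=22), BondModel(0.0027, 1.23), n=1500
        )
        _, p = ks_two_sample(two, single)
        assert p > 0.01

    def test_two_dna_mean_below_matched_single_dna(self):
        """Stretching the extra chain lowers the effective ramp and the mean."""
        two = simulate_two_dna_pull(
            PullingProtocol(seed=23), 2e-3, {1.23: 0.5, 1.61: 0.5}, n=1200
        )
        singles = [
            simulate_rupture_distribution(
                PullingProtocol(seed=24 + i), BondModel(2e-3, d), n=1200
            ).mean
            for i, d in enumerate((1.23, 1.61))
        ]
        assert two.mean < np.mean(singles)

    def test_delta_choice_probabilities_validated(self):
        with pytest.raises(ValueError):
            simulate_two_dna_pull(
                PullingProtocol(seed=1), 2e-3, {1.23: 0.6, 1.61: 0.6}, n=10
            )

    def test_recorded_deltas_come_from_choices(self):
        s = simulate_two_dna_pull(
            PullingProtocol(seed=25), 2e-3, {1.23: 0.5, 1.61: 0.5}, n=60
        )
        assert set(np.unique(s.events.delta_nm)) <= {1.23, 1.61}
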