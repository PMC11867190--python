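import numpy as np
import pytest

from pbdrates.params import PBDParams
from pbdrates.rates import (
    PiecewiseConstantRates,
    discretize_trajectory,
    equivalent_constant_rates,
    equivalent_rate_trajectory,
)

STUDY = PBDParams(0.5, 1.0, 0.4, 0.2, 0.2)


class TestConstantRates:
    def test_death_rate_is_good_lineage_extinction_rate(self, rate_defaults):
        assert equivalent_constant_rates(rate_defaults).mu_tilde == 0.1

    def test_certain_completion_gives_initiation_rate(self):
        p = PBDParams(0.3, 0.4, 0.3, 0.1, 0.0)
        const = equivalent_constant_rates(p)
        assert const.pi == 0.0
        assert const.lambda_tilde == p.lambda1

    def test_tree_sim_defaults_values(self):
        const = equivalent_constant_rates(STUDY)
        assert const.pi == pytest.approx(0.1292, abs=2e-4)
        assert const.lambda_tilde == pytest.approx(0.4354, abs=2e-4)

    def test_all_rates_zero_convention(self):
        const = equivalent_constant_rates(PBDParams(0.0, 0.0, 0.0, 0.0, 0.0))
        assert const.lambda_tilde == const.mu_tilde == const.pi == 0.0


class TestRateTrajectory:
    def test_birth_rate_vanishes_at_present(self, rate_defaults):
        traj = equivalent_rate_trajectory(rate_defaults, 30.0, 201)
        assert abs(traj.lambda_hat[-1]) < 1e-6

    def test_death_rate_equals_mu1_at_present(self, rate_defaults):
        traj = equivalent_rate_trajectory(rate_defaults, 30.0, 201)
        assert traj.mu_hat[-1] == pytest.approx(rate_defaults.mu1, abs=1e-6)

    def test_deep_past_asymptote(self, rate_defaults):
        traj = equivalent_rate_trajectory(rate_defaults, 30.0, 201)
        lt = equivalent_constant_rates(rate_defaults).lambda_tilde
        assert lt == pytest.approx(0.2606, abs=1e-4)
        assert abs(traj.lambda_hat[0] / lt - 1.0) < 0.01
        assert not traj.fallback[0]

    def test_decay_confined_near_present(self, rate_defaults):
        """lambda_hat stays within 1% of lambda_tilde except in the last
        ~10/lambda2 Myr before the present."""
        T = 30.0
        traj = equivalent_rate_trajectory(rate_defaults, T, 601)
        lt = equivalent_constant_rates(rate_defaults).lambda_tilde
        early = traj.t <= T - 10.0 / rate_defaults.lambda2
        assert np.all(np.abs(traj.lambda_hat[early] / lt - 1.0) < 0.01)

    def test_decay_onset_ordering_with_completion_rate(self):
        """Lower completion rates push the birth-rate decay further into the
        past: the age at which lambda_hat first drops 5% below lambda_tilde
        decreases with lambda2."""
        T = 30.0
        onsets = []
        for l2 in (0.1, 0.4, 1.0):
            p = PBDParams(0.3, l2, 0.3, 0.1, 0.1)
            traj = equivalent_rate_trajectory(p, T, 1201)
            lt = equivalent_constant_rates(p).lambda_tilde
            below = traj.lambda_hat < 0.95 * lt
            onsets.append(T - traj.t[np.argmax(below)])  # age before present
        assert onsets[0] > onsets[1] > onsets[2]

    def test_death_rate_nearly_constant_with_dip_near_present(self, rate_defaults):
        """mu_hat is almost constant: a modest dip followed by recovery to mu1
        right at the present, with far less relative variation than lambda_hat."""
        traj = equivalent_rate_trajectory(rate_defaults, 30.0, 601)
        mu1 = rate_defaults.mu1
        rel = traj.mu_hat / mu1 - 1.0
        assert np.max(np.abs(rel)) < 0.20
        i_min = int(np.argmin(traj.mu_hat))
        assert traj.t[i_min] < 30.0  # dip strictly before the present
        assert traj.mu_hat[-1] == pytest.approx(mu1, abs=1e-6)
        lam_span = np.ptp(traj.lambda_hat) / equivalent_constant_rates(rate_defaults).lambda_tilde
        assert np.max(np.abs(rel)) < 0.25 * lam_span

    def test_slow_incipient_mode_limit_when_k_below_nu(self):
        """When the incipient relaxation constant k is smaller than
        nu = lambda_tilde + mu_tilde, the deep-past limit of the equivalent
        birth rate is min(k, nu) * lambda_tilde / nu, not lambda_tilde:
        the slow incipient transient dominates the 0/0 limit."""
        p = PBDParams(1.033, 0.081, 0.5, 1.41, 0.83)
        const = equivalent_constant_rates(p)
        nu = const.lambda_tilde + const.mu_tilde
        assert p.k < nu  # the regime under test
        traj = equivalent_rate_trajectory(p, 23.0, 47)
        predicted = p.k * const.lambda_tilde / nu
        assert not traj.fallback[0]
        assert traj.lambda_hat[0] == pytest.approx(predicted, rel=1e-3)

    def test_fallback_substitutes_asymptotic_rates(self, rate_defaults):
        """For very long durations pNG underflows and the flagged points carry
        exactly the constant equivalent rates."""
        traj = equivalent_rate_trajectory(rate_defaults, 400.0, 101)
        const = equivalent_constant_rates(rate_defaults)
        assert traj.fallback.any()
        assert np.all(traj.lambda_hat[traj.fallback] == const.lambda_tilde)
        assert np.all(traj.mu_hat[traj.fallback] == const.mu_tilde)

    def test_rate_map_is_invertible_where_png_positive(self, rate_defaults):
        """(pSG, pEG) -> (lambda_hat, mu_hat) is a linear bijection: solving
        the probability dynamics with the recovered rates returns the curves."""
        T = 20.0
        traj = equivalent_rate_trajectory(rate_defaults, T, 401)
        from pbdrates.probabilities import solve_probability_curves

        h = T - traj.t  # horizons
        c = solve_probability_curves(rate_defaults, np.sort(h))
        pSG, pEG = c.pSG[::-1], c.pEG[::-1]  # aligned with process time
        # reconstruct the derivatives from the rates (invert the linear map)
        lam, mu = traj.lambda_hat, traj.mu_hat
        dSG = lam - (lam + mu) * pSG
        dEG = mu - (lam + mu) * pEG
        assert np.allclose(dSG[1:], c.d_pSG[::-1][1:], atol=1e-8)
        assert np.allclose(dEG[1:], c.d_pEG[::-1][1:], atol=1e-8)


class TestDiscretization:
    def test_single_interval_is_midpoint_evaluation(self, rate_defaults):
        traj = equivalent_rate_trajectory(rate_defaults, 15.0, 201)
        pw = discretize_trajectory(traj, 1)
        mid_idx = np.argmin(np.abs(traj.t - 7.5))
        assert pw.lam[0] == pytest.approx(traj.lambda_hat[mid_idx], rel=1e-6)

    def test_constant_trajectory_reproduced(self):
        pw = PiecewiseConstantRates.constant(0.4, 0.1, 15.0)
        assert pw.lambda_at(0.0) == pw.lambda_at(14.9) == 0.4
        assert pw.mu_at(7.0) == 0.1

    def test_200_intervals_preserve_rate_integral(self, rate_defaults):
        traj = equivalent_rate_trajectory(rate_defaults, 15.0, 2001)
        pw = discretize_trajectory(traj, 200)
        dense = np.trapezoid(traj.lambda_hat, traj.t)
        piecewise = float(np.sum(pw.lam * np.diff(pw.edges)))
        assert abs(piecewise / dense - 1.0) < 0.01

    def test_discretization_close_to_dense_away_from_present(self, rate_defaults):
        traj = equivalent_rate_trajectory(rate_defaults, 15.0, 2001)
        pw = discretize_trajectory(traj, 200)
        lt = equivalent_constant_rates(rate_defaults).lambda_tilde
        # compare on the dense grid, excluding the final interval
        for i in range(190):
            sel = (traj.t >= pw.edges[i]) & (traj.t < pw.edges[i + 1])
            assert np.max(np.abs(traj.lambda_hat[sel] - pw.lam[i])) < 0.02 * lt

    def test_invalid_arguments(self, rate_defaults):
        traj = equivalent_rate_trajectory(rate_defaults, 15.0, 51)
        with pytest.raises(ValueError):
            discretize_trajectory(traj, 0)
        with pytest.raises(ValueError):
            PiecewiseConstantRates(edges=[0.0, 1.0], lam=[-0.1], mu=[0.0])
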