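"""Simulator tests: kernel truncation, the defining error-recursion
identity, dropout channel behavior, ensemble statistics and determinism."""

import math

import numpy as np
import pytest

from grnest.fixtures import example_4_1
from grnest.model import EstimatorGains, ExponentialKernel, GRNModel
from grnest.simulator import (
    DelaySchedule,
    NoiseIntensity,
    Trajectory,
    ensemble_mean_square,
    hinf_ratio,
    simulate,
    truncate_kernel,
)

I2 = np.eye(2)


def scalar_model(a=0.5, **over):
    """n=1 model with all couplings off: x(k+1) = -a x(k - rho1)."""
    kw = dict(
        A=[[a]], B=[[0.0]], C=[[a]], D=[[0.0]], E=[[0.0]], F=[[0.0]],
        H=[[1e-4]], Lx=[[1.0]], Ly=[[1.0]], M=[[1.0]], N=[[1.0]],
        rho1=0, rho2=0, delta_m=0, delta_M=1, tau_m=0, tau_M=1,
    )
    kw.update(over)
    return GRNModel(**kw)


FLAT = DelaySchedule.constant(delta=1, tau=1)


class TestKernelTruncation:
    def test_single_term_kernel(self):
        class OneTerm:
            def __call__(self, s):
                return 1.0 if s == 1 else 0.0

        s_max, w = truncate_kernel(OneTerm(), rel_tol=1e-9)
        assert s_max == 1 and np.allclose(w, [1.0])

    def test_exponential_total_mass_closed_form(self):
        k = ExponentialKernel(2.0)
        expected = math.exp(-2) / (1 - math.exp(-2))
        assert k.total_mass == pytest.approx(expected, rel=1e-12)
        assert k.total_mass == pytest.approx(0.15652, abs=5e-6)

    def test_truncation_length_matches_tail_oracle(self):
        # oracle: direct tail summation of e^(-2s)
        k = ExponentialKernel(2.0)
        rel_tol = 1e-12
        s_max, w = truncate_kernel(k, rel_tol=rel_tol)
        total = sum(math.exp(-2 * s) for s in range(1, 200))
        tail = sum(math.exp(-2 * s) for s in range(s_max + 1, 400))
        tail_prev = sum(math.exp(-2 * s) for s in range(s_max, 400))
        assert tail <= rel_tol * total < tail_prev
        assert s_max == 14
        assert len(w) == s_max and w[0] == pytest.approx(math.exp(-2))

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            truncate_kernel(ExponentialKernel(1.0), rel_tol=0.0)


class TestSimulateBasics:
    def test_origin_is_equilibrium(self):
        fx = example_4_1("4.1a")
        hist = (np.zeros((6, 2)), np.zeros((6, 2)))
        tr = simulate(
            fx.model, EstimatorGains.zero(2), fx.schedule, 40,
            seed=0, history=hist, noise=False,
        )
        assert np.all(tr.x == 0) and np.all(tr.y == 0)
        assert np.all(tr.xhat == 0) and np.all(tr.yhat == 0)

    def test_scalar_decay_closed_form(self):
        m = scalar_model(a=0.5)
        hist = (np.ones((2, 1)), np.zeros((2, 1)))
        tr = simulate(
            m, EstimatorGains.zero(1), FLAT, 20, seed=0,
            history=hist, noise=False,
        )
        expected = (-0.5) ** np.arange(21)
        assert np.allclose(tr.x[:, 0], expected, atol=1e-14)

    def test_always_on_measurement_channel(self):
        fx = example_4_1("4.1a")
        m = fx.model
        m2 = GRNModel(
            A=m.A, B=m.B, C=m.C, D=m.D, E=m.E, F=m.F, H=m.H,
            Lx=m.Lx, Ly=m.Ly, M=m.M, N=m.N,
            rho1=m.rho1, rho2=m.rho2,
            delta_m=m.delta_m, delta_M=m.delta_M,
            tau_m=m.tau_m, tau_M=m.tau_M,
            mu_kernel=m.mu_kernel, xi_kernel=m.xi_kernel,
            alpha0=1.0, beta0=1.0, uncertainty=m.uncertainty,
        )
        tr = simulate(m2, EstimatorGains.zero(2), fx.schedule, 50, seed=3)
        assert np.all(tr.alpha == 1)
        assert np.allclose(tr.Zx_tilde, tr.x @ m2.M.T)

    def test_bernoulli_draws_are_binary(self):
        fx = example_4_1("4.1b")
        tr = simulate(fx.model, EstimatorGains.zero(2), fx.schedule, 100, seed=9)
        assert set(np.unique(tr.alpha)) <= {0.0, 1.0}
        assert set(np.unique(tr.beta)) <= {0.0, 1.0}

    def test_horizon_validation(self):
        m = scalar_model()
        with pytest.raises(ValueError):
            simulate(m, EstimatorGains.zero(1), FLAT, 0)

    def test_schedule_bounds_enforced(self):
        m = scalar_model()  # delta_M = 1
        bad = DelaySchedule.constant(delta=3, tau=0)
        with pytest.raises(ValueError):
            simulate(m, EstimatorGains.zero(1), bad, 10)

    def test_non_integer_schedule_rejected(self):
        m = scalar_model()
        bad = DelaySchedule(delta=lambda k: 0.5, tau=lambda k: 0)
        with pytest.raises(ValueError):
            simulate(m, EstimatorGains.zero(1), bad, 10)


class TestErrorRecursionIdentity:
    @pytest.mark.parametrize("seed", range(5))
    def test_direct_recursion_matches_subtraction(self, seed):
        """The closed error recursion is definitionally the difference of
        the plant and estimator recursions; both paths must agree."""
        fx = example_4_1("4.1a")
        gains = example_4_1("4.1b").gains
        rng = np.random.default_rng(seed)
        hist = (rng.uniform(0, 1, (6, 2)), rng.uniform(0, 1, (6, 2)))
        tr = simulate(
            fx.model, gains, fx.schedule, 60, seed=seed, history=hist,
            uncertainty_mode="paper-trig", track_error_recursion=True,
        )
        scale = max(np.abs(tr.xerr).max(), np.abs(tr.yerr).max(), 1.0)
        dev = max(
            np.abs(tr.xerr - tr.xerr_direct).max(),
            np.abs(tr.yerr - tr.yerr_direct).max(),
        )
        assert dev / scale <= 1e-10


class TestDeterminism:
    def test_bitwise_reproducible_per_seed(self):
        fx = example_4_1("4.1b")
        a = simulate(fx.model, fx.gains, fx.schedule, 50, seed=11)
        b = simulate(fx.model, fx.gains, fx.schedule, 50, seed=11)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.alpha, b.alpha)

    def test_noise_toggle_does_not_shift_dropout_stream(self):
        """Per-role RNG partitioning: switching process noise off must leave
        the Bernoulli measurement draws untouched."""
        fx = example_4_1("4.1b")
        a = simulate(fx.model, fx.gains, fx.schedule, 80, seed=5, noise=True)
        b = simulate(fx.model, fx.gains, fx.schedule, 80, seed=5, noise=False)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.beta, b.beta)

    def test_truncation_refinement_negligible(self):
        fx = example_4_1("4.1a")
        kw = dict(seed=2, noise=False)
        a = simulate(fx.model, EstimatorGains.zero(2), fx.schedule, 60,
                     kernel_rel_tol=1e-10, **kw)
        b = simulate(fx.model, EstimatorGains.zero(2), fx.schedule, 60,
                     kernel_rel_tol=5e-11, **kw)
        sup = np.abs(a.x).max()
        assert np.abs(a.x - b.x).max() <= 10 * 1e-10 * max(sup, 1.0)


class TestNoiseIntensity:
    def test_zero_factor(self):
        ni = NoiseIntensity(np.zeros((2, 2)), 0.01 * I2)
        assert np.all(ni(np.ones(2)) == 0)

    def test_square_root_factor_is_tight(self):
        H = np.array([[0.02, 0.005], [0.005, 0.01]])
        ni = NoiseIntensity.from_bound(H)
        assert np.allclose(ni.Sigma.T @ ni.Sigma, H, atol=1e-12)

    def test_bound_violation_rejected(self):
        with pytest.raises(ValueError):
            NoiseIntensity(np.eye(2), 0.01 * I2)

    def test_bound_holds_on_random_states(self):
        rng = np.random.default_rng(7)
        H = np.diag([0.05, 0.02])
        Sigma = 0.5 * NoiseIntensity.from_bound(H).Sigma
        ni = NoiseIntensity(Sigma, H)
        for _ in range(100):
            x = rng.standard_normal(2)
            s = ni(x)
            assert s @ s <= x @ H @ x + 1e-12


class TestEnsembleStatistics:
    @staticmethod
    def _traj_from_series(e):
        """Trajectory whose squared error energy equals the given series."""
        K = len(e) - 1
        z = np.zeros((K + 1, 1))
        x = np.sqrt(e)[:, None]
        return Trajectory(
            x=x, y=z, xhat=x, yhat=z, Zx=z, Zy=z, Zx_tilde=z, Zy_tilde=z,
            alpha=np.ones(K + 1), beta=np.ones(K + 1),
            omega=np.zeros(K + 1), vx=z, vy=z,
            history_x=z[:1], history_y=z[:1],
        )

    def test_exact_geometric_series_fit(self):
        e = 3.0 * 0.8 ** np.arange(60)
        t = self._traj_from_series(e)
        _, mu, alpha, r2, _ = ensemble_mean_square([t, t])
        assert abs(mu - 0.8) <= 1e-8
        assert abs(alpha - 3.0) <= 1e-6
        assert r2 > 1 - 1e-12

    def test_constant_series_gives_unit_rate(self):
        e = np.full(40, 2.5)
        t = self._traj_from_series(e)
        _, mu, _, _, _ = ensemble_mean_square([t, t])
        assert mu == pytest.approx(1.0, abs=1e-12)

    def test_ar1_squared_process(self):
        m = scalar_model(a=0.5)
        hist = (np.ones((2, 1)), np.zeros((2, 1)))
        runs = [
            simulate(m, EstimatorGains.zero(1), FLAT, 40, seed=s,
                     history=hist, noise=False)
            for s in range(2)
        ]
        _, mu, _, _, _ = ensemble_mean_square(runs, burn_in=1)
        assert abs(mu - 0.25) <= 1e-8

    def test_all_zero_series_flagged(self):
        t = self._traj_from_series(np.zeros(30))
        series, mu, *_ = ensemble_mean_square([t, t])
        assert mu is None and np.all(series == 0)

    def test_single_trajectory_rejected(self):
        t = self._traj_from_series(np.ones(10))
        with pytest.raises(ValueError):
            ensemble_mean_square([t])


class TestHinfRatio:
    @staticmethod
    def _traj(x, vx):
        K = x.shape[0] - 1
        z = np.zeros_like(x)
        return Trajectory(
            x=x, y=z, xhat=x, yhat=z, Zx=z, Zy=z, Zx_tilde=z, Zy_tilde=z,
            alpha=np.ones(K + 1), beta=np.ones(K + 1),
            omega=np.zeros(K + 1), vx=vx, vy=z,
            history_x=z[:1], history_y=z[:1],
        )

    def test_zero_output_gives_zero_ratio(self):
        v = np.ones((20, 1))
        t = self._traj(np.zeros((20, 1)), v)
        assert hinf_ratio([t]) == 0.0

    def test_passthrough_gives_unit_ratio(self):
        v = np.linspace(1, 2, 20)[:, None]
        t = self._traj(v.copy(), v)
        # xhat = x so the error is zero; |xbar|^2 = |x|^2 = |v|^2
        assert hinf_ratio([t]) == pytest.approx(1.0, rel=1e-12)

    def test_zero_disturbance_rejected(self):
        t = self._traj(np.ones((10, 1)), np.zeros((10, 1)))
        with pytest.raises(ZeroDivisionError):
            hinf_ratio([t])


class TestSeriesInequality:
    def test_weighted_series_bound_holds(self):
        """Quadratic form of a weighted sum is bounded by the weighted sum
        of quadratic forms times the total weight (finite truncations)."""
        from grnest.lmi import series_inequality_slack

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 5))
            m = int(rng.integers(1, 12))
            G = rng.standard_normal((n, n))
            M = G @ G.T
            a = rng.uniform(0, 2, m)
            xs = rng.standard_normal((m, n))
            assert series_inequality_slack(M, a, xs) >= -1e-10
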