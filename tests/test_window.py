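"""Distributed-delay window filter against its oracles.

The two key correctness anchors: (i) with a point-mass (lag-zero) kernel
the window filter must reproduce the non-delayed extended Kalman--Bucy
filter exactly, and (ii) for linear delayed hazards the linearization is
exact, so the filter must match a brute-force linear-Gaussian Kalman
recursion on the stacked window vector built from explicit matrices.
"""

import time

import numpy as np
import pytest
from scipy import stats

from dlnafilter import (
    GaussianState,
    MeasurementModel,
    ObservedSeries,
    ParameterSet,
    PointMassDelay,
    WindowMeasurement,
    WindowState,
    delayed_kalman_update,
    ekbf_loglik,
    filter_loglik,
    init_window,
    kalman_update,
    lna_propagate,
    make_gamma_kernel,
    propagate_window,
    ttfl_network,
)
from dlnafilter.lna import nondelayed_dynamics
from dlnafilter.model import DelayedReactionNetwork, Hazard
from dlnafilter.window import (
    _advance_scalar,
    _kernel_matrix,
    _ttfl_coeffs,
    _update_scalar,
    window_obs_row,
)
from tests.conftest import true_params_for


def _window(M, mean_last=50.0, var_last=4.0, dt=0.1, rng=None):
    mean = np.full(M, 30.0)
    mean[-1] = mean_last
    if rng is None:
        cov = np.zeros((M, M))
        cov[-1, -1] = var_last
    else:
        A = rng.normal(size=(M, M)) * 0.3
        cov = A @ A.T + np.eye(M) * 0.1
        cov[-1, -1] += var_last
    times = (np.arange(M) - (M - 1)) * dt
    return WindowState(grid_times=times, mean=mean, cov=cov, p=1)


def _point_mass_ttfl(params):
    net = ttfl_network(params)
    net.kernels[0] = PointMassDelay()
    return net


class TestDegenerateKernelEquivalence:
    def test_propagation_matches_nondelayed_lna(self, params_true):
        """Point-mass kernel: trailing moments = non-delayed LNA, 200 steps."""
        net = _point_mass_ttfl(params_true)
        dyn = nondelayed_dynamics(net)
        dt = 0.1
        w = _window(31, mean_last=50.0, var_last=4.0, dt=dt)
        state = GaussianState(mean=[50.0], cov=[[4.0]])
        for k in range(200):
            w = propagate_window(w, net, dt)
            state = lna_propagate(state, dyn, 0.0, dt, dt)
            m, P = w.current_state()
            assert m[0] == pytest.approx(state.mean[0], rel=1e-8)
            assert P[0, 0] == pytest.approx(state.cov[0, 0], rel=1e-8)

    def test_loglik_matches_ekbf(self, params_true):
        """Point-mass kernel + observation of the current state only."""
        params = params_true.replace(kappa=0.02, sigma_eps=0.05)
        net = _point_mass_ttfl(params)
        dyn = nondelayed_dynamics(net)
        dt, exposure = 0.1, 0.5
        n_sub = 5
        rng = np.random.default_rng(8)
        series = ObservedSeries(
            times=(np.arange(40) + 1) * exposure,
            values=1.0 + 0.3 * np.sin(np.arange(40)) + rng.normal(0, 0.05, 40),
            exposure=exposure,
        )
        M = 11
        w = _window(M, mean_last=50.0, var_last=4.0, dt=dt)
        obs_row = np.zeros(M)
        obs_row[-1] = params.kappa
        wm = WindowMeasurement(obs_row=obs_row, noise_var=params.sigma_eps**2)
        ll = 0.0
        for y in series.values:
            for _ in range(n_sub):
                w = propagate_window(w, net, dt)
            m, P = w.current_state()
            S = params.kappa**2 * P[0, 0] + params.sigma_eps**2
            ll += stats.norm.logpdf(y, params.kappa * m[0], np.sqrt(S))
            w = delayed_kalman_update(w, wm, y)
        init = GaussianState(mean=[50.0], cov=[[4.0]])
        mm = MeasurementModel(
            obs_matrix=[[params.kappa]], noise_cov=[[params.sigma_eps**2]]
        )
        ll_ekbf, _, _ = ekbf_loglik(series, dyn, mm, init, dt)
        assert ll == pytest.approx(ll_ekbf, rel=1e-8)


class TestPropagation:
    def test_zero_hazards_shift_only(self):
        net = DelayedReactionNetwork(
            1, [[1.0]], [[-1.0]],
            [Hazard(lambda u: 0.0, grad=lambda u: np.zeros(1))],
            [Hazard(lambda x: 0.0, grad=lambda x: np.zeros(1))],
            [PointMassDelay()],
        )
        rng = np.random.default_rng(3)
        w = _window(12, rng=rng)
        out = propagate_window(w, net, 0.1)
        # retained moments are the old window shifted by one lattice point
        assert np.allclose(out.mean[:-1, 0], w.mean[1:, 0])
        assert np.allclose(out.cov[:-1, :-1], w.cov[1:, 1:])
        # the new point duplicates the old current state (no dynamics)
        assert out.mean[-1, 0] == pytest.approx(w.mean[-1, 0])
        assert out.cov[-1, -1] == pytest.approx(w.cov[-1, -1])

    def test_linear_delayed_hazard_matches_stacked_recursion(self):
        """nu(u) = a - b u with death mu x: exact linear-Gaussian system."""
        a, b, mu, dt = 30.0, 0.1, 0.5, 0.1
        M = 21
        kern = make_gamma_kernel(1.0, 0.4, max_lag=2.0, grid_step=dt)
        net = DelayedReactionNetwork(
            1, [[1.0]], [[-1.0]],
            [Hazard(lambda u: a - b * u[0], grad=lambda u: np.array([-b]))],
            [Hazard(lambda x: mu * x[0], grad=lambda x: np.array([mu]))],
            [type("G", (), {"discretize": lambda self, g: kern})()],
        )
        rng = np.random.default_rng(4)
        w = _window(M, mean_last=50.0, var_last=4.0, dt=dt, rng=rng)
        # oracle state
        m_vec = w.mean[:, 0].copy()
        P = w.cov.copy()
        kw = np.zeros(M)
        kw_rev = kern.weights[::-1]
        kw[M - len(kw_rev):] = kw_rev
        shift = np.eye(M, k=1)[: M - 1]
        for _ in range(60):
            u = kw @ m_vec
            row = -b * dt * kw
            row[-1] += 1.0 - mu * dt
            T = np.vstack([shift, row])
            c = np.zeros(M)
            c[-1] = a * dt
            Q = np.zeros((M, M))
            Q[-1, -1] = (a - b * u + mu * m_vec[-1]) * dt
            m_vec = T @ m_vec + c
            P = T @ P @ T.T + Q
            w = propagate_window(w, net, dt)
        assert np.allclose(w.mean[:, 0], m_vec, rtol=1e-9, atol=1e-9)
        assert np.allclose(w.cov, P, rtol=1e-8, atol=1e-9)


class TestWindowUpdate:
    def test_infinite_noise_no_change(self, rng):
        w = _window(10, rng=np.random.default_rng(1))
        row = window_obs_row(10, 5, kappa=1.0, dt=0.1)
        wm = WindowMeasurement(obs_row=row, noise_var=1e18)
        out = delayed_kalman_update(w, wm, 1000.0)
        assert np.allclose(out.mean, w.mean, atol=1e-8)
        assert np.allclose(out.cov, w.cov, rtol=1e-10)

    def test_trailing_marginal_matches_plain_kalman(self):
        """Observation touching only the current state: the trailing
        marginal must obey the ordinary scalar Kalman update."""
        w = _window(10, rng=np.random.default_rng(2))
        kappa, noise = 0.7, 0.3
        row = np.zeros(10)
        row[-1] = kappa
        wm = WindowMeasurement(obs_row=row, noise_var=noise)
        y = 40.0
        out = delayed_kalman_update(w, wm, y)
        m, P = w.current_state()
        ref = kalman_update(
            GaussianState(mean=m, cov=P),
            MeasurementModel(obs_matrix=[[kappa]], noise_cov=[[noise]]),
            np.array([y]),
        )
        m2, P2 = out.current_state()
        assert m2[0] == pytest.approx(ref.mean[0], rel=1e-10)
        assert P2[0, 0] == pytest.approx(ref.cov[0, 0], rel=1e-10)

    def test_exact_observation_conditions_whole_window(self):
        """Noise-free observation of the current state: the update is the
        closed-form Gaussian conditional with regression P_st / P_tt."""
        w = _window(8, rng=np.random.default_rng(5))
        row = np.zeros(8)
        row[-1] = 1.0
        wm = WindowMeasurement(obs_row=row, noise_var=0.0)
        y = 42.0
        out = delayed_kalman_update(w, wm, y)
        m2, P2 = out.current_state()
        assert m2[0] == pytest.approx(y, rel=1e-10)
        assert P2[0, 0] == pytest.approx(0.0, abs=1e-9)
        Ptt = w.cov[-1, -1]
        for s in range(7):
            expected = w.mean[s, 0] + w.cov[s, -1] / Ptt * (y - w.mean[-1, 0])
            assert out.mean[s, 0] == pytest.approx(expected, rel=1e-9)


class TestScalarFastPath:
    def test_matches_generic_network_machinery(self, params_true):
        dt = 0.1
        net = ttfl_network(params_true)
        rng = np.random.default_rng(6)
        M = int(round(params_true.tau_max / dt)) + 1
        w = _window(M, rng=rng)
        Kw = _kernel_matrix(net, M, dt)[:, 0]
        coeffs = _ttfl_coeffs(params_true)
        mean_s, cov_s = w.mean[:, 0].copy(), w.cov.copy()
        wg = w
        for _ in range(5):
            mean_s, cov_s = _advance_scalar(mean_s, cov_s, coeffs, Kw, dt, 0.0)
            wg = propagate_window(wg, net, dt)
        assert np.allclose(wg.mean[:, 0], mean_s, rtol=1e-12)
        assert np.allclose(wg.cov, cov_s, rtol=1e-10, atol=1e-12)
        # and the update step
        f_tail = window_obs_row(M, 5, 0.02, dt)[M - 6:]
        mean_u, cov_u, mu_pred, S = _update_scalar(
            mean_s, cov_s, f_tail, M - 6, 0.01, 1.2, 0.0
        )
        row = window_obs_row(M, 5, 0.02, dt)
        wm = WindowMeasurement(obs_row=row, noise_var=0.01)
        wu = delayed_kalman_update(wg, wm, 1.2)
        assert np.allclose(wu.mean[:, 0], mean_u, rtol=1e-10)
        assert np.allclose(wu.cov, cov_u, rtol=1e-8, atol=1e-12)


def test_compiled_and_python_paths_agree(series_one, params_true):
    """The numba fast path must reproduce the plain-numpy recursion."""
    import dlnafilter.window as W

    params = true_params_for(series_one, params_true)
    r_fast = W.filter_loglik(series_one, params, dt=0.25, smoothing=False)
    assert W._HAVE_NUMBA
    W._HAVE_NUMBA = False
    try:
        r_py = W.filter_loglik(series_one, params, dt=0.25, smoothing=False)
    finally:
        W._HAVE_NUMBA = True
    assert r_fast.loglik == pytest.approx(r_py.loglik, rel=1e-10)
    assert np.allclose(r_fast.pred_mean, r_py.pred_mean, rtol=1e-9)
    assert np.allclose(r_fast.window.cov, r_py.window.cov,
                       rtol=1e-7, atol=1e-10)


def _linear_filter_oracle(series, params, a, b, dt):
    """Full-pass linear-Gaussian oracle replicating the filter's structure
    (growing initialization window, then stacked sliding window) with
    explicit transition matrices and textbook Kalman algebra."""
    exposure = series.exposure
    n_sub = int(round(exposure / dt))
    m_steps = int(round(params.tau_max / dt))
    n_head = int(round(params.tau_max / exposure))
    kern = make_gamma_kernel(
        params.delay_mean, params.delay_sd, params.tau_max, dt
    )
    tail = params.kappa * dt * np.r_[0.5, np.ones(n_sub - 1), 0.5]
    noise = params.sigma_eps**2
    x0 = max(series.values[0] / (params.kappa * exposure), 1e-6)
    mean = np.array([x0])
    P = np.array([[params.beta * x0]])
    nu0, mu0, mu = params.init_rate, params.mu0, params.mu
    ll = 0.0
    obs_idx = 0
    # growth phase: birth--death dynamics
    for k in range(1, m_steps + 1):
        sz = mean.size
        T = np.vstack([np.eye(sz), np.zeros(sz)])
        T[-1, -1] = 1.0 - mu0 * dt
        c = np.zeros(sz + 1)
        c[-1] = nu0 * dt
        Q = np.zeros((sz + 1, sz + 1))
        Q[-1, -1] = (nu0 + mu0 * mean[-1]) * dt
        mean = T @ mean + c
        P = T @ P @ T.T + Q
        if k % n_sub == 0:
            F = np.zeros(sz + 1)
            F[-n_sub - 1:] = tail
            y = series.values[obs_idx]
            S = F @ P @ F + noise
            ll += stats.norm.logpdf(y, F @ mean, np.sqrt(S))
            K = P @ F / S
            mean = mean + K * (y - F @ mean)
            P = P - np.outer(K, F @ P)
            obs_idx += 1
    # sliding phase: delayed linear dynamics nu(u) = a - b u
    M = m_steps + 1
    kw = kern.weights[::-1]
    shift = np.eye(M, k=1)[: M - 1]
    F = np.zeros(M)
    F[-n_sub - 1:] = tail
    for i in range(n_head, len(series)):
        for _ in range(n_sub):
            u = kw @ mean
            row = -b * dt * kw
            row[-1] += 1.0 - mu * dt
            T = np.vstack([shift, row])
            c = np.zeros(M)
            c[-1] = a * dt
            Q = np.zeros((M, M))
            Q[-1, -1] = (a - b * u + mu * mean[-1]) * dt
            mean = T @ mean + c
            P = T @ P @ T.T + Q
        y = series.values[i]
        S = F @ P @ F + noise
        ll += stats.norm.logpdf(y, F @ mean, np.sqrt(S))
        K = P @ F / S
        mean = mean + K * (y - F @ mean)
        P = P - np.outer(K, F @ P)
    return float(ll), mean, P


class TestFilterLoglik:
    def _linear_setup(self):
        a, b = 30.0, 0.1
        params = ParameterSet(
            mu=0.5, delay_mean=1.0, delay_sd=0.4, tau_max=3.0,
            kappa=0.02, sigma_eps=0.05, init_rate=25.0, mu0=0.5, beta=1.0,
        )
        rng = np.random.default_rng(12)
        times = (np.arange(30) + 1) * 0.5
        values = 0.5 + 0.1 * np.sin(times) + rng.normal(0, 0.05, 30)
        series = ObservedSeries(times=times, values=values, exposure=0.5)
        coeffs = lambda x, u: (a - b * u - 0.5 * x, -0.5, -b,
                               a - b * u + 0.5 * x)
        return series, params, a, b, coeffs

    def test_linear_model_matches_stacked_kalman_oracle(self):
        series, params, a, b, coeffs = self._linear_setup()
        res = filter_loglik(series, params, dt=0.1, coeffs=coeffs)
        ll_oracle, mean_o, P_o = _linear_filter_oracle(series, params, a, b, 0.1)
        assert res.loglik == pytest.approx(ll_oracle, rel=1e-6)
        assert np.allclose(res.window.mean[:, 0], mean_o, rtol=1e-8)
        assert np.allclose(res.window.cov, P_o, rtol=1e-6, atol=1e-12)

    def test_smoothing_never_exceeds_predictive_variance(
        self, series_one, params_true
    ):
        params = true_params_for(series_one, params_true)
        res = filter_loglik(series_one, params, dt=0.25)
        assert np.all(
            res.smooth_var_signal <= res.pred_var_signal * (1 + 1e-9)
        )

    def test_window_cov_symmetric_psd_throughout(self, series_one, params_true):
        params = true_params_for(series_one, params_true)
        res = filter_loglik(series_one, params, dt=0.5)
        C = res.window.cov
        assert np.allclose(C, C.T, atol=1e-10)
        evals = np.linalg.eigvalsh(C)
        assert evals.min() > -1e-8 * max(1.0, evals.max())
        assert np.all(res.pred_var_signal > 0)
        assert np.all(res.state_var >= 0)

    def test_requires_span_beyond_max_delay(self, params_true):
        short = ObservedSeries(
            times=(np.arange(30) + 1) * 0.5,
            values=np.ones(30),
            exposure=0.5,
        )
        with pytest.raises(ValueError, match="span"):
            filter_loglik(short, params_true, dt=0.5)

    def test_mismatched_dt_rejected(self, series_one, params_true):
        with pytest.raises(ValueError, match="divide"):
            filter_loglik(series_one, params_true, dt=0.3)


class TestInitWindow:
    def test_uninformative_observations_give_prior_lna_moments(self):
        params = ParameterSet(sigma_eps=1e6, kappa=1.0, beta=2.0,
                              init_rate=40.0, mu0=0.5)
        n_head = int(round(params.tau_max / 0.5))
        rng = np.random.default_rng(9)
        head = ObservedSeries(
            times=(np.arange(n_head) + 1) * 0.5,
            values=40.0 + rng.normal(0, 1, n_head),
            exposure=0.5,
        )
        init = init_window(head, params, dt=0.5)
        x0 = head.values[0] / (params.kappa * 0.5)
        from dlnafilter import birth_death_network

        ref = lna_propagate(
            GaussianState(mean=[x0], cov=[[params.beta * x0]]),
            birth_death_network(params.init_rate, params.mu0),
            0.0, params.tau_max, 0.5,
        )
        m, P = init.window.current_state()
        assert m[0] == pytest.approx(ref.mean[0], rel=1e-6)
        assert P[0, 0] == pytest.approx(ref.cov[0, 0], rel=1e-6)

    def test_head_must_cover_max_delay(self, params_true):
        head = ObservedSeries(
            times=(np.arange(10) + 1) * 0.5, values=np.ones(10), exposure=0.5
        )
        with pytest.raises(ValueError, match="head"):
            init_window(head, params_true, dt=0.5)


def test_cost_grows_superlinearly_in_window_length(params_true):
    """Dense window covariance: per-step cost ~ quadratic in lattice size."""
    net = ttfl_network(params_true)

    def best_time(M, reps=5):
        w = _window(M, dt=0.1)
        times = []
        for _ in range(reps):
            t0 = time.perf_counter()
            for _ in range(20):
                w2 = propagate_window(w, net, 0.1)
            times.append(time.perf_counter() - t0)
        return min(times)

    t_small, t_big = best_time(100), best_time(800)
    # linear scaling would give a ratio of ~8 for the 8x larger window;
    # the dense-covariance update must be above that
    assert t_big / t_small > 9.0
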