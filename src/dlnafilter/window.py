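"""LNA filtering for systems with distributed delays.

A hazard that depends on a kernel-weighted integral of the past breaks the
Markov property of the current state, but the process *restricted to the
window* ``[t - tau_m, t]`` is Markov.  The filter therefore tracks a joint
Gaussian summary — mean vector and full covariance matrix — of the latent
state over a sliding lattice of ``m + 1 = tau_m/dt + 1`` time points.

One Euler step linearizes the delayed chemical Langevin equation: plain
hazards are expanded about the current mean and delayed hazards about the
kernel-weighted mean integral, so the window vector evolves under an
affine-Gaussian map and its joint covariance (including cross-covariances
between the new point and every retained lag) propagates in closed form.
Each observation then conditions the *entire* window via a Kalman step
whose gain involves the cross-covariance between the window and the
current state.  Moments recorded when a lattice point finally leaves the
window form a 'partial' smoothing density: each past state is conditioned
on all observations received while it was still inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    DelayedReactionNetwork,
    ParameterSet,
    ttfl_network,
)
from .simulate import ObservedSeries

__all__ = [
    "WindowState",
    "WindowMeasurement",
    "FilterResult",
    "propagate_window",
    "delayed_kalman_update",
    "init_window",
    "filter_loglik",
    "window_obs_row",
]

COV_FLOOR = 1e-10
INNOV_FLOOR_FACTOR = 1e-12


@dataclass
class WindowState:
    """Joint Gaussian over the latent states on the window lattice.

    ``mean`` has shape (M, p) with the newest time in the last row;
    ``cov`` is the full (M*p) x (M*p) covariance in the same (time-major)
    ordering; ``grid_times`` is the lattice ending at the current time.
    """

    grid_times: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    p: int = 1

    def __post_init__(self) -> None:
        self.grid_times = np.atleast_1d(np.asarray(self.grid_times, dtype=float))
        self.mean = np.asarray(self.mean, dtype=float).reshape(
            self.grid_times.size, self.p
        )
        n = self.grid_times.size * self.p
        self.cov = np.asarray(self.cov, dtype=float).reshape(n, n)
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def n_points(self) -> int:
        return self.grid_times.size

    @property
    def t(self) -> float:
        return float(self.grid_times[-1])

    @property
    def dt(self) -> float:
        if self.grid_times.size < 2:
            raise ValueError("window has a single lattice point")
        return float(self.grid_times[1] - self.grid_times[0])

    def current_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Marginal mean and covariance of the newest lattice point."""
        q = (self.n_points - 1) * self.p
        return self.mean[-1].copy(), self.cov[q:, q:].copy()


@dataclass
class WindowMeasurement:
    """Scalar observation acting linearly on the window vector."""

    obs_row: np.ndarray
    noise_var: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        self.obs_row = np.asarray(self.obs_row, dtype=float).ravel()
        if self.noise_var < 0:
            raise ValueError("noise_var must be non-negative")


def window_obs_row(
    n_points: int,
    n_sub: int,
    kappa: float,
    dt: float,
    p: int = 1,
    species: int = 0,
    scheme: str = "trapezoid",
) -> np.ndarray:
    """Row vector implementing ``y = kappa * integral_{t-Delta}^{t} X ds``.

    The integral over the trailing exposure interval (``n_sub`` lattice
    steps) is discretized with trapezoid weights by default, or a right
    Riemann sum (``scheme="riemann"``).
    """
    if n_points < n_sub + 1:
        raise ValueError("window too short for the exposure interval")
    if scheme == "trapezoid":
        coeffs = np.ones(n_sub + 1)
        coeffs[0] = coeffs[-1] = 0.5
    elif scheme == "riemann":
        coeffs = np.ones(n_sub + 1)
        coeffs[0] = 0.0
    else:
        raise ValueError(f"unknown quadrature scheme {scheme!r}")
    row = np.zeros((n_points, p))
    row[n_points - 1 - n_sub :, species] = kappa * dt * coeffs
    return row.ravel()


def _exposure_weights(
    n_sub: int, kappa: float, dt: float, scheme: str
) -> np.ndarray:
    """Non-zero tail of the observation row (n_sub + 1 entries)."""
    coeffs = np.ones(n_sub + 1)
    if scheme == "trapezoid":
        coeffs[0] = coeffs[-1] = 0.5
    elif scheme == "riemann":
        coeffs[0] = 0.0
    else:
        raise ValueError(f"unknown quadrature scheme {scheme!r}")
    return kappa * dt * coeffs


_LOG_2PI = float(np.log(2.0 * np.pi))


def _norm_logpdf(y: float, mean: float, var: float) -> float:
    return -0.5 * (_LOG_2PI + np.log(var) + (y - mean) ** 2 / var)


# --------------------------------------------------------------------------
# Core moment step
# --------------------------------------------------------------------------

def _kernel_matrix(net: DelayedReactionNetwork, n_points: int, dt: float) -> np.ndarray:
    """Per-species kernel weights aligned with the window ordering.

    Entry (i, s) weights window point i (lag (n_points-1-i)*dt) in the
    delayed integral for species s.
    """
    p = net.n_species
    Kw = np.zeros((n_points, p))
    for s, kern in enumerate(net.kernels):
        w = kern.discretize(dt).weights
        k = min(len(w), n_points)
        # lag j maps to window index n_points-1-j
        Kw[n_points - k :, s] = w[:k][::-1]
    return Kw


def _step_moments(
    mean: np.ndarray,
    cov: np.ndarray,
    net: DelayedReactionNetwork,
    Kw: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One linearized Euler step; returns (new_mean_point, cross, var_new).

    ``cross`` is the (p, M*p) covariance between the new point and the
    current window; ``var_new`` the (p, p) marginal of the new point.
    """
    M, p = mean.shape
    x = mean[-1]
    u = (Kw * mean).sum(axis=0)
    g = net.drift_plain(x)
    f = net.drift_delayed(u)
    Jg = net.jac_plain(x)
    Jf = net.jac_delayed(u)
    A = net.diffusion(x, u)

    # affine map: X_new = x_new_mean + T (X_window - mean_window) + noise
    T = dt * (Jf[:, None, :] * Kw[None, :, :])  # (p, M, p)
    T[:, M - 1, :] += np.eye(p) + dt * Jg
    T = T.reshape(p, M * p)

    new_mean = x + (g + f) * dt
    cross = T @ cov
    var_new = cross @ T.T + A * dt
    var_new = 0.5 * (var_new + var_new.T)
    return new_mean, cross, var_new


def _advance_raw(
    mean: np.ndarray,
    cov: np.ndarray,
    net: DelayedReactionNetwork,
    Kw: np.ndarray,
    dt: float,
    t_new: float,
    grow: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One lattice step on raw (mean, cov) arrays; blocks are assembled
    symmetric by construction so no full re-symmetrization is needed."""
    M, p = mean.shape
    new_mean, cross, var_new = _step_moments(mean, cov, net, Kw, dt)
    if not (np.all(np.isfinite(new_mean)) and np.all(np.isfinite(var_new))):
        raise FloatingPointError(f"non-finite window moments at t={t_new:.4f}")
    np.fill_diagonal(var_new, np.maximum(np.diag(var_new), 0.0))
    if grow:
        n = (M + 1) * p
        cov2 = np.empty((n, n))
        cov2[: M * p, : M * p] = cov
        cov2[M * p :, : M * p] = cross
        cov2[: M * p, M * p :] = cross.T
        cov2[M * p :, M * p :] = var_new
        mean2 = np.vstack([mean, new_mean[None, :]])
    else:
        n = M * p
        q = (M - 1) * p
        cov2 = np.empty((n, n))
        cov2[:q, :q] = cov[p:, p:]
        cov2[q:, :q] = cross[:, p:]
        cov2[:q, q:] = cross[:, p:].T
        cov2[q:, q:] = var_new
        mean2 = np.vstack([mean[1:], new_mean[None, :]])
    return mean2, cov2


# --- scalar (p = 1) fast path -------------------------------------------
# filter_loglik always works with the one-species TTFL (and the linear
# birth--death model on the initialization window), so the per-step
# coefficients are computed in plain scalar arithmetic; equivalence with
# the generic network machinery is asserted in the test suite.

def _ttfl_coeffs(params: ParameterSet):
    """Returns f(x, u) -> (drift, J_g, J_f, diffusion) for the TTFL."""
    r_max, k_pc, n, mu = params.r_max, params.k_pc, params.n, params.mu

    def coeffs(x: float, u: float):
        uc = u if u > 0.0 else 0.0
        ratio = (uc / k_pc) ** n
        nu = r_max / (1.0 + ratio)
        if uc > 0.0:
            jf = -n * ratio * r_max / (uc * (1.0 + ratio) ** 2)
        else:
            jf = 0.0
        death = mu * x if x > 0.0 else 0.0
        return nu - mu * x, -mu, jf, nu + death

    return coeffs


def _bd_coeffs(birth: float, death_rate: float):
    def coeffs(x: float, u: float):
        death = death_rate * x if x > 0.0 else 0.0
        return birth - death_rate * x, -death_rate, 0.0, birth + death

    return coeffs


def _advance_scalar(
    mean: np.ndarray,
    cov: np.ndarray,
    coeffs,
    Kw: np.ndarray,
    dt: float,
    t_new: float,
    grow: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One lattice step for a single-species model on (M,) / (M, M) arrays."""
    M = mean.shape[0]
    x = mean[-1]
    u = Kw @ mean
    drift, jg, jf, diff = coeffs(x, u)
    b = (dt * jf) * Kw
    b[-1] += 1.0 + dt * jg
    new_mean = x + drift * dt
    cross = b @ cov
    var_new = float(cross @ b) + diff * dt
    if not (np.isfinite(new_mean) and np.isfinite(var_new)):
        raise FloatingPointError(f"non-finite window moments at t={t_new:.4f}")
    if var_new < 0.0:
        var_new = 0.0
    if grow:
        cov2 = np.empty((M + 1, M + 1))
        cov2[:M, :M] = cov
        cov2[M, :M] = cross
        cov2[:M, M] = cross
        cov2[M, M] = var_new
        mean2 = np.append(mean, new_mean)
    else:
        cov2 = np.empty((M, M))
        cov2[: M - 1, : M - 1] = cov[1:, 1:]
        cov2[M - 1, : M - 1] = cross[1:]
        cov2[: M - 1, M - 1] = cross[1:]
        cov2[M - 1, M - 1] = var_new
        mean2 = np.empty(M)
        mean2[: M - 1] = mean[1:]
        mean2[M - 1] = new_mean
    return mean2, cov2


def _update_scalar(
    mean: np.ndarray,
    cov: np.ndarray,
    f_tail: np.ndarray,
    nz0: int,
    noise_var: float,
    y: float,
    t: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Kalman step for a single-species model; F is zero before nz0."""
    PFt = cov[:, nz0:] @ f_tail
    S = float(f_tail @ PFt[nz0:]) + noise_var
    if S <= max(noise_var * INNOV_FLOOR_FACTOR, 0.0):
        raise ValueError(f"non-positive innovation variance ({S}) at t={t:.4f}")
    pred_mean = float(f_tail @ mean[nz0:])
    C = PFt / S
    mean2 = mean + C * (y - pred_mean)
    cov2 = cov - np.outer(C, PFt)
    d = np.diag(cov2)
    if np.any(d < 0):
        np.fill_diagonal(cov2, np.maximum(d, 0.0))
    return mean2, cov2, pred_mean, S


try:  # compiled kernel for the inference-critical TTFL path
    from numba import njit

    @njit(cache=False)
    def _main_loop_ttfl(
        mean, cov, Kw, f_tail, nz0, ys, n_sub, dt,
        r_max, k_pc, n_hill, mu, noise_var,
    ):  # pragma: no cover - exercised via filter_loglik
        M = mean.shape[0]
        n_obs = ys.size
        n_tail = f_tail.size
        pred_mean = np.empty(n_obs)
        pred_var = np.empty(n_obs)
        b = np.empty(M)
        cross = np.empty(M)
        PFt = np.empty(M)
        ll = 0.0
        log2pi = np.log(2.0 * np.pi)
        for i in range(n_obs):
            for _ in range(n_sub):
                x = mean[M - 1]
                u = 0.0
                for j in range(M):
                    u += Kw[j] * mean[j]
                if u < 0.0:
                    u = 0.0
                if u > 0.0:
                    ratio = (u / k_pc) ** n_hill
                    nu = r_max / (1.0 + ratio)
                    jf = -n_hill * ratio * r_max / (u * (1.0 + ratio) ** 2)
                else:
                    nu = r_max
                    jf = 0.0
                death = mu * x if x > 0.0 else 0.0
                drift = nu - mu * x
                diff = nu + death
                for j in range(M):
                    b[j] = dt * jf * Kw[j]
                b[M - 1] += 1.0 - mu * dt
                for r in range(M):
                    acc = 0.0
                    for c in range(M):
                        acc += cov[r, c] * b[c]
                    cross[r] = acc
                var_new = diff * dt
                for j in range(M):
                    var_new += b[j] * cross[j]
                if var_new < 0.0:
                    var_new = 0.0
                new_mean = x + drift * dt
                if not (np.isfinite(new_mean) and np.isfinite(var_new)):
                    return np.nan, pred_mean, pred_var
                for r in range(M - 1):
                    mean[r] = mean[r + 1]
                mean[M - 1] = new_mean
                for r in range(M - 1):
                    for c in range(M - 1):
                        cov[r, c] = cov[r + 1, c + 1]
                for r in range(M - 1):
                    cov[r, M - 1] = cross[r + 1]
                    cov[M - 1, r] = cross[r + 1]
                cov[M - 1, M - 1] = var_new
            # window-wide Kalman update for the integrated-light row
            for r in range(M):
                acc = 0.0
                for k in range(n_tail):
                    acc += cov[r, nz0 + k] * f_tail[k]
                PFt[r] = acc
            S = noise_var
            pred = 0.0
            for k in range(n_tail):
                S += f_tail[k] * PFt[nz0 + k]
                pred += f_tail[k] * mean[nz0 + k]
            if S <= 0.0:
                return np.nan, pred_mean, pred_var
            innov = ys[i] - pred
            ll += -0.5 * (log2pi + np.log(S) + innov * innov / S)
            pred_mean[i] = pred
            pred_var[i] = S
            for r in range(M):
                cr = PFt[r] / S
                mean[r] += cr * innov
                for c in range(M):
                    cov[r, c] -= cr * PFt[c]
            for r in range(M):
                if cov[r, r] < 0.0:
                    cov[r, r] = 0.0
        return ll, pred_mean, pred_var

    @njit(cache=False)
    def _init_loop_bd(
        x0, var0, ys, n_sub, m, dt, nu0, mu0, f_tail, noise_var
    ):  # pragma: no cover - exercised via init_window
        M = m + 1
        mean = np.zeros(M)
        cov = np.zeros((M, M))
        mean[0] = x0
        cov[0, 0] = var0
        n_head = ys.size
        n_tail = f_tail.size
        pred_mean = np.empty(n_head)
        pred_var = np.empty(n_head)
        ll = 0.0
        log2pi = np.log(2.0 * np.pi)
        obs_idx = 0
        a = 1.0 - mu0 * dt
        for k in range(1, M):
            x = mean[k - 1]
            death = mu0 * x if x > 0.0 else 0.0
            for j in range(k):
                c = a * cov[k - 1, j]
                cov[k, j] = c
                cov[j, k] = c
            var_new = a * a * cov[k - 1, k - 1] + (nu0 + death) * dt
            cov[k, k] = var_new if var_new > 0.0 else 0.0
            mean[k] = x + (nu0 - mu0 * x) * dt
            if k % n_sub == 0:
                nz0 = k - n_sub
                S = noise_var
                pred = 0.0
                PFt = np.zeros(k + 1)
                for r in range(k + 1):
                    acc = 0.0
                    for t in range(n_tail):
                        acc += cov[r, nz0 + t] * f_tail[t]
                    PFt[r] = acc
                for t in range(n_tail):
                    S += f_tail[t] * PFt[nz0 + t]
                    pred += f_tail[t] * mean[nz0 + t]
                if S <= 0.0:
                    ll = np.nan
                    break
                innov = ys[obs_idx] - pred
                ll += -0.5 * (log2pi + np.log(S) + innov * innov / S)
                pred_mean[obs_idx] = pred
                pred_var[obs_idx] = S
                for r in range(k + 1):
                    cr = PFt[r] / S
                    mean[r] += cr * innov
                    for cc in range(k + 1):
                        cov[r, cc] -= cr * PFt[cc]
                for r in range(k + 1):
                    if cov[r, r] < 0.0:
                        cov[r, r] = 0.0
                obs_idx += 1
        return mean, cov, ll, pred_mean, pred_var

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _advance(
    w: WindowState, net: DelayedReactionNetwork, Kw: np.ndarray, dt: float,
    grow: bool = False,
) -> WindowState:
    mean2, cov2 = _advance_raw(
        w.mean, w.cov, net, Kw, dt, w.t + dt, grow=grow
    )
    if grow:
        times2 = np.append(w.grid_times, w.t + dt)
    else:
        times2 = w.grid_times + dt
    return WindowState(grid_times=times2, mean=mean2, cov=cov2, p=w.p)


def propagate_window(
    w: WindowState, net: DelayedReactionNetwork, dt: float
) -> WindowState:
    """Advance the window by one lattice step.

    The oldest lattice point is dropped and the new state appended, with
    its cross-covariances against every retained lag computed from the
    linearized delayed dynamics.  ``dt`` must equal the window grid step.
    """
    if abs(dt - w.dt) > 1e-9:
        raise ValueError(f"dt={dt} does not match window grid step {w.dt}")
    Kw = _kernel_matrix(net, w.n_points, dt)
    return _advance(w, net, Kw, dt, grow=False)


def delayed_kalman_update(
    w: WindowState, m: WindowMeasurement, y: float
) -> WindowState:
    """Condition the whole window on a scalar observation.

    The coefficient of adaptation ``C = P F' / (F P F' + sigma_eps^2)``
    is a full window-length vector, so every lattice point — the entire
    past up to ``t - tau_m`` — is revised by the observation at ``t``.
    """
    new, _, _ = _update_window(w, m.obs_row, m.noise_var, y)
    return new


def _update_raw(
    mean: np.ndarray,
    cov: np.ndarray,
    F: np.ndarray,
    noise_var: float,
    y: float,
    t: float,
    nz0: int = 0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Kalman step on raw arrays; returns (mean2, cov2, pred_mean, S).

    ``nz0`` is the index of the first non-zero entry of ``F`` (the
    observation row touches only the trailing exposure block, so the gain
    vector costs O(M * n_sub) instead of O(M^2)).
    """
    mean_flat = mean.reshape(-1)
    f_tail = F[nz0:]
    PFt = cov[:, nz0:] @ f_tail
    S = float(f_tail @ PFt[nz0:]) + noise_var
    floor = noise_var * INNOV_FLOOR_FACTOR
    if S <= max(floor, 0.0):
        raise ValueError(f"non-positive innovation variance ({S}) at t={t:.4f}")
    pred_mean = float(f_tail @ mean_flat[nz0:])
    C = PFt / S
    mean2 = (mean_flat + C * (y - pred_mean)).reshape(mean.shape)
    # outer(C, PFt) = outer(PFt, PFt)/S is exactly symmetric, so the
    # difference stays symmetric without an explicit re-symmetrization
    cov2 = cov - np.outer(C, PFt)
    d = np.diag(cov2)
    if np.any(d < 0):
        np.fill_diagonal(cov2, np.maximum(d, 0.0))
    return mean2, cov2, pred_mean, S


def _update_window(
    w: WindowState, F: np.ndarray, noise_var: float, y: float
) -> tuple[WindowState, float, float]:
    nz = np.nonzero(F)[0]
    nz0 = int(nz[0]) if nz.size else 0
    mean2, cov2, pred_mean, S = _update_raw(
        w.mean, w.cov, F, noise_var, y, w.t, nz0=nz0
    )
    new = WindowState(
        grid_times=w.grid_times.copy(), mean=mean2, cov=cov2, p=w.p
    )
    return new, pred_mean, S


# --------------------------------------------------------------------------
# Initialization over [0, tau_m]
# --------------------------------------------------------------------------

@dataclass
class InitResult:
    """Window state at tau_m plus the head observations' contribution."""

    window: WindowState
    loglik: float
    obs_times: np.ndarray
    pred_mean: np.ndarray
    pred_var_signal: np.ndarray
    pending: dict = field(default_factory=dict)


def init_window(
    series_head: ObservedSeries,
    params: ParameterSet,
    dt: float,
    obs_scheme: str = "trapezoid",
) -> InitResult:
    """Build the joint window Gaussian over the first ``[0, tau_max]``.

    Past mRNA levels are unknown over the initialization window, so the
    dynamics there are modelled as a linear birth--death process with
    constant transcription ``init_rate`` and degradation ``mu0``.  The
    state at time zero has prior mean taken from the first observation
    de-scaled by ``kappa * exposure`` and variance ``beta`` times that mean
    (or ``var_x0`` when given).  The window is grown one lattice point at a
    time, assimilating each head observation and accumulating its
    likelihood contribution, so the full joint covariance at ``tau_max`` is
    available for the delayed filter.
    """
    exposure = series_head.exposure
    tau_m = params.tau_max
    n_sub = _ratio(exposure, dt, "exposure", "dt")
    m = _ratio(tau_m, dt, "tau_max", "dt")
    n_head = _ratio(tau_m, exposure, "tau_max", "exposure")
    if len(series_head) != n_head:
        raise ValueError(
            f"initialization head must contain exactly {n_head} observations "
            f"covering (0, {tau_m}], got {len(series_head)}"
        )
    t_origin = series_head.times[0] - exposure

    x0 = max(series_head.values[0] / (params.kappa * exposure), 1e-6)
    var0 = params.var_x0 if params.var_x0 is not None else params.beta * x0
    mean = np.array([x0])
    cov = np.array([[var0]])
    coeffs0 = _bd_coeffs(params.init_rate, params.mu0)
    f_tail = _exposure_weights(n_sub, params.kappa, dt, obs_scheme)
    noise_var = params.sigma_eps**2

    pending = {i: (i + 1) * n_sub - n_sub for i in range(n_head)}
    if _HAVE_NUMBA:
        ys = np.ascontiguousarray(series_head.values, dtype=float)
        mean, cov, loglik, pred_mean, pred_var = _init_loop_bd(
            x0, var0, ys, n_sub, m, dt,
            params.init_rate, params.mu0, f_tail, noise_var,
        )
        if not np.isfinite(loglik):
            raise FloatingPointError(
                "non-finite moments in the initialization window"
            )
        pred_var_signal = pred_var - noise_var
    else:
        loglik = 0.0
        pred_mean = np.empty(n_head)
        pred_var_signal = np.empty(n_head)
        obs_idx = 0
        for k in range(1, m + 1):
            Kw = np.zeros(k)
            Kw[-1] = 1.0  # point-mass kernel: u = current state
            mean, cov = _advance_scalar(
                mean, cov, coeffs0, Kw, dt, t_origin + k * dt, grow=True
            )
            if k % n_sub == 0:
                y = float(series_head.values[obs_idx])
                mean, cov, mu_pred, S = _update_scalar(
                    mean, cov, f_tail, k - n_sub, noise_var, y,
                    t_origin + k * dt,
                )
                loglik += _norm_logpdf(y, mu_pred, S)
                pred_mean[obs_idx] = mu_pred
                pred_var_signal[obs_idx] = S - noise_var
                obs_idx += 1
    w = WindowState(
        grid_times=t_origin + np.arange(m + 1) * dt, mean=mean, cov=cov, p=1
    )
    return InitResult(
        window=w,
        loglik=loglik,
        obs_times=series_head.times.copy(),
        pred_mean=pred_mean,
        pred_var_signal=pred_var_signal,
        pending=pending,
    )


def _ratio(big: float, small: float, big_name: str, small_name: str) -> int:
    r = big / small
    if abs(r - round(r)) > 1e-6:
        raise ValueError(f"{small_name}={small} must divide {big_name}={big}")
    return int(round(r))


# --------------------------------------------------------------------------
# Full filter pass
# --------------------------------------------------------------------------

@dataclass
class FilterResult:
    """Output of one delayed-LNA filter pass.

    Predictive moments are for the *observation scale*: ``pred_mean`` is
    ``F rho`` (the one-step predicted integrated light), ``pred_var_signal``
    is ``F P F'`` (no measurement noise) and ``pred_var_obs`` adds
    ``sigma_eps^2``.  ``smooth_*`` are the partial-smoothing analogues per
    observation; ``state_*`` the per-lattice-point latent moments at the
    last time each point was inside the window.
    """

    loglik: float
    head_loglik: float
    obs_times: np.ndarray
    pred_mean: np.ndarray
    pred_var_signal: np.ndarray
    pred_var_obs: np.ndarray
    smooth_mean: np.ndarray
    smooth_var_signal: np.ndarray
    state_times: np.ndarray
    state_mean: np.ndarray
    state_var: np.ndarray
    window: WindowState
    n_head: int
    sigma_eps: float


def filter_loglik(
    series: ObservedSeries,
    params: ParameterSet,
    dt: float = 0.1,
    obs_scheme: str = "trapezoid",
    smoothing: bool = True,
    include_head: bool = True,
    coeffs=None,
) -> FilterResult:
    """Delayed-LNA filter pass with marginal likelihood.

    Initializes the window over the first ``tau_max`` hours of
    observations, then alternates linearized delayed propagation with
    window-wide Kalman updates at each observation time, accumulating the
    Gaussian innovation log-density ``N(y; F rho, F P F' + sigma_eps^2)``.
    With ``smoothing=True`` the partial-smoothing moments (per lattice
    point and per observation bin) are recorded as each quantity leaves the
    sliding window.

    ``include_head`` controls whether the initialization-window
    observations contribute to ``loglik``.  The head is always assimilated
    to build the window state, but its likelihood comes from the
    instrumental step-transcription model, which is misspecified for an
    oscillating head segment; inference excludes it (the head is
    instrumental to obtaining the first window moments), while the
    filtering API reports the full likelihood by default.  The head
    contribution is always available separately as ``head_loglik``.

    ``coeffs`` (advanced) replaces the TTFL step law after the
    initialization window: a callable ``(x, u) -> (drift, J_g, J_f,
    diffusion)`` for the current state ``x`` and delayed integral ``u``;
    the delay kernel is still taken from ``params``.
    """
    exposure = series.exposure
    n_sub = _ratio(exposure, dt, "exposure", "dt")
    n_head = _ratio(params.tau_max, exposure, "tau_max", "exposure")
    n_obs = len(series)
    if n_obs <= n_head:
        raise ValueError(
            f"series must span more than tau_max={params.tau_max} h "
            f"(need > {n_head} observations, got {n_obs})"
        )

    head = ObservedSeries(
        times=series.times[:n_head],
        values=series.values[:n_head],
        exposure=exposure,
    )
    init = init_window(head, params, dt, obs_scheme=obs_scheme)
    w = init.window
    M = w.n_points
    mean, cov = w.mean.reshape(-1).copy(), w.cov
    t_cur = w.t
    net = ttfl_network(params)
    Kw = np.ascontiguousarray(_kernel_matrix(net, M, dt)[:, 0])
    default_model = coeffs is None
    if coeffs is None:
        coeffs = _ttfl_coeffs(params)
    f_tail = _exposure_weights(n_sub, params.kappa, dt, obs_scheme)
    nz0 = M - 1 - n_sub
    noise_var = params.sigma_eps**2

    if default_model and not smoothing and _HAVE_NUMBA:
        # compiled fast path used by MCMC: same recursion, no smoothing
        ys = np.ascontiguousarray(series.values[n_head:], dtype=float)
        ll_main, pm, pv = _main_loop_ttfl(
            mean, cov, Kw, f_tail, nz0, ys, n_sub, dt,
            params.r_max, params.k_pc, params.n, params.mu, noise_var,
        )
        if not np.isfinite(ll_main):
            raise FloatingPointError(
                "non-finite window moments during the filter pass"
            )
        loglik = init.loglik + ll_main
        pred_mean = np.empty(n_obs)
        pred_var_signal = np.empty(n_obs)
        pred_mean[:n_head] = init.pred_mean
        pred_var_signal[:n_head] = init.pred_var_signal
        pred_mean[n_head:] = pm
        pred_var_signal[n_head:] = pv - noise_var
        t_end = t_cur + (n_obs - n_head) * exposure
        w = WindowState(
            grid_times=t_end - (M - 1 - np.arange(M)) * dt,
            mean=mean, cov=cov, p=1,
        )
        nan = np.full(n_obs, np.nan)
        return FilterResult(
            loglik=(
                float(loglik) if include_head
                else float(loglik - init.loglik)
            ),
            head_loglik=float(init.loglik),
            obs_times=series.times.copy(),
            pred_mean=pred_mean,
            pred_var_signal=pred_var_signal,
            pred_var_obs=pred_var_signal + noise_var,
            smooth_mean=nan,
            smooth_var_signal=nan.copy(),
            state_times=np.empty(0),
            state_mean=np.empty(0),
            state_var=np.empty(0),
            window=w,
            n_head=n_head,
            sigma_eps=params.sigma_eps,
        )

    loglik = init.loglik
    pred_mean = np.empty(n_obs)
    pred_var_signal = np.empty(n_obs)
    pred_mean[:n_head] = init.pred_mean
    pred_var_signal[:n_head] = init.pred_var_signal
    smooth_mean = np.full(n_obs, np.nan)
    smooth_var_signal = np.full(n_obs, np.nan)
    pending = dict(init.pending) if smoothing else {}
    state_times: list[float] = []
    state_mean: list[float] = []
    state_var: list[float] = []

    for i in range(n_head, n_obs):
        if smoothing:
            # observations whose exposure block loses lattice points during
            # the coming shifts have reached their final (partial-smoothing)
            # moments now; the rest shift down by n_sub positions
            for obs_i in [k for k, s in pending.items() if s < n_sub]:
                _record_smoothed(
                    mean, cov, pending.pop(obs_i), n_sub, params, dt,
                    obs_scheme, obs_i, smooth_mean, smooth_var_signal,
                )
            for k in pending:
                pending[k] -= n_sub
        for _ in range(n_sub):
            if smoothing:
                state_times.append(t_cur - (M - 1) * dt)
                state_mean.append(float(mean[0]))
                state_var.append(float(cov[0, 0]))
            t_cur += dt
            mean, cov = _advance_scalar(mean, cov, coeffs, Kw, dt, t_cur)
        y = float(series.values[i])
        mean, cov, mu_pred, S = _update_scalar(
            mean, cov, f_tail, nz0, noise_var, y, t_cur
        )
        loglik += _norm_logpdf(y, mu_pred, S)
        pred_mean[i] = mu_pred
        pred_var_signal[i] = S - noise_var
        if smoothing:
            pending[i] = M - 1 - n_sub

    w = WindowState(
        grid_times=t_cur - (M - 1 - np.arange(M)) * dt, mean=mean, cov=cov, p=1
    )
    if smoothing:
        for obs_i, start in pending.items():
            _record_smoothed(
                mean, cov, start, n_sub, params, dt, obs_scheme, obs_i,
                smooth_mean, smooth_var_signal,
            )
        for j in range(M):
            state_times.append(float(w.grid_times[j]))
            state_mean.append(float(mean[j]))
            state_var.append(float(cov[j, j]))

    return FilterResult(
        loglik=float(loglik) if include_head else float(loglik - init.loglik),
        head_loglik=float(init.loglik),
        obs_times=series.times.copy(),
        pred_mean=pred_mean,
        pred_var_signal=pred_var_signal,
        pred_var_obs=pred_var_signal + noise_var,
        smooth_mean=smooth_mean,
        smooth_var_signal=smooth_var_signal,
        state_times=np.asarray(state_times),
        state_mean=np.asarray(state_mean),
        state_var=np.asarray(state_var),
        window=w,
        n_head=n_head,
        sigma_eps=params.sigma_eps,
    )


def _record_smoothed(
    mean: np.ndarray,
    cov: np.ndarray,
    start: int,
    n_sub: int,
    params: ParameterSet,
    dt: float,
    obs_scheme: str,
    obs_i: int,
    smooth_mean: np.ndarray,
    smooth_var: np.ndarray,
) -> None:
    """Final moments of one observation's integrated-signal functional."""
    if start < 0:
        return
    if obs_scheme == "trapezoid":
        coeffs = np.ones(n_sub + 1)
        coeffs[0] = coeffs[-1] = 0.5
    else:
        coeffs = np.ones(n_sub + 1)
        coeffs[0] = 0.0
    row = params.kappa * dt * coeffs
    sl = slice(start, start + n_sub + 1)
    smooth_mean[obs_i] = float(row @ mean.reshape(-1)[sl])
    smooth_var[obs_i] = float(row @ (cov[sl, sl.start : sl.stop] @ row))
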