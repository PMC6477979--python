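"""Ground-truth simulation of delayed reaction networks.

The exact process is a Markov jump process whose transcription hazard
depends on a kernel-weighted integral of the past state.  The simulator
stores the trajectory on a fine regular grid (0.01 h by default) and holds
the delayed hazards piecewise-constant over each grid step — the delayed
integral is refreshed at the start of every step and Gillespie exponential
clocks run within it, with every selected reaction applied immediately.
Non-delayed hazards are refreshed after every reaction event, so linear
sub-models (pure death, constant immigration) are simulated exactly.

The measurement emulator reproduces a bioluminescence camera: counts are
rescaled by their mean level, summed over an exposure window (0.5 h), and
corrupted with additive Gaussian noise calibrated to a signal-to-noise
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DelayedReactionNetwork, ParameterSet, deterministic_fixed_point, ttfl_network

__all__ = [
    "Trajectory",
    "ObservedSeries",
    "delayed_ssa",
    "constant_history",
    "corrupt_measurements",
    "detrend_series",
    "generate_dataset",
    "simulate_observations",
]

STORE_STEP = 0.01  # hours; trajectory storage grid


@dataclass
class Trajectory:
    """Species counts stored on a fixed fine time grid (hours)."""

    times: np.ndarray
    counts: np.ndarray  # (n_times, n_species) integers

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if self.counts.shape[0] != self.times.size:
            self.counts = self.counts.T
        if self.counts.shape[0] != self.times.size:
            raise ValueError("counts and times length mismatch")

    @property
    def store_step(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ObservedSeries:
    """Equally spaced intensity observations.

    Time stamps mark the END of each exposure bin: the value at time t is
    the integrated light over [t - exposure, t].
    """

    times: np.ndarray
    values: np.ndarray
    exposure: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values length mismatch")
        if self.times.size >= 2:
            gaps = np.diff(self.times)
            if not np.allclose(gaps, gaps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("observation times must be equally spaced")

    def __len__(self) -> int:
        return self.times.size


def constant_history(level: float, max_lag: float, n_species: int = 1,
                     store_step: float = STORE_STEP) -> Trajectory:
    """A flat history trajectory over [-max_lag, 0] at integer level."""
    n = int(round(max_lag / store_step))
    times = np.arange(-n, 1) * store_step
    counts = np.full((n + 1, n_species), int(round(level)), dtype=np.int64)
    return Trajectory(times=times, counts=counts)


def delayed_ssa(
    net: DelayedReactionNetwork,
    history: Trajectory,
    horizon: float,
    seed: int,
    store_step: float = STORE_STEP,
) -> Trajectory:
    """Simulate the delayed network forward by ``horizon`` hours.

    ``history`` must cover ``[-max_lag, 0]`` on the storage grid.  The
    returned trajectory covers ``[0, horizon]`` (the time-0 point repeats
    the last history state).
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    if history.times.size >= 2 and abs(history.store_step - store_step) > 1e-9:
        raise ValueError("history grid step differs from store_step")
    max_lag = net.max_lag
    n_lag = int(round(max_lag / store_step))
    if history.times.size < n_lag + 1:
        raise ValueError(
            f"history must cover the maximum lag {max_lag} h "
            f"({n_lag + 1} grid points, got {history.times.size})"
        )
    rng = np.random.default_rng(seed)
    p = net.n_species
    # kernel weights per species on the storage lattice, newest-lag first
    # reversed so that dot(w_rev, window_slice) = sum_j w_j X(t - j*dt)
    w_rev = np.zeros((n_lag + 1, p))
    for s, kern in enumerate(net.kernels):
        dk = kern.discretize(store_step)
        w = dk.weights
        w_rev[n_lag + 1 - len(w):, s] = w[::-1]

    n_steps = int(round(horizon / store_step))
    n_hist = history.times.size
    counts = np.zeros((n_hist + n_steps, p), dtype=np.int64)
    counts[:n_hist] = history.counts
    x = counts[n_hist - 1].astype(float).copy()

    Sd = net.stoich_delayed
    Sp = net.stoich_plain
    w_reactions = Sd.shape[1]
    S_all = np.hstack([Sd, Sp]).T  # (r, p), rows are reaction jumps

    for k in range(n_steps):
        idx_now = n_hist - 1 + k
        window = counts[idx_now - n_lag : idx_now + 1]
        u = (w_rev * window).sum(axis=0)
        hd = net.hazards_delayed_at(u)
        t_rem = store_step
        while True:
            hp = net.hazards_plain_at(x)
            haz = np.concatenate([hd, hp])
            total = haz.sum()
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if wait > t_rem:
                break
            t_rem -= wait
            j = rng.choice(haz.size, p=haz / total)
            x = x + S_all[j]
            if np.any(x < 0):
                x = np.maximum(x, 0.0)
        counts[idx_now + 1] = x.astype(np.int64)

    times = np.arange(n_steps + 1) * store_step
    return Trajectory(times=times, counts=counts[n_hist - 1 :])


def _binned_signal(traj: Trajectory, exposure: float, species: int = 0,
                   rescale: bool = True) -> tuple[np.ndarray, np.ndarray, float]:
    """Sum counts within exposure bins (end-stamped), optionally rescaling
    by the overall mean count first.  Returns (times, binned, mean_level)."""
    step = traj.store_step
    per_bin = exposure / step
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("exposure must be a multiple of the storage grid step")
    per_bin = int(round(per_bin))
    x = traj.counts[:, species].astype(float)
    mean_level = x.mean() if rescale else 1.0
    if mean_level <= 0:
        mean_level = 1.0
    x = x / mean_level
    n_bins = (x.size - 1) // per_bin
    # bin k sums samples at (k-1)*per_bin+1 .. k*per_bin (excludes t=0)
    body = x[1 : n_bins * per_bin + 1].reshape(n_bins, per_bin)
    binned = body.sum(axis=1)
    times = traj.times[0] + (np.arange(n_bins) + 1) * exposure
    return times, binned, mean_level


def corrupt_measurements(
    traj: Trajectory,
    exposure: float,
    snr: float,
    seed: int,
    rescale: bool = True,
    snr_definition: str = "sd",
) -> ObservedSeries:
    """Camera-style measurement emulation.

    Counts are divided by their overall mean level, summed over each
    exposure bin, and corrupted with i.i.d. Gaussian noise of standard
    deviation ``sd(binned signal)/snr`` (``snr_definition="sd"``, default)
    or ``mean(binned signal)/snr`` (``"mean"``).
    """
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    times, clean, mean_level = _binned_signal(traj, exposure, rescale=rescale)
    if snr_definition == "sd":
        scale = clean.std(ddof=0)
    elif snr_definition == "mean":
        scale = clean.mean()
    else:
        raise ValueError(f"unknown snr_definition {snr_definition!r}")
    sigma_eps = scale / snr
    rng = np.random.default_rng(seed)
    values = clean + rng.normal(0.0, sigma_eps, size=clean.size)
    # kappa maps molecule-hours to observed intensity: the binned value
    # approximates  (1/(step*mean)) * integral of X over the bin
    kappa_true = 1.0 / (traj.store_step * mean_level) if rescale else 1.0 / traj.store_step
    meta = {
        "seed": seed,
        "snr": snr,
        "snr_definition": snr_definition,
        "sigma_eps": float(sigma_eps),
        "kappa": float(kappa_true),
        "mean_level": float(mean_level),
        "truth": clean.copy(),
    }
    return ObservedSeries(times=times, values=values, exposure=exposure, meta=meta)


def detrend_series(
    raw: ObservedSeries, total_decay: float = 0.30, span: float = 120.0
) -> ObservedSeries:
    """Remove a linear intensity decay (luciferin consumption).

    Divides the values by ``f(t) = 1 - total_decay * t / span``; the
    default emulates a ~30% linear decrease over five days.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if not (0 <= total_decay < 1):
        raise ValueError("total_decay must lie in [0, 1)")
    f = 1.0 - total_decay * raw.times / span
    if np.any(f <= 0):
        raise ValueError("decay factor reaches zero within the series range")
    meta = dict(raw.meta)
    meta["detrended"] = {"total_decay": total_decay, "span": span}
    return ObservedSeries(
        times=raw.times.copy(),
        values=raw.values / f,
        exposure=raw.exposure,
        meta=meta,
    )


def generate_dataset(
    params: ParameterSet,
    n_rep: int,
    snr: float,
    seed: int,
    horizon: float = 120.0,
    exposure: float = 0.5,
    burn_in: float = 72.0,
    store_step: float = STORE_STEP,
) -> list[ObservedSeries]:
    """Replicated synthetic observation series from the TTFL model.

    Each replicate runs the delayed SSA from a constant history at the
    deterministic fixed point, discards ``burn_in`` hours (letting the
    intrinsic noise establish the oscillation), and converts the remaining
    ``horizon`` hours into camera observations at the given signal-to-noise
    ratio.  Per-replicate seeds are ``seed * 10000 + replicate index``.
    """
    net = ttfl_network(params)
    level = deterministic_fixed_point(params)
    history = constant_history(level, params.tau_max, store_step=store_step)
    out: list[ObservedSeries] = []
    n_burn = int(round(burn_in / store_step))
    for r in range(n_rep):
        rep_seed = seed * 10000 + r
        traj = delayed_ssa(net, history, burn_in + horizon, seed=rep_seed,
                           store_step=store_step)
        kept = Trajectory(
            times=traj.times[n_burn:] - traj.times[n_burn],
            counts=traj.counts[n_burn:],
        )
        obs = corrupt_measurements(kept, exposure, snr, seed=rep_seed + 1)
        obs.meta["params"] = params.to_dict()
        obs.meta["replicate"] = r
        obs.meta["master_seed"] = seed
        out.append(obs)
    return out


def simulate_observations(
    params: ParameterSet,
    horizon: float,
    seed: int,
    exposure: float = 0.5,
    burn_in: float = 0.0,
    history: Trajectory | None = None,
    store_step: float = STORE_STEP,
) -> ObservedSeries:
    """Observations under the model's own measurement equation.

    Unlike :func:`corrupt_measurements` (which normalizes by the realized
    mean level), this applies ``y = kappa * integral X ds + eps`` with the
    ``kappa`` and ``sigma_eps`` from ``params`` — the form used for
    posterior-predictive simulation.
    """
    net = ttfl_network(params)
    if history is None:
        level = deterministic_fixed_point(params)
        history = constant_history(level, params.tau_max, store_step=store_step)
    traj = delayed_ssa(net, history, burn_in + horizon, seed=seed,
                       store_step=store_step)
    n_burn = int(round(burn_in / store_step))
    kept = Trajectory(times=traj.times[n_burn:] - traj.times[n_burn],
                      counts=traj.counts[n_burn:])
    times, sums, _ = _binned_signal(kept, exposure, rescale=False)
    clean = params.kappa * store_step * sums
    rng = np.random.default_rng(seed + 7)
    values = clean + rng.normal(0.0, params.sigma_eps, size=clean.size)
    meta = {"seed": seed, "truth": clean, "params": params.to_dict()}
    return ObservedSeries(times=times, values=values, exposure=exposure, meta=meta)
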